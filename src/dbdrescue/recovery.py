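"""Recovery of missing DNA-binding domains for MHD-only proteins.

The rescue protocol: (1) find the nearest full-architecture homolog
(DBD + MHD) in a reference panel by protein local alignment; (2) search the
gene body plus an upstream window of genomic sequence for the missing
DBD-coding segment, by a translated local search with the neighbor's DBD
segment and by a global spliced alignment with the neighbor's full-length
protein; (3) validate candidate peptides against a position log-odds
profile of the panel's own DBD segments plus conserved-residue pattern
rules; candidates overlapping the annotated MHD are rejected. Failures are
classified (no neighbor, undefined 'N' regions, partial hits, DBD beyond
the window, insufficient conservation).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .align import (
    DEFAULT_PARAMS,
    AlignmentHit,
    ScoringParams,
    _aligner,
    evalue as _evalue,
    local_align_protein,
    translated_search,
)
from .motifs import check_validation_patterns, classify_architecture, find_zn2c6_motif
from .seq import reverse_complement, translate
from .spliced import SplicedAlignment, spliced_align
from .types import (
    C2H2,
    MHD,
    ZN2C6,
    DomainHit,
    GeneModel,
    GenomeRecord,
    ProteinRecord,
    Thresholds,
)

CANDIDATE_SLACK_AA = 6  # residues added on each side of a raw candidate
N_RUN_MIN = 10          # nt of consecutive N declaring an undefined region
FAILURE_REASONS = (
    "no_neighbor", "no_genomic_sequence", "n_region",
    "partial_hit", "too_distant", "low_similarity",
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA20_INDEX = {c: i for i, c in enumerate(_AA20)}
_NULL_SEED = 0x5EED
_NULL_SIZE = 10_000


@dataclass
class PanelEntry:
    protein: ProteinRecord
    domains: list[DomainHit]

    def interval(self, domain_type: str) -> tuple[int, int]:
        for h in self.domains:
            if h.domain_type == domain_type:
                return (h.start, h.end)
        raise KeyError(f"{self.protein.protein_id}: no {domain_type} annotation")

    def dbd_segment(self, dbd_type: str) -> ProteinRecord:
        s, e = self.interval(dbd_type)
        return ProteinRecord(
            f"{self.protein.protein_id}|dbd",
            self.protein.sequence[s:e],
            source="reference_panel",
        )


@dataclass
class ReferencePanel:
    entries: list[PanelEntry]
    dbd_type: str

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference panel is empty")

    @property
    def total_residues(self) -> int:
        return sum(len(e.protein) for e in self.entries)


def build_reference_panel(
    proteins: list[ProteinRecord],
    domain_hits: list[DomainHit],
    dbd_type: str,
) -> ReferencePanel:
    """Panel of exactly the proteins whose architecture is {dbd_type}-MHD."""
    if dbd_type not in (ZN2C6, C2H2):
        raise ValueError(f"dbd_type must be {ZN2C6} or {C2H2}")
    by_protein: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    wanted = f"{dbd_type}-MHD"
    entries = [
        PanelEntry(p, by_protein.get(p.protein_id, []))
        for p in proteins
        if classify_architecture(by_protein.get(p.protein_id, [])) == wanted
    ]
    if not entries:
        raise ValueError(f"no {wanted} proteins for the reference panel")
    return ReferencePanel(entries, dbd_type)


# ---------------------------------------------------------------------------
# profile stand-in for the Pfam domain HMM


@dataclass
class DbdProfile:
    """Ungapped position log-odds profile over the panel's DBD segments.

    Segments are anchored at their first cysteine; per-column log-odds are
    taken against a uniform background. The score of a peptide is the best
    sliding-window column sum, and its 'E-value' is the empirical
    exceedance probability under a fixed null of random background peptides
    (computed once per profile).
    """

    dbd_type: str
    columns: np.ndarray          # (length, 21): 20 residues + other/X at 0.0
    null_scores: np.ndarray      # sorted ascending

    @property
    def length(self) -> int:
        return int(self.columns.shape[0])

    def _encode(self, peptide: str) -> np.ndarray:
        return np.array([_AA20_INDEX.get(c, 20) for c in peptide], dtype=np.intp)

    def score(self, peptide: str) -> float:
        if not peptide:
            return -math.inf
        L = self.length
        enc = self._encode(peptide)
        if len(enc) < L:
            enc = np.concatenate([enc, np.full(L - len(enc), 20, dtype=np.intp)])
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        scores = self.columns[np.arange(L)[None, :], windows].sum(axis=1)
        return float(scores.max())

    def evalue(self, score: float) -> float:
        """Empirical exceedance probability of ``score`` under the null."""
        n = len(self.null_scores)
        above = n - np.searchsorted(self.null_scores, score, side="left")
        return float((1 + above) / (1 + n))


def build_profile(panel: ReferencePanel, min_segments: int = 5) -> DbdProfile:
    segments = []
    for entry in panel.entries:
        s, e = entry.interval(panel.dbd_type)
        seg = entry.protein.sequence[s:e]
        anchor = seg.find("C")
        if anchor >= 0 and len(seg) - anchor >= 10:
            segments.append(seg[anchor:])
    if len(segments) < min_segments:
        raise ValueError(
            f"need >= {min_segments} anchored DBD segments, got {len(segments)}"
        )
    L = int(np.median([len(s) for s in segments]))
    counts = np.ones((L, 20))  # +1 pseudocount
    for seg in segments:
        for i, c in enumerate(seg[:L]):
            k = _AA20_INDEX.get(c)
            if k is not None:
                counts[i, k] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    logodds = np.log2(freqs / (1.0 / 20.0))
    columns = np.zeros((L, 21))
    columns[:, :20] = logodds
    profile = DbdProfile(panel.dbd_type, columns, np.array([0.0]))
    rng = np.random.default_rng(_NULL_SEED)
    null = rng.integers(0, 20, size=(_NULL_SIZE, L + 10))
    offsets = null.shape[1] - L + 1
    best = np.full(_NULL_SIZE, -np.inf)
    cols = np.arange(L)
    for k in range(offsets):
        s = columns[cols[None, :], null[:, k : k + L]].sum(axis=1)
        np.maximum(best, s, out=best)
    profile.null_scores = np.sort(best)
    return profile


# ---------------------------------------------------------------------------
# genomic context extraction


@dataclass(frozen=True)
class GenomicContext:
    """A gene's genomic neighborhood in transcript orientation.

    ``offset`` is the number of upstream nucleotides actually available
    (less than the requested window when the gene sits near a scaffold
    edge). ``fwd_start``/``fwd_end`` delimit the region on the forward
    strand of the scaffold.
    """

    scaffold_id: str
    strand: str
    sequence: str
    offset: int
    fwd_start: int
    fwd_end: int

    def to_forward(self, span: tuple[int, int]) -> tuple[int, int]:
        a, b = span
        if self.strand == "+":
            return (self.fwd_start + a, self.fwd_start + b)
        return (self.fwd_end - b, self.fwd_end - a)

    def to_context(self, fwd_span: tuple[int, int]) -> tuple[int, int]:
        s, e = fwd_span
        if self.strand == "+":
            return (s - self.fwd_start, e - self.fwd_start)
        return (self.fwd_end - e, self.fwd_end - s)


def extract_genomic_context(
    gene: GeneModel,
    genome: GenomeRecord | dict[str, GenomeRecord],
    window: int = 1000,
) -> GenomicContext:
    """Gene span plus up to ``window`` upstream nucleotides, in transcript
    orientation ('upstream' is the 3' side in scaffold coordinates for
    minus-strand genes)."""
    scaffold = genome if isinstance(genome, GenomeRecord) else genome[gene.scaffold_id]
    if scaffold.scaffold_id != gene.scaffold_id:
        raise ValueError("scaffold/gene mismatch")
    lo, hi = gene.span
    L = len(scaffold)
    if gene.strand == "+":
        start = max(0, lo - window)
        offset = lo - start
        seq = scaffold.sequence[start:hi]
        return GenomicContext(scaffold.scaffold_id, "+", seq, offset, start, hi)
    end = min(L, hi + window)
    offset = end - hi
    seq = reverse_complement(scaffold.sequence[lo:end])
    return GenomicContext(scaffold.scaffold_id, "-", seq, offset, lo, end)


def protein_to_forward(gene: GeneModel, interval: tuple[int, int]) -> list[tuple[int, int]]:
    """Map a protein-coordinate interval to forward-strand genomic pieces
    through the gene's exon structure."""
    a, b = 3 * interval[0], 3 * interval[1]
    out = []
    t0 = 0
    for s, e in gene.exons:  # transcript order
        length = e - s
        o1, o2 = max(t0, a), min(t0 + length, b)
        if o1 < o2:
            if gene.strand == "+":
                out.append((s + (o1 - t0), s + (o2 - t0)))
            else:
                out.append((e - (o2 - t0), e - (o1 - t0)))
        t0 += length
    return out


# ---------------------------------------------------------------------------
# nearest neighbor


def find_nearest_neighbor(
    query: ProteinRecord,
    panel: ReferencePanel,
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams = DEFAULT_PARAMS,
) -> tuple[PanelEntry, AlignmentHit] | None:
    """Best panel entry by E-value (< ``neighbor_evalue``); ties resolve by
    bitscore descending, then entry id lexicographic."""
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    n = panel.total_residues
    best: tuple[float, str, PanelEntry] | None = None
    for entry in sorted(panel.entries, key=lambda e: e.protein.protein_id):
        score = aligner.score(query.sequence, entry.protein.sequence)
        if score <= 0:
            continue
        ev = _evalue(score, len(query), n, params)
        if ev >= thresholds.neighbor_evalue:
            continue
        key = (-score, entry.protein.protein_id)
        if best is None or key < (best[0], best[1]):
            best = (-score, entry.protein.protein_id, entry)
    if best is None:
        return None
    entry = best[2]
    hit = local_align_protein(query, entry.protein, params, search_space=n)
    return entry, hit


# ---------------------------------------------------------------------------
# candidate search and validation


@dataclass
class Candidate:
    method: str                     # local | global | both
    peptide: str
    ctx_span: tuple[int, int]
    pieces: tuple[tuple[int, int], ...]
    reverse: bool = False
    profile_evalue: float = math.inf
    profile_score: float = -math.inf
    patterns_ok: bool = False


@dataclass(frozen=True)
class RecoveredDBD:
    protein_id: str
    dbd_type: str
    peptide: str
    genomic_span: tuple[int, int]
    scaffold_id: str
    method: str
    profile_evalue: float
    patterns_ok: bool
    neighbor_id: str


@dataclass(frozen=True)
class FailureReport:
    protein_id: str
    reason: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.reason not in FAILURE_REASONS:
            raise ValueError(f"unknown failure reason {self.reason!r}")


def _local_candidates(
    seg: ProteinRecord,
    context: str,
    thresholds: Thresholds,
    params: ScoringParams,
) -> list[Candidate]:
    ctx_rec = GenomeRecord("ctx", context)
    hits = translated_search(seg, ctx_rec, params)
    out = []
    for h in hits:
        if h.evalue >= thresholds.local_evalue:
            continue
        ts, te = h.target_span
        ts2 = ts - 3 * min(CANDIDATE_SLACK_AA, ts // 3)
        te2 = te + 3 * min(CANDIDATE_SLACK_AA, (len(context) - te) // 3)
        dna = context[ts2:te2]
        if h.strand == "-":
            dna = reverse_complement(dna)
        out.append(
            Candidate(
                method="local",
                peptide=translate(dna),
                ctx_span=(ts2, te2),
                pieces=((ts2, te2),),
                reverse=h.strand == "-",
            )
        )
    return out


def _dbd_anchor_score(
    neighbor: PanelEntry,
    aln: SplicedAlignment,
    context: str,
    interval: tuple[int, int],
    params: ScoringParams,
) -> float:
    """Net score contribution of the alignment region projected from the
    neighbor's DBD: substitution scores of its codon-aligned residues minus
    intron charges inside that genomic span and deletion charges for
    unplaced DBD residues.

    A global-in-query alignment must place every residue somewhere; over
    random upstream DNA the DBD residues get scattered across spurious
    intron-patched fragments whose net contribution hovers around zero,
    whereas a genuine DBD-coding segment contributes strongly. Candidates
    are required to be positively anchored.
    """
    from .spliced import (
        DEL_COST,
        INS_COST,
        _codon_table,
        _sub_matrix,
        encode_dna,
        encode_protein,
    )

    ds, de = interval
    pieces = aln.query_coverage((ds, de))
    sub = _sub_matrix(params.matrix_name)
    ca = _codon_table()
    q = encode_protein(neighbor.protein.sequence)
    g = encode_dna(context)
    total = 0.0
    aligned = 0
    aligned_nt = 0
    for (qs, qe), (gs, ge) in pieces:
        for k in range(qe - qs):
            c0 = gs + 3 * k
            total += sub[q[qs + k], ca[g[c0], g[c0 + 1], g[c0 + 2]]]
            aligned += 1
        aligned_nt += ge - gs
    if pieces:
        span = (pieces[0][1][0], pieces[-1][1][1])
        intron_nt = sum(
            ge - gs for gs, ge, _, _ in aln.introns if span[0] <= gs < span[1]
        )
        n_introns = sum(1 for gs, ge, _, _ in aln.introns if span[0] <= gs < span[1])
        gap_nt = (span[1] - span[0]) - aligned_nt - intron_nt
        total -= params.intron_open * n_introns
        total -= INS_COST * max(0, gap_nt) / 3.0
    total -= DEL_COST * ((de - ds) - aligned)
    return total


def _global_candidate(
    neighbor: PanelEntry,
    dbd_type: str,
    context: str,
    params: ScoringParams,
) -> tuple[Candidate | None, SplicedAlignment, bool]:
    """Spliced alignment of the full neighbor; the candidate is the genomic
    projection of the neighbor's DBD interval, required to be positively
    anchored. Returns (candidate, alignment, anchored flag)."""
    aln = spliced_align(neighbor.protein, context, params, target_scaffold="ctx")
    ds, de = neighbor.interval(dbd_type)
    if not aln.blocks:
        return None, aln, False
    # demand a modest per-residue margin; genuine DBD-coding segments score
    # several substitution-matrix points per residue, spurious placements
    # over intergenic DNA hover around zero after gap/intron charges
    anchored = (
        _dbd_anchor_score(neighbor, aln, context, (ds, de), params)
        > 1.5 * (de - ds)
    )
    if not anchored:
        return None, aln, False
    pieces = aln.query_coverage((max(0, ds - CANDIDATE_SLACK_AA),
                                 de + CANDIDATE_SLACK_AA))
    if not pieces:
        return None, aln, False
    dna = "".join(context[gs:ge] for _, (gs, ge) in pieces)
    cand = Candidate(
        method="global",
        peptide=translate(dna),
        ctx_span=(pieces[0][1][0], pieces[-1][1][1]),
        pieces=tuple(g for _, g in pieces),
    )
    return cand, aln, True


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _trim_to_motif(cand: Candidate, dbd_type: str) -> None:
    """Restrict an accepted candidate to the motif span when unambiguous."""
    if dbd_type != ZN2C6:
        return
    matches = find_zn2c6_motif(cand.peptide)
    if not matches:
        return
    a, b = matches[0]
    if len(cand.pieces) == 1 and not cand.reverse:
        s, _ = cand.ctx_span
        cand.ctx_span = (s + 3 * a, s + 3 * b)
        cand.pieces = (cand.ctx_span,)
    cand.peptide = cand.peptide[a:b]


def _n_runs(context: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"N{%d,}" % N_RUN_MIN, context)]


def _search_and_validate(
    protein_id: str,
    neighbor: PanelEntry,
    dbd_type: str,
    context: GenomicContext,
    profile: DbdProfile,
    thresholds: Thresholds,
    params: ScoringParams,
    excluded_ctx_spans: list[tuple[int, int]],
) -> tuple[Candidate | None, list[Candidate], SplicedAlignment, bool]:
    """Run both search methods on one context; returns (accepted, all
    candidates, global alignment, anchored flag)."""
    seg = neighbor.dbd_segment(dbd_type)
    candidates = _local_candidates(seg, context.sequence, thresholds, params)
    gcand, aln, anchored = _global_candidate(neighbor, dbd_type,
                                             context.sequence, params)
    if gcand is not None:
        candidates.append(gcand)
    # method upgrade: positionally agreeing local/global candidates are 'both'
    for c in candidates:
        for d in candidates:
            if (
                c.method != d.method
                and "both" not in (c.method, d.method)
                and _overlap(c.ctx_span, d.ctx_span) > 0
            ):
                c.method = "both"
    kept = []
    for c in candidates:
        if any(_overlap(c.ctx_span, ex) > 0 for ex in excluded_ctx_spans):
            continue
        c.profile_score = profile.score(c.peptide)
        c.profile_evalue = profile.evalue(c.profile_score)
        c.patterns_ok = check_validation_patterns(c.peptide, dbd_type)
        kept.append(c)
    accepted = [
        c for c in kept
        if c.profile_evalue < thresholds.profile_evalue and c.patterns_ok
    ]
    if not accepted:
        return None, kept, aln, anchored
    accepted.sort(
        key=lambda c: (
            -c.profile_score,
            0 if c.method == "both" else 1,
            c.ctx_span,
        )
    )
    best = accepted[0]
    _trim_to_motif(best, dbd_type)
    return best, kept, aln, anchored


def recover_dbd(
    gene: GeneModel,
    protein: ProteinRecord,
    genome: dict[str, GenomeRecord],
    panel: ReferencePanel,
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams = DEFAULT_PARAMS,
    profile: DbdProfile | None = None,
    domains: list[DomainHit] | None = None,
) -> RecoveredDBD | FailureReport:
    """Attempt to recover the missing DBD of an MHD-only protein.

    ``domains`` are the query protein's own annotations (must classify as
    MHD-only); the annotated MHD region is excluded from candidates.
    """
    domains = domains or []
    if domains and classify_architecture(domains) != "MHD-only":
        raise ValueError(f"{protein.protein_id}: query is not MHD-only")
    if gene.scaffold_id not in genome:
        return FailureReport(protein.protein_id, "no_genomic_sequence",
                             f"scaffold {gene.scaffold_id} absent")
    context = extract_genomic_context(gene, genome, thresholds.upstream_window)
    found = find_nearest_neighbor(protein, panel, thresholds, params)
    if found is None:
        return FailureReport(protein.protein_id, "no_neighbor",
                             f"no panel hit at E<{thresholds.neighbor_evalue}")
    neighbor, _ = found
    if profile is None:
        profile = build_profile(panel)
    mhd_spans = [
        context.to_context(fwd)
        for h in domains
        if h.domain_type == MHD
        for fwd in protein_to_forward(gene, (h.start, h.end))
    ]
    best, kept, aln, anchored = _search_and_validate(
        protein.protein_id, neighbor, panel.dbd_type, context, profile,
        thresholds, params, mhd_spans,
    )
    if best is not None:
        return RecoveredDBD(
            protein_id=protein.protein_id,
            dbd_type=panel.dbd_type,
            peptide=best.peptide,
            genomic_span=context.to_forward(best.ctx_span),
            scaffold_id=context.scaffold_id,
            method=best.method,
            profile_evalue=best.profile_evalue,
            patterns_ok=best.patterns_ok,
            neighbor_id=neighbor.protein.protein_id,
        )
    n_runs = _n_runs(context.sequence)
    if kept:
        if n_runs and all(
            any(_overlap(c.ctx_span, r) > 0 for r in n_runs) for c in kept
        ):
            return FailureReport(protein.protein_id, "n_region",
                                 "all candidates overlap undefined sequence")
        if any(
            c.profile_evalue < thresholds.profile_evalue or c.patterns_ok
            for c in kept
        ):
            return FailureReport(protein.protein_id, "partial_hit",
                                 "candidate passes only part of the validation")
        return FailureReport(protein.protein_id, "low_similarity",
                             "candidates fail profile and pattern checks")
    if n_runs:
        return FailureReport(protein.protein_id, "n_region",
                             "undefined sequence in the searched region")
    # the neighbor's non-DBD region aligned but its DBD found no anchored
    # placement: the DBD-coding segment must lie beyond the searched window
    ds, de = neighbor.interval(panel.dbd_type)
    first_aligned = aln.blocks[0][0][0] if aln.blocks else None
    body = len(neighbor.protein) - (de - ds)
    body_aligned = aln.aligned_query_residues - sum(
        qe - qs for (qs, qe), _ in aln.query_coverage((ds, de))
    )
    if (
        first_aligned is not None
        and (first_aligned >= de or not anchored)
        and body_aligned >= 0.5 * body
    ):
        return FailureReport(
            protein.protein_id, "too_distant",
            "neighbor DBD has no anchored placement inside the window",
        )
    return FailureReport(protein.protein_id, "low_similarity",
                         "no candidate DBD-coding segment found")


def cterm_control(
    gene: GeneModel,
    protein: ProteinRecord,
    genome: dict[str, GenomeRecord],
    panel: ReferencePanel,
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams = DEFAULT_PARAMS,
    profile: DbdProfile | None = None,
    domains: list[DomainHit] | None = None,
) -> RecoveredDBD | None:
    """False-positive control: run the identical machinery on the region
    downstream of the annotated MHD (C-terminal side). Returns an accepted
    recovery there, or None."""
    domains = domains or []
    mhd_hits = [h for h in domains if h.domain_type == MHD]
    if not mhd_hits or gene.scaffold_id not in genome:
        return None
    scaffold = genome[gene.scaffold_id]
    window = thresholds.upstream_window
    mhd_pieces = protein_to_forward(gene, (mhd_hits[0].start, mhd_hits[0].end))
    lo, hi = gene.span
    L = len(scaffold)
    if gene.strand == "+":
        start = max(p[1] for p in mhd_pieces)
        end = min(L, hi + window)
        if end - start < 3:
            return None
        seq = scaffold.sequence[start:end]
        context = GenomicContext(scaffold.scaffold_id, "+", seq, 0, start, end)
    else:
        end = min(p[0] for p in mhd_pieces)
        start = max(0, lo - window)
        if end - start < 3:
            return None
        seq = reverse_complement(scaffold.sequence[start:end])
        context = GenomicContext(scaffold.scaffold_id, "-", seq, 0, start, end)
    found = find_nearest_neighbor(protein, panel, thresholds, params)
    if found is None:
        return None
    neighbor, _ = found
    if profile is None:
        profile = build_profile(panel)
    best, _, _, _ = _search_and_validate(
        protein.protein_id, neighbor, panel.dbd_type, context, profile,
        thresholds, params, [],
    )
    if best is None:
        return None
    return RecoveredDBD(
        protein_id=protein.protein_id,
        dbd_type=panel.dbd_type,
        peptide=best.peptide,
        genomic_span=context.to_forward(best.ctx_span),
        scaffold_id=context.scaffold_id,
        method=best.method,
        profile_evalue=best.profile_evalue,
        patterns_ok=best.patterns_ok,
        neighbor_id=neighbor.protein.protein_id,
    )
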