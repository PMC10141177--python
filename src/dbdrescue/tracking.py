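"""Reference-guided diagnosis of gene-annotation errors.

Given a full-architecture reference protein (known to carry the Zn2C6
motif) and the genome assembly in which its ortholog was predicted without
the motif, a translated search locates the homologous genomic segments and
a fixed rule cascade names the probable cause:

1. qualifying hits on two or more scaffolds  -> assembly_split
2. one scaffold, hits in >= 2 reading frames -> frameshift
3. a single hit covering 100% of the query   -> wrong_start
4. otherwise                                 -> undetermined

A hit qualifies when its percent identity exceeds ``identity_min`` and its
aligned length exceeds ``hit_len_min`` residues. A corrected protein is
then reconstructed by translating the qualifying same-scaffold hits in
their own reading frames and concatenating them in query order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import DEFAULT_PARAMS, AlignmentHit, ScoringParams, translated_search
from .motifs import find_zn2c6_motif
from .seq import reverse_complement, translate
from .types import GenomeRecord, ProteinRecord, Thresholds

CAUSES = ("assembly_split", "frameshift", "wrong_start", "undetermined")


@dataclass
class ErrorDiagnosis:
    protein_id: str
    cause: str
    evidence: list[AlignmentHit] = field(default_factory=list)
    scaffold_count: int = 0
    frame_count: int = 0
    coverage: int = 0  # integer percent of reference residues covered


@dataclass
class CorrectedProtein:
    protein_id: str
    sequence: str
    source_blocks: list[tuple[str, tuple[int, int]]]
    motif_found: bool
    partial: bool = False
    fragments: tuple[str, ...] = ()


def _refine_hit(hit: AlignmentHit, thresholds: Thresholds) -> AlignmentHit | None:
    """Trim a hit to its best sub-alignment above the identity threshold.

    A local alignment may gain score from a few chance-matching columns
    beyond a frameshift or other breakpoint, diluting its overall identity.
    The qualifying rule is therefore applied to the maximal sub-alignment
    whose identity exceeds the threshold: columns are weighted +1 for a
    match and -t/(100-t) otherwise (t the identity threshold, so any
    positive-sum window has identity > t) and the maximum-sum window is
    found by a linear scan.
    """
    if (
        hit.identity > thresholds.identity_min
        and hit.aligned_length > thresholds.hit_len_min
    ):
        return hit
    if not hit.ops:
        return None
    penalty = thresholds.identity_min / (100.0 - thresholds.identity_min)
    best_sum = 0.0
    best = None  # (start, end) columns
    cur_sum = 0.0
    cur_start = 0
    for k, (_, _, match) in enumerate(hit.ops):
        cur_sum += 1.0 if match else -penalty
        if cur_sum <= 0:
            cur_sum = 0.0
            cur_start = k + 1
        elif cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, k + 1)
    if best is None or best[1] - best[0] <= thresholds.hit_len_min:
        return None
    a, b = best
    qa = sum(op[0] for op in hit.ops[:a])
    qb = qa + sum(op[0] for op in hit.ops[a:b])
    ta = sum(op[1] for op in hit.ops[:a])
    tb = ta + sum(op[1] for op in hit.ops[a:b])
    matches = sum(1 for op in hit.ops[a:b] if op[2])
    qs, _ = hit.query_span
    ts, te = hit.target_span
    if hit.strand == "-":
        new_tspan = (te - 3 * tb, te - 3 * ta)
    else:
        new_tspan = (ts + 3 * ta, ts + 3 * tb)
    return AlignmentHit(
        query_id=hit.query_id,
        target_id=hit.target_id,
        query_span=(qs + qa, qs + qb),
        target_span=new_tspan,
        strand=hit.strand,
        frame=hit.frame,
        score=hit.score,
        bitscore=hit.bitscore,
        evalue=hit.evalue,
        identity=100.0 * matches / (b - a),
        aligned_length=b - a,
        ops=hit.ops[a:b],
    )


def _qualifying(hits: list[AlignmentHit], thresholds: Thresholds) -> list[AlignmentHit]:
    refined = (_refine_hit(h, thresholds) for h in hits)
    return [h for h in refined if h is not None]


def _coverage(hits: list[AlignmentHit], query_len: int) -> int:
    """Integer percent of query residues inside the union of hit spans."""
    if not hits:
        return 0
    spans = sorted(h.query_span for h in hits)
    covered = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return round(100 * covered / query_len)


def diagnose(
    reference: ProteinRecord,
    genome: list[GenomeRecord],
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams = DEFAULT_PARAMS,
) -> ErrorDiagnosis:
    """Apply the rule cascade to the qualifying translated-search hits of
    ``reference`` against ``genome`` (the scaffolds of one assembly)."""
    all_hits: list[AlignmentHit] = []
    total_residues = sum(2 * len(g) // 3 for g in genome)
    for scaffold in genome:
        all_hits.extend(
            translated_search(
                reference, scaffold, params, search_space=max(total_residues, 1)
            )
        )
    hits = _qualifying(all_hits, thresholds)
    hits.sort(key=lambda h: (h.target_id, h.target_span, h.strand, h.frame))
    cov = _coverage(hits, len(reference))
    scaffolds = {h.target_id for h in hits}
    frames = {(h.target_id, h.strand, h.frame) for h in hits}
    diag = ErrorDiagnosis(
        protein_id=reference.protein_id,
        cause="undetermined",
        evidence=hits,
        scaffold_count=len(scaffolds),
        frame_count=len(frames),
        coverage=cov,
    )
    if not hits:
        return diag
    if len(scaffolds) >= 2:
        diag.cause = "assembly_split"
    elif len(frames) >= 2:
        diag.cause = "frameshift"
    elif len(hits) == 1 and cov == 100:
        diag.cause = "wrong_start"
    return diag


def _hit_peptide(hit: AlignmentHit, scaffold: GenomeRecord) -> str:
    s, e = hit.target_span
    dna = scaffold.sequence[s:e]
    if hit.strand == "-":
        dna = reverse_complement(dna)
    return translate(dna)


def _assemble(hits: list[AlignmentHit], genome_by_id: dict[str, GenomeRecord]):
    """Concatenate hit translations in query order, resolving query-coordinate
    overlaps in favor of the higher-scoring hit."""
    parts: list[list] = []  # [qstart, qend, peptide, score, block]
    for h in sorted(hits, key=lambda h: (h.query_span, h.target_span)):
        pep = _hit_peptide(h, genome_by_id[h.target_id])
        parts.append([h.query_span[0], h.query_span[1], pep, h.score,
                      (h.target_id, h.target_span)])
    for prev, cur in zip(parts, parts[1:]):
        overlap = prev[1] - cur[0]
        if overlap > 0:
            if cur[3] > prev[3]:
                prev[2] = prev[2][: max(0, len(prev[2]) - overlap)]
                prev[1] -= overlap
            else:
                cur[2] = cur[2][overlap:]
                cur[0] += overlap
    sequence = "".join(p[2] for p in parts)
    blocks = [p[4] for p in parts]
    return sequence, blocks


def reconstruct(
    diagnosis: ErrorDiagnosis,
    genome: list[GenomeRecord],
    thresholds: Thresholds = Thresholds(),
) -> CorrectedProtein:
    """Rebuild a corrected protein from the diagnostic hits.

    For single-scaffold causes the qualifying hits are translated in their
    own frames and concatenated; for ``assembly_split`` each scaffold yields
    a fragment and the result is flagged partial (the motif is searched per
    fragment, so a motif spanning the split stays unfound).
    """
    hits = _qualifying(diagnosis.evidence, thresholds)
    if not hits:
        raise ValueError(
            f"{diagnosis.protein_id}: no qualifying hits to reconstruct from"
        )
    genome_by_id = {g.scaffold_id: g for g in genome}
    scaffolds = sorted({h.target_id for h in hits})
    if diagnosis.cause == "assembly_split":
        fragments = []
        blocks: list[tuple[str, tuple[int, int]]] = []
        for sid in scaffolds:
            frag, fb = _assemble([h for h in hits if h.target_id == sid], genome_by_id)
            fragments.append(frag)
            blocks.extend(fb)
        motif = any(find_zn2c6_motif(f) for f in fragments)
        return CorrectedProtein(
            protein_id=diagnosis.protein_id,
            sequence="".join(fragments),
            source_blocks=blocks,
            motif_found=motif,
            partial=True,
            fragments=tuple(fragments),
        )
    sequence, blocks = _assemble(hits, genome_by_id)
    return CorrectedProtein(
        protein_id=diagnosis.protein_id,
        sequence=sequence,
        source_blocks=blocks,
        motif_found=bool(find_zn2c6_motif(sequence)),
    )
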