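"""Protein local alignment and six-frame translated search.

Stand-ins for BLASTP and TBLASTN at desk scale: optimal Smith-Waterman
local alignment (BLOSUM62, gap cost 11 + k) with Karlin-Altschul E-value
statistics, and a translated search that aligns a protein query against all
six reading frames of a scaffold, reporting hits in genomic nucleotide
coordinates of the forward strand. No heuristic seeding: queries are small
enough for full dynamic programming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .seq import reverse_complement, translate
from .types import GenomeRecord, ProteinRecord


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring and score-statistics parameters.

    Gap cost convention is BLAST's: a gap of length k costs
    ``gap_open + k * gap_extend``. Karlin-Altschul lambda/K default to the
    gapped BLOSUM62 values; exact BLAST parity is not a goal, only the scale
    at which the protocol's E-value thresholds are meaningful.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    intron_open: float = 15.0
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend, self.intron_open) <= 0:
            raise ValueError("penalties must be positive")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


DEFAULT_PARAMS = ScoringParams()


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment hit.

    ``target_span`` is in nucleotides (forward-strand coordinates) when the
    target is DNA, in residues otherwise. ``frame`` is 0/1/2 and ``strand``
    '+'/'-' for translated hits; protein-protein hits use frame 0, '+'.
    """

    query_id: str
    target_id: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    strand: str
    frame: int
    score: float
    bitscore: float
    evalue: float
    identity: float
    aligned_length: int
    # per-column (query_advance, target_advance, is_match) of the alignment,
    # target advance in residues of the translated frame; used by hit
    # refinement in the diagnostics
    ops: tuple[tuple[int, int, bool], ...] = field(default=(), repr=False,
                                                   compare=False)

    @property
    def frame_key(self) -> tuple[str, int]:
        return (self.strand, self.frame)


def evalue(raw_score: float, query_len: int, search_space: int,
           params: ScoringParams = DEFAULT_PARAMS) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    return params.ka_k * query_len * search_space * math.exp(
        -params.ka_lambda * raw_score
    )


def bitscore(raw_score: float, params: ScoringParams = DEFAULT_PARAMS) -> float:
    return (params.ka_lambda * raw_score - math.log(params.ka_k)) / math.log(2)


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # biopython charges open_gap_score for the first gap position, so BLAST's
    # 11 + k maps to open -12 / extend -1
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _alignment_stats(aln):
    """(query_span, target_span, identity_pct, aligned_length, ops) of a
    local alignment produced by ``_aligner().align(query, target)``."""
    qblocks, tblocks = aln.aligned
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    ts, te = int(tblocks[0][0]), int(tblocks[-1][1])
    qseq, tseq = aln.sequences
    identities = 0
    ops: list[tuple[int, int, bool]] = []
    prev_q = prev_t = None
    for (q0, q1), (t0, t1) in zip(qblocks, tblocks):
        if prev_q is not None:
            ops.extend(((1, 0, False),) * (q0 - prev_q))  # target gap
            ops.extend(((0, 1, False),) * (t0 - prev_t))  # query gap
        for k in range(q1 - q0):
            match = qseq[q0 + k] == tseq[t0 + k]
            identities += match
            ops.append((1, 1, match))
        prev_q, prev_t = q1, t1
    columns = len(ops)
    identity = 100.0 * identities / columns if columns else 0.0
    return (qs, qe), (ts, te), identity, columns, tuple(ops)


def local_align_protein(
    query: ProteinRecord,
    target: ProteinRecord,
    params: ScoringParams = DEFAULT_PARAMS,
    search_space: int | None = None,
) -> AlignmentHit | None:
    """Optimal Smith-Waterman local alignment of two proteins.

    Returns ``None`` when the optimal local score is not positive.
    ``search_space`` (effective database residues) defaults to the target
    length.
    """
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    score = aligner.score(query.sequence, target.sequence)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(query.sequence, target.sequence)))
    qspan, tspan, identity, columns, ops = _alignment_stats(aln)
    n = search_space if search_space is not None else len(target)
    return AlignmentHit(
        query_id=query.protein_id,
        target_id=target.protein_id,
        query_span=qspan,
        target_span=tspan,
        strand="+",
        frame=0,
        score=score,
        bitscore=bitscore(score, params),
        evalue=evalue(score, len(query), n, params),
        identity=identity,
        aligned_length=columns,
        ops=ops,
    )


def _frame_hits(query: str, frame_protein: str, aligner, min_raw: float,
                max_hits: int) -> list[tuple[float, object, int]]:
    """Greedy non-overlapping local hits of ``query`` against one frame
    translation: best hit, then recurse left and right of its target span.

    Returns (score, alignment, target_offset) triples.
    """
    out: list[tuple[float, object, int]] = []
    stack = [(frame_protein, 0)]
    while stack and len(out) < max_hits:
        segment, offset = stack.pop()
        if len(segment) < 5:
            continue
        score = aligner.score(query, segment)
        if score < min_raw:
            continue
        aln = next(iter(aligner.align(query, segment)))
        out.append((score, aln, offset))
        tblocks = aln.aligned[1]
        ts, te = int(tblocks[0][0]), int(tblocks[-1][1])
        stack.append((segment[:ts], offset))
        stack.append((segment[te:], offset + te))
    return out


def translated_search(
    query: ProteinRecord,
    genome: GenomeRecord,
    params: ScoringParams = DEFAULT_PARAMS,
    search_space: int | None = None,
    min_raw: float = 40.0,
    max_hits_per_frame: int = 4,
    table: int = 1,
) -> list[AlignmentHit]:
    """Local alignments of ``query`` against all six translated frames of
    ``genome``, sorted by E-value ascending.

    Target spans are nucleotide intervals on the forward strand. Stop codons
    translate to ``*`` and score as mismatches against every residue.
    """
    if len(genome) < 3:
        return []
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    n = search_space if search_space is not None else 2 * len(genome) // 3
    dna_fwd = genome.sequence
    dna_rev = reverse_complement(dna_fwd)
    length = len(dna_fwd)
    hits: list[AlignmentHit] = []
    for strand, dna in (("+", dna_fwd), ("-", dna_rev)):
        for frame in range(3):
            prot = translate(dna, frame, table)
            if not prot:
                continue
            for score, aln, offset in _frame_hits(
                query.sequence, prot, aligner, min_raw, max_hits_per_frame
            ):
                qspan, tspan, identity, columns, ops = _alignment_stats(aln)
                a = frame + 3 * (tspan[0] + offset)
                b = frame + 3 * (tspan[1] + offset)
                if strand == "+":
                    nt_span = (a, b)
                else:
                    nt_span = (length - b, length - a)
                hits.append(
                    AlignmentHit(
                        query_id=query.protein_id,
                        target_id=genome.scaffold_id,
                        query_span=qspan,
                        target_span=nt_span,
                        strand=strand,
                        frame=frame,
                        score=score,
                        bitscore=bitscore(score, params),
                        evalue=evalue(score, len(query), n, params),
                        identity=identity,
                        aligned_length=columns,
                        ops=ops,
                    )
                )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.target_span))
    return hits


def hits_to_table(hits: list[AlignmentHit]):
    """Hits as a DataFrame mirroring the BLAST outfmt-6 column convention."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.target_id,
                "pident": round(h.identity, 2),
                "length": h.aligned_length,
                "qstart": h.query_span[0],
                "qend": h.query_span[1],
                "sstart": h.target_span[0],
                "send": h.target_span[1],
                "strand": h.strand,
                "frame": h.frame,
                "evalue": h.evalue,
                "bitscore": round(h.bitscore, 1),
            }
            for h in hits
        ]
    )
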