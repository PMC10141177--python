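"""Simplified spliced protein-to-genome alignment.

A codon-level dynamic program aligns a protein query to genomic DNA:
global in the query (every residue aligned or deleted), local in the
genome, with introns allowed between codon-aligned blocks. Introns must
start ``GT``, end ``AG`` and be at least ``min_intron`` nucleotides long;
within exons, query-residue deletions and genomic codon insertions carry
linear costs. There is no frameshift state: frame disruptions are the
province of the translated-search diagnostics, not the spliced aligner.

The DP kernel is JIT-compiled with numba; for a query of m residues and a
context of n nucleotides it fills an (m+1) x (n+1) table with an O(1)
running-maximum intron transition, so alignment is O(m n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from Bio.Align import substitution_matrices

from .align import DEFAULT_PARAMS, ScoringParams
from .types import ProteinRecord

# linear within-exon gap costs (per deleted residue / per inserted codon);
# chosen so that a genuine intron (one intron_open charge) always beats
# codon-insertion chains across it
DEL_COST = 4.0
INS_COST = 4.0
MIN_INTRON = 20

_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_X = _AA_INDEX["X"]
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

_SUB_CACHE: dict[str, np.ndarray] = {}
_CODON_AA: np.ndarray | None = None


def _sub_matrix(name: str) -> np.ndarray:
    mat = _SUB_CACHE.get(name)
    if mat is None:
        m = substitution_matrices.load(name)
        if str(m.alphabet) != _ALPHABET:
            raise ValueError(f"unsupported matrix alphabet for {name}")
        mat = np.asarray(m, dtype=np.float64)
        _SUB_CACHE[name] = mat
    return mat


def _codon_table() -> np.ndarray:
    global _CODON_AA
    if _CODON_AA is None:
        from .seq import translate

        tab = np.full((5, 5, 5), _X, dtype=np.int8)
        bases = "ACGT"
        for i, a in enumerate(bases):
            for j, b in enumerate(bases):
                for k, c in enumerate(bases):
                    tab[i, j, k] = _AA_INDEX[translate(a + b + c)]
        _CODON_AA = tab
    return _CODON_AA


def encode_protein(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, _X) for c in seq], dtype=np.int8)


def encode_dna(seq: str) -> np.ndarray:
    return np.array([_NT_INDEX.get(c, 4) for c in seq], dtype=np.int8)


@dataclass(frozen=True)
class SplicedAlignment:
    """Result of :func:`spliced_align`.

    ``blocks`` are ((query_start, query_end), (genomic_start, genomic_end))
    pairs with genomic length exactly three times the protein length;
    ``introns`` are (genomic_start, genomic_end, donor, acceptor) tuples.
    A degenerate alignment (no positive-scoring chain) has empty blocks and
    score 0.
    """

    query_id: str
    target_scaffold: str
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    introns: tuple[tuple[int, int, str, str], ...]
    score: float

    @property
    def aligned_query_residues(self) -> int:
        return sum(qe - qs for (qs, qe), _ in self.blocks)

    def query_coverage(self, interval: tuple[int, int]) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Sub-blocks of the alignment overlapping a query interval."""
        a, b = interval
        out = []
        for (qs, qe), (gs, ge) in self.blocks:
            o1, o2 = max(qs, a), min(qe, b)
            if o1 < o2:
                out.append(((o1, o2), (gs + 3 * (o1 - qs), gs + 3 * (o2 - qs))))
        return out


@njit(cache=True)
def _dp_kernel(q, g, sub, ca_end, donor, acceptor,
               del_cost, ins_cost, intron_open, min_intron):  # pragma: no cover
    m = q.shape[0]
    n = g.shape[0]
    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    ptr = np.zeros((m + 1, n + 1), np.int8)
    don = np.full((m + 1, n + 1), -1, np.int32)
    for j in range(n + 1):
        M[0, j] = 0.0
    for i in range(1, m + 1):
        run_max = NEG
        run_arg = -1
        qi = q[i - 1]
        for j in range(n + 1):
            jp = j - min_intron
            if jp >= 0 and donor[jp]:
                if M[i, jp] > run_max:
                    run_max = M[i, jp]
                    run_arg = jp
            best = M[i - 1, j] - del_cost
            code = 2
            d = -1
            if j >= 3:
                v = M[i - 1, j - 3] + sub[qi, ca_end[j]]
                if v > best:
                    best = v
                    code = 1
                v = M[i, j - 3] - ins_cost
                if v > best:
                    best = v
                    code = 3
            if j >= 2 and acceptor[j]:
                v = run_max - intron_open
                if v > best:
                    best = v
                    code = 4
                    d = run_arg
            M[i, j] = best
            ptr[i, j] = code
            don[i, j] = d
    return M, ptr, don


def spliced_align(
    query: ProteinRecord,
    genomic: str,
    params: ScoringParams = DEFAULT_PARAMS,
    target_scaffold: str = "",
    min_intron: int = MIN_INTRON,
    del_cost: float = DEL_COST,
    ins_cost: float = INS_COST,
) -> SplicedAlignment:
    """Best spliced alignment of ``query`` against ``genomic`` DNA.

    Ties among equal-scoring chains resolve toward fewer introns and then
    the leftmost genomic start (the DP prefers non-intron transitions and
    the traceback takes the leftmost best end).
    """
    if len(genomic) < 3:
        return SplicedAlignment(query.protein_id, target_scaffold, (), (), 0.0)
    q = encode_protein(query.sequence)
    g = encode_dna(genomic)
    sub = _sub_matrix(params.matrix_name)
    ca = _codon_table()
    n = len(g)
    # aa of the codon ENDING at j (i.e. g[j-3:j]); index 0..n
    ca_end = np.full(n + 1, _X, dtype=np.int8)
    for j in range(3, n + 1):
        ca_end[j] = ca[g[j - 3], g[j - 2], g[j - 1]]
    donor = np.zeros(n + 1, dtype=np.bool_)
    acceptor = np.zeros(n + 1, dtype=np.bool_)
    for j in range(n - 1):
        if g[j] == 2 and g[j + 1] == 3:  # GT
            donor[j] = True
    for j in range(2, n + 1):
        if g[j - 2] == 0 and g[j - 1] == 2:  # AG
            acceptor[j] = True
    M, ptr, don = _dp_kernel(
        q, g, sub, ca_end, donor, acceptor,
        float(del_cost), float(ins_cost), float(params.intron_open),
        int(min_intron),
    )
    m = len(q)
    jbest = int(np.argmax(M[m]))
    best = float(M[m, jbest])
    if best <= 0:
        return SplicedAlignment(query.protein_id, target_scaffold, (), (), 0.0)
    # traceback
    matches: list[tuple[int, int]] = []  # (query index, genomic codon start)
    introns: list[tuple[int, int, str, str]] = []
    i, j = m, jbest
    while i > 0:
        code = ptr[i, j]
        if code == 1:
            matches.append((i - 1, j - 3))
            i -= 1
            j -= 3
        elif code == 2:
            i -= 1
        elif code == 3:
            j -= 3
        elif code == 4:
            jd = int(don[i, j])
            introns.append((jd, j, genomic[jd : jd + 2], genomic[j - 2 : j]))
            j = jd
        else:
            break
    matches.reverse()
    introns.reverse()
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for qi, gj in matches:
        if blocks and blocks[-1][0][1] == qi and blocks[-1][1][1] == gj:
            (qs, _), (gs, _) = blocks[-1]
            blocks[-1] = ((qs, qi + 1), (gs, gj + 3))
        else:
            blocks.append(((qi, qi + 1), (gj, gj + 3)))
    return SplicedAlignment(
        query.protein_id, target_scaffold, tuple(blocks), tuple(introns), best
    )
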