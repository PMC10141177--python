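"""Independent brute-force oracles used to cross-check the aligners and the
motif engine. These deliberately share no code with the package: plain
Python dynamic programming and exhaustive enumeration at tiny sizes.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

_B62 = substitution_matrices.load("BLOSUM62")
_B62_IDX = {c: i for i, c in enumerate(_B62.alphabet)}

NEG = float("-inf")


def blosum62(a: str, b: str) -> float:
    return float(_B62[_B62_IDX[a], _B62_IDX[b]])


def gotoh_local_score(q: str, t: str, gap_open: float = 11.0,
                      gap_extend: float = 1.0) -> float:
    """Optimal Smith-Waterman score under affine gaps costing open + k*ext
    (a gap of length 1 costs gap_open + gap_extend)."""
    m, n = len(q), len(t)
    first = gap_open + gap_extend
    M = [[0.0] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target (q advances)
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (t advances)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + blosum62(q[i - 1], t[j - 1]))
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


# -- motif enumeration ------------------------------------------------------

def brute_zn2c6(protein: str) -> list[tuple[int, int]]:
    """All leftmost-shortest Zn2C6 motif matches by explicit spacer
    enumeration: for every start position try s3 = 5..16 then s5 = 6..8 in
    ascending order and keep the first hit."""
    out = []
    n = len(protein)
    for start in range(n):
        if protein[start] != "C":
            continue
        found = None
        for s3 in range(5, 17):
            for s5 in range(6, 9):
                pos = [start]
                for spacer in (2, 6, s3, 2, s5):
                    pos.append(pos[-1] + spacer + 1)
                end = pos[-1] + 1
                if end > n:
                    continue
                if all(protein[p] == "C" for p in pos):
                    found = (start, end)
                    break
            if found:
                break
        if found:
            out.append(found)
    return out


# -- translation ------------------------------------------------------------

_TABLE = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for _stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    _TABLE[_stop] = "*"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def table_translate_revcomp(dna: str) -> str:
    """Frame -1 translation by direct table lookup on the hand-complemented
    reverse sequence."""
    rc = "".join(_COMP[c] for c in reversed(dna))
    out = []
    for i in range(0, len(rc) - 2, 3):
        out.append(_TABLE.get(rc[i : i + 3], "X"))
    return "".join(out)


# -- spliced alignment ------------------------------------------------------

def codon_global_local(q: str, g: str, del_cost: float = 4.0,
                       ins_cost: float = 4.0) -> float:
    """Intron-free codon-level alignment: global in the query (residues
    aligned to codons or deleted), local in the genome (free start/end),
    genomic codons skippable at ``ins_cost`` each."""
    m, n = len(q), len(g)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0
    for i in range(1, m + 1):
        for j in range(n + 1):
            best = M[i - 1][j] - del_cost
            if j >= 3:
                codon = g[j - 3 : j]
                aa = _TABLE.get(codon, "X")
                v = M[i - 1][j - 3] + blosum62(q[i - 1], aa)
                best = max(best, v)
                best = max(best, M[i][j - 3] - ins_cost)
            M[i][j] = best
    return max(M[m])


def best_single_intron(q: str, g: str, intron_open: float = 15.0,
                       min_intron: int = 20, del_cost: float = 4.0,
                       ins_cost: float = 4.0):
    """Exhaustive enumeration: best of the intron-free alignment and every
    GT..AG excision of length >= min_intron, charged ``intron_open``.

    Returns (score, intron interval or None).
    """
    best = (codon_global_local(q, g, del_cost, ins_cost), None)
    donors = [i for i in range(len(g) - 1) if g[i : i + 2] == "GT"]
    acceptors = [i for i in range(1, len(g)) if g[i - 1 : i + 1] == "AG"]
    for d in donors:
        for a in acceptors:
            end = a + 1
            if end - d < min_intron:
                continue
            spliced = g[:d] + g[end:]
            s = codon_global_local(q, spliced, del_cost, ins_cost) - intron_open
            if s > best[0]:
                best = (s, (d, end))
    return best
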