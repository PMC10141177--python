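"""Genetic-code translation and strand arithmetic.

Translation is a direct codon-table lookup so that the package's contract
holds exactly: any codon containing an ``N`` yields ``X`` (no ambiguity
resolution), stop codons render as ``*`` and a trailing partial codon is
dropped.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement as _bio_revcomp

_TABLES: dict[int, dict[str, str]] = {}


def _codon_map(table_id: int) -> dict[str, str]:
    tab = _TABLES.get(table_id)
    if tab is None:
        ct = CodonTable.unambiguous_dna_by_id[table_id]
        tab = dict(ct.forward_table)
        for stop in ct.stop_codons:
            tab[stop] = "*"
        _TABLES[table_id] = tab
    return tab


def reverse_complement(dna: str) -> str:
    return _bio_revcomp(dna)


def translate(dna: str, frame: int = 0, table: int = 1) -> str:
    """Translate ``dna`` starting at ``frame`` (0, 1 or 2).

    Codons containing characters outside {A,C,G,T} translate to ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    tab = _codon_map(table)
    s = dna[frame:]
    out = []
    for i in range(0, len(s) - 2, 3):
        out.append(tab.get(s[i : i + 3], "X"))
    return "".join(out)
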