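"""Zinc-finger motif detection and protein domain-architecture classification.

The binuclear-cluster (Zn2C6) domain is recognized by its six-cysteine
spacing motif ``C-x(2)-C-x(6)-C-x(5,16)-C-x(2)-C-x(6,8)-C``. Looser
per-pattern occurrence rules (two ``C-x(2)-C`` for Zn2C6; one each of
``C-x(2,4)-C`` and ``H-x(3,5)-H`` for C2H2) are used downstream to validate
recovered candidates.
"""

from __future__ import annotations

import re
from collections.abc import Iterable

from .types import C2H2, MHD, VALIDATION_SPECS, ZN2C6, DomainHit

# Lazy quantifiers on the variable spacers: per start position the match
# enumerated is the one with the smallest third spacer, then the smallest
# fifth spacer ("leftmost-shortest"). The lookahead makes overlapping start
# positions visible.
_ZN2C6_SCAN = re.compile(r"(?=(C.{2}C.{6}C.{5,16}?C.{2}C.{6,8}?C))")


def find_zn2c6_motif(protein: str) -> list[tuple[int, int]]:
    """All matches of the full Zn2C6 six-cysteine motif in ``protein``.

    Every start position with a match is reported; alternative spacings at
    one start are collapsed to the leftmost-shortest. ``X`` never satisfies
    a cysteine position (the pattern requires a literal ``C``).
    """
    return [
        (m.start(), m.start() + len(m.group(1)))
        for m in _ZN2C6_SCAN.finditer(protein)
    ]


def check_validation_patterns(peptide: str, domain_type: str) -> bool:
    """True iff ``peptide`` contains the required counts of conserved-residue
    patterns for ``domain_type`` (non-overlapping matches, greedy left to
    right)."""
    spec = VALIDATION_SPECS.get(domain_type)
    if spec is None:
        raise ValueError(f"no validation patterns for domain type {domain_type!r}")
    for pattern, need in zip(spec.patterns, spec.min_occurrences):
        # re.findall is non-overlapping and leftmost-first, i.e. greedy
        # left-to-right counting of disjoint occurrences.
        if len(re.findall(pattern, peptide)) < need:
            return False
    return True


def classify_architecture(hits: Iterable[DomainHit]) -> str:
    """Classify one protein's domain multiset.

    Returns one of ``"Zn2C6-MHD"``, ``"C2H2-MHD"``, ``"MHD-only"``,
    ``"other"``. A protein carrying both DBD types with an MHD counts as
    Zn2C6-MHD (the binuclear cluster takes precedence).
    """
    hits = list(hits)
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    kinds = {h.domain_type for h in hits}
    if MHD not in kinds:
        return "other"
    if ZN2C6 in kinds:
        return "Zn2C6-MHD"
    if C2H2 in kinds:
        return "C2H2-MHD"
    return "MHD-only"
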