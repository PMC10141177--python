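"""Summary tables: ortholog accounting, error-cause spectra and the
before/after redistribution of domain architectures once recovered DBDs are
reassigned.

Displayed percentages are rounded to the nearest integer; the underlying
frames keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .recovery import RecoveredDBD
from .tracking import ErrorDiagnosis

CAUSE_ORDER = ("frameshift", "assembly_split", "wrong_start", "undetermined", "none")
ARCHITECTURES = ("Zn2C6-MHD", "C2H2-MHD", "MHD-only")


def ortholog_accounting(
    n_reference_genes: int, n_strains: int, n_found: int
) -> tuple[int, int, int]:
    """(expected, missing, missing percent) ortholog counts across strains."""
    if min(n_reference_genes, n_strains, n_found) < 0:
        raise ValueError("counts must be non-negative")
    expected = n_reference_genes * n_strains
    if n_found > expected:
        raise ValueError(f"found {n_found} orthologs but expected only {expected}")
    missing = expected - n_found
    pct = round(100 * missing / expected) if expected else 0
    return expected, missing, pct


def cause_table(diagnoses) -> pd.DataFrame:
    """Counts and percentages per diagnosed cause.

    Accepts cause labels or :class:`ErrorDiagnosis` objects; percentages are
    over the total number of diagnoses.
    """
    causes = [
        d.cause if isinstance(d, ErrorDiagnosis) else str(d) for d in diagnoses
    ]
    if not causes:
        raise ValueError("no diagnoses to tabulate")
    total = len(causes)
    rows = []
    seen = set()
    for cause in list(CAUSE_ORDER) + sorted(set(causes) - set(CAUSE_ORDER)):
        n = causes.count(cause)
        if n == 0 or cause in seen:
            continue
        seen.add(cause)
        rows.append(
            {
                "cause": cause,
                "count": n,
                "percent": 100 * n / total,
                "percent_rounded": round(100 * n / total),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SummaryTable:
    """Architecture counts before and after reassigning recovered DBDs.

    Percentages are over the MHD-containing total (architectures outside
    the three MHD classes are excluded from the denominator).
    """

    before_counts: dict[str, int]
    after_counts: dict[str, int]
    before_pct: dict[str, float]
    after_pct: dict[str, float]
    denominator: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "architecture": a,
                    "before": self.before_counts.get(a, 0),
                    "after": self.after_counts.get(a, 0),
                    "before_pct": round(self.before_pct.get(a, 0.0)),
                    "after_pct": round(self.after_pct.get(a, 0.0)),
                }
                for a in ARCHITECTURES
            ]
        )


def rescue_table(
    architectures_before: dict[str, str],
    recoveries: list[RecoveredDBD],
) -> SummaryTable:
    """Reassign each accepted recovery from MHD-only to its DBD architecture.

    ``architectures_before`` maps protein id to its annotated architecture;
    a recovery for a protein that is not MHD-only is an error. The total
    protein count is conserved exactly.
    """
    before: dict[str, int] = {a: 0 for a in ARCHITECTURES}
    for arch in architectures_before.values():
        if arch in before:
            before[arch] += 1
    after = dict(before)
    reassigned: set[str] = set()
    for rec in recoveries:
        arch = architectures_before.get(rec.protein_id)
        if arch != "MHD-only":
            raise ValueError(
                f"recovery for {rec.protein_id} but its architecture is {arch!r}"
            )
        if rec.protein_id in reassigned:
            continue  # first accepted candidate wins
        reassigned.add(rec.protein_id)
        after["MHD-only"] -= 1
        after[f"{rec.dbd_type}-MHD"] += 1
    denom = sum(before.values())
    before_pct = {a: 100 * n / denom if denom else 0.0 for a, n in before.items()}
    after_pct = {a: 100 * n / denom if denom else 0.0 for a, n in after.items()}
    return SummaryTable(before, after, before_pct, after_pct, denom)
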