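"""Core domain types shared by every stage of the pipeline.

Coordinates are 0-based half-open throughout; GFF3 I/O converts to and from
the 1-based closed convention at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

DNA_ALPHABET = set("ACGTN")
# the 20 residues plus X; '*' admitted because translations of mispredicted
# gene models legitimately contain stop codons
AA_ALPHABET = set("ARNDCQEGHILKMFPSTWYVX*")

ZN2C6 = "Zn2C6"
C2H2 = "C2H2"
MHD = "MHD"
DOMAIN_TYPES = (ZN2C6, C2H2, MHD)


@dataclass(frozen=True)
class GenomeRecord:
    """A genome scaffold: id plus DNA over {A,C,G,T,N}."""

    scaffold_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"scaffold {self.scaffold_id}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"scaffold {self.scaffold_id}: illegal DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; ``source`` distinguishes reference-panel entries from queries."""

    protein_id: str
    sequence: str
    source: str = "query"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: illegal residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene model.

    ``exons`` are CDS intervals in scaffold coordinates, stored sorted in the
    5'->3' orientation of the transcript (descending scaffold coordinates on
    the minus strand).
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    protein_id: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"gene {self.gene_id}: bad exon interval [{s},{e})")
        srt = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(srt, srt[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        # normalize to transcript orientation
        self.exons = srt if self.strand == "+" else srt[::-1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint [min start, max end) on the scaffold."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass(frozen=True)
class DomainHit:
    """A domain annotation on a protein (0-based half-open protein coordinates)."""

    protein_id: str
    domain_type: str
    start: int
    end: int
    score: float = math.nan

    def __post_init__(self) -> None:
        if self.domain_type not in DOMAIN_TYPES:
            raise ValueError(f"unknown domain type {self.domain_type!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad domain interval [{self.start},{self.end})")


@dataclass(frozen=True)
class MotifSpec:
    """Spacing patterns defining a zinc-finger domain type.

    ``patterns`` are regular expressions; ``min_occurrences`` gives the
    required count of non-overlapping matches per pattern.
    """

    domain_type: str
    patterns: tuple[str, ...]
    min_occurrences: tuple[int, ...]


# Validation patterns used after profile scoring: the binuclear cluster needs
# two C-x(2)-C pairs; the classical zinc finger one C-x(2,4)-C and one
# H-x(3,5)-H.
ZN2C6_FULL_MOTIF = r"C.{2}C.{6}C.{5,16}C.{2}C.{6,8}C"
VALIDATION_SPECS = {
    ZN2C6: MotifSpec(ZN2C6, (r"C.{2}C",), (2,)),
    C2H2: MotifSpec(C2H2, (r"C.{2,4}C", r"H.{3,5}H"), (1, 1)),
}


@dataclass(frozen=True)
class Thresholds:
    """All cut-offs of the error-tracking / recovery protocol."""

    neighbor_evalue: float = 0.005       # BLASTP nearest-neighbor acceptance
    local_evalue: float = 1e-4           # translated local search acceptance
    profile_evalue: float = 0.1          # profile (HMM stand-in) acceptance
    identity_min: float = 95.0           # percent identity for diagnostic hits
    hit_len_min: int = 20                # residues, diagnostic hit length
    upstream_window: int = 1000          # nt searched upstream of the gene

    def __post_init__(self) -> None:
        if min(self.neighbor_evalue, self.local_evalue, self.profile_evalue) <= 0:
            raise ValueError("E-value thresholds must be positive")
        if not 0 < self.identity_min <= 100:
            raise ValueError("identity_min must be in (0, 100]")
        if self.hit_len_min <= 0 or self.upstream_window <= 0:
            raise ValueError("length thresholds must be positive")
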