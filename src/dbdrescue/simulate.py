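"""Synthetic fungal-like benchmark cohorts with planted annotation errors.

Each gene emulates a compact fungal zinc-cluster transcription-factor
locus: an N-terminal Zn2C6 (or C2H2) DNA-binding domain, a short linker, a
long conserved middle-homology region (a 250-residue block shared across
the cohort with per-gene divergence, so that neighbor searches have
signal) and a short tail, with 0-3 short GT-AG introns. Errors are planted
with known ground truth:

* ``frameshift``            1-2 nt inserted at a codon boundary between the
                            DBD and the MHD; the annotation covers only the
                            in-frame region downstream of the insertion.
* ``assembly_split``        the scaffold is cut inside the gene; the
                            annotated model keeps only the MHD-bearing part.
* ``wrong_start``           clean genome, annotation starts downstream of
                            the DBD.
* ``missing_upstream_exon`` the DBD sits in an upstream exon separated by
                            an intron that the annotation treats as
                            intergenic sequence.
* ``none``                  clean control with full architecture.

Spacer, linker and prefix residues are drawn cysteine-free so the planted
motif is the unique Zn2C6 match in its neighborhood and recovered peptides
can be compared to the truth exactly.

Two default profiles pin the study conditions: ``yeast_defaults``
(intronless genes, error spectrum 75% frameshift / 4% split / 18% wrong
start / 3% clean) for the reference-guided diagnosis protocol, and
``pan_fungal_defaults`` (introns allowed, planted DBD within 1000 nt
upstream, panel homologs at ~70% identity) for the DBD-recovery protocol.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_domain_tsv, write_fasta, write_gff3
from .motifs import check_validation_patterns, find_zn2c6_motif
from .seq import reverse_complement, translate
from .types import (
    C2H2,
    MHD,
    ZN2C6,
    DomainHit,
    GeneModel,
    GenomeRecord,
    ProteinRecord,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ERROR_KINDS = ("none", "frameshift", "assembly_split", "wrong_start",
               "missing_upstream_exon")

_CODONS: dict[str, list[str]] = {}


def _codons_for(aa: str) -> list[str]:
    if not _CODONS:
        from .seq import _codon_map

        for codon, a in sorted(_codon_map(1).items()):
            _CODONS.setdefault(a, []).append(codon)
    return _CODONS[aa]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; ``seed`` is mandatory for reproducibility."""

    seed: int
    n_genes: int = 200
    error_spectrum: dict[str, float] = field(
        default_factory=lambda: {
            "frameshift": 0.75, "assembly_split": 0.04,
            "wrong_start": 0.18, "none": 0.03,
        }
    )
    dbd_type: str = ZN2C6
    plant_dbd: bool = True
    intron_count_range: tuple[int, int] = (0, 3)
    intron_len_range: tuple[int, int] = (30, 80)
    upstream_dbd_distance_range: tuple[int, int] = (120, 900)
    neighbor_identity: float = 70.0
    mhd_len: int = 250
    mhd_divergence: float = 0.12
    linker_len_range: tuple[int, int] = (28, 45)
    minus_strand_prob: float = 0.5
    window: int = 1000

    def __post_init__(self) -> None:
        total = sum(self.error_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"error spectrum sums to {total}, not 1")
        unknown = set(self.error_spectrum) - set(ERROR_KINDS)
        if unknown:
            raise ValueError(f"unknown error kinds {sorted(unknown)}")

    @classmethod
    def yeast_defaults(cls, seed: int, n_genes: int = 200) -> "SimConfig":
        """Budding-yeast-like conditions: intronless genes, the observed
        error spectrum of closely related strain assemblies."""
        return cls(seed=seed, n_genes=n_genes, intron_count_range=(0, 0))

    @classmethod
    def pan_fungal_defaults(cls, seed: int, n_genes: int = 200) -> "SimConfig":
        """Broad-fungal conditions for the recovery protocol: MHD-only
        annotations whose DBD lies within 1000 nt upstream, panel homologs
        at ~70% identity, 0-3 short introns."""
        return cls(
            seed=seed,
            n_genes=n_genes,
            error_spectrum={
                "wrong_start": 0.4, "missing_upstream_exon": 0.3,
                "frameshift": 0.3,
            },
        )

    @classmethod
    def null_defaults(cls, seed: int, n_genes: int = 200) -> "SimConfig":
        """Negative-control conditions: no DBD anywhere in the genome; panel
        entries carry an unrelated DBD so the recovery machinery runs."""
        return cls(
            seed=seed, n_genes=n_genes, plant_dbd=False,
            error_spectrum={"none": 1.0},
        )


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    protein_id: str
    planted_error: str
    dbd_type: str
    true_dbd_peptide: str
    scaffold_id: str
    true_dbd_genomic_span: tuple[int, int]
    dbd_distance_nt: int  # annotated gene start to DBD start; -1 when clean


@dataclass
class GeneBundle:
    scaffolds: list[GenomeRecord]
    gene: GeneModel
    protein: ProteinRecord            # annotated (possibly truncated) protein
    domains: list[DomainHit]          # annotations of the annotated protein
    reference: ProteinRecord          # error-free full-architecture protein
    panel_protein: ProteinRecord
    panel_domains: list[DomainHit]
    truth: TruthRecord


@dataclass
class Cohort:
    config: SimConfig
    genomes: list[GenomeRecord]
    genes: list[GeneModel]
    proteome: list[ProteinRecord]
    domains: list[DomainHit]
    references: list[ProteinRecord]
    panel_proteins: list[ProteinRecord]
    panel_domains: list[DomainHit]
    truth: list[TruthRecord]
    gene_scaffolds: dict[str, list[str]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fna",
            "genes": out / "genes.gff3",
            "proteome": out / "proteome.faa",
            "domains": out / "domains.tsv",
            "references": out / "references.faa",
            "panel": out / "panel.faa",
            "panel_domains": out / "panel_domains.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta(self.genomes, paths["genome"])
        write_gff3(self.genes, paths["genes"])
        write_fasta(self.proteome, paths["proteome"])
        write_domain_tsv(self.domains, paths["domains"])
        write_fasta(self.references, paths["references"])
        write_fasta(self.panel_proteins, paths["panel"])
        write_domain_tsv(self.panel_domains, paths["panel_domains"])
        pd.DataFrame(
            [
                {
                    "gene_id": t.gene_id,
                    "protein_id": t.protein_id,
                    "planted_error": t.planted_error,
                    "dbd_type": t.dbd_type,
                    "true_dbd_peptide": t.true_dbd_peptide,
                    "scaffold_id": t.scaffold_id,
                    "dbd_start": t.true_dbd_genomic_span[0],
                    "dbd_end": t.true_dbd_genomic_span[1],
                    "dbd_distance_nt": t.dbd_distance_nt,
                }
                for t in self.truth
            ]
        ).to_csv(paths["truth"], sep="\t", index=False)
        return paths

    def sha256(self) -> str:
        h = hashlib.sha256()
        for g in self.genomes:
            h.update(g.scaffold_id.encode())
            h.update(g.sequence.encode())
        for p in self.proteome + self.panel_proteins:
            h.update(p.protein_id.encode())
            h.update(p.sequence.encode())
        return h.hexdigest()


def _sample_aa(rng, n: int, exclude: str = "") -> str:
    pool = [a for a in AA20 if a not in exclude]
    return "".join(pool[i] for i in rng.integers(0, len(pool), size=n))


def _sample_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def make_dbd(dbd_type: str, rng) -> str:
    """A peptide that constructively satisfies the domain's motif rules.

    Zn2C6: the full six-cysteine motif with spacers sampled from the allowed
    ranges (length 27-40); C2H2: one C-x(2,4)-C and one H-x(3,5)-H within
    23-28 residues. Spacer residues are cysteine-free (and histidine-free
    for C2H2) so the planted motif span is unambiguous.
    """
    if dbd_type == ZN2C6:
        s3 = int(rng.integers(5, 17))
        s5 = int(rng.integers(6, 9))
        return (
            "C" + _sample_aa(rng, 2, "C")
            + "C" + _sample_aa(rng, 6, "C")
            + "C" + _sample_aa(rng, s3, "C")
            + "C" + _sample_aa(rng, 2, "C")
            + "C" + _sample_aa(rng, s5, "C")
            + "C"
        )
    if dbd_type == C2H2:
        s1 = int(rng.integers(2, 5))
        s2 = int(rng.integers(3, 6))
        target = int(rng.integers(23, 29))
        mid = max(2, target - 4 - s1 - s2)
        return (
            "C" + _sample_aa(rng, s1, "CH")
            + "C" + _sample_aa(rng, mid, "CH")
            + "H" + _sample_aa(rng, s2, "CH")
            + "H"
        )
    raise ValueError(f"unknown dbd_type {dbd_type!r}")


def _backtranslate(protein: str, rng) -> str:
    out = []
    for aa in protein:
        codons = _codons_for(aa)
        out.append(codons[int(rng.integers(0, len(codons)))])
    return "".join(out)


def _mutate(protein: str, rate: float, rng, frozen: set[int] = frozenset()) -> str:
    chars = list(protein)
    for i in range(len(chars)):
        if i in frozen:
            continue
        if rng.random() < rate:
            alternatives = [a for a in AA20 if a != chars[i]]
            chars[i] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(chars)


def _motif_positions(dbd: str, d0: int, dbd_type: str) -> set[int]:
    """Protein positions of the anchoring residues (C, and H for C2H2)."""
    anchors = "C" if dbd_type == ZN2C6 else "CH"
    return {d0 + i for i, c in enumerate(dbd) if c in anchors}


def _clip_exons(segments, c0: int):
    """Genomic pieces of the CDS range [c0, end) given (cds_start, cds_end,
    genomic_start) segments."""
    out = []
    for cs, ce, gs in segments:
        o1 = max(cs, c0)
        if o1 < ce:
            out.append((gs + (o1 - cs), gs + (ce - cs)))
    return out


def make_gene(config: SimConfig, rng, consensus_mhd: str, index: int) -> GeneBundle:
    """Generate one gene locus with its planted error and truth labels."""
    for _attempt in range(30):
        bundle = _try_make_gene(config, rng, consensus_mhd, index)
        if bundle is not None:
            return bundle
    raise RuntimeError(f"gene {index}: could not satisfy motif constraints")


def _try_make_gene(config, rng, consensus_mhd, index):
    gid, pid, sid = f"g{index:03d}", f"p{index:03d}", f"s{index:03d}"
    kinds = sorted(config.error_spectrum)
    probs = np.array([config.error_spectrum[k] for k in kinds])
    error = kinds[int(rng.choice(len(kinds), p=probs / probs.sum()))]

    prefix = "M" + _sample_aa(rng, int(rng.integers(3, 8)), "C")
    dbd = make_dbd(config.dbd_type, rng) if config.plant_dbd else ""
    linker = _sample_aa(rng, int(rng.integers(*config.linker_len_range)), "C")
    mhd = _mutate(consensus_mhd, config.mhd_divergence, rng)
    tail = _sample_aa(rng, int(rng.integers(8, 16)), "C")
    truth_protein = prefix + dbd + linker + mhd + tail
    d0, d1 = len(prefix), len(prefix) + len(dbd)
    mhd_p0 = d1 + len(linker)
    mhd_p1 = mhd_p0 + len(mhd)

    if config.plant_dbd and find_zn2c6_motif(truth_protein[:d0]):
        return None  # pathological prefix, resample

    cds = _backtranslate(truth_protein, rng) + "TAA"

    # introns: an optional dedicated one after the DBD exon, plus 0-n inside
    # the MHD coding region, all at codon boundaries
    introns: list[tuple[int, str]] = []
    dbd_distance = -1
    p_cut = 0
    if error == "missing_upstream_exon":
        p1 = d1 + 2
        target = int(rng.integers(*config.upstream_dbd_distance_range))
        ilen = max(24, target - 3 * (p1 - d0))
        introns.append((3 * p1, "GT" + _sample_dna(rng, ilen - 4) + "AG"))
        p_cut = p1
    n_extra = int(rng.integers(config.intron_count_range[0],
                               config.intron_count_range[1] + 1))
    if n_extra:
        lo, hi = mhd_p0 + 5, mhd_p1 - 5
        positions = sorted(rng.choice(np.arange(lo, hi), size=n_extra,
                                      replace=False))
        for p in positions:
            ilen = int(rng.integers(*config.intron_len_range))
            introns.append((3 * int(p), "GT" + _sample_dna(rng, ilen - 4) + "AG"))
    introns.sort()

    pad = config.window + 600
    up_pad = _sample_dna(rng, pad + int(rng.integers(0, 200)))
    down_pad = _sample_dna(rng, pad + int(rng.integers(0, 200)))

    # assemble the plus-strand scaffold; segments map CDS to genomic coords
    pieces = [up_pad]
    segments: list[tuple[int, int, int]] = []  # (cds_start, cds_end, genomic_start)
    cursor = len(up_pad)
    prev = 0
    for cpos, iseq in introns:
        seg = cds[prev:cpos]
        segments.append((prev, cpos, cursor))
        pieces.append(seg)
        cursor += len(seg)
        pieces.append(iseq)
        cursor += len(iseq)
        prev = cpos
    segments.append((prev, len(cds), cursor))
    pieces.append(cds[prev:])
    cursor += len(cds) - prev
    pieces.append(down_pad)
    scaffold_seq = "".join(pieces)

    def cds_to_genomic(c: int) -> int:
        for cs, ce, gs in segments:
            if cs <= c <= ce:
                return gs + (c - cs)
        raise ValueError(c)

    dbd_span = (cds_to_genomic(3 * d0), cds_to_genomic(3 * d1)) if config.plant_dbd else (0, 0)

    if error in ("frameshift", "wrong_start", "assembly_split"):
        p_cut = int(rng.integers(d1 + 4, d1 + len(linker) - 6))

    scaffolds: list[tuple[str, str]] = []
    if error == "none":
        scaffolds.append((sid, scaffold_seq))
        exons = _clip_exons(segments, 0)
        gene_scaffold = sid
    elif error in ("wrong_start", "missing_upstream_exon"):
        scaffolds.append((sid, scaffold_seq))
        exons = _clip_exons(segments, 3 * p_cut)
        gene_scaffold = sid
    elif error == "frameshift":
        b = int(rng.integers(1, 3))
        g0 = cds_to_genomic(3 * p_cut)
        scaffold_seq = scaffold_seq[:g0] + _sample_dna(rng, b) + scaffold_seq[g0:]
        scaffolds.append((sid, scaffold_seq))
        exons = [(s + b, e + b) for s, e in _clip_exons(segments, 3 * p_cut)]
        gene_scaffold = sid
    elif error == "assembly_split":
        cut = cds_to_genomic(3 * p_cut)
        scaffolds.append((sid + "a", scaffold_seq[:cut]))
        scaffolds.append((sid + "b", scaffold_seq[cut:]))
        exons = [(s - cut, e - cut) for s, e in _clip_exons(segments, 3 * p_cut)]
        gene_scaffold = sid + "b"
    else:
        raise AssertionError(error)

    annotated = truth_protein[p_cut:]
    if error != "none" and config.plant_dbd and find_zn2c6_motif(annotated):
        return None  # planted error failed to remove the motif, resample
    if error == "none" and config.plant_dbd and not find_zn2c6_motif(annotated):
        return None

    if config.plant_dbd and p_cut > 0:
        gene_start = exons[0][0]
        dbd_distance = gene_start - dbd_span[0]
        if error == "assembly_split":
            dbd_distance = -1  # DBD on a different scaffold

    strand = "+"
    if rng.random() < config.minus_strand_prob:
        strand = "-"
        flipped = []
        for scaf_id, seq in scaffolds:
            flipped.append((scaf_id, reverse_complement(seq)))
        lengths = {scaf_id: len(seq) for scaf_id, seq in scaffolds}
        Lg = lengths[gene_scaffold]
        exons = [(Lg - e, Lg - s) for s, e in exons]
        dbd_scaffold = scaffolds[0][0] if error == "assembly_split" else gene_scaffold
        Ld = lengths[dbd_scaffold]
        dbd_span = (Ld - dbd_span[1], Ld - dbd_span[0])
        scaffolds = flipped

    gene = GeneModel(gid, gene_scaffold, strand, exons, pid)
    protein = ProteinRecord(pid, annotated)
    domains = [DomainHit(pid, MHD, mhd_p0 - p_cut, mhd_p1 - p_cut)]
    if error == "none" and config.plant_dbd:
        domains.append(DomainHit(pid, config.dbd_type, d0, d1))

    # full-architecture panel homolog at the configured identity
    rate = 1.0 - config.neighbor_identity / 100.0
    ref_id = f"{pid}|ref"
    if config.plant_dbd:
        frozen = _motif_positions(dbd, d0, config.dbd_type)
        panel_seq = _mutate(truth_protein, rate, rng, frozen)
        panel_domains = [
            DomainHit(ref_id, config.dbd_type, d0, d1),
            DomainHit(ref_id, MHD, mhd_p0, mhd_p1),
        ]
    else:
        decoy = make_dbd(config.dbd_type, rng)
        panel_seq = (
            truth_protein[:1] + decoy + _mutate(truth_protein[1:], rate, rng)
        )
        shift = len(decoy)
        panel_domains = [
            DomainHit(ref_id, config.dbd_type, 1, 1 + shift),
            DomainHit(ref_id, MHD, mhd_p0 + shift, mhd_p1 + shift),
        ]
    if config.dbd_type == C2H2 and config.plant_dbd:
        seg = panel_seq[d0:d1]
        if not check_validation_patterns(seg, C2H2):
            return None

    dbd_scaffold_id = scaffolds[0][0] if error == "assembly_split" else gene_scaffold
    truth = TruthRecord(
        gene_id=gid,
        protein_id=pid,
        planted_error=error,
        dbd_type=config.dbd_type if config.plant_dbd else "",
        true_dbd_peptide=dbd,
        scaffold_id=dbd_scaffold_id,
        true_dbd_genomic_span=dbd_span,
        dbd_distance_nt=dbd_distance,
    )
    return GeneBundle(
        scaffolds=[GenomeRecord(i, s) for i, s in scaffolds],
        gene=gene,
        protein=protein,
        domains=domains,
        reference=ProteinRecord(f"{pid}|truth", truth_protein),
        panel_protein=ProteinRecord(ref_id, panel_seq, source="reference_panel"),
        panel_domains=panel_domains,
        truth=truth,
    )


def make_cohort(config: SimConfig, outdir: str | Path | None = None) -> Cohort:
    """Generate a full cohort; byte-identical across runs with equal seed."""
    rng = np.random.default_rng(config.seed)
    consensus = _sample_aa(rng, config.mhd_len)
    while find_zn2c6_motif(consensus):
        consensus = _sample_aa(rng, config.mhd_len)
    genomes: list[GenomeRecord] = []
    genes: list[GeneModel] = []
    proteome: list[ProteinRecord] = []
    domains: list[DomainHit] = []
    references: list[ProteinRecord] = []
    panel_proteins: list[ProteinRecord] = []
    panel_domains: list[DomainHit] = []
    truth: list[TruthRecord] = []
    gene_scaffolds: dict[str, list[str]] = {}
    for i in range(config.n_genes):
        b = make_gene(config, rng, consensus, i)
        genomes.extend(b.scaffolds)
        genes.append(b.gene)
        proteome.append(b.protein)
        domains.extend(b.domains)
        references.append(b.reference)
        panel_proteins.append(b.panel_protein)
        panel_domains.extend(b.panel_domains)
        truth.append(b.truth)
        gene_scaffolds[b.gene.gene_id] = [s.scaffold_id for s in b.scaffolds]
    cohort = Cohort(
        config=config,
        genomes=genomes,
        genes=genes,
        proteome=proteome,
        domains=domains,
        references=references,
        panel_proteins=panel_proteins,
        panel_domains=panel_domains,
        truth=truth,
        gene_scaffolds=gene_scaffolds,
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort
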