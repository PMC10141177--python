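"""End-to-end runners tying the generator, diagnostics and recovery together.

These functions operate on an in-memory :class:`~dbdrescue.simulate.Cohort`
(or equivalent parsed inputs) and return per-gene result rows suitable for
summary tables: the screening step (does the annotated protein carry the
motif?) gates the reference-guided diagnosis, mirroring the protocol in
which only motif-less orthologs are investigated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import DEFAULT_PARAMS, ScoringParams
from .motifs import classify_architecture, find_zn2c6_motif
from .recovery import (
    FailureReport,
    RecoveredDBD,
    build_profile,
    build_reference_panel,
    cterm_control,
    recover_dbd,
)
from .simulate import Cohort
from .tracking import ErrorDiagnosis, diagnose
from .types import Thresholds


@dataclass
class TrackingResult:
    gene_id: str
    protein_id: str
    planted: str
    called: str
    diagnosis: ErrorDiagnosis | None


def run_error_tracking(
    cohort: Cohort,
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[TrackingResult]:
    """Screen annotated proteins for the Zn2C6 motif and diagnose the
    motif-less ones against their own assembly scaffolds."""
    by_id = {g.scaffold_id: g for g in cohort.genomes}
    results = []
    for gene, protein, reference, truth in zip(
        cohort.genes, cohort.proteome, cohort.references, cohort.truth
    ):
        if find_zn2c6_motif(protein.sequence):
            results.append(
                TrackingResult(gene.gene_id, protein.protein_id,
                               truth.planted_error, "none", None)
            )
            continue
        assembly = [by_id[s] for s in cohort.gene_scaffolds[gene.gene_id]]
        diag = diagnose(reference, assembly, thresholds, params)
        results.append(
            TrackingResult(gene.gene_id, protein.protein_id,
                           truth.planted_error, diag.cause, diag)
        )
    return results


@dataclass
class RecoveryResult:
    gene_id: str
    protein_id: str
    planted: str
    outcome: RecoveredDBD | FailureReport
    true_peptide: str

    @property
    def accepted(self) -> bool:
        return isinstance(self.outcome, RecoveredDBD)

    @property
    def exact(self) -> bool:
        return self.accepted and self.outcome.peptide == self.true_peptide


def run_recovery(
    cohort: Cohort,
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[RecoveryResult]:
    """Run the rescue protocol for every MHD-only protein in the cohort."""
    panel = build_reference_panel(
        cohort.panel_proteins, cohort.panel_domains, cohort.config.dbd_type
    )
    profile = build_profile(panel)
    genome = {g.scaffold_id: g for g in cohort.genomes}
    domains_by_protein: dict[str, list] = {}
    for h in cohort.domains:
        domains_by_protein.setdefault(h.protein_id, []).append(h)
    results = []
    for gene, protein, truth in zip(cohort.genes, cohort.proteome, cohort.truth):
        doms = domains_by_protein.get(protein.protein_id, [])
        if classify_architecture(doms) != "MHD-only":
            continue
        outcome = recover_dbd(
            gene, protein, genome, panel, thresholds, params,
            profile=profile, domains=doms,
        )
        results.append(
            RecoveryResult(gene.gene_id, protein.protein_id,
                           truth.planted_error, outcome, truth.true_dbd_peptide)
        )
    return results


def run_cterm_control(
    cohort: Cohort,
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[tuple[str, RecoveredDBD | None]]:
    """Apply the recovery machinery downstream of the MHD of every protein
    (false-positive control); returns (protein_id, hit-or-None) pairs."""
    panel = build_reference_panel(
        cohort.panel_proteins, cohort.panel_domains, cohort.config.dbd_type
    )
    profile = build_profile(panel)
    genome = {g.scaffold_id: g for g in cohort.genomes}
    domains_by_protein: dict[str, list] = {}
    for h in cohort.domains:
        domains_by_protein.setdefault(h.protein_id, []).append(h)
    out = []
    for gene, protein in zip(cohort.genes, cohort.proteome):
        doms = domains_by_protein.get(protein.protein_id, [])
        hit = cterm_control(
            gene, protein, genome, panel, thresholds, params,
            profile=profile, domains=doms,
        )
        out.append((protein.protein_id, hit))
    return out
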