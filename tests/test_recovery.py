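"""The DBD rescue protocol: panel, context, neighbor search, recovery."""

from __future__ import annotations

import numpy as np
import pytest

from dbdrescue.motifs import find_zn2c6_motif
from dbdrescue.recovery import (
    FailureReport,
    RecoveredDBD,
    build_profile,
    build_reference_panel,
    cterm_control,
    extract_genomic_context,
    find_nearest_neighbor,
    protein_to_forward,
    recover_dbd,
)
from dbdrescue.seq import reverse_complement
from dbdrescue.simulate import SimConfig, make_cohort, make_dbd
from dbdrescue.types import (
    DomainHit,
    GeneModel,
    GenomeRecord,
    ProteinRecord,
    Thresholds,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(AA20[i] for i in rng.integers(0, 20, n))


def _panel_inputs(rng, n_full=10, n_mhd_only=3):
    proteins, hits = [], []
    for i in range(n_full):
        pid = f"full{i}"
        seq = "M" + make_dbd("Zn2C6", rng) + _random_protein(rng, 260)
        proteins.append(ProteinRecord(pid, seq, source="reference_panel"))
        hits.append(DomainHit(pid, "Zn2C6", 1, 1 + len(make_dbd("Zn2C6", rng))))
        hits.append(DomainHit(pid, "MHD", 60, 260))
    for i in range(n_mhd_only):
        pid = f"only{i}"
        proteins.append(ProteinRecord(pid, _random_protein(rng, 260)))
        hits.append(DomainHit(pid, "MHD", 10, 250))
    return proteins, hits


class TestPanel:
    def test_filter_semantics(self):
        rng = np.random.default_rng(50)
        proteins, hits = _panel_inputs(rng)
        panel = build_reference_panel(proteins, hits, "Zn2C6")
        assert len(panel.entries) == 10
        assert all(e.protein.protein_id.startswith("full") for e in panel.entries)

    def test_empty_panel_is_error(self):
        rng = np.random.default_rng(51)
        proteins, hits = _panel_inputs(rng)
        with pytest.raises(ValueError):
            build_reference_panel(proteins, hits, "C2H2")

    def test_dual_dbd_protein_goes_to_zn2c6_panel_only(self):
        rng = np.random.default_rng(52)
        pid = "dual"
        seq = "M" + make_dbd("Zn2C6", rng) + make_dbd("C2H2", rng) + _random_protein(rng, 230)
        proteins = [ProteinRecord(pid, seq)]
        hits = [
            DomainHit(pid, "Zn2C6", 1, 30),
            DomainHit(pid, "C2H2", 35, 60),
            DomainHit(pid, "MHD", 70, 230),
        ]
        panel = build_reference_panel(proteins, hits, "Zn2C6")
        assert len(panel.entries) == 1
        with pytest.raises(ValueError):
            build_reference_panel(proteins, hits, "C2H2")


class TestContext:
    SCAF = None

    @staticmethod
    def _scaffold(rng, n=8000):
        return GenomeRecord("s", "".join("ACGT"[i] for i in rng.integers(0, 4, n)))

    def test_plus_strand_window(self):
        scaf = self._scaffold(np.random.default_rng(53))
        gene = GeneModel("g", "s", "+", [(5000, 6200)], "p")
        ctx = extract_genomic_context(gene, scaf, window=1000)
        assert (ctx.fwd_start, ctx.fwd_end) == (4000, 6200)
        assert ctx.offset == 1000
        assert ctx.sequence == scaf.sequence[4000:6200]

    def test_scaffold_start_clamp(self):
        scaf = self._scaffold(np.random.default_rng(54))
        gene = GeneModel("g", "s", "+", [(200, 800)], "p")
        ctx = extract_genomic_context(gene, scaf, window=1000)
        assert ctx.fwd_start == 0 and ctx.offset == 200

    def test_minus_strand_reverse_complement(self):
        scaf = self._scaffold(np.random.default_rng(55))
        gene = GeneModel("g", "s", "-", [(5000, 6200)], "p")
        ctx = extract_genomic_context(gene, scaf, window=1000)
        assert (ctx.fwd_start, ctx.fwd_end) == (5000, 7200)
        assert ctx.offset == 1000
        assert ctx.sequence == reverse_complement(scaf.sequence[5000:7200])
        # coordinate mapping round-trips
        assert ctx.to_forward(ctx.to_context((5100, 5200))) == (5100, 5200)

    def test_protein_to_forward_minus_strand(self):
        gene = GeneModel("g", "s", "-", [(100, 160), (40, 70)], "p")
        # first 10 residues -> last 30 nt of the high-coordinate exon
        assert protein_to_forward(gene, (0, 10)) == [(130, 160)]
        # residues spanning the junction
        pieces = protein_to_forward(gene, (15, 25))
        assert pieces == [(100, 115), (55, 70)]


class TestNearestNeighbor:
    def _panel(self, rng):
        proteins, hits = _panel_inputs(rng)
        return build_reference_panel(proteins, hits, "Zn2C6")

    def test_mutated_copy_finds_its_source(self):
        rng = np.random.default_rng(56)
        panel = self._panel(rng)
        src = panel.entries[3].protein
        chars = list(src.sequence)
        for k in range(0, len(chars), 10):  # ~90% identity
            chars[k] = "A" if chars[k] != "A" else "G"
        query = ProteinRecord("q", "".join(chars))
        entry, hit = find_nearest_neighbor(query, panel)
        assert entry.protein.protein_id == src.protein_id
        assert hit.evalue < 0.005

    def test_random_query_finds_nothing(self):
        rng = np.random.default_rng(57)
        panel = self._panel(rng)
        assert find_nearest_neighbor(ProteinRecord("q", _random_protein(rng, 40)),
                                     panel) is None

    def test_tie_broken_lexicographically(self):
        rng = np.random.default_rng(58)
        seq = "M" + make_dbd("Zn2C6", rng) + _random_protein(rng, 200)
        hits = []
        proteins = []
        for pid in ("B", "A"):
            proteins.append(ProteinRecord(pid, seq, source="reference_panel"))
            hits.append(DomainHit(pid, "Zn2C6", 1, 28))
            hits.append(DomainHit(pid, "MHD", 50, 200))
        panel = build_reference_panel(proteins, hits, "Zn2C6")
        entry, _ = find_nearest_neighbor(ProteinRecord("q", seq), panel)
        assert entry.protein.protein_id == "A"


def _recover_inputs(cohort):
    from dbdrescue.recovery import build_profile, build_reference_panel

    panel = build_reference_panel(cohort.panel_proteins, cohort.panel_domains,
                                  cohort.config.dbd_type)
    profile = build_profile(panel)
    genome = {g.scaffold_id: g for g in cohort.genomes}
    domains = {}
    for h in cohort.domains:
        domains.setdefault(h.protein_id, []).append(h)
    return panel, profile, genome, domains


class TestRecovery:
    def test_truncated_annotation_recovers_planted_dbd(self, small_recovery_cohort):
        c = small_recovery_cohort
        panel, profile, genome, domains = _recover_inputs(c)
        hits = 0
        for gene, protein, truth in zip(c.genes, c.proteome, c.truth):
            res = recover_dbd(gene, protein, genome, panel,
                              profile=profile, domains=domains[protein.protein_id])
            if isinstance(res, RecoveredDBD):
                hits += 1
                assert res.patterns_ok
                assert res.peptide == truth.true_dbd_peptide
                # reported genomic span matches the planted location
                assert res.scaffold_id == truth.scaffold_id
                assert res.genomic_span == truth.true_dbd_genomic_span
        assert hits >= len(c.genes) - 1

    def test_too_distant_dbd_reported(self):
        cfg = SimConfig(
            seed=61, n_genes=6, intron_count_range=(0, 0),
            error_spectrum={"missing_upstream_exon": 1.0},
            upstream_dbd_distance_range=(1400, 1600),
        )
        c = make_cohort(cfg)
        panel, profile, genome, domains = _recover_inputs(c)
        for gene, protein in zip(c.genes, c.proteome):
            res = recover_dbd(gene, protein, genome, panel,
                              profile=profile, domains=domains[protein.protein_id])
            assert isinstance(res, FailureReport)
            assert res.reason in ("too_distant", "low_similarity")

    def test_n_region_reported(self, small_recovery_cohort):
        c = small_recovery_cohort
        panel, profile, genome, domains = _recover_inputs(c)
        truth = c.truth[0]
        gene, protein = c.genes[0], c.proteome[0]
        scaf = genome[gene.scaffold_id]
        s, e = truth.true_dbd_genomic_span
        masked = dict(genome)
        masked[gene.scaffold_id] = GenomeRecord(
            scaf.scaffold_id,
            scaf.sequence[:s] + "N" * (e - s) + scaf.sequence[e:],
        )
        res = recover_dbd(gene, protein, masked, panel,
                          profile=profile, domains=domains[protein.protein_id])
        assert isinstance(res, FailureReport)
        assert res.reason == "n_region"

    def test_missing_scaffold_reported(self, small_recovery_cohort):
        c = small_recovery_cohort
        panel, profile, genome, domains = _recover_inputs(c)
        gene, protein = c.genes[0], c.proteome[0]
        res = recover_dbd(gene, protein, {}, panel,
                          profile=profile, domains=domains[protein.protein_id])
        assert isinstance(res, FailureReport)
        assert res.reason == "no_genomic_sequence"

    def test_strand_invariance(self, small_recovery_cohort):
        """Reverse-complementing a scaffold and flipping the gene strand
        yields the identical recovered peptide."""
        c = small_recovery_cohort
        panel, profile, genome, domains = _recover_inputs(c)
        gene, protein = c.genes[0], c.proteome[0]
        res1 = recover_dbd(gene, protein, genome, panel,
                           profile=profile, domains=domains[protein.protein_id])
        scaf = genome[gene.scaffold_id]
        L = len(scaf)
        flipped_genome = dict(genome)
        flipped_genome[gene.scaffold_id] = GenomeRecord(
            scaf.scaffold_id, reverse_complement(scaf.sequence)
        )
        flipped_gene = GeneModel(
            gene.gene_id, gene.scaffold_id,
            "-" if gene.strand == "+" else "+",
            [(L - e, L - s) for s, e in gene.exons],
            gene.protein_id,
        )
        res2 = recover_dbd(flipped_gene, protein, flipped_genome, panel,
                           profile=profile, domains=domains[protein.protein_id])
        assert isinstance(res1, RecoveredDBD) and isinstance(res2, RecoveredDBD)
        assert res1.peptide == res2.peptide
        s1 = res1.genomic_span
        assert res2.genomic_span == (L - s1[1], L - s1[0])

    def test_non_mhd_only_query_rejected(self, small_recovery_cohort):
        c = small_recovery_cohort
        panel, profile, genome, _ = _recover_inputs(c)
        pid = c.proteome[0].protein_id
        bad = [DomainHit(pid, "Zn2C6", 0, 28), DomainHit(pid, "MHD", 60, 200)]
        with pytest.raises(ValueError):
            recover_dbd(c.genes[0], c.proteome[0], genome, panel,
                        profile=profile, domains=bad)


class TestCtermControl:
    def test_clean_genes_give_no_hit(self, small_recovery_cohort):
        c = small_recovery_cohort
        panel, profile, genome, domains = _recover_inputs(c)
        hits = 0
        for gene, protein in zip(c.genes, c.proteome):
            res = cterm_control(gene, protein, genome, panel,
                                profile=profile, domains=domains[protein.protein_id])
            hits += res is not None
        assert hits == 0

    def test_planted_downstream_decoy_is_caught(self, small_recovery_cohort):
        c = small_recovery_cohort
        panel, profile, genome, domains = _recover_inputs(c)
        # pick a plus-strand gene and splice a DBD coding sequence into its
        # downstream intergenic region
        idx = next(i for i, g in enumerate(c.genes) if g.strand == "+")
        gene, protein, truth = c.genes[idx], c.proteome[idx], c.truth[idx]
        rng = np.random.default_rng(62)
        from dbdrescue.simulate import _backtranslate

        decoy_cds = _backtranslate(truth.true_dbd_peptide, rng)
        scaf = genome[gene.scaffold_id]
        pos = gene.span[1] + 300
        doctored = dict(genome)
        doctored[gene.scaffold_id] = GenomeRecord(
            scaf.scaffold_id,
            scaf.sequence[:pos] + decoy_cds + scaf.sequence[pos:],
        )
        res = cterm_control(gene, protein, doctored, panel,
                            profile=profile, domains=domains[protein.protein_id])
        assert isinstance(res, RecoveredDBD)
        assert find_zn2c6_motif(res.peptide)

    def test_empty_downstream_region_gives_none(self, small_recovery_cohort):
        c = small_recovery_cohort
        panel, profile, genome, domains = _recover_inputs(c)
        idx = next(i for i, g in enumerate(c.genes) if g.strand == "+")
        gene, protein = c.genes[idx], c.proteome[idx]
        # truncate the scaffold right at the MHD end so nothing lies downstream
        mhd = [h for h in domains[protein.protein_id] if h.domain_type == "MHD"][0]
        pieces = protein_to_forward(gene, (mhd.start, mhd.end))
        scaf = genome[gene.scaffold_id]
        end = max(p[1] for p in pieces)
        cut = dict(genome)
        cut[gene.scaffold_id] = GenomeRecord(scaf.scaffold_id,
                                             scaf.sequence[: end + 1])
        res = cterm_control(gene, protein, cut, panel,
                            profile=profile, domains=domains[protein.protein_id])
        assert res is None


class TestProfile:
    def test_true_dbd_scores_far_above_null(self, small_recovery_cohort):
        c = small_recovery_cohort
        panel, profile, _, _ = _recover_inputs(c)
        for truth in c.truth[:5]:
            ev = profile.evalue(profile.score(truth.true_dbd_peptide))
            assert ev < 0.01

    def test_random_peptide_not_significant(self, small_recovery_cohort):
        panel, profile, _, _ = _recover_inputs(small_recovery_cohort)
        rng = np.random.default_rng(63)
        sig = sum(
            profile.evalue(profile.score(_random_protein(rng, 35))) < 0.1
            for _ in range(50)
        )
        assert sig <= 10
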