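"""Local protein alignment, translated search and score statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dbdrescue.align import (
    DEFAULT_PARAMS,
    evalue,
    local_align_protein,
    translated_search,
)
from dbdrescue.seq import reverse_complement, translate
from dbdrescue.types import GenomeRecord, ProteinRecord

from oracles import gotoh_local_score

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(AA20[i] for i in rng.integers(0, 20, n))


def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestLocalAlign:
    def test_self_alignment(self):
        rng = np.random.default_rng(2)
        seq = _random_protein(rng, 50)
        hit = local_align_protein(ProteinRecord("a", seq), ProteinRecord("b", seq))
        assert hit.identity == 100.0
        assert hit.aligned_length == 50

    def test_exact_substring(self):
        query = ProteinRecord("q", "MKTAYIAKQR")
        target = ProteinRecord("t", "WWWWWMKTAYIAKQRWWWWW")
        hit = local_align_protein(query, target)
        assert hit.identity == 100.0
        assert hit.query_span == (0, 10)
        assert hit.target_span == (5, 15)

    def test_score_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = ProteinRecord("a", _random_protein(rng, int(rng.integers(10, 60))))
            b = ProteinRecord("b", _random_protein(rng, int(rng.integers(10, 60))))
            ha, hb = local_align_protein(a, b), local_align_protein(b, a)
            assert (ha is None) == (hb is None)
            if ha is not None:
                assert ha.score == hb.score

    def test_matches_gotoh_oracle(self):
        """Optimal local score equals an independent affine-gap DP oracle
        on random short pairs."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = _random_protein(rng, int(rng.integers(5, 31)))
            b = _random_protein(rng, int(rng.integers(5, 31)))
            hit = local_align_protein(ProteinRecord("a", a), ProteinRecord("b", b))
            expected = gotoh_local_score(a, b)
            got = hit.score if hit is not None else 0.0
            assert got == pytest.approx(expected)


class TestTranslatedSearch:
    def test_exact_back_mapping(self):
        rng = np.random.default_rng(5)
        dna = _random_dna(rng, 600)
        interval = (120, 120 + 150)
        query = ProteinRecord("q", translate(dna[interval[0]: interval[1]]))
        hits = translated_search(query, GenomeRecord("s", dna))
        top = hits[0]
        assert top.identity == 100.0
        assert top.strand == "+" and top.frame == interval[0] % 3
        assert top.target_span == interval

    def test_reverse_strand_back_mapping(self):
        rng = np.random.default_rng(6)
        dna = _random_dna(rng, 600)
        interval = (200, 200 + 120)
        query = ProteinRecord(
            "q", translate(reverse_complement(dna[interval[0]: interval[1]]))
        )
        hits = translated_search(query, GenomeRecord("s", dna))
        top = hits[0]
        assert top.identity == 100.0
        assert top.strand == "-"
        assert top.target_span == interval

    def test_all_n_genome_yields_nothing(self):
        query = ProteinRecord("q", "MKTAYIAKQRMKTAYIAKQR")
        assert translated_search(query, GenomeRecord("s", "N" * 300)) == []

    def test_frameshift_yields_two_frames(self):
        """Inserting 1 or 2 nt (never 3) inside a coding region splits the
        translated hits across reading frames on one scaffold."""
        rng = np.random.default_rng(8)
        for _ in range(30):
            prot = _random_protein(rng, 80)
            cds = "".join(
                {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
                 "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
                 "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
                 "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}[a]
                for a in prot
            )
            pos = int(rng.integers(90, 150))
            ins = _random_dna(rng, int(rng.integers(1, 3)))
            dna = _random_dna(rng, 100) + cds[:pos] + ins + cds[pos:] + _random_dna(rng, 100)
            hits = translated_search(ProteinRecord("q", prot), GenomeRecord("s", dna))
            from dbdrescue.tracking import _qualifying
            from dbdrescue.types import Thresholds

            strong = _qualifying(hits, Thresholds())
            frames = {(h.strand, h.frame) for h in strong}
            assert len(frames) >= 2


class TestEvalue:
    def test_monotone_in_score(self):
        assert evalue(100, 300, 1_000_000) < evalue(50, 300, 1_000_000)

    def test_zero_score_closed_form(self):
        p = DEFAULT_PARAMS
        assert evalue(0, 200, 5000, p) == pytest.approx(p.ka_k * 200 * 5000)

    def test_hand_computed(self):
        p = DEFAULT_PARAMS
        expected = 0.041 * 100 * 10_000 * math.exp(-0.267 * 60)
        assert evalue(60, 100, 10_000, p) == pytest.approx(expected)
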