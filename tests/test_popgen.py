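import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladon.codes import STANDARD
from cladon.io import CladeMap, CodonAlignment, GeneRecord, ValidationError
from cladon.popgen import (
    group_popgen,
    jukes_cantor,
    ng86_pair,
    ng86_pathway_diffs,
    ng86_site_counts,
    segregating_sites_and_pi,
    tajimas_d,
)


def _aln(*seqs):
    return CodonAlignment(
        tuple(GeneRecord(f"s{i + 1}", s) for i, s in enumerate(seqs))
    )


class TestDiversity:
    def test_two_sequences_one_difference(self):
        # 12 compared sites, 1 difference -> pi_site = 1/12
        s = segregating_sites_and_pi(_aln("ATGAAATTTGGG", "ATGAAATTTGGC"))
        assert s.S == 1
        assert s.pi_site == pytest.approx(1 / 12)

    def test_three_sequence_hand_count(self):
        # per 3-site block {AAA, AAT, ATT}: pair differences 1+2+1 -> 4/3
        s = segregating_sites_and_pi(_aln("AAA", "AAT", "ATT"))
        assert s.S == 2
        assert s.pi_total == pytest.approx(4 / 3)
        assert s.pi_site == pytest.approx(4 / 9)
        assert s.theta_w == pytest.approx(2 / 1.5)

    def test_identical_sequences(self):
        s = segregating_sites_and_pi(_aln(*["ATGAAA"] * 4))
        assert s.S == 0 and s.pi_site == 0.0
        assert s.tajima_d is None and s.tajima_d_reason == "S=0"

    def test_pair_too_small_for_tajima(self):
        s = segregating_sites_and_pi(_aln("ATGAAA", "ATGAAG"))
        assert s.tajima_d is None and s.tajima_d_reason == "n<4"

    def test_complete_deletion(self):
        # gap column removed from comparison for every sequence
        s = segregating_sites_and_pi(_aln("ATG-AATTT", "ATGCAATTC"))
        assert s.L == 8 and s.S == 1

    def test_single_sequence_rejected(self):
        with pytest.raises(ValidationError):
            segregating_sites_and_pi(_aln("ATG"))


def _tajima_oracle(n, S, pi_total):
    """Independent spelling of Tajima (1989): variance assembled from the
    raw harmonic sums without intermediate c/e constants."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    e1 = (b1 - 1 / a1) / a1
    e2 = (b2 - (n + 2) / (a1 * n) + a2 / a1**2) / (a1**2 + a2)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_frozen_four_sequence_example(self):
        # n=4, S=3, pi_total=10/6: frozen via the independent oracle
        d, reason = tajimas_d(4, 3, 10 / 6)
        assert reason == ""
        assert d == pytest.approx(_tajima_oracle(4, 3, 10 / 6), abs=1e-12)
        assert d == pytest.approx(0.168, abs=2e-3)

    def test_undefined_cases(self):
        assert tajimas_d(10, 0, 0.0) == (None, "S=0")
        assert tajimas_d(3, 5, 2.0) == (None, "n<4")

    @given(
        st.integers(4, 60),
        st.integers(1, 200),
        st.floats(0.0, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_oracle(self, n, S, pi_total):
        d, _ = tajimas_d(n, S, pi_total)
        assert d == pytest.approx(_tajima_oracle(n, S, pi_total), abs=1e-9)


class TestNG86Sites:
    def test_phe_and_met(self):
        assert ng86_site_counts("TTT") == pytest.approx((1 / 3, 8 / 3))
        assert ng86_site_counts("ATG") == pytest.approx((0.0, 3.0))

    def test_sites_sum_to_three_for_all_sense_codons(self):
        for codon in STANDARD.sense_codons:
            s, n = ng86_site_counts(codon)
            assert s + n == pytest.approx(3.0)
            assert 0 <= s <= 3

    def test_stop_codon_rejected(self):
        with pytest.raises(ValidationError):
            ng86_site_counts("TAA")


class TestNG86Pathways:
    def test_single_difference(self):
        assert ng86_pathway_diffs("TTT", "TTA") == (0.0, 1.0, False)

    def test_identity(self):
        assert ng86_pathway_diffs("AAA", "AAA") == (0.0, 0.0, False)

    def test_two_difference_average(self):
        # TTT->GTA via GTT (nonsyn+syn) or TTA (nonsyn+nonsyn)
        sd, nd, skip = ng86_pathway_diffs("TTT", "GTA")
        assert (sd, nd, skip) == (0.5, 1.5, False)

    def test_symmetry(self):
        for a, b in [("TTT", "GTA"), ("ATG", "CGC"), ("AAA", "TTT")]:
            assert ng86_pathway_diffs(a, b) == ng86_pathway_diffs(b, a)

    def test_diff_count_conserved_across_all_pairs(self):
        """Pathway-averaged Sd+Nd equals the raw nucleotide difference count
        for every included sense-codon pair (exhaustive oracle)."""
        for a, b in itertools.product(STANDARD.sense_codons, repeat=2):
            ndiff = sum(x != y for x, y in zip(a, b))
            sd, nd, skip = ng86_pathway_diffs(a, b)
            if skip:
                assert ndiff >= 2  # only multi-step pairs can be stop-locked
            else:
                assert sd + nd == pytest.approx(ndiff)

    def test_include_stop_paths_variant(self):
        # with stop-including averaging no pair is ever excluded
        for a, b in itertools.product(STANDARD.sense_codons, repeat=2):
            sd, nd, skip = ng86_pathway_diffs(a, b, include_stop_paths=True)
            assert not skip
            assert sd + nd == pytest.approx(sum(x != y for x, y in zip(a, b)))


class TestNG86Pair:
    def test_identical_sequences(self):
        a = GeneRecord("a", "ATGAAATTTGGG")
        b = GeneRecord("b", "ATGAAATTTGGG")
        r = ng86_pair(a, b)
        assert r.dN == 0.0 and r.dS == 0.0 and r.omega is None

    def test_jukes_cantor_closed_form(self):
        assert jukes_cantor(0.3) == pytest.approx(0.3831, abs=1e-4)
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.75) is None

    def test_symmetric_in_arguments(self):
        a = GeneRecord("a", "ATGAAATTTGGGCATCGA")
        b = GeneRecord("b", "ATGAAGTTCGGACACCGC")
        ra, rb = ng86_pair(a, b), ng86_pair(b, a)
        assert ra.Sd == rb.Sd and ra.Nd == rb.Nd
        assert ra.dS == rb.dS and ra.dN == rb.dN

    def test_gapped_codons_dropped_pairwise(self):
        a = GeneRecord("a", "ATG---TTT")
        b = GeneRecord("b", "ATGAAATTC")
        r = ng86_pair(a, b)
        assert r.n_codons_compared == 2 and r.n_codons_excluded == 1

    def test_monotone_in_divergence(self):
        ps = [0.05, 0.1, 0.2, 0.4]
        ds = [jukes_cantor(p) for p in ps]
        assert all(x < y for x, y in zip(ds, ds[1:]))


class TestGroupPopgen:
    def test_one_summary_per_group(self, tiny_alignment):
        out = group_popgen(
            tiny_alignment, CladeMap.from_alignment(tiny_alignment), "clade"
        )
        assert [s.group_id for s in out] == ["c1", "c2"]
        assert all(s.n == 2 for s in out)

    def test_identical_group_zero_pi(self):
        aln = _aln("ATGAAA", "ATGAAA", "ATGAAA")
        cm = CladeMap(
            clade_of={"s1": "x", "s2": "x", "s3": "x"}, order_of={}
        )
        (s,) = group_popgen(aln, cm, "clade")
        assert s.pi_site == 0.0

    def test_empty_grouping_rejected(self):
        # no labels anywhere -> no usable group
        aln = _aln("ATGAAA", "ATGAAG", "ATGAAC")
        with pytest.raises(ValidationError):
            group_popgen(aln, CladeMap(), "order")
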