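"""Marker statistics: frequencies, unbiased gene diversity, exact HWE tests."""

import math

import numpy as np
import pytest

import tdrive as td
from tdrive.popgen import MarkerGenotype, hwe_exact_test, summarize_all


def mk(pairs, t_class="WT", locus="L"):
    return [MarkerGenotype(f"i{i}", t_class, locus, a, b)
            for i, (a, b) in enumerate(pairs)]


class TestFrequenciesAndHeterozygosity:
    def test_allele_frequencies_worked_example(self):
        # 15 +/+ mice at D17Mit28 with allele counts 7, 2, 11, 10
        pairs = [("1", "1")] * 3 + [("1", "3")] * 1 + [("2", "3")] * 2 + \
                [("3", "3")] * 4 + [("4", "4")] * 5
        freqs = td.allele_frequencies(mk(pairs))
        assert freqs == pytest.approx(
            {"1": 7 / 30, "2": 2 / 30, "3": 11 / 30, "4": 10 / 30})

    def test_single_homozygote(self):
        assert td.allele_frequencies(mk([("A", "A")])) == {"A": 1.0}

    def test_generated_frequencies_match_generator(self):
        loci = [td.LocusConfig("L", {"WT": [0.6, 0.4]})]
        g = td.simulate_marker_genotypes(
            td.MarkerSimConfig(loci=loci, n_per_class={"WT": 2000}, seed=9))
        freqs = td.allele_frequencies(g)
        assert freqs["1"] == pytest.approx(0.6, abs=0.02)

    @pytest.mark.parametrize(
        "freqs,n,expected",
        [
            ([0.500, 0.036, 0.464], 14, 0.553),   # MHC Aalpha, +/t group
            ([0.233, 0.067, 0.367, 0.333], 15, 0.720),  # D17Mit28, +/+ group
            ([1.0], 10, 0.0),                     # monomorphic
        ],
    )
    def test_unbiased_expected_het(self, freqs, n, expected):
        assert td.unbiased_expected_het(freqs, n) == pytest.approx(expected, abs=5e-4)

    def test_unbiased_estimator_approaches_gene_diversity(self):
        p = [0.5, 0.3, 0.2]
        plain = 1 - sum(x * x for x in p)
        assert abs(td.unbiased_expected_het(p, 10**6) - plain) < 1e-5

    def test_observed_het(self):
        assert td.observed_het(mk([("A", "B"), ("A", "B")])) == 1.0
        assert td.observed_het(mk([("A", "A"), ("B", "B")])) == 0.0

    def test_observed_het_hw_draw(self):
        loci = [td.LocusConfig("L", {"WT": [0.5, 0.5]})]
        g = td.simulate_marker_genotypes(
            td.MarkerSimConfig(loci=loci, n_per_class={"WT": 4000}, seed=4))
        assert td.observed_het(g) == pytest.approx(0.5, abs=0.025)

    def test_table_frequency_back_conversion(self):
        assert td.counts_from_frequencies([0.500, 0.036, 0.464], 14) == [14, 1, 13]
        assert td.counts_from_frequencies([0.233, 0.067, 0.367, 0.333], 15) == \
            [7, 2, 11, 10]
        with pytest.raises(ValueError):
            td.counts_from_frequencies([0.9, 0.1], 2)  # 3.6 copies of allele 1

    def test_printed_heterozygosity_table_reproduced(self):
        # the six printed per-locus/per-group H_exp values, from printed
        # frequencies back-converted to integer allele counts
        printed = [
            ([0.233, 0.067, 0.367, 0.333], 15, 0.720),       # D17Mit28 +/+
            ([0.500, 0.036, 0.107, 0.250, 0.107], 14, 0.688),  # D17Mit28 +/t
            ([0.167, 0.067, 0.768], 15, 0.393),              # Aalpha +/+
            ([0.500, 0.036, 0.464], 14, 0.553),              # Aalpha +/t
            ([0.067, 0.233, 0.700], 15, 0.467),              # Ebeta +/+
            ([0.500, 0.107, 0.036, 0.357], 14, 0.632),       # Ebeta +/t
        ]
        for freqs, n, expected in printed:
            counts = td.counts_from_frequencies(freqs, n)
            exact = [c / (2 * n) for c in counts]
            assert round(td.unbiased_expected_het(exact, n), 3) == expected


class TestHweExact:
    def test_all_heterozygotes_strong_excess(self):
        gs = mk([("A", "a")] * 14)
        res = hwe_exact_test(gs, alternative="excess")
        # oracle: only one array (all heterozygotes) has 14 hets, so the
        # one-sided p equals its conditional probability
        # (n!/g_Aa!) 2^h a_A! a_a! / (2n)! = 2^14 14! 14! / 28!
        p_oracle = math.exp(
            14 * math.log(2) + 2 * math.lgamma(15) - math.lgamma(29))
        assert "enumeration" in res.method
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)

    def test_monomorphic_locus(self):
        res = hwe_exact_test(mk([("A", "A")] * 5))
        assert res.p_value == 1.0 and "monomorphic" in res.method

    def test_monte_carlo_agrees_with_enumeration_small_samples(self):
        # every configuration with <= 8 individuals and <= 3 alleles that
        # we spot-check: MC must agree with enumeration within MC error
        configs = [
            [("A", "a")] * 4 + [("A", "A")] * 2 + [("a", "a")] * 2,
            [("A", "A")] * 3 + [("a", "a")] * 3,
            [("A", "B")] * 2 + [("B", "C")] * 3 + [("A", "C")] * 3,
            [("A", "A"), ("A", "B"), ("B", "C"), ("C", "C"), ("A", "C")],
        ]
        for pairs in configs:
            gs = mk(pairs)
            exact = hwe_exact_test(gs)
            assert "enumeration" in exact.method
            mc = hwe_exact_test(gs, max_enumeration=0, n_permutations=20000,
                                seed=11)
            se = math.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
            assert mc.p_value == pytest.approx(exact.p_value,
                                               abs=max(4 * se, 0.01))

    def test_enumeration_probabilities_sum_to_one(self):
        from tdrive.popgen import _enumerate_arrays, _log_prob
        acounts = {"A": 5, "B": 4, "C": 3}
        total = sum(math.exp(_log_prob(arr, acounts))
                    for arr in _enumerate_arrays(acounts))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_null_calibration(self):
        # HW-equilibrium draws: p-values roughly uniform
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(300):
            a = rng.random((40, 2)) < 0.5
            gs = mk([("A" if x else "B", "A" if y else "B") for x, y in a])
            ps.append(hwe_exact_test(gs).p_value)
        assert 0.02 < np.mean(np.asarray(ps) < 0.05) < 0.09
        assert np.mean(ps) > 0.4


class TestFishersMethod:
    def test_known_value(self):
        res = td.fishers_method([0.5] * 21)
        assert res.statistic == pytest.approx(-2 * 21 * math.log(0.5), rel=1e-12)
        assert res.df == 42

    def test_all_ones(self):
        assert td.fishers_method([1.0, 1.0]).statistic == 0.0

    def test_single_p_round_trip(self):
        p = 0.163
        res = td.fishers_method([p])
        assert res.statistic == pytest.approx(-2 * math.log(p), rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            td.fishers_method([0.0, 0.5])


class TestDifferentiation:
    def test_identical_groups_nonsignificant(self):
        pairs = [("A", "B")] * 5 + [("A", "A")] * 5 + [("B", "B")] * 5
        gs = mk(pairs, "WT") + mk(pairs, "HET")
        res = td.differentiation_exact_test(gs, n_permutations=2000, seed=0)
        assert res["L"].p_value > 0.5

    def test_disjoint_allele_sets_near_minimum(self):
        gs = mk([("A", "B")] * 5, "WT") + mk([("C", "D")] * 5, "HET")
        res = td.differentiation_exact_test(gs, n_permutations=5000, seed=0)
        assert res["L"].p_value < 0.01

    def test_t_linked_private_allele_detected(self, marker_genotypes):
        res = td.differentiation_exact_test(marker_genotypes,
                                            n_permutations=5000, seed=0)
        # both t-linked loci carry a private allele at frequency 0.5 in the
        # +/t class: differentiation must be strong, and the global
        # combination stronger than any neutral locus alone
        assert res["D17Mit28"].p_value < 0.01
        assert res["Aalpha"].p_value < 0.01
        assert res["global"].p_value < 0.001


class TestSummaries:
    def test_t_linked_locus_summary(self, marker_genotypes):
        summaries = {(s.locus, s.group): s for s in summarize_all(
            marker_genotypes, seed=1)}
        s = summaries[("D17Mit28", "HET")]
        assert s.h_obs == 1.0
        assert s.direction == "excess"
        assert s.n == 14
        wt = summaries[("D17Mit28", "WT")]
        assert "1" not in wt.alleles  # t allele private to +/t mice
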