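import itertools
import random

import numpy as np
import pytest

from conftest import enumerate_mwu, kw_h_formula
from vdjbias.clonotypes import UsageProfile
from vdjbias.locus import ZoneAssignment
from vdjbias.stats import (
    StatsError,
    kruskal_wallis,
    low_ric_effect,
    mann_whitney,
    rank_correlation,
    significance_stars,
    zone_bias_report,
)


def _profile(freqs: dict[str, float], segment="V", samples=("s1",)):
    per_sample = {s: {segment: dict(freqs), ("J" if segment == "V" else "V"): {}} for s in samples}
    return UsageProfile(frequencies=per_sample, basis="unique_clonotypes")


class TestKruskalWallis:
    def test_textbook_three_groups(self):
        res = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert res.statistic == pytest.approx(7.2)
        assert 0 < res.p_value < 0.05

    def test_no_variation_gives_zero_h(self):
        res = kruskal_wallis([5, 5], [5, 5], [5])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            kruskal_wallis([1, 2], [])

    def test_h_matches_rank_formula_on_random_inputs(self):
        rng = random.Random(11)
        for _ in range(50):
            k = rng.randint(2, 4)
            groups = [
                [rng.randint(0, 8) for _ in range(rng.randint(1, 4))] for _ in range(k)
            ]
            if sum(len(g) for g in groups) < 3:
                continue
            if len({v for g in groups for v in g}) < 2:
                continue
            res = kruskal_wallis(*groups)
            assert res.statistic == pytest.approx(kw_h_formula(groups), abs=1e-10)

    def test_two_group_h_is_squared_normalized_mwu(self):
        # for two tie-free groups, KW H equals the square of the
        # standardized U statistic (chi-square(1) form)
        rng = random.Random(12)
        for _ in range(20):
            n1, n2 = rng.randint(2, 3), rng.randint(2, 3)
            vals = rng.sample(range(100), n1 + n2)
            a, b = vals[:n1], vals[n1:]
            h = kruskal_wallis(a, b).statistic
            u = mann_whitney(a, b).statistic
            mu, var = n1 * n2 / 2, n1 * n2 * (n1 + n2 + 1) / 12
            assert h == pytest.approx((u - mu) ** 2 / var, abs=1e-10)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_midpoint_u(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n1*n2/2

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1])

    @pytest.mark.parametrize("alternative", ["two_sided", "less", "greater"])
    def test_exact_p_matches_enumeration(self, alternative):
        rng = random.Random(13)
        for _ in range(40):
            n1 = rng.randint(1, 4)
            n2 = rng.randint(1, 8 - n1)
            vals = rng.sample(range(1000), n1 + n2)
            a, b = vals[:n1], vals[n1:]
            res = mann_whitney(a, b, alternative=alternative)
            u, p = enumerate_mwu(a, b, alternative=alternative)
            assert res.statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)


class TestRankCorrelation:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, p = rank_correlation(x, [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = rank_correlation(x, [50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_rho_matches_hand_rank_formula(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 0.5, 9.0, 2.5, 6.0]
        # tie-free: rho = 1 - 6*sum(d^2)/(n(n^2-1)) on ranks
        rx = [3, 1, 4, 2, 5]
        ry = [2, 1, 5, 3, 4]
        d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
        expected = 1 - 6 * d2 / (5 * 24)
        rho, _ = rank_correlation(x, y)
        assert rho == pytest.approx(expected)

    def test_permutation_p_is_seeded_and_sane(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=10)
        y = x + rng.normal(scale=0.1, size=10)
        rho1, p1 = rank_correlation(x, y, seed=42)
        rho2, p2 = rank_correlation(x, y, seed=42)
        assert (rho1, p1) == (rho2, p2)
        assert p1 < 0.01  # strong monotone association

    def test_constant_vector_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            rank_correlation([1, 1, 1], [1, 2, 3])


class TestSignificanceStars:
    def test_star_conventions(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == ""


def _zone_assignment(zones):
    return ZoneAssignment(analysis="V-to-D1", zones=zones, boundaries=(0.0, 0.0))


class TestZoneBiasReport:
    def test_constructed_proximal_dominance(self):
        zones = {}
        freqs = {}
        scores = {}
        rng = np.random.default_rng(15)
        for i in range(6):
            zones[f"P{i}"] = "proximal"
            freqs[f"P{i}"] = 0.10 + 0.001 * rng.random()
            zones[f"M{i}"] = "middle"
            freqs[f"M{i}"] = 0.05 + 0.001 * rng.random()
            zones[f"D{i}"] = "distal"
            freqs[f"D{i}"] = 0.01 + 0.001 * rng.random()
            for z in ("P", "M", "D"):
                scores[f"{z}{i}"] = -40 + rng.random()
        total = sum(freqs.values())
        freqs = {g: f / total for g, f in freqs.items()}
        rep = zone_bias_report(_profile(freqs), _zone_assignment(zones), scores)
        assert rep.frequency_ordering == "P>M>D"
        assert rep.kruskal.p_value < 0.01
        assert rep.pairwise["D-vs-M"].p_value < 0.05

    def test_zone_means_match_brute_force(self):
        zones = {"a": "distal", "b": "distal", "c": "middle", "d": "proximal"}
        freqs = {"a": 0.4, "b": 0.2, "c": 0.3, "d": 0.1}
        scores = {"a": -40.0, "b": -42.0, "c": -30.0, "d": -50.0}
        rep = zone_bias_report(_profile(freqs), _zone_assignment(zones), scores)
        assert rep.zone_mean_frequency["distal"] == pytest.approx((0.4 + 0.2) / 2)
        assert rep.zone_mean_ric["distal"] == pytest.approx(-41.0)
        assert rep.frequency_ordering == "D>M>P"
        assert rep.ric_ordering == "M>D>P"

    def test_flat_frequencies_flagged_non_significant(self):
        zones = {f"g{i}": z for i, z in enumerate(["distal", "middle", "proximal"] * 3)}
        freqs = {g: 1 / 9 for g in zones}
        scores = {g: -40.0 for g in zones}
        rep = zone_bias_report(_profile(freqs), _zone_assignment(zones), scores)
        assert rep.kruskal.statistic == 0.0
        assert any("not significant" in f for f in rep.flags)

    def test_invariant_to_gene_ordering(self):
        zones = {"a": "distal", "b": "middle", "c": "proximal", "d": "middle"}
        freqs = {"a": 0.4, "b": 0.2, "c": 0.3, "d": 0.1}
        scores = {"a": -40.0, "b": -42.0, "c": -30.0, "d": -50.0}
        r1 = zone_bias_report(_profile(freqs), _zone_assignment(zones), scores)
        rev = _zone_assignment(dict(reversed(list(zones.items()))))
        r2 = zone_bias_report(_profile(freqs), rev, scores)
        assert r1.to_dict() == r2.to_dict()

    def test_missing_score_rejected(self):
        zones = {"a": "distal", "b": "middle", "c": "proximal"}
        freqs = {"a": 0.5, "b": 0.3, "c": 0.2}
        with pytest.raises(StatsError, match="a"):
            zone_bias_report(_profile(freqs), _zone_assignment(zones), {"b": -1.0, "c": -2.0})


class TestLowRICEffect:
    def test_constructed_separation_is_significant(self):
        freqs, scores = {}, {}
        for i in range(5):
            freqs[f"low{i}"] = 0.001 + i * 1e-5
            scores[f"low{i}"] = -50.0 - i
        for i in range(7):
            freqs[f"ok{i}"] = 0.05 + i * 1e-4
            scores[f"ok{i}"] = -40.0 + i * 0.1
        total = sum(freqs.values())
        freqs = {g: f / total for g, f in freqs.items()}
        res = low_ric_effect(_profile(freqs), scores)
        assert res.testable
        assert res.test.p_value < 0.05
        assert res.mean_frequency_very_low < res.mean_frequency_normal

    def test_no_gene_below_threshold_not_testable(self):
        freqs = {"a": 0.5, "b": 0.5}
        scores = {"a": -40.0, "b": -30.0}
        res = low_ric_effect(_profile(freqs), scores)
        assert not res.testable and res.test is None

    def test_type_one_error_calibrated_under_label_shuffle(self):
        # permuting scores against frequencies: rejection at 0.05 stays
        # near or below nominal (the one-sided exact test is conservative)
        rng = np.random.default_rng(16)
        genes = [f"g{i}" for i in range(24)]
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            freqs = rng.dirichlet(np.ones(24))
            scores = np.concatenate([rng.normal(-50, 1, 5), rng.normal(-40, 1, 19)])
            rng.shuffle(scores)
            res = low_ric_effect(
                _profile(dict(zip(genes, freqs))), dict(zip(genes, scores))
            )
            if res.testable and res.test.p_value < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.09
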