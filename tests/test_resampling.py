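"""Permutation ANOVA, interaction ANOVA, chi-squared, classical tests."""

import numpy as np
import pytest
from scipy import stats

from oblfp.resampling import (
    chi2_proportions,
    interaction_anova,
    permutation_anova,
    two_sample_test,
)


class TestPermutationAnova:
    def test_identical_constant_groups(self):
        res = permutation_anova([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]], n_perm=100, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_disjoint_5v5(self):
        res = permutation_anova(
            [[1, 2, 3, 4, 5], [10, 11, 12, 13, 14]], exhaustive=True
        )
        assert res.n_perm == 252
        assert res.p_value == pytest.approx(2.0 / 252.0)

    def test_statistic_matches_scipy_f(self, rng):
        groups = [rng.normal(size=8), rng.normal(1.0, 1.0, 7), rng.normal(size=9)]
        res = permutation_anova(groups, n_perm=50, seed=0)
        assert res.statistic == pytest.approx(stats.f_oneway(*groups).statistic)

    def test_seeded_determinism(self, rng):
        groups = [rng.normal(size=10), rng.normal(size=10)]
        p1 = permutation_anova(groups, n_perm=500, seed=42).p_value
        p2 = permutation_anova(groups, n_perm=500, seed=42).p_value
        assert p1 == p2

    def test_add_one_rule_floor(self, rng):
        res = permutation_anova(
            [rng.normal(10, 0.1, 10), rng.normal(0, 0.1, 10)], n_perm=200, seed=1
        )
        assert res.p_value == pytest.approx(1.0 / 201.0)

    def test_null_type1_error_calibrated(self, rng):
        # reduced Monte Carlo; full calibration runs in the validation suite
        rej = 0
        n_sims = 200
        for _ in range(n_sims):
            res = permutation_anova(
                [rng.standard_normal(10), rng.standard_normal(10)],
                n_perm=200,
                seed=int(rng.integers(2**31)),
            )
            rej += res.p_value <= 0.05
        assert rej / n_sims == pytest.approx(0.05, abs=0.04)


class TestInteractionAnova:
    @staticmethod
    def _design(n):
        g = np.repeat(["control", "opsin"], 2 * n)
        l = np.tile(np.repeat(["pre", "laser"], n), 2)
        return g, l

    def test_additive_null_calibrated(self, rng):
        n, rej, n_sims = 10, 0, 200
        g, l = self._design(n)
        for _ in range(n_sims):
            v = (
                rng.standard_normal(4 * n)
                + np.where(g == "opsin", 1.0, 0.0)
                + np.where(l == "laser", -0.5, 0.0)
            )
            rej += interaction_anova(v, g, l).p_value <= 0.05
        assert rej / n_sims == pytest.approx(0.05, abs=0.05)

    def test_crossed_effect_power_matches_noncentral_f(self, rng):
        # one-cell shift delta at n/cell: interaction noncentrality
        # lambda = n * delta^2 / 4; empirical power should track it
        n, delta, alpha, n_sims = 30, 1.0, 0.01, 120
        g, l = self._design(n)
        lam = n * delta**2 / 4.0
        crit = stats.f.isf(alpha, 1, 4 * n - 4)
        power = stats.ncf.sf(crit, 1, 4 * n - 4, lam)
        hits = 0
        for _ in range(n_sims):
            v = rng.standard_normal(4 * n)
            v[(g == "opsin") & (l == "laser")] += delta
            hits += interaction_anova(v, g, l).p_value < alpha
        assert hits / n_sims == pytest.approx(power, abs=0.12)

    def test_invariant_to_main_effects(self, rng):
        n = 12
        g, l = self._design(n)
        v = rng.standard_normal(4 * n)
        f0 = interaction_anova(v, g, l).statistic
        shifted = v + np.where(g == "opsin", 3.0, 0.0) + np.where(l == "laser", -2.0, 0.0)
        f1 = interaction_anova(shifted, g, l).statistic
        assert f1 == pytest.approx(f0, rel=1e-8)

    def test_constant_cells_give_p_one(self):
        g, l = self._design(3)
        with pytest.warns(UserWarning):
            res = interaction_anova(np.ones(12), g, l)
        assert res.p_value == 1.0

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="cells"):
            interaction_anova(
                [1.0, 2.0, 3.0],
                ["control", "control", "opsin"],
                ["pre", "laser", "pre"],
            )

    def test_permutation_variant_agrees_with_analytic(self, rng):
        n = 15
        g, l = self._design(n)
        v = rng.standard_normal(4 * n)
        v[(g == "opsin") & (l == "laser")] += 1.2
        p_analytic = interaction_anova(v, g, l).p_value
        p_perm = interaction_anova(v, g, l, n_perm=400, seed=3).p_value
        assert (p_analytic < 0.05) == (p_perm < 0.05)


class TestChi2Proportions:
    def test_hand_computed_example(self):
        res = chi2_proportions(90, 100, 50, 100)
        assert res.statistic == pytest.approx(38.095, abs=0.01)
        assert res.p_value < 1e-9

    def test_equal_proportions(self):
        res = chi2_proportions(50, 100, 50, 100)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_degenerate_zero_margin(self):
        res = chi2_proportions(0, 50, 0, 50)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chi2_proportions(5, 3, 1, 10)


class TestTwoSample:
    def test_paired_identical_gives_p_one(self):
        res = two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="paired_t")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_support_ranksum(self, rng):
        res = two_sample_test(
            rng.uniform(10, 11, 20), rng.uniform(0, 1, 20), method="ranksum"
        )
        assert res.p_value < 1e-6

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError, match="equal-length"):
            two_sample_test([1.0, 2.0], [1.0], method="paired_t")

    def test_ranksum_power_tracks_direct_simulation(self, rng):
        # rank-sum rejection rate at a 1 SD shift, vs its own Monte Carlo
        n_sims = 150
        rej = sum(
            two_sample_test(
                rng.normal(1, 1, 30), rng.normal(0, 1, 30)
            ).p_value < 0.05
            for _ in range(n_sims)
        ) / n_sims
        # theoretical power of the rank-sum at d=1, n=30 is ~0.96
        assert rej == pytest.approx(0.96, abs=0.07)
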