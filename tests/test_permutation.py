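"""Permutation GLM engine: OLS oracles, enumeration oracles, Smith identities."""

import numpy as np
import pytest
import statsmodels.api as sm

from cardiodiv import (
    exact_interaction_test,
    exact_two_group_test,
    interaction_test,
    ols_fit,
    smith_orthogonalize,
    two_group_test,
)
from cardiodiv.permutation import RankDeficiencyError


def interaction_design(i_n, i_m):
    return np.column_stack([i_n, i_m, i_n * i_m]).astype(float)


def balanced_groups(per_group):
    i_n = np.repeat([1, 0, 1], per_group)
    i_m = np.repeat([0, 1, 1], per_group)
    return i_n, i_m


class TestOlsFit:
    def test_exact_interpolation(self, rng):
        X = rng.normal(size=(12, 3))
        b = np.array([0.5, -1.2, 2.0])
        fit = ols_fit(X, X @ b)
        np.testing.assert_allclose(fit.coefficients, b, atol=1e-10)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-10)

    def test_intercept_only_gives_mean(self, rng):
        y = rng.normal(size=9)
        fit = ols_fit(np.ones((9, 1)), y)
        assert fit.coefficients[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_statsmodels(self, rng):
        """Independent OLS cross-check on a random over-determined system."""
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        fit = ols_fit(X, y)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.fitted, ref.fittedvalues, atol=1e-10)

    def test_saturated_interaction_closed_form(self, rng):
        i_n, i_m = balanced_groups(5)
        y = rng.normal(size=15)
        fit = ols_fit(interaction_design(i_n, i_m), y, ("i_n", "i_m", "inter"))
        only_n = y[(i_n == 1) & (i_m == 0)].mean()
        only_m = y[(i_n == 0) & (i_m == 1)].mean()
        double = y[(i_n == 1) & (i_m == 1)].mean()
        assert fit.coefficient("inter") == pytest.approx(
            double - only_n - only_m, abs=1e-10
        )

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(25, 3))
        fit = ols_fit(X, rng.normal(size=25))
        for j in range(3):
            col = X[:, j] / np.linalg.norm(X[:, j])
            assert abs(col @ fit.residuals) < 1e-8

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(RankDeficiencyError, match="collinear"):
            ols_fit(X, np.zeros(6), ("a", "b"))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ols_fit(np.ones((5, 1)), np.zeros(4))


class TestSmithOrthogonalize:
    def test_idempotent_when_already_orthogonal(self):
        nuisance = np.column_stack([np.ones(4)])
        z = np.array([1.0, -1.0, 1.0, -1.0])
        np.testing.assert_allclose(smith_orthogonalize(nuisance, z), z, atol=1e-12)

    def test_zero_when_in_span(self):
        nuisance = np.column_stack([np.ones(5), np.arange(5.0)])
        z = 2.0 + 3.0 * np.arange(5.0)
        np.testing.assert_allclose(
            smith_orthogonalize(nuisance, z), np.zeros(5), atol=1e-10
        )

    def test_matches_projection_oracle(self):
        """z* on the balanced three-genotype design vs an independent
        normal-equations projection."""
        i_n, i_m = balanced_groups(4)
        N = np.column_stack([i_n, i_m]).astype(float)
        z = (i_n * i_m).astype(float)
        z_star = smith_orthogonalize(N, z)
        proj = N @ np.linalg.inv(N.T @ N) @ N.T @ z
        np.testing.assert_allclose(z_star, z - proj, atol=1e-10)
        np.testing.assert_allclose(N.T @ z_star, 0, atol=1e-10)

    def test_rank_deficient_nuisance(self):
        N = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(RankDeficiencyError):
            smith_orthogonalize(N, np.arange(6.0))


class TestTwoGroup:
    def test_constant_response_p_one(self):
        res = two_group_test(np.ones(8), np.repeat([0, 1], 4), 500, seed=1)
        assert res.p_value == 1.0
        assert res.exceed_count == 500

    def test_exact_enumeration_hand_case(self):
        """y=(0,0,1,1) vs groups (0,0,1,1): of the C(4,2)=6 assignments only
        the observed one attains the maximal mean difference, so p = 1/6."""
        y = np.array([0.0, 0.0, 1.0, 1.0])
        g = np.array([0, 0, 1, 1])
        res = exact_two_group_test(y, g)
        assert res.observed_stat == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 6)

    def test_reversed_labels_mirror(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        res = exact_two_group_test(y, np.array([1, 1, 0, 0]))
        assert res.observed_stat == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_p_value_formula_edge(self):
        # strongly separated groups: no permuted slope can exceed the observed
        y = np.concatenate([np.zeros(6), np.ones(6)])
        g = np.repeat([0, 1], 6)
        res = two_group_test(y, g, 999, seed=3)
        # observed is the unique maximum but ties occur whenever a permutation
        # reproduces the split; p = (ties + 1)/(N + 1) >= 1/(N+1)
        assert res.p_value == (res.exceed_count + 1) / 1000

    def test_observed_stat_is_ols_slope(self, rng):
        y = rng.normal(size=14)
        g = rng.permutation(np.repeat([0, 1], 7))
        res = two_group_test(y, g, 10, seed=0)
        X = np.column_stack([np.ones(14), g])
        assert res.observed_stat == pytest.approx(
            ols_fit(X, y).coefficients[1], abs=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            two_group_test(np.ones(4), np.zeros(4, dtype=int), 10, seed=0)
        with pytest.raises(ValueError):
            two_group_test(np.ones(4), np.array([0, 0, 1, 1]), 0, seed=0)

    def test_seed_determinism(self, rng):
        y = rng.normal(size=10)
        g = np.repeat([0, 1], 5)
        a = two_group_test(y, g, 2000, seed=42)
        b = two_group_test(y, g, 2000, seed=42)
        assert a == b
        c = two_group_test(y, g, 20000, seed=43)
        d = two_group_test(y, g, 20000, seed=44)
        se = np.sqrt(c.p_value * (1 - c.p_value) / 20000)
        assert abs(c.p_value - d.p_value) < 4 * se + 1e-9


class TestInteraction:
    def test_additive_response_zero_coefficient(self):
        i_n, i_m = balanced_groups(3)
        a, b = 0.2, 0.5
        y = a * i_n + b * i_m  # double group mean is exactly a + b
        res = interaction_test(y, i_n, i_m, 99, seed=0)
        assert res.observed_stat == pytest.approx(0.0, abs=1e-12)

    def test_group_mean_construction(self, rng):
        """beta3 equals the super-additive increment delta by construction."""
        i_n, i_m = balanced_groups(4)
        a, b, delta = 0.1, 0.3, 0.25
        means = a * i_n + b * i_m + delta * i_n * i_m
        res = interaction_test(means, i_n, i_m, 99, seed=0)
        assert res.observed_stat == pytest.approx(delta, abs=1e-12)

    def test_constant_response_p_one(self):
        i_n, i_m = balanced_groups(3)
        res = interaction_test(np.full(9, 0.4), i_n, i_m, 299, seed=5)
        assert res.p_value == 1.0

    def test_fwl_identity(self, rng):
        """beta3 from the joint fit equals <z*, y>/<z*, z*>."""
        i_n, i_m = balanced_groups(5)
        y = rng.normal(size=15)
        X = interaction_design(i_n, i_m)
        beta3 = ols_fit(X, y, ("n", "m", "nm")).coefficient("nm")
        z_star = smith_orthogonalize(X[:, :2], X[:, 2])
        assert beta3 == pytest.approx((z_star @ y) / (z_star @ z_star), abs=1e-10)

    def test_empty_group_error(self):
        i_n = np.array([1, 1, 0, 0])
        i_m = np.array([0, 0, 1, 1])  # no (1,1) group
        with pytest.raises(ValueError, match="empty"):
            interaction_test(np.zeros(4), i_n, i_m, 10, seed=0)

    def test_seed_determinism(self, rng):
        i_n, i_m = balanced_groups(4)
        y = rng.normal(size=12)
        a = interaction_test(y, i_n, i_m, 3000, seed=7)
        b = interaction_test(y, i_n, i_m, 3000, seed=7)
        assert a == b

    def test_four_group_variant_with_baseline(self, rng):
        """Intercept model over four groups: b3 is the interaction contrast
        of group means, and (0,0) embryos are required."""
        i_n = np.repeat([0, 1, 0, 1], 4)
        i_m = np.repeat([0, 0, 1, 1], 4)
        y = rng.normal(size=16)
        res = interaction_test(y, i_n, i_m, 99, seed=0, include_baseline=True)
        g = lambda a, b: y[(i_n == a) & (i_m == b)].mean()
        expected = g(1, 1) - g(1, 0) - g(0, 1) + g(0, 0)
        assert res.observed_stat == pytest.approx(expected, abs=1e-10)
        with pytest.raises(ValueError, match="baseline"):
            interaction_test(y[4:], i_n[4:], i_m[4:], 99, seed=0,
                             include_baseline=True)


class TestExactOracles:
    def test_exact_two_group_constant(self):
        res = exact_two_group_test(np.ones(6), np.repeat([0, 1], 3))
        assert res.p_value == 1.0

    def test_budget_exceeded(self):
        with pytest.raises(ValueError, match="budget"):
            exact_two_group_test(np.zeros(30), np.repeat([0, 1], 15),
                                 max_assignments=1000)

    def test_exact_interaction_constant(self):
        i_n = np.array([1, 1, 0, 0, 1, 1])
        i_m = np.array([0, 0, 1, 1, 1, 1])
        res = exact_interaction_test(np.full(6, 0.2), i_n, i_m)
        assert res.p_value == 1.0
        assert res.n_permutations == 720

    def test_too_many_embryos(self):
        i_n, i_m = np.repeat([1, 0, 1], 3), np.repeat([0, 1, 1], 3)
        with pytest.raises(ValueError, match="enumeration limit"):
            exact_interaction_test(np.zeros(9), i_n, i_m)

    def test_monte_carlo_agrees_with_enumeration_two_group(self, rng):
        """Monte-Carlo p within 3 SE of the exact p on random small samples."""
        for _ in range(10):
            n1 = int(rng.integers(2, 5))
            n0 = int(rng.integers(2, 5))
            y = rng.normal(size=n0 + n1)
            g = rng.permutation(np.repeat([0, 1], [n0, n1]))
            exact = exact_two_group_test(y, g)
            mc = two_group_test(y, g, 20000, seed=int(rng.integers(2**31)))
            se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
            assert abs(mc.p_value - exact.p_value) <= 3 * se + 1e-4

    def test_monte_carlo_agrees_with_enumeration_interaction(self, rng):
        i_n = np.array([1, 1, 0, 0, 1, 1])
        i_m = np.array([0, 0, 1, 1, 1, 1])
        for _ in range(5):
            y = rng.normal(size=6)
            exact = exact_interaction_test(y, i_n, i_m)
            mc = interaction_test(y, i_n, i_m, 20000,
                                  seed=int(rng.integers(2**31)))
            se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
            assert abs(mc.p_value - exact.p_value) <= 3 * se + 1e-4
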