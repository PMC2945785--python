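"""GLM likelihood-ratio tests and pooled permutation inference.

Poisson and Gaussian fits are cross-checked against statsmodels (an
independent route to the same likelihoods); permutation p-values are
checked against brute-force exceedance counting.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from rnadiff.de_stats import (
    ModelSpec,
    NullStatistics,
    design_matrix,
    fit_and_lrt,
    lrt_all,
    permutation_pvalues,
    permute_null,
)
from rnadiff.normalize import NormalizationFactors


def factors_of(q):
    q = np.asarray(q, dtype=float)
    return NormalizationFactors([f"s{j}" for j in range(len(q))], q)


LAB4 = ["A", "A", "B", "B"]


class TestDesignMatrix:
    def test_two_group_term_mode_columns(self):
        f = factors_of([1.0, 2.0, 3.0, 4.0])
        spec = ModelSpec(norm_mode="term")
        d = design_matrix(LAB4, f, spec)
        assert d.X_full.shape == (4, 3) and d.df == 1
        np.testing.assert_allclose(d.X_full[:, 1], np.log(f.values))
        np.testing.assert_allclose(d.X_full[:, 2], [0, 0, 1, 1])
        assert d.X_null.shape == (4, 2)  # intercept + log q only

    def test_continuous_outcome_single_column(self):
        f = factors_of([1.0, 1.0, 1.0, 1.0])
        d = design_matrix([0.1, 0.5, 0.7, 0.9], f, ModelSpec(norm_mode="term", outcome="continuous"))
        # constant log q is dropped with a warning: intercept + y only
        np.testing.assert_allclose(d.X_full[:, -1], [0.1, 0.5, 0.7, 0.9])
        assert d.df == 1

    def test_k_groups_give_k_minus_1_columns(self):
        f = factors_of(np.ones(6))
        d = design_matrix(["A", "B", "C", "A", "B", "C"], f, ModelSpec())
        assert d.df == 2 and d.X_full.shape[1] == 3

    def test_single_level_outcome_is_no_contrast_error(self):
        with pytest.raises(ValueError, match="contrast"):
            design_matrix(["A", "A", "A"], factors_of(np.ones(3)), ModelSpec())

    def test_offset_mode_puts_log_q_in_offset_not_columns(self):
        f = factors_of([1.0, 2.0, 3.0, 4.0])
        d = design_matrix(LAB4, f, ModelSpec(norm_mode="offset"))
        assert d.X_full.shape == (4, 2)
        np.testing.assert_allclose(d.offset, np.log(f.values))


class TestPoissonLRT:
    def test_two_group_closed_form_deviance(self):
        # group MLEs are the group means: D = 2[22 log(11/20) + 58 log(29/20)]
        d = design_matrix(LAB4, factors_of(np.ones(4)), ModelSpec())
        res = fit_and_lrt([10, 12, 30, 28], d, ModelSpec())
        expect = 2 * (22 * np.log(11 / 20) + 58 * np.log(29 / 20))
        assert res.D == pytest.approx(expect, abs=1e-6)

    def test_empty_group_zero_counts_closed_form(self):
        d = design_matrix(LAB4, factors_of(np.ones(4)), ModelSpec())
        res = fit_and_lrt([0, 0, 5, 5], d, ModelSpec())
        assert res.D == pytest.approx(2 * 10 * np.log(2), abs=1e-6)

    def test_constant_counts_give_zero_statistic_p_one(self):
        d = design_matrix(LAB4, factors_of(np.ones(4)), ModelSpec())
        res = fit_and_lrt([7, 7, 7, 7], d, ModelSpec())
        assert res.D == 0.0 and res.p_asymptotic == 1.0

    def test_negative_counts_rejected(self):
        d = design_matrix(LAB4, factors_of(np.ones(4)), ModelSpec())
        with pytest.raises(ValueError):
            fit_and_lrt([-1, 2, 3, 4], d, ModelSpec())

    def test_non_integer_counts_rejected_for_poisson(self):
        d = design_matrix(LAB4, factors_of(np.ones(4)), ModelSpec())
        with pytest.raises(ValueError, match="integer"):
            fit_and_lrt([1.5, 2, 3, 4], d, ModelSpec())

    @pytest.mark.parametrize("norm_mode", ["offset", "term"])
    def test_matches_statsmodels_glm(self, norm_mode):
        rng = np.random.default_rng(42)
        n = 12
        q = np.exp(rng.uniform(-0.5, 0.5, n))
        labels = ["A"] * 6 + ["B"] * 6
        spec = ModelSpec(norm_mode=norm_mode)
        d = design_matrix(labels, factors_of(q), spec)
        for _ in range(5):
            y = rng.poisson(q * rng.uniform(5, 50), size=n)
            ours = fit_and_lrt(y, d, spec)
            off = d.offset if norm_mode == "offset" else None
            full = sm.GLM(y, d.X_full, family=sm.families.Poisson(), offset=off).fit()
            null = sm.GLM(y, d.X_null, family=sm.families.Poisson(), offset=off).fit()
            assert ours.D == pytest.approx(2 * (full.llf - null.llf), abs=1e-6)

    def test_offset_with_equal_factors_equivalent_to_no_normalization(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(20, size=8)
        labels = ["A"] * 4 + ["B"] * 4
        spec = ModelSpec(norm_mode="offset")
        d_eq = design_matrix(labels, factors_of(np.full(8, 3.7)), spec)
        d_one = design_matrix(labels, factors_of(np.ones(8)), spec)
        a = fit_and_lrt(y, d_eq, spec)
        b = fit_and_lrt(y, d_one, spec)
        assert a.D == pytest.approx(b.D, abs=1e-8)


class TestGaussianLRT:
    def test_matches_statsmodels_ols_profile_likelihood(self):
        rng = np.random.default_rng(3)
        n = 10
        labels = ["A"] * 5 + ["B"] * 5
        spec = ModelSpec(family="gaussian", norm_mode="term")
        q = np.exp(rng.uniform(-0.5, 0.5, n))
        d = design_matrix(labels, factors_of(q), spec)
        y = rng.poisson(30, size=n)
        ours = fit_and_lrt(y, d, spec)
        z = np.log(y + 0.5)
        full = sm.OLS(z, d.X_full).fit()
        null = sm.OLS(z, d.X_null).fit()
        assert ours.D == pytest.approx(2 * (full.llf - null.llf), abs=1e-8)

    def test_statistic_is_monotone_in_squared_t(self):
        """Two-group Gaussian D is a monotone function of the pooled t^2."""
        rng = np.random.default_rng(9)
        n = 14
        labels = ["A"] * 7 + ["B"] * 7
        spec = ModelSpec(family="gaussian", norm_mode="offset")
        d = design_matrix(labels, factors_of(np.ones(n)), spec)
        t2s, Ds = [], []
        for _ in range(30):
            y = rng.poisson(rng.uniform(5, 200), size=n)
            z = np.log(y + 0.5)
            t, _ = stats.ttest_ind(z[7:], z[:7])
            t2s.append(t**2)
            Ds.append(fit_and_lrt(y, d, spec).D)
        order = np.argsort(t2s)
        assert (np.diff(np.array(Ds)[order]) >= -1e-9).all()

    def test_ttest_variant_matches_scipy(self):
        rng = np.random.default_rng(10)
        n = 12
        labels = ["A"] * 6 + ["B"] * 6
        spec = ModelSpec(family="gaussian", norm_mode="offset", gaussian_test="ttest")
        d = design_matrix(labels, factors_of(np.ones(n)), spec)
        y = rng.poisson(40, size=n)
        ours = fit_and_lrt(y, d, spec)
        z = np.log(y + 0.5)
        t, p = stats.ttest_ind(z[6:], z[:6], equal_var=True)
        assert ours.D == pytest.approx(t**2, rel=1e-9)
        assert ours.p_asymptotic == pytest.approx(p, rel=1e-9)

    def test_identical_transformed_counts_give_zero(self):
        spec = ModelSpec(family="gaussian")
        d = design_matrix(LAB4, factors_of(np.ones(4)), spec)
        res = fit_and_lrt([5, 5, 5, 5], d, spec)
        assert res.D == 0.0 and res.p_asymptotic == 1.0


class TestPermutation:
    def test_null_matrix_shape_and_label_multisets(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20, size=(7, 6))
        labels = ["A", "A", "A", "B", "B", "B"]
        f = factors_of(np.ones(6))
        nulls = permute_null(counts, labels, f, ModelSpec(), B=4, seed=11)
        assert nulls.matrix.shape == (7, 4)
        for perm in nulls.permutations:
            assert sorted(np.asarray(labels, dtype=object)[perm]) == sorted(labels)

    def test_identical_seed_reproduces_null_matrix(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20, size=(5, 6))
        labels = ["A"] * 3 + ["B"] * 3
        f = factors_of(np.ones(6))
        a = permute_null(counts, labels, f, ModelSpec(), B=3, seed=5)
        b = permute_null(counts, labels, f, ModelSpec(), B=3, seed=5)
        assert (a.matrix == b.matrix).all()

    def test_spec_example_counts(self):
        # m=2, B=2: nulls {0,2,3,6}; exceedances of 5 and 1 are 1 and 3
        p = permutation_pvalues([5.0, 1.0], np.array([[0.0, 2.0], [3.0, 6.0]]))
        np.testing.assert_allclose(p, [2 / 5, 4 / 5])

    def test_formula_floor_when_observed_beats_every_null(self):
        p = permutation_pvalues([10.0], np.array([[1.0, 2.0, 3.0]]))
        assert p[0] == pytest.approx(1 / 4)

    def test_ties_do_not_count_as_exceeding(self):
        p = permutation_pvalues([2.0], np.array([[2.0, 2.0, 2.0]]))
        assert p[0] == pytest.approx(1 / 4)

    @pytest.mark.parametrize("seed", range(20))
    def test_linear_scan_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 51))
        B = int(rng.integers(1, 21))
        obs = rng.exponential(1.0, size=m)
        nulls = rng.exponential(1.0, size=(m, B))
        if seed % 3 == 0:  # inject exact ties
            nulls.flat[:: max(1, nulls.size // 5)] = obs[0]
        fast = permutation_pvalues(obs, nulls)
        brute = np.array(
            [((nulls > d).sum() + 1) / (m * B + 1) for d in obs]
        )
        np.testing.assert_array_equal(fast, brute)

    def test_invariant_to_common_monotone_rescaling(self):
        rng = np.random.default_rng(2)
        obs = rng.exponential(1.0, size=10)
        nulls = rng.exponential(1.0, size=(10, 5))
        base = permutation_pvalues(obs, nulls)
        resc = permutation_pvalues(np.sqrt(obs), np.sqrt(nulls))
        np.testing.assert_array_equal(base, resc)

    def test_empty_null_matrix_errors(self):
        with pytest.raises(ValueError):
            permutation_pvalues([1.0], np.empty((0, 0)))

    def test_b_below_one_errors(self):
        with pytest.raises(ValueError):
            permute_null(np.ones((2, 4)), LAB4, factors_of(np.ones(4)), ModelSpec(), B=0, seed=1)


class TestBatchedAgainstSingle:
    def test_lrt_all_rows_equal_individual_fits(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(30, size=(12, 8))
        labels = ["A"] * 4 + ["B"] * 4
        f = factors_of(np.exp(rng.uniform(-0.3, 0.3, 8)))
        for spec in (ModelSpec(), ModelSpec(family="gaussian", norm_mode="term")):
            d = design_matrix(labels, f, spec)
            D, p, conv = lrt_all(counts, d, spec)
            for i in range(12):
                single = fit_and_lrt(counts[i], d, spec)
                assert single.D == pytest.approx(D[i], abs=1e-9)
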