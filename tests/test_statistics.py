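import numpy as np
import pytest
from scipy import stats as sps

from protride import (
    ResidualSet,
    adjust_tail_probs,
    assemble_results,
    call_outliers,
    compute_residuals,
    fit_t_two_pass,
    gaussian_tail_probs,
    t_tail_probs,
)
from protride.stats import TDistFit


def _residuals(e):
    e = np.asarray(e, dtype=float)
    return ResidualSet(
        e=e, mean_j=np.nanmean(e, axis=0), sd_j=np.nanstd(e, axis=0, ddof=1)
    )


class TestGaussianTails:
    def test_center_gives_probability_one(self, rng):
        e = rng.normal(size=(20, 3))
        res = _residuals(e)
        e2 = e.copy()
        e2[0] = res.mean_j
        p = gaussian_tail_probs(_residuals_with(e2, res))
        np.testing.assert_allclose(p[0], 1.0)

    def test_known_quantile(self):
        # z = 1.959964 corresponds to a two-sided tail probability of 5%
        e = np.zeros((3, 1))
        res = ResidualSet(e=np.array([[1.959964], [0.0], [0.0]]),
                          mean_j=np.array([0.0]), sd_j=np.array([1.0]))
        p = gaussian_tail_probs(res)
        assert p[0, 0] == pytest.approx(0.05, abs=1e-4)

    def test_symmetry_about_the_mean(self, rng):
        e = rng.normal(2.0, 1.0, size=(50, 2))
        res = _residuals(e)
        mirrored = ResidualSet(e=2 * res.mean_j - res.e, mean_j=res.mean_j, sd_j=res.sd_j)
        np.testing.assert_allclose(
            gaussian_tail_probs(res), gaussian_tail_probs(mirrored), rtol=1e-12
        )


def _residuals_with(e, res):
    return ResidualSet(e=e, mean_j=res.mean_j, sd_j=res.sd_j)


class TestTwoPassT:
    def test_parameter_recovery_from_t_residuals(self):
        rng = np.random.default_rng(11)
        e = 2.0 + 1.5 * rng.standard_t(5, size=(150, 500))
        tfit = fit_t_two_pass(_residuals(e))
        assert 3.5 <= tfit.nu0 <= 6.5
        assert tfit.nu0 == np.median(tfit.first_pass_nu)
        assert abs(tfit.mu_j.mean() - 2.0) < 0.1
        assert abs(tfit.tau_j.mean() - 1.5) < 0.15

    def test_gaussian_residuals_give_large_df(self):
        nu0s = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            e = rng.normal(size=(150, 60))
            nu0s.append(fit_t_two_pass(_residuals(e)).nu0)
        assert min(nu0s) > 20

    def test_too_few_observations_rejected(self):
        e = np.full((8, 3), 1.0)
        with pytest.raises(ValueError, match="observed residuals"):
            fit_t_two_pass(_residuals(np.random.default_rng(0).normal(size=(8, 3))))


class TestTTails:
    def test_location_gives_probability_one(self):
        tfit = TDistFit(nu0=5.0, mu_j=np.array([1.0]), tau_j=np.array([2.0]),
                        first_pass_nu=np.array([5.0]))
        res = ResidualSet(e=np.array([[1.0]]), mean_j=np.array([1.0]), sd_j=np.array([2.0]))
        assert t_tail_probs(res, tfit)[0, 0] == pytest.approx(1.0)

    def test_cauchy_closed_form(self):
        # F(1) = 3/4 for the Cauchy distribution, so the two-sided tail is 1/2
        tfit = TDistFit(nu0=1.0, mu_j=np.array([0.0]), tau_j=np.array([1.0]),
                        first_pass_nu=np.array([1.0]))
        res = ResidualSet(e=np.array([[1.0]]), mean_j=np.array([0.0]), sd_j=np.array([1.0]))
        assert t_tail_probs(res, tfit)[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_large_df_agrees_with_gaussian(self, rng):
        e = rng.normal(size=(100, 5))
        res = _residuals(e)
        tfit = TDistFit(nu0=1e4, mu_j=res.mean_j, tau_j=res.sd_j,
                        first_pass_nu=np.full(5, 1e4))
        assert np.nanmax(np.abs(t_tail_probs(res, tfit) - gaussian_tail_probs(res))) < 1e-3

    def test_monotone_in_distance_from_location(self, rng):
        tfit = TDistFit(nu0=4.0, mu_j=np.array([0.5]), tau_j=np.array([1.0]),
                        first_pass_nu=np.array([4.0]))
        e = np.linspace(0.5, 8.0, 30).reshape(-1, 1)
        res = ResidualSet(e=e, mean_j=np.array([0.0]), sd_j=np.array([1.0]))
        p = t_tail_probs(res, tfit)[:, 0]
        assert np.all(np.diff(p) <= 1e-15)


class TestAdjustment:
    def test_hand_computed_examples(self):
        p = np.array([0.01, 0.02, 0.5])
        np.testing.assert_allclose(
            adjust_tail_probs(p, "by"), [0.055, 0.055, 0.9166667], atol=1e-4
        )
        np.testing.assert_allclose(adjust_tail_probs(p, "bh"), [0.03, 0.03, 0.5], atol=1e-12)

    def test_degenerate_inputs(self):
        np.testing.assert_array_equal(adjust_tail_probs(np.ones(4), "by"), np.ones(4))
        assert adjust_tail_probs(np.array([]), "bh").size == 0

    def test_matches_bruteforce_min_over_k(self, rng):
        # q(j) = min_{k >= j} (m/k) c(m) p_(k), truncated at 1
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            for method, cm in (("bh", 1.0), ("by", np.sum(1.0 / np.arange(1, m + 1)))):
                order = np.argsort(p)
                ps = p[order]
                brute_sorted = np.minimum.accumulate(
                    ((m / np.arange(1, m + 1)) * cm * ps)[::-1]
                )[::-1]
                brute = np.empty(m)
                brute[order] = np.minimum(brute_sorted, 1.0)
                np.testing.assert_allclose(adjust_tail_probs(p, method), brute, atol=1e-12)

    def test_by_dominates_bh_dominates_raw(self, rng):
        p = rng.random(200)
        bh = adjust_tail_probs(p, "bh")
        by = adjust_tail_probs(p, "by")
        assert np.all(by >= bh - 1e-15)
        assert np.all(bh >= p - 1e-15)


class TestCallsAndResults:
    def test_cutoff_is_inclusive(self):
        adjusted = np.array([0.1, 0.100001, 0.05])
        np.testing.assert_array_equal(call_outliers(adjusted, 0.1), [1, 0, 1])
        np.testing.assert_array_equal(call_outliers(adjusted, 0.0), [0, 0, 0])

    def test_assembled_table_contents(self, rng):
        X = rng.normal(20, 1, size=(4, 3))
        M = np.ones_like(X)
        M[1, 2] = 0
        X = np.where(M > 0, X, np.nan)
        X_hat = np.nan_to_num(X.copy())
        X_hat[0, 0] = X[0, 0] + 5.93  # 61-fold under-expression
        res = compute_residuals(X, X_hat, M)
        P = gaussian_tail_probs(res)
        table = assemble_results(X, X_hat, M, res, P, P, cutoff=0.1)
        assert len(table) == int(M.sum())
        row = table[(table.sample_id == 0) & (table.protein_id == 0)].iloc[0]
        assert row.log2_fc == pytest.approx(-5.93)
        assert row.fold_change == pytest.approx(1 / 61.0, rel=0.01)
        same = table[(table.sample_id == 2) & (table.protein_id == 1)].iloc[0]
        assert same.fold_change == pytest.approx(2 ** (X[2, 1] - X_hat[2, 1]))

    def test_identical_prediction_gives_unit_fold_change(self, rng):
        X = rng.normal(size=(3, 3))
        M = np.ones_like(X)
        res = compute_residuals(X, X, M)
        P = np.ones_like(X)
        table = assemble_results(X, X, M, res, P, P)
        np.testing.assert_allclose(table.fold_change, 1.0)
        np.testing.assert_allclose(table.log2_fc, 0.0)
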