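"""GCI, bootstrap and MOVER interval constructions for the CV difference."""

import numpy as np
import pytest
from scipy import stats

from weibullcv import (
    DegenerateSampleError,
    WeibullParams,
    bootstrap_delta_draws,
    bootstrap_se_interval,
    cv_from_shape,
    empirical_quantile,
    fit_weibull_mle,
    gci_delta_interval,
    gpq_shape_draw,
    hendricks_robey_cv_interval,
    mover_delta_interval,
    percentile_bootstrap_interval,
    sample_weibull,
)
from weibullcv.intervals import _gpq_shape_batch


def _brute_quantile(draws, p):
    s = np.sort(np.asarray(draws, dtype=float))
    h = p * (s.size - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, s.size - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


class TestEmpiricalQuantile:
    def test_median_of_odd_set(self):
        assert empirical_quantile([1, 2, 3, 4, 5], 0.5) == 3.0

    def test_boundary_behaviour(self):
        d = [3.0, 1.0, 7.0, 5.0]
        assert empirical_quantile(d, 1e-9) == pytest.approx(min(d))
        assert empirical_quantile(d, 1 - 1e-9) == pytest.approx(max(d))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            d = rng.normal(size=rng.integers(2, 40))
            p = float(rng.uniform(0.01, 0.99))
            assert empirical_quantile(d, p) == pytest.approx(_brute_quantile(d, p))

    def test_rejects_empty_and_bad_p(self):
        with pytest.raises(ValueError):
            empirical_quantile([], 0.5)
        with pytest.raises(ValueError):
            empirical_quantile([1.0], 1.0)


class TestGPQ:
    def test_linearity_in_observed_shape(self):
        d1 = gpq_shape_draw(1.0, 20, np.random.default_rng(3))
        d2 = gpq_shape_draw(2.0, 20, np.random.default_rng(3))
        assert d2 == pytest.approx(2.0 * d1)

    def test_pivot_distribution_parameter_free(self, rng):
        # R_k / k_hat_obs = 1/k_hat* must not depend on the data's parameters
        a = _gpq_shape_batch(1.0, 30, 400, np.random.default_rng(10))[0] / 1.0
        b = _gpq_shape_batch(5.3, 30, 400, np.random.default_rng(11))[0] / 5.3
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_synthetic_shape_fit_consistency(self):
        # mean of k_hat* from Weibull(1,1) at n=50 is near 1 (small upward bias)
        r_k, _, k_star, _ = _gpq_shape_batch(1.0, 50, 10_000, np.random.default_rng(4))
        assert abs(k_star.mean() - 1.0) < 0.05


class TestGCI:
    def test_deterministic_given_seed(self, two_small_samples):
        x, y = two_small_samples
        a = gci_delta_interval(x, y, q=300, rng=np.random.default_rng(5))
        b = gci_delta_interval(x, y, q=300, rng=np.random.default_rng(5))
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_invariant_to_common_rescaling(self, two_small_samples):
        x, y = two_small_samples
        a = gci_delta_interval(x, y, q=300, rng=np.random.default_rng(6))
        b = gci_delta_interval(10 * x, 10 * y, q=300, rng=np.random.default_rng(6))
        assert a.lower == pytest.approx(b.lower, abs=1e-6)
        assert a.upper == pytest.approx(b.upper, abs=1e-6)

    def test_contains_plug_in_estimate_usually(self, rng):
        hits = 0
        for seed in range(30):
            x = sample_weibull(15, WeibullParams(1.0, 2.0), rng)
            y = sample_weibull(15, WeibullParams(1.0, 2.0), rng)
            dh = cv_from_shape(fit_weibull_mle(x).params.shape) - cv_from_shape(
                fit_weibull_mle(y).params.shape
            )
            iv = gci_delta_interval(x, y, q=300, rng=np.random.default_rng(seed))
            hits += iv.lower <= dh <= iv.upper
        assert hits >= 27


class TestBootstrap:
    def test_constant_sample_fails_fast(self):
        with pytest.raises(DegenerateSampleError):
            bootstrap_delta_draws(np.full(5, 2.0), [1.0, 2.0, 3.0], B=100)

    def test_single_resample_reduction(self, two_small_samples):
        x, y = two_small_samples
        draws = bootstrap_delta_draws(x, y, B=1, rng=np.random.default_rng(8))
        rng = np.random.default_rng(8)
        xb = x[rng.integers(0, x.size, size=(1, x.size))][0]
        yb = y[rng.integers(0, y.size, size=(1, y.size))][0]
        expect = xb.std(ddof=1) / xb.mean() - yb.std(ddof=1) / yb.mean()
        assert draws.delta_star[0] == pytest.approx(expect)

    def test_mle_statistic_centers_on_plug_in(self, rng):
        x = sample_weibull(100, WeibullParams(1.0, 2.0), rng)
        y = sample_weibull(100, WeibullParams(1.0, 2.0), rng)
        dh = cv_from_shape(fit_weibull_mle(x).params.shape) - cv_from_shape(
            fit_weibull_mle(y).params.shape
        )
        draws = bootstrap_delta_draws(x, y, B=2000, rng=rng, statistic="mle")
        assert abs(draws.delta_star.mean() - dh) < 0.02

    def test_percentile_interval_equals_quantiles_of_draws(self, two_small_samples):
        x, y = two_small_samples
        iv = percentile_bootstrap_interval(x, y, alpha=0.05, B=400, rng=np.random.default_rng(9))
        draws = bootstrap_delta_draws(x, y, B=400, rng=np.random.default_rng(9))
        assert iv.lower == pytest.approx(empirical_quantile(draws.delta_star, 0.025))
        assert iv.upper == pytest.approx(empirical_quantile(draws.delta_star, 0.975))

    def test_quantile_nesting_across_levels(self, two_small_samples):
        x, y = two_small_samples
        wide = percentile_bootstrap_interval(x, y, alpha=0.05, B=400, rng=np.random.default_rng(9))
        narrow = percentile_bootstrap_interval(x, y, alpha=0.5, B=400, rng=np.random.default_rng(9))
        assert wide.lower <= narrow.lower and narrow.upper <= wide.upper

    def test_se_interval_symmetric_about_plug_in(self, two_small_samples):
        x, y = two_small_samples
        dh = cv_from_shape(fit_weibull_mle(x).params.shape) - cv_from_shape(
            fit_weibull_mle(y).params.shape
        )
        iv = bootstrap_se_interval(x, y, B=300, rng=np.random.default_rng(12))
        assert (iv.lower + iv.upper) / 2 == pytest.approx(dh)

    def test_se_interval_degenerate_with_single_draw(self, two_small_samples):
        # B = 1 leaves no spread to estimate: zero-length interval at delta-hat
        x, y = two_small_samples
        iv = bootstrap_se_interval(x, y, B=1, rng=np.random.default_rng(13))
        assert iv.length == 0.0

    def test_invariant_to_common_rescaling(self, two_small_samples):
        x, y = two_small_samples
        a = percentile_bootstrap_interval(x, y, B=300, rng=np.random.default_rng(14))
        b = percentile_bootstrap_interval(5 * x, 5 * y, B=300, rng=np.random.default_rng(14))
        assert a.lower == pytest.approx(b.lower, abs=1e-6)
        assert a.upper == pytest.approx(b.upper, abs=1e-6)


class TestHendricksRobey:
    def test_worked_arithmetic(self):
        # lambda-hat 0.6860, n = 12: t(0.975, 11) = 2.20099, half-width 0.30820
        iv = hendricks_robey_cv_interval(0.6860, 12, 0.05)
        assert iv.lower == pytest.approx(0.3778, abs=1e-4)
        assert iv.upper == pytest.approx(0.9942, abs=1e-4)

    def test_collapses_as_alpha_to_one(self):
        iv = hendricks_robey_cv_interval(0.5, 20, alpha=0.9999)
        assert iv.length < 1e-4

    @pytest.mark.parametrize("n", [5, 20, 80])
    def test_width_formula(self, n):
        lam, alpha = 0.4, 0.05
        iv = hendricks_robey_cv_interval(lam, n, alpha)
        t = stats.t.ppf(0.975, n - 1)
        assert iv.length == pytest.approx(2 * t * lam / np.sqrt(2 * n))


class TestMover:
    def test_worked_example_coastal_stations(self):
        iv = mover_delta_interval(0.6860, 12, 0.1317, 11, 0.05)
        assert iv.lower == pytest.approx(0.2398, abs=2e-4)
        assert iv.upper == pytest.approx(0.8689, abs=2e-4)

    def test_worked_example_regional_stations(self):
        iv = mover_delta_interval(0.4441, 12, 0.2906, 20, 0.05)
        assert iv.lower == pytest.approx(-0.0678, abs=2e-4)

    def test_symmetric_inputs_give_symmetric_interval(self):
        iv = mover_delta_interval(0.3, 25, 0.3, 25, 0.05)
        assert iv.lower == pytest.approx(-iv.upper)

    def test_interval_ordering_invariant(self, rng):
        for _ in range(20):
            lam_x, lam_y = rng.uniform(0.05, 2, size=2)
            n, m = rng.integers(2, 60, size=2)
            iv = mover_delta_interval(lam_x, int(n), lam_y, int(m), 0.05)
            assert iv.lower <= iv.upper
            assert iv.length == pytest.approx(iv.upper - iv.lower)
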