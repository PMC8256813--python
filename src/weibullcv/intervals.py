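"""Frequentist interval constructions for the difference of Weibull CVs.

Four constructions are provided for delta = CV(k_X) - CV(k_Y):

* generalized confidence interval (GCI) from generalized pivotal quantities
  of the two shape parameters,
* percentile bootstrap,
* bootstrap with standard errors (normal interval around the plug-in
  estimate, SE from the bootstrap draws),
* MOVER recombination of per-group Hendricks-Robey CV intervals.

The GPQ of a Weibull shape exploits pivotality of k_hat/k: if k_hat* is the
shape MLE of a fresh Weibull(1,1) sample of the same size, then
R_k = k_hat_obs / k_hat* has the conditional distribution of k given the
data, free of unknown parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    DegenerateSampleError,
    _as_values,
    _fit_shape_batch,
    cv_from_shape,
    fit_weibull_mle,
)

__all__ = [
    "IntervalEstimate",
    "GPQDraws",
    "BootstrapDraws",
    "METHOD_TAGS",
    "empirical_quantile",
    "gpq_shape_draw",
    "gpq_scale_draw",
    "gci_delta_interval",
    "bootstrap_delta_draws",
    "percentile_bootstrap_interval",
    "bootstrap_se_interval",
    "hendricks_robey_cv_interval",
    "mover_delta_interval",
]

#: canonical tags for the six delta-interval constructions
METHOD_TAGS = ("GCI", "PB", "BS", "MOVER_HR", "MCMC", "HPD")

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class IntervalEstimate:
    """A two-sided interval [lower, upper] at confidence/credibility level
    1 - alpha, tagged with the method that produced it."""

    lower: float
    upper: float
    method: str
    level: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.upper):
            raise ValueError("interval endpoints out of order")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")

    @property
    def length(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class GPQDraws:
    """Monte-Carlo draws of the shape GPQs and the induced delta pivot."""

    r_kx: np.ndarray
    r_ky: np.ndarray
    r_delta: np.ndarray

    @property
    def q(self) -> int:
        return int(self.r_delta.size)


@dataclass(frozen=True)
class BootstrapDraws:
    """Bootstrap draws of the CV difference; ``n_failed`` counts resamples
    discarded (and redrawn) because the inner MLE failed."""

    delta_star: np.ndarray
    n_failed: int = 0

    @property
    def B(self) -> int:
        return int(self.delta_star.size)


def empirical_quantile(draws, p: float) -> float:
    """Order-statistic quantile with linear interpolation at p(N-1)+1."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly between 0 and 1")
    return float(np.quantile(draws, p, method="linear"))


def _shape_fits_with_redraw(draw_rows, R: int, n: int, tol: float = 1e-6):
    """Fit shape MLEs to R freshly drawn rows, redrawing rows whose fit is
    degenerate or non-convergent.  ``draw_rows(r)`` yields an (r, n) array.

    Returns (k_hat (R,), a_hat (R,), n_failed).
    """
    x = draw_rows(R)
    k, a, conv, _, _ = _fit_shape_batch(x, tol=tol)
    bad = ~(conv & np.isfinite(k) & (k > 0))
    n_failed = 0
    attempts = 0
    while bad.any():
        attempts += 1
        if attempts > _MAX_REDRAWS:
            raise RuntimeError("MLE repeatedly failed on redrawn replicates")
        n_failed += int(bad.sum())
        xr = draw_rows(int(bad.sum()))
        kr, ar, convr, _, _ = _fit_shape_batch(xr, tol=tol)
        k[bad], a[bad] = kr, ar
        okr = convr & np.isfinite(kr) & (kr > 0)
        idx = np.flatnonzero(bad)
        bad[idx[okr]] = False
    return k, a, n_failed


def _gpq_shape_batch(k_hat_obs: float, n: int, q: int, rng: np.random.Generator):
    """q draws of R_k = k_hat_obs / k_hat*, with k_hat* refitted to fresh
    Weibull(1,1) samples of size n."""
    k_star, a_star, n_failed = _shape_fits_with_redraw(
        lambda r: rng.weibull(1.0, size=(r, n)), q, n
    )
    return k_hat_obs / k_star, a_star, k_star, n_failed


def gpq_shape_draw(k_hat_obs: float, n: int, rng: np.random.Generator) -> float:
    """One generalized-pivotal draw for the shape parameter."""
    if not (k_hat_obs > 0):
        raise ValueError("observed shape MLE must be positive")
    if n < 2:
        raise ValueError("n must be at least 2")
    r_k, _, _, _ = _gpq_shape_batch(k_hat_obs, n, 1, rng)
    return float(r_k[0])


def gpq_scale_draw(
    a_hat_obs: float, k_hat_obs: float, n: int, rng: np.random.Generator
) -> float:
    """One generalized-pivotal draw for the scale parameter,
    R_a = (1/a_hat*)^(k_hat*/k_hat_obs) * a_hat_obs, sharing the Weibull(1,1)
    fit with the paired shape draw."""
    if not (a_hat_obs > 0 and k_hat_obs > 0):
        raise ValueError("observed MLEs must be positive")
    _, a_star, k_star, _ = _gpq_shape_batch(k_hat_obs, n, 1, rng)
    return float((1.0 / a_star[0]) ** (k_star[0] / k_hat_obs) * a_hat_obs)


def gci_delta_interval(
    x,
    y,
    alpha: float = 0.05,
    q: int = 2500,
    rng: np.random.Generator | None = None,
) -> IntervalEstimate:
    """Generalized confidence interval for the CV difference.

    The observed shape MLEs are computed once; q independent pairs of shape
    GPQs are mapped through the CV function and differenced, and the
    alpha/2, 1-alpha/2 empirical quantiles of the pivot form the interval.
    """
    if q < 100:
        raise ValueError("q must be at least 100")
    rng = np.random.default_rng(rng)
    xv, yv = _as_values(x), _as_values(y)
    fit_x, fit_y = fit_weibull_mle(xv), fit_weibull_mle(yv)
    if not (fit_x.converged and fit_y.converged):
        raise RuntimeError("MLE did not converge on the observed data")
    draws = _gpq_delta_draws(fit_x.params.shape, xv.size, fit_y.params.shape, yv.size, q, rng)
    return IntervalEstimate(
        lower=empirical_quantile(draws.r_delta, alpha / 2),
        upper=empirical_quantile(draws.r_delta, 1 - alpha / 2),
        method="GCI",
        level=1 - alpha,
    )


def _gpq_delta_draws(kx0, n, ky0, m, q, rng) -> GPQDraws:
    r_kx, _, _, _ = _gpq_shape_batch(kx0, n, q, rng)
    r_ky, _, _, _ = _gpq_shape_batch(ky0, m, q, rng)
    return GPQDraws(r_kx=r_kx, r_ky=r_ky, r_delta=cv_from_shape(r_kx) - cv_from_shape(r_ky))


def _moment_cv_rows(x: np.ndarray) -> np.ndarray:
    """Empirical CV (sample sd / mean, ddof=1) of each row."""
    return x.std(axis=1, ddof=1) / x.mean(axis=1)


def bootstrap_delta_draws(
    x,
    y,
    B: int = 500,
    rng: np.random.Generator | None = None,
    statistic: str = "moment",
) -> BootstrapDraws:
    """B nonparametric bootstrap draws of the CV difference.

    Each group is resampled with replacement at its own size and the
    per-resample CV difference is one draw.  ``statistic`` selects how the
    resample CV is computed: ``"moment"`` (default) uses the empirical
    sd/mean, which is what reproduces the reference coverage behaviour of
    the bootstrap intervals; ``"mle"`` refits the Weibull by maximum
    likelihood and maps the shape through the CV function.  With the MLE
    statistic, resamples whose fit fails (e.g. too few distinct values) are
    redrawn and counted in ``n_failed``.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if statistic not in ("moment", "mle"):
        raise ValueError("statistic must be 'moment' or 'mle'")
    rng = np.random.default_rng(rng)
    xv, yv = _as_values(x), _as_values(y)
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise DegenerateSampleError("cannot bootstrap a constant sample")
    if statistic == "moment":
        xb = xv[rng.integers(0, xv.size, size=(B, xv.size))]
        yb = yv[rng.integers(0, yv.size, size=(B, yv.size))]
        return BootstrapDraws(delta_star=_moment_cv_rows(xb) - _moment_cv_rows(yb))
    kx, _, fx = _shape_fits_with_redraw(
        lambda r: xv[rng.integers(0, xv.size, size=(r, xv.size))], B, xv.size
    )
    ky, _, fy = _shape_fits_with_redraw(
        lambda r: yv[rng.integers(0, yv.size, size=(r, yv.size))], B, yv.size
    )
    return BootstrapDraws(
        delta_star=cv_from_shape(kx) - cv_from_shape(ky), n_failed=fx + fy
    )


def percentile_bootstrap_interval(
    x,
    y,
    alpha: float = 0.05,
    B: int = 500,
    rng: np.random.Generator | None = None,
    statistic: str = "moment",
) -> IntervalEstimate:
    """Percentile-bootstrap interval: empirical alpha/2 and 1-alpha/2
    quantiles of the sorted bootstrap CV differences."""
    draws = bootstrap_delta_draws(x, y, B=B, rng=rng, statistic=statistic)
    return IntervalEstimate(
        lower=empirical_quantile(draws.delta_star, alpha / 2),
        upper=empirical_quantile(draws.delta_star, 1 - alpha / 2),
        method="PB",
        level=1 - alpha,
    )


def bootstrap_se_interval(
    x,
    y,
    alpha: float = 0.05,
    B: int = 500,
    rng: np.random.Generator | None = None,
    statistic: str = "moment",
) -> IntervalEstimate:
    """Normal-theory bootstrap interval: the MLE plug-in delta_hat
    +/- z_{1-alpha/2} times the standard deviation of the bootstrap draws."""
    xv, yv = _as_values(x), _as_values(y)
    fit_x, fit_y = fit_weibull_mle(xv), fit_weibull_mle(yv)
    delta_hat = cv_from_shape(fit_x.params.shape) - cv_from_shape(fit_y.params.shape)
    draws = bootstrap_delta_draws(xv, yv, B=B, rng=rng, statistic=statistic)
    se = float(np.std(draws.delta_star, ddof=1)) if draws.B > 1 else 0.0
    z = stats.norm.ppf(1 - alpha / 2)
    return IntervalEstimate(
        lower=delta_hat - z * se,
        upper=delta_hat + z * se,
        method="BS",
        level=1 - alpha,
    )


def hendricks_robey_cv_interval(
    lambda_hat: float, n: int, alpha: float = 0.05
) -> IntervalEstimate:
    """Hendricks-Robey interval for a single CV:
    lambda_hat +/- t_{1-alpha/2, n-1} * lambda_hat / sqrt(2n)."""
    if n < 2:
        raise ValueError("n must be at least 2")
    if not (lambda_hat > 0):
        raise ValueError("lambda_hat must be positive")
    t = stats.t.ppf(1 - alpha / 2, df=n - 1)
    half = t * lambda_hat / np.sqrt(2.0 * n)
    return IntervalEstimate(
        lower=lambda_hat - half, upper=lambda_hat + half, method="HR", level=1 - alpha
    )


def mover_delta_interval(
    lambda_hat_x: float,
    n: int,
    lambda_hat_y: float,
    m: int,
    alpha: float = 0.05,
) -> IntervalEstimate:
    """MOVER interval for the CV difference from per-group Hendricks-Robey
    limits: the one-sided margins of the two component intervals are
    recombined in quadrature around the plug-in difference."""
    ix = hendricks_robey_cv_interval(lambda_hat_x, n, alpha)
    iy = hendricks_robey_cv_interval(lambda_hat_y, m, alpha)
    d = lambda_hat_x - lambda_hat_y
    lower = d - np.sqrt((lambda_hat_x - ix.lower) ** 2 + (iy.upper - lambda_hat_y) ** 2)
    upper = d + np.sqrt((ix.upper - lambda_hat_x) ** 2 + (lambda_hat_y - iy.lower) ** 2)
    return IntervalEstimate(
        lower=float(lower), upper=float(upper), method="MOVER_HR", level=1 - alpha
    )


def _mover_bounds_batch(lam_x: np.ndarray, n: int, lam_y: np.ndarray, m: int, alpha: float):
    """Vectorized MOVER bounds for the simulation engine (no RNG needed)."""
    tx = stats.t.ppf(1 - alpha / 2, df=n - 1)
    ty = stats.t.ppf(1 - alpha / 2, df=m - 1)
    hx = tx * lam_x / np.sqrt(2.0 * n)
    hy = ty * lam_y / np.sqrt(2.0 * m)
    d = lam_x - lam_y
    margin = np.sqrt(hx**2 + hy**2)  # symmetric HR components
    return d - margin, d + margin
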