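"""Two-parameter Weibull primitives: density, sampling, the coefficient of
variation as a function of shape, and maximum-likelihood fitting.

The Weibull density with scale ``a > 0`` and shape ``k > 0`` is

    f(x; a, k) = (k/a) (x/a)^{k-1} exp[-(x/a)^k],   x > 0.

Its coefficient of variation depends on the shape alone,

    CV(k) = sqrt( Gamma(1 + 2/k) / Gamma(1 + 1/k)^2 - 1 ),

so two-sample inference on the difference of CVs reduces to inference on the
two shape parameters.  The MLE of the shape solves a one-dimensional score
equation, handled here by a safeguarded Newton-Raphson iteration started at
the Menon closed-form estimator; the scale then follows in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DegenerateSampleError",
    "Observations",
    "WeibullParams",
    "MLEFit",
    "weibull_pdf",
    "cv_from_shape",
    "delta_from_shapes",
    "menon_initial_shape",
    "fit_weibull_mle",
    "sample_weibull",
]

# cv_from_shape overflows double precision only below this shape; reject
# rather than return inf from the scalar API.
_MIN_SHAPE_FOR_CV = 2.0 / 1400.0


class DegenerateSampleError(ValueError):
    """All observations identical: the log-scale spread is zero and neither
    the Menon estimator nor the shape MLE is defined."""


@dataclass(frozen=True)
class Observations:
    """A single sample of strictly positive measurements."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a sample needs at least two observations")
        if not np.all(np.isfinite(v)) or np.any(v <= 0.0):
            raise ValueError("observations must be finite and strictly positive")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape pair of a two-parameter Weibull distribution."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0.0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not (self.shape > 0.0 and math.isfinite(self.shape)):
            raise ValueError(f"shape must be positive, got {self.shape}")


@dataclass(frozen=True)
class MLEFit:
    """Result of the Newton-Raphson maximum-likelihood fit.

    ``final_score`` is the value of the shape score function F at exit;
    ``menon_start`` the closed-form starting value for the iteration.
    """

    params: WeibullParams
    iterations: int
    converged: bool
    final_score: float
    menon_start: float


def _as_values(obs) -> np.ndarray:
    if isinstance(obs, Observations):
        return obs.values
    return Observations(np.asarray(obs, dtype=float)).values


def weibull_pdf(x, params: WeibullParams):
    """Weibull density at ``x`` (scalar or array of positive reals)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("the Weibull density is defined for x > 0 only")
    a, k = params.scale, params.shape
    t = x / a
    out = (k / a) * t ** (k - 1.0) * np.exp(-(t**k))
    return out if out.ndim else float(out)


def cv_from_shape(shape_k):
    """Coefficient of variation of a Weibull distribution with shape ``k``.

    Scale-free: CV(k) = sqrt(Gamma(1+2/k)/Gamma(1+1/k)^2 - 1).  Evaluated via
    log-gamma so that large shapes do not overflow the Gamma function itself.
    Raises ``OverflowError`` for shapes so small that the CV exceeds double
    range (k below ~0.0014).
    """
    k = np.asarray(shape_k, dtype=float)
    if np.any(~np.isfinite(k)) or np.any(k <= 0.0):
        raise ValueError("shape must be positive and finite")
    if np.any(k < _MIN_SHAPE_FOR_CV):
        raise OverflowError("CV overflows double precision for shape < ~0.0014")
    log_ratio = gammaln(1.0 + 2.0 / k) - 2.0 * gammaln(1.0 + 1.0 / k)
    out = np.sqrt(np.expm1(log_ratio))
    return out if out.ndim else float(out)


def delta_from_shapes(shape_kx, shape_ky):
    """Difference of Weibull CVs, ``delta = CV(k_X) - CV(k_Y)``."""
    return cv_from_shape(shape_kx) - cv_from_shape(shape_ky)


def _log_spread(z: np.ndarray) -> float:
    """Sum of squared deviations of the logs (the s^2 of the Menon start)."""
    return float(np.sum((z - z.mean()) ** 2))


def menon_initial_shape(obs) -> float:
    """Menon's closed-form asymptotically unbiased shape estimator.

    With z_i = ln x_i and s^2 = sum_i (z_i - mean z)^2,
    k_u = (pi/sqrt(6)) * sqrt((n-1)/s^2).  Used as the Newton starting value.
    """
    x = _as_values(obs)
    z = np.log(x)
    s2 = _log_spread(z)
    if s2 <= 0.0:
        raise DegenerateSampleError("all observations identical")
    n = x.size
    return (math.pi / math.sqrt(6.0)) * math.sqrt((n - 1) / s2)


def _fit_shape_batch(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MLE over the rows of ``x`` (R, n).

    Returns (k_hat, a_hat, converged, iterations, final_score), length R each.
    Degenerate rows (zero log spread) come back NaN / not-converged; the
    caller owns the redraw policy.  Rows are normalized by their geometric
    mean first -- the shape MLE is scale-invariant and this keeps x**k well
    inside double range during the iteration.
    """
    x = np.asarray(x, dtype=float)
    z = np.log(x)
    zbar = z.mean(axis=1, keepdims=True)
    zc = z - zbar  # log data centred at geometric mean
    s2 = np.sum(zc**2, axis=1)
    R, n = x.shape
    ok = s2 > 0.0

    k = np.full(R, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        k[ok] = (math.pi / math.sqrt(6.0)) * np.sqrt((n - 1) / s2[ok])

    converged = np.zeros(R, dtype=bool)
    iters = np.zeros(R, dtype=int)
    score = np.full(R, np.nan)

    active = ok.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        ka = k[active]
        za = zc[active]
        with np.errstate(over="ignore", invalid="ignore"):
            w = np.exp(ka[:, None] * za)  # (x/gm)^k
            s2w = w.sum(axis=1)
            s3w = (w * za).sum(axis=1)
            s4w = (w * za * za).sum(axis=1)
            # zbar of centred logs is 0, so F = 1/k - s3/s2
            F = 1.0 / ka - s3w / s2w
            f = 1.0 / ka**2 + (s2w * s4w - s3w**2) / s2w**2
            step = F / f
        bad = ~np.isfinite(step)
        k_new = np.where(bad, np.nan, np.maximum(ka + np.where(bad, 0.0, step), 1e-8))
        k[active] = k_new
        iters[active] += 1
        score[active] = F
        done = np.abs(F) <= tol
        idx = np.flatnonzero(active)
        converged[idx[done & ~bad]] = True
        still = np.zeros(R, dtype=bool)
        still[idx[~done & ~bad]] = True
        active = still

    scale = np.full(R, np.nan)
    good = np.isfinite(k)
    if good.any():
        with np.errstate(over="ignore", invalid="ignore"):
            sw = np.exp(k[good, None] * zc[good]).sum(axis=1)
            scale[good] = np.exp(zbar[good, 0]) * (sw / n) ** (1.0 / k[good])
    return k, scale, converged, iters, score


def fit_weibull_mle(obs, tol: float = 1e-6, max_iter: int = 100) -> MLEFit:
    """Maximum-likelihood fit of the two-parameter Weibull.

    The shape solves the score equation F(k) = 1/k + mean(ln x)
    - sum(x^k ln x)/sum(x^k) = 0 by Newton-Raphson from the Menon start;
    the scale is then (mean of x^k)^(1/k).  ``converged`` records whether
    ``|F|`` fell below ``tol`` within ``max_iter`` iterations; callers in
    resampling loops decide their own retry policy on failure.
    """
    if tol <= 0.0:
        raise ValueError("tol must be positive")
    x = _as_values(obs)
    start = menon_initial_shape(x)  # raises DegenerateSampleError if needed
    k, a, conv, iters, score = _fit_shape_batch(x[None, :], tol=tol, max_iter=max_iter)
    if not np.isfinite(k[0]):
        return MLEFit(
            params=WeibullParams(scale=float(np.mean(x)), shape=start),
            iterations=int(iters[0]),
            converged=False,
            final_score=float("nan"),
            menon_start=start,
        )
    return MLEFit(
        params=WeibullParams(scale=float(a[0]), shape=float(k[0])),
        iterations=int(iters[0]),
        converged=bool(conv[0]),
        final_score=float(score[0]),
        menon_start=start,
    )


def sample_weibull(n: int, params: WeibullParams, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. Weibull(scale, shape) variates (inverse transform)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not isinstance(params, WeibullParams):
        params = WeibullParams(*params)
    u = rng.random(n)
    return params.scale * (-np.log1p(-u)) ** (1.0 / params.shape)
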