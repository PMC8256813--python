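"""Bayesian inference for the Weibull via Gibbs sampling with a random-walk
Metropolis step, and credible intervals for the CV difference.

Under the reparametrization a' = (1/a)^k the Weibull density becomes
f(x; a', k) = a' k x^{k-1} exp(-a' x^k), so with independent gamma priors
gamma(v1, z1) on a' and gamma(v2, z2) on k the full conditional of a' given
k is conjugate gamma(v1 + n, z1 + sum x^k).  The shape k has no conjugate
conditional and is updated by a random-walk Metropolis step targeting the
exact full conditional (likelihood times its gamma prior), with the
acceptance ratio evaluated in log space.

For two groups, per-iteration CV differences delta^t = CV(k_X^t) - CV(k_Y^t)
yield equal-tailed and highest-posterior-density credible intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateSampleError,
    _as_values,
    _fit_shape_batch,
    cv_from_shape,
    menon_initial_shape,
)
from .intervals import IntervalEstimate, empirical_quantile

__all__ = [
    "GammaPrior",
    "MCMCSettings",
    "PosteriorSample",
    "log_likelihood",
    "conditional_scale_draw",
    "rwm_shape_step",
    "gibbs_sampler",
    "delta_chain",
    "equal_tailed_credible_interval",
    "hpd_interval",
]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma hyperparameters: gamma(v1, z1) on the transformed scale a' and
    gamma(v2, z2) on the shape k (shape/rate parametrization)."""

    v1: float = 0.1
    z1: float = 0.1
    v2: float = 0.1
    z2: float = 0.1

    def __post_init__(self) -> None:
        if min(self.v1, self.z1, self.v2, self.z2) <= 0.0:
            raise ValueError("all hyperparameters must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length, burn-in, proposal scale and adaptation switch.

    ``proposal_sd=None`` starts from 2.4 times the asymptotic standard
    deviation of the shape MLE (~1.87 k/sqrt(n)); with ``adapt=True`` the
    scale is tuned during burn-in toward a 20-45% acceptance rate and then
    frozen, so retained draws come from a fixed kernel.
    """

    iterations: int = 20_000
    burn_in: int = 1_000
    proposal_sd: float | None = None
    adapt: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must be smaller than iterations")
        if self.proposal_sd is not None and self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")


@dataclass(frozen=True)
class PosteriorSample:
    """Retained MCMC draws for one group; ``accepted`` counts Metropolis
    acceptances over all post-burn-in iterations."""

    a_prime: np.ndarray
    k: np.ndarray
    accepted: int

    @property
    def size(self) -> int:
        return int(self.k.size)

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.size if self.size else float("nan")


def log_likelihood(a_prime: float, k: float, obs) -> float:
    """Weibull log-likelihood in the (a', k) parametrization:
    n ln a' + n ln k + (k-1) sum ln x - a' sum x^k."""
    if not (a_prime > 0 and k > 0):
        raise ValueError("a_prime and k must be positive")
    x = _as_values(obs)
    with np.errstate(over="raise"):
        try:
            sxk = float(np.sum(x**k))
        except FloatingPointError as exc:
            raise OverflowError("x**k overflows double precision") from exc
    n = x.size
    return n * math.log(a_prime) + n * math.log(k) + (k - 1) * float(
        np.sum(np.log(x))
    ) - a_prime * sxk


def conditional_scale_draw(
    k: float, obs, prior: GammaPrior, rng: np.random.Generator
) -> float:
    """One conjugate draw of a' given k: gamma(v1 + n, z1 + sum x^k).

    ``obs`` may be empty, in which case this reduces to a prior draw.
    """
    if not (k > 0):
        raise ValueError("k must be positive")
    x = np.asarray(obs, dtype=float).ravel() if not hasattr(obs, "values") else obs.values
    if np.any(x <= 0):
        raise ValueError("observations must be positive")
    shape = prior.v1 + x.size
    rate = prior.z1 + float(np.sum(x**k))
    return float(rng.gamma(shape, 1.0 / rate))


def _log_cond_k(k: float, a_prime: float, x: np.ndarray, slogx: float, prior: GammaPrior) -> float:
    n = x.size
    with np.errstate(over="ignore"):
        sxk = float(np.sum(x**k))
    if not math.isfinite(sxk):
        return -math.inf
    return (
        (prior.v2 - 1.0) * math.log(k)
        - prior.z2 * k
        + n * math.log(k)
        + (k - 1.0) * slogx
        - a_prime * sxk
    )


def rwm_shape_step(
    k_current: float,
    a_prime: float,
    obs,
    prior: GammaPrior,
    proposal_sd: float,
    rng: np.random.Generator,
) -> float:
    """One random-walk Metropolis update of the shape.

    Proposes k* = k + eps with eps ~ N(0, proposal_sd^2); nonpositive
    proposals have zero prior density and are rejected outright; otherwise
    the log acceptance ratio uses the exact full conditional.
    """
    if not (k_current > 0 and a_prime > 0 and proposal_sd > 0):
        raise ValueError("inputs must be positive")
    x = _as_values(obs)
    slogx = float(np.sum(np.log(x)))
    k_star = k_current + proposal_sd * rng.standard_normal()
    if k_star <= 0.0:
        return k_current
    log_a = _log_cond_k(k_star, a_prime, x, slogx, prior) - _log_cond_k(
        k_current, a_prime, x, slogx, prior
    )
    if math.log(rng.random()) <= min(0.0, log_a):
        return k_star
    return k_current


def _gibbs_batch(
    X: np.ndarray,
    prior: GammaPrior,
    settings: MCMCSettings,
    rng: np.random.Generator,
    k_init: np.ndarray | None = None,
    a_init: np.ndarray | None = None,
):
    """Run R independent Gibbs/RWM chains at once, one per row of X (R, n).

    Returns (a_chains, k_chains, accepted) with chains of shape
    (R, iterations - burn_in).  Vectorizing across chains is what makes the
    Monte-Carlo coverage study tractable on one CPU.
    """
    X = np.asarray(X, dtype=float)
    R, n = X.shape
    logX = np.log(X)
    slogx = logX.sum(axis=1)
    T, burn = settings.iterations, settings.burn_in

    if k_init is None:
        k, _, conv, _, _ = _fit_shape_batch(X)
        bad = ~(np.isfinite(k) & (k > 0))
        if bad.any():  # fall back to the Menon start, then to a unit shape
            for i in np.flatnonzero(bad):
                try:
                    k[i] = menon_initial_shape(X[i])
                except DegenerateSampleError:
                    k[i] = 1.0
    else:
        k = np.array(k_init, dtype=float)
    if a_init is None:
        with np.errstate(over="ignore"):
            a_prime = (prior.v1 + n) / (prior.z1 + np.exp(k[:, None] * logX).sum(axis=1))
    else:
        a_prime = np.array(a_init, dtype=float)

    if settings.proposal_sd is None:
        sd = 1.87 * k / math.sqrt(n)  # 2.4 x asymptotic sd of the shape MLE
    else:
        sd = np.full(R, float(settings.proposal_sd))
    adapt_window = 50

    keep = T - burn
    a_chains = np.empty((R, keep))
    k_chains = np.empty((R, keep))
    accepted = np.zeros(R, dtype=int)
    window_acc = np.zeros(R)

    def log_cond(kv, av, rows):
        with np.errstate(over="ignore"):
            sxk = np.exp(kv[:, None] * logX[rows]).sum(axis=1)
        out = (
            (prior.v2 - 1.0 + n) * np.log(kv)
            - prior.z2 * kv
            + (kv - 1.0) * slogx[rows]
            - av * sxk
        )
        return np.where(np.isfinite(sxk), out, -np.inf)

    all_rows = np.arange(R)
    for t in range(T):
        with np.errstate(over="ignore"):
            sxk = np.exp(k[:, None] * logX).sum(axis=1)
        a_prime = rng.gamma(prior.v1 + n, 1.0 / (prior.z1 + sxk))

        k_star = k + sd * rng.standard_normal(R)
        valid = k_star > 0.0
        log_a = np.full(R, -np.inf)
        if valid.any():
            rows = all_rows[valid]
            log_a[valid] = log_cond(k_star[valid], a_prime[valid], rows) - log_cond(
                k[valid], a_prime[valid], rows
            )
        acc = np.log(rng.random(R)) <= np.minimum(0.0, log_a)
        k = np.where(acc, k_star, k)

        if t < burn:
            if settings.adapt:
                window_acc += acc
                if (t + 1) % adapt_window == 0:
                    rate = window_acc / adapt_window
                    sd = sd * np.where(rate > 0.45, 1.25, np.where(rate < 0.20, 0.8, 1.0))
                    window_acc[:] = 0.0
        else:
            accepted += acc
            a_chains[:, t - burn] = a_prime
            k_chains[:, t - burn] = k
    return a_chains, k_chains, accepted


def gibbs_sampler(obs, prior: GammaPrior, settings: MCMCSettings) -> PosteriorSample:
    """Gibbs sampler for one group: conjugate a' draws alternate with RWM
    shape updates; the first ``burn_in`` iterations are discarded.

    The chain starts at the MLE (Menon fallback) so the short default
    burn-in begins in the high-density region.  Fully reproducible from
    ``settings.seed``.
    """
    x = _as_values(obs)
    rng = np.random.default_rng(settings.seed)
    a_chains, k_chains, accepted = _gibbs_batch(x[None, :], prior, settings, rng)
    return PosteriorSample(a_prime=a_chains[0], k=k_chains[0], accepted=int(accepted[0]))


def delta_chain(post_x: PosteriorSample, post_y: PosteriorSample) -> np.ndarray:
    """Per-iteration CV difference delta^t = CV(k_X^t) - CV(k_Y^t)."""
    if post_x.size != post_y.size:
        raise ValueError("retained chain lengths differ")
    return cv_from_shape(post_x.k) - cv_from_shape(post_y.k)


def equal_tailed_credible_interval(delta, alpha: float = 0.05) -> IntervalEstimate:
    """Equal-tailed credible interval: alpha/2 and 1-alpha/2 empirical
    quantiles of the delta draws."""
    return IntervalEstimate(
        lower=empirical_quantile(delta, alpha / 2),
        upper=empirical_quantile(delta, 1 - alpha / 2),
        method="MCMC",
        level=1 - alpha,
    )


def hpd_interval(draws, alpha: float = 0.05) -> IntervalEstimate:
    """Highest-posterior-density interval: the shortest contiguous window of
    the sorted draws containing ceil((1-alpha) N) points."""
    s = np.sort(np.asarray(draws, dtype=float))
    N = s.size
    if N == 0:
        raise ValueError("empty draw vector")
    w = int(math.ceil((1.0 - alpha) * N))
    w = min(max(w, 1), N)
    if w == N:
        lo, hi = s[0], s[-1]
    else:
        widths = s[w - 1 :] - s[: N - w + 1]
        i = int(np.argmin(widths))
        lo, hi = s[i], s[i + w - 1]
    return IntervalEstimate(lower=float(lo), upper=float(hi), method="HPD", level=1 - alpha)
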