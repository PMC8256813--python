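"""Monte-Carlo evaluation of coverage probability and expected length.

For a scenario (n, m, a_X, a_Y, k_X, k_Y, alpha) the engine repeatedly draws
the two Weibull samples, constructs each requested interval for the CV
difference, and averages the indicator that the interval contains the true
delta (coverage) and the interval width (expected length).  A master seed
spawns one independent substream per method plus one for the data, so a
subset of methods can be rerun without perturbing the draws of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bayes import GammaPrior, MCMCSettings, _gibbs_batch, hpd_interval
from .core import WeibullParams, _fit_shape_batch, cv_from_shape, delta_from_shapes
from .intervals import (
    METHOD_TAGS,
    IntervalEstimate,
    _mover_bounds_batch,
    _moment_cv_rows,
    _shape_fits_with_redraw,
)
from scipy import stats

__all__ = ["Scenario", "MethodResult", "evaluate_interval", "run_scenario",
           "default_grid", "run_grid", "results_to_frame"]

#: sample-size pairs of the coverage study
SIZE_GRID = ((10, 10), (10, 20), (20, 20), (30, 30), (30, 50), (50, 50), (50, 100), (100, 100))
#: second-group shapes of the coverage study (first group shape fixed at 1)
SHAPE_GRID = (0.5, 1.0, 2.0, 2.5, 4.0, 9.0)
#: common scale values of the coverage study
SCALE_GRID = (0.5, 2.0)


@dataclass(frozen=True)
class Scenario:
    """One simulation cell and its tuning constants."""

    n: int
    m: int
    a_x: float = 0.5
    a_y: float = 0.5
    k_x: float = 1.0
    k_y: float = 1.0
    alpha: float = 0.05
    M: int = 5_000
    q: int = 2_500
    B: int = 500
    mcmc: MCMCSettings = field(default_factory=lambda: MCMCSettings(iterations=20_000, burn_in=1_000))
    prior: GammaPrior = field(default_factory=GammaPrior)
    methods: tuple[str, ...] = METHOD_TAGS
    bootstrap_statistic: str = "moment"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be at least 1")
        unknown = set(self.methods) - set(METHOD_TAGS)
        if unknown:
            raise ValueError(f"unknown method tags: {sorted(unknown)}")

    @property
    def true_delta(self) -> float:
        return float(delta_from_shapes(self.k_x, self.k_y))

    def to_json(self) -> str:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "Scenario":
        d = json.loads(text)
        d["mcmc"] = MCMCSettings(**d["mcmc"])
        d["prior"] = GammaPrior(**d["prior"])
        d["methods"] = tuple(d["methods"])
        return cls(**d)


@dataclass(frozen=True)
class MethodResult:
    """Coverage and expected length of one method in one scenario cell."""

    method: str
    coverage: float
    expected_length: float
    mc_se_coverage: float
    mc_se_length: float
    replicates_used: int
    n_redrawn: int = 0


def evaluate_interval(interval: IntervalEstimate, true_delta: float) -> tuple[int, float]:
    """Coverage indicator (endpoints inclusive) and interval length."""
    covered = int(interval.lower <= true_delta <= interval.upper)
    return covered, interval.length


def _draw_valid_samples(rng, M, n, m, params_x, params_y):
    """Draw M replicate sample pairs whose observed MLEs converge, redrawing
    failures; returns data, fitted shapes and the redraw count."""
    redrawn = 0

    def draw_x(r):
        return params_x.scale * rng.weibull(params_x.shape, size=(r, n))

    def draw_y(r):
        return params_y.scale * rng.weibull(params_y.shape, size=(r, m))

    X = draw_x(M)
    Y = draw_y(M)
    kx, ax, convx, _, _ = _fit_shape_batch(X)
    ky, ay, convy, _, _ = _fit_shape_batch(Y)
    bad = ~(convx & convy & np.isfinite(kx) & np.isfinite(ky) & (kx > 0) & (ky > 0))
    attempts = 0
    while bad.any():
        attempts += 1
        if attempts > 100:
            raise RuntimeError("observed-data MLE repeatedly failed")
        redrawn += int(bad.sum())
        idx = np.flatnonzero(bad)
        X[idx] = draw_x(idx.size)
        Y[idx] = draw_y(idx.size)
        kxr, axr, cxr, _, _ = _fit_shape_batch(X[idx])
        kyr, ayr, cyr, _, _ = _fit_shape_batch(Y[idx])
        kx[idx], ax[idx], ky[idx], ay[idx] = kxr, axr, kyr, ayr
        ok = cxr & cyr & np.isfinite(kxr) & np.isfinite(kyr) & (kxr > 0) & (kyr > 0)
        bad[idx[ok]] = False
    return X, Y, kx, ax, ky, ay, redrawn


def run_scenario(s: Scenario) -> list[MethodResult]:
    """Estimate coverage probability and expected length for every requested
    method at one scenario cell.

    The Bayesian equal-tailed (MCMC) and HPD intervals are two summaries of
    the same pair of Gibbs chains, so they share one sampler run per
    replicate.  Reported ``mc_se_coverage`` is the binomial standard error
    sqrt(p(1-p)/M).
    """
    ss = np.random.SeedSequence(s.seed)
    # fixed spawn order: data stream + one stream per canonical method tag
    children = ss.spawn(1 + len(METHOD_TAGS))
    data_rng = np.random.default_rng(children[0])
    method_rng = {tag: np.random.default_rng(c) for tag, c in zip(METHOD_TAGS, children[1:])}

    params_x = WeibullParams(s.a_x, s.k_x)
    params_y = WeibullParams(s.a_y, s.k_y)
    X, Y, kx, ax, ky, ay, redrawn = _draw_valid_samples(
        data_rng, s.M, s.n, s.m, params_x, params_y
    )
    lam_x, lam_y = cv_from_shape(kx), cv_from_shape(ky)
    delta_hat = lam_x - lam_y
    true_delta = s.true_delta
    a2, a1 = s.alpha / 2.0, 1.0 - s.alpha / 2.0

    bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    if "MOVER_HR" in s.methods:
        bounds["MOVER_HR"] = _mover_bounds_batch(lam_x, s.n, lam_y, s.m, s.alpha)

    if "GCI" in s.methods:
        rng = method_rng["GCI"]
        lo = np.empty(s.M)
        hi = np.empty(s.M)
        for i in range(s.M):
            kxs, _, _ = _shape_fits_with_redraw(
                lambda r: rng.weibull(1.0, size=(r, s.n)), s.q, s.n
            )
            kys, _, _ = _shape_fits_with_redraw(
                lambda r: rng.weibull(1.0, size=(r, s.m)), s.q, s.m
            )
            r_delta = cv_from_shape(kx[i] / kxs) - cv_from_shape(ky[i] / kys)
            lo[i] = np.quantile(r_delta, a2)
            hi[i] = np.quantile(r_delta, a1)
        bounds["GCI"] = (lo, hi)

    for tag in ("PB", "BS"):
        if tag not in s.methods:
            continue
        rng = method_rng[tag]
        lo = np.empty(s.M)
        hi = np.empty(s.M)
        z = stats.norm.ppf(a1)
        for i in range(s.M):
            xi, yi = X[i], Y[i]
            if s.bootstrap_statistic == "moment":
                xb = xi[rng.integers(0, s.n, size=(s.B, s.n))]
                yb = yi[rng.integers(0, s.m, size=(s.B, s.m))]
                d_star = _moment_cv_rows(xb) - _moment_cv_rows(yb)
            else:
                kxs, _, _ = _shape_fits_with_redraw(
                    lambda r: xi[rng.integers(0, s.n, size=(r, s.n))], s.B, s.n
                )
                kys, _, _ = _shape_fits_with_redraw(
                    lambda r: yi[rng.integers(0, s.m, size=(r, s.m))], s.B, s.m
                )
                d_star = cv_from_shape(kxs) - cv_from_shape(kys)
            if tag == "PB":
                lo[i] = np.quantile(d_star, a2)
                hi[i] = np.quantile(d_star, a1)
            else:
                se = d_star.std(ddof=1)
                lo[i] = delta_hat[i] - z * se
                hi[i] = delta_hat[i] + z * se
        bounds[tag] = (lo, hi)

    if "MCMC" in s.methods or "HPD" in s.methods:
        rng = method_rng["MCMC"]
        _, kcx, _ = _gibbs_batch(X, s.prior, s.mcmc, rng, k_init=kx.copy())
        _, kcy, _ = _gibbs_batch(Y, s.prior, s.mcmc, rng, k_init=ky.copy())
        d_chains = cv_from_shape(kcx) - cv_from_shape(kcy)  # (M, kept)
        if "MCMC" in s.methods:
            bounds["MCMC"] = (
                np.quantile(d_chains, a2, axis=1),
                np.quantile(d_chains, a1, axis=1),
            )
        if "HPD" in s.methods:
            lo = np.empty(s.M)
            hi = np.empty(s.M)
            for i in range(s.M):
                iv = hpd_interval(d_chains[i], s.alpha)
                lo[i], hi[i] = iv.lower, iv.upper
            bounds["HPD"] = (lo, hi)

    results = []
    for tag in METHOD_TAGS:
        if tag not in s.methods:
            continue
        lo, hi = bounds[tag]
        covered = (lo <= true_delta) & (true_delta <= hi)
        p = float(covered.mean())
        lengths = hi - lo
        results.append(
            MethodResult(
                method=tag,
                coverage=p,
                expected_length=float(lengths.mean()),
                mc_se_coverage=float(np.sqrt(p * (1.0 - p) / s.M)),
                mc_se_length=float(lengths.std(ddof=1) / np.sqrt(s.M)) if s.M > 1 else 0.0,
                replicates_used=s.M,
                n_redrawn=redrawn,
            )
        )
    return results


def default_grid(reduced: bool = False, seed: int = 0) -> list[Scenario]:
    """The full coverage-study grid: scale in {0.5, 2} common to both groups,
    k_X = 1, k_Y in {0.5, 1, 2, 2.5, 4, 9}, eight sample-size pairs (96 cells).

    ``reduced=True`` scales the replication and tuning counts down (M=500,
    q=500, B=200, T=2000/burn-in 500) for desk-scale runs.
    """
    if reduced:
        M, q, B = 500, 500, 200
        mcmc = MCMCSettings(iterations=2_000, burn_in=500)
    else:
        M, q, B = 5_000, 2_500, 500
        mcmc = MCMCSettings(iterations=20_000, burn_in=1_000)
    grid = []
    cell = 0
    for a in SCALE_GRID:
        for k_y in SHAPE_GRID:
            for n, m in SIZE_GRID:
                grid.append(
                    Scenario(
                        n=n, m=m, a_x=a, a_y=a, k_x=1.0, k_y=k_y,
                        M=M, q=q, B=B, mcmc=mcmc, seed=seed + cell,
                    )
                )
                cell += 1
    return grid


def run_grid(scenarios: list[Scenario]) -> pd.DataFrame:
    """Run a list of scenarios and stack the results into a table."""
    rows = []
    for sc in scenarios:
        for r in run_scenario(sc):
            rows.append(
                dict(
                    n=sc.n, m=sc.m, a=sc.a_x, k_x=sc.k_x, k_y=sc.k_y,
                    method=r.method, coverage=r.coverage,
                    expected_length=r.expected_length, mc_se=r.mc_se_coverage,
                    replicates=r.replicates_used,
                )
            )
    return pd.DataFrame(rows)


def results_to_frame(results: list[MethodResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])
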