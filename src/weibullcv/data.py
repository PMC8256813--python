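"""Data ingestion, the two-sample analysis workflow, distribution screening
by AIC/BIC, and synthetic fixture generation.

Accepted input layouts:

* two files, one strictly positive value per line (or a one-column CSV);
* one "wide" CSV with two columns, possibly of unequal length (trailing
  blanks in the shorter column);
* one "long" CSV with a value column and a group-label column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import (
    GammaPrior,
    MCMCSettings,
    _gibbs_batch,
    equal_tailed_credible_interval,
    hpd_interval,
)
from .core import Observations, WeibullParams, cv_from_shape, fit_weibull_mle, sample_weibull
from .intervals import (
    METHOD_TAGS,
    bootstrap_se_interval,
    gci_delta_interval,
    mover_delta_interval,
    percentile_bootstrap_interval,
)

__all__ = [
    "TwoSampleData",
    "FitComparison",
    "read_samples",
    "model_fit_report",
    "analyze_two_samples",
    "generate_fixture",
]


@dataclass(frozen=True)
class TwoSampleData:
    """Two independent samples with display labels."""

    group_x: Observations
    group_y: Observations
    labels: tuple[str, str] = ("X", "Y")


@dataclass(frozen=True)
class FitComparison:
    """AIC/BIC screening of candidate families for one sample."""

    table: pd.DataFrame  # columns: family, loglik, n_params, aic, bic, best flags

    @property
    def best_aic(self) -> str:
        t = self.table.dropna(subset=["aic"])
        return str(t.loc[t["aic"].idxmin(), "family"])

    @property
    def best_bic(self) -> str:
        t = self.table.dropna(subset=["bic"])
        return str(t.loc[t["bic"].idxmin(), "family"])


def _parse_column(vals, source: str) -> np.ndarray:
    out = []
    for line_no, v in vals:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        s = str(v).strip()
        if not s:
            continue
        try:
            f = float(s)
        except ValueError:
            raise ValueError(f"{source}, line {line_no}: non-numeric value {s!r}")
        if not np.isfinite(f) or f <= 0.0:
            raise ValueError(f"{source}, line {line_no}: values must be > 0, got {s}")
        out.append(f)
    if len(out) < 2:
        raise ValueError(f"{source}: need at least two positive values per group")
    return np.asarray(out)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[""])


def _has_header(df: pd.DataFrame) -> bool:
    # pandas promoted the first row to column names; if any of them is not
    # a number, the file had a header row
    def numeric(c):
        try:
            float(str(c))
            return True
        except ValueError:
            return False

    return not all(numeric(c) for c in df.columns)


def _column_values(df: pd.DataFrame, col) -> list[tuple[int, object]]:
    had_header = _has_header(df)
    if not had_header:
        names = list(df.columns)
        df = pd.concat([pd.DataFrame([names], columns=names), df], ignore_index=True)
    offset = 2 if had_header else 1
    return [(i + offset, v) for i, v in enumerate(df[col])]


def read_samples(
    path_x,
    path_y=None,
    long_format: bool = False,
    value_col: str | None = None,
    group_col: str | None = None,
    labels: tuple[str, str] | None = None,
) -> TwoSampleData:
    """Read and validate a two-sample dataset.

    With two paths, each file contributes one group (single column).  With a
    single path, the file is either wide (two columns, possibly ragged) or,
    when ``long_format`` is set, long with ``value_col``/``group_col``.
    Nonpositive or non-numeric entries raise with their line number.
    """
    if path_y is not None:
        dfx, dfy = _read_table(path_x), _read_table(path_y)
        x = _parse_column(_column_values(dfx, dfx.columns[0]), str(path_x))
        y = _parse_column(_column_values(dfy, dfy.columns[0]), str(path_y))
        lab = labels or (Path(str(path_x)).stem, Path(str(path_y)).stem)
        return TwoSampleData(Observations(x), Observations(y), lab)

    df = _read_table(path_x)
    if long_format:
        vcol = value_col or df.columns[0]
        gcol = group_col or df.columns[1]
        if not _has_header(df):
            raise ValueError("long format requires a header row")
        groups = list(dict.fromkeys(df[gcol]))
        if len(groups) != 2:
            raise ValueError(f"long format needs exactly two groups, got {groups}")
        samples = []
        for g in groups:
            mask = df[gcol] == g
            vals = [(i + 2, v) for i, v in zip(np.flatnonzero(mask.values), df.loc[mask, vcol])]
            samples.append(_parse_column(vals, f"{path_x} (group {g})"))
        lab = labels or (str(groups[0]), str(groups[1]))
        return TwoSampleData(Observations(samples[0]), Observations(samples[1]), lab)

    if df.shape[1] < 2:
        raise ValueError("wide format needs two columns (or pass two files)")
    cols = list(df.columns[:2])
    x = _parse_column(_column_values(df, cols[0]), f"{path_x} (column {cols[0]})")
    y = _parse_column(_column_values(df, cols[1]), f"{path_x} (column {cols[1]})")
    lab = labels or ((str(cols[0]), str(cols[1])) if _has_header(df) else ("X", "Y"))
    return TwoSampleData(Observations(x), Observations(y), lab)


def model_fit_report(obs) -> FitComparison:
    """Fit Weibull, exponential, gamma and log-normal by maximum likelihood
    and rank them by AIC/BIC (AIC = 2p - 2 lnL, BIC = p ln n - 2 lnL)."""
    x = obs.values if isinstance(obs, Observations) else np.asarray(obs, dtype=float)
    if x.size < 3:
        raise ValueError("model screening needs at least three observations")
    n = x.size
    rows = []

    def add(family, loglik, p):
        rows.append(
            dict(
                family=family,
                loglik=loglik,
                n_params=p,
                aic=2 * p - 2 * loglik if loglik is not None else np.nan,
                bic=p * np.log(n) - 2 * loglik if loglik is not None else np.nan,
            )
        )

    try:
        fit = fit_weibull_mle(x)
        a, k = fit.params.scale, fit.params.shape
        ll = float(np.sum(stats.weibull_min.logpdf(x, k, scale=a)))
        add("weibull", ll, 2)
    except Exception:
        add("weibull", None, 2)

    mean = float(np.mean(x))
    add("exponential", float(np.sum(stats.expon.logpdf(x, scale=mean))), 1)

    try:
        shape, _, scale = stats.gamma.fit(x, floc=0)
        add("gamma", float(np.sum(stats.gamma.logpdf(x, shape, scale=scale))), 2)
    except Exception:
        add("gamma", None, 2)

    mu = float(np.mean(np.log(x)))
    sigma = float(np.std(np.log(x)))  # MLE (ddof=0)
    if sigma > 0:
        add("lognormal", float(np.sum(stats.lognorm.logpdf(x, sigma, scale=np.exp(mu)))), 2)
    else:
        add("lognormal", None, 2)

    table = pd.DataFrame(rows)
    table["best_aic"] = table["aic"] == table["aic"].min()
    table["best_bic"] = table["bic"] == table["bic"].min()
    return FitComparison(table=table)


def analyze_two_samples(
    data: TwoSampleData,
    alpha: float = 0.05,
    methods: tuple[str, ...] = METHOD_TAGS,
    q: int = 2_500,
    B: int = 500,
    mcmc: MCMCSettings | None = None,
    prior: GammaPrior | None = None,
    bootstrap_statistic: str = "moment",
    seed: int = 0,
) -> dict:
    """Full two-sample workflow: per-group MLEs and CVs, the plug-in CV
    difference, and one interval row per requested method.

    Deterministic given ``seed``: each stochastic method draws from its own
    substream, so running a subset of methods reproduces the full run's
    numbers for those methods.
    """
    unknown = set(methods) - set(METHOD_TAGS)
    if unknown:
        raise ValueError(f"unknown method tags: {sorted(unknown)}")
    mcmc = mcmc or MCMCSettings()
    prior = prior or GammaPrior()
    x, y = data.group_x.values, data.group_y.values
    fit_x, fit_y = fit_weibull_mle(x), fit_weibull_mle(y)
    lam_x = cv_from_shape(fit_x.params.shape)
    lam_y = cv_from_shape(fit_y.params.shape)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(METHOD_TAGS))
    rngs = {tag: np.random.default_rng(c) for tag, c in zip(METHOD_TAGS, children)}

    intervals = []
    if "GCI" in methods:
        intervals.append(gci_delta_interval(x, y, alpha=alpha, q=q, rng=rngs["GCI"]))
    if "PB" in methods:
        intervals.append(
            percentile_bootstrap_interval(
                x, y, alpha=alpha, B=B, rng=rngs["PB"], statistic=bootstrap_statistic
            )
        )
    if "BS" in methods:
        intervals.append(
            bootstrap_se_interval(
                x, y, alpha=alpha, B=B, rng=rngs["BS"], statistic=bootstrap_statistic
            )
        )
    if "MOVER_HR" in methods:
        intervals.append(mover_delta_interval(lam_x, x.size, lam_y, y.size, alpha=alpha))
    if "MCMC" in methods or "HPD" in methods:
        rng = rngs["MCMC"]
        _, kcx, _ = _gibbs_batch(x[None, :], prior, mcmc, rng)
        _, kcy, _ = _gibbs_batch(y[None, :], prior, mcmc, rng)
        d = cv_from_shape(kcx[0]) - cv_from_shape(kcy[0])
        if "MCMC" in methods:
            intervals.append(equal_tailed_credible_interval(d, alpha=alpha))
        if "HPD" in methods:
            intervals.append(hpd_interval(d, alpha=alpha))

    rows = [
        dict(method=iv.method, lower=iv.lower, upper=iv.upper, length=iv.length)
        for iv in intervals
    ]
    return dict(
        labels=data.labels,
        n=x.size,
        m=y.size,
        scale_x=fit_x.params.scale,
        shape_x=fit_x.params.shape,
        scale_y=fit_y.params.scale,
        shape_y=fit_y.params.shape,
        cv_x=lam_x,
        cv_y=lam_y,
        delta_hat=lam_x - lam_y,
        alpha=alpha,
        seed=seed,
        intervals=pd.DataFrame(rows),
    )


def generate_fixture(
    params_x: WeibullParams,
    n: int,
    params_y: WeibullParams,
    m: int,
    seed: int,
    out_prefix,
) -> TwoSampleData:
    """Write a long-format CSV fixture plus a JSON sidecar recording the
    generating parameters and the true CV difference."""
    rng = np.random.default_rng(seed)
    x = sample_weibull(n, params_x, rng)
    y = sample_weibull(m, params_y, rng)
    prefix = Path(str(out_prefix))
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        dict(value=np.concatenate([x, y]), group=["X"] * n + ["Y"] * m)
    )
    df.to_csv(prefix.with_suffix(".csv"), index=False, float_format="%.17g")
    true_delta = float(cv_from_shape(params_x.shape) - cv_from_shape(params_y.shape))
    sidecar = dict(
        seed=seed,
        n=n,
        m=m,
        scale_x=params_x.scale,
        shape_x=params_x.shape,
        scale_y=params_y.scale,
        shape_y=params_y.shape,
        true_delta=true_delta,
    )
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return TwoSampleData(Observations(x), Observations(y))
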