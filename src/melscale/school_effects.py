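"""Derived, reportable cluster-level quantities.

Everything here is computed from stored posterior draws of the fitted
model: shrunken cluster effects with credible intervals, school-specific
residual variances at a common reference covariate profile, the
random-slope variance decomposition, plausible-value ranges (PVRs),
variance partition summaries, ranks, and significance flags for
caterpillar plots.

A PVR describes the population spread of cluster effects —
``center +/- z * sqrt(variance)`` of the random-effect distribution —
and is not a credible interval for any single cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import AnalysisTable
from .mcmc_engine import FitResult

__all__ = [
    "ReferenceProfile",
    "shrunken_effects",
    "cluster_variance",
    "cluster_mean_adjusted",
    "total_adjusted_variance",
    "pvr",
    "population_average_variance",
    "within_cluster_range",
    "variance_explained_and_vpc",
    "rank_and_flag",
    "caterpillar_data",
]


@dataclass
class ReferenceProfile:
    """Common covariate values at which cluster summaries are compared.

    Cluster-specific variances and mean effects depend on covariates, so
    fair cross-cluster comparison requires evaluating them at one common
    profile: by default the sample means of the variance-function
    covariates (zero for standardized scores), the sample mean of ``x1``
    for the slope contribution, and the mean of the per-cluster sample
    variances of ``x1`` for the slope variance component.
    """

    variance_covariates: dict[str, float] = field(default_factory=dict)
    mean_x1: float = 0.0
    var_x1: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_x1) or not np.isfinite(self.var_x1):
            raise ValueError("profile values must be finite")
        if self.var_x1 < 0:
            raise ValueError("var_x1 must be >= 0")

    @classmethod
    def from_table(cls, table: AnalysisTable) -> "ReferenceProfile":
        frame = table.design_frame()
        cov = {
            c: float(frame[c].mean())
            for c in frame.columns
            if c not in ("unit_id", "cluster_id", "y")
        }
        g = table.group_codes
        x1 = table.data["x1"].to_numpy(dtype=float)
        n_j = table.n_j
        m = np.bincount(g, weights=x1, minlength=table.J) / n_j
        ss = np.bincount(g, weights=x1**2, minlength=table.J)
        with np.errstate(invalid="ignore"):
            per_cluster_var = np.where(
                n_j > 1, (ss - n_j * m**2) / np.maximum(n_j - 1, 1), np.nan
            )
        return cls(
            variance_covariates=cov,
            mean_x1=float(np.mean(x1)),
            var_x1=float(np.nanmean(per_cluster_var)),
        )

    def variance_design_row(self, spec) -> np.ndarray:
        row = [1.0]
        for name in spec.variance_covariates:
            if name not in self.variance_covariates:
                raise KeyError(f"profile missing variance covariate {name!r}")
            row.append(self.variance_covariates[name])
        return np.asarray(row)


def _require_effects(fit: FitResult) -> np.ndarray:
    if fit.effects is None:
        raise ValueError("fit did not store effect draws")
    # flatten chains x iterations -> draws
    e = fit.effects
    return e.reshape(-1, e.shape[-2], e.shape[-1])


def _summarize(draws: np.ndarray, level: float) -> dict[str, np.ndarray]:
    """Posterior mean/SD and equal-tailed CI over axis 0."""
    lo, hi = 50 * (1 - level), 50 * (1 + level)
    return {
        "mean": draws.mean(axis=0),
        "sd": draws.std(axis=0, ddof=1),
        "lo": np.percentile(draws, lo, axis=0),
        "hi": np.percentile(draws, hi, axis=0),
    }


def shrunken_effects(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Per-cluster posterior summaries of the raw effects.

    The posterior means are shrunken toward zero relative to raw
    per-cluster statistics, more strongly for smaller clusters.
    """
    E = _require_effects(fit)
    rows = {"cluster_id": fit.cluster_ids, "n_j": fit.n_j}
    for k, name in enumerate(fit.spec.effect_names):
        s = _summarize(E[:, :, k], level)
        for stat, vals in s.items():
            rows[f"{name}_{stat}"] = vals
    return pd.DataFrame(rows)


def cluster_mean_adjusted(
    fit: FitResult, profile: ReferenceProfile | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Cluster mean effect at a common prior score: ``u0_j + u1_j * xbar``.

    Reduces to the ``u0_j`` summary for intercept-only specs (and at
    ``xbar = 0`` for any spec).
    """
    profile = profile or ReferenceProfile()
    E = _require_effects(fit)
    draws = E[:, :, 0]
    if fit.spec.random_slope:
        draws = draws + E[:, :, 1] * profile.mean_x1
    s = _summarize(draws, level)
    return pd.DataFrame(
        {
            "cluster_id": fit.cluster_ids,
            "n_j": fit.n_j,
            **{f"mean_effect_{k}": v for k, v in s.items()},
        }
    )


def _variance_draws(fit: FitResult, profile: ReferenceProfile) -> np.ndarray:
    """Draws of sigma2_e,j = exp(alpha' xref + v_j), shape (draws, J)."""
    xref = profile.variance_design_row(fit.spec)
    a = fit.alpha.reshape(-1, fit.alpha.shape[-1]) @ xref  # (draws,)
    if fit.spec.random_scale:
        E = _require_effects(fit)
        return np.exp(a[:, None] + E[:, :, fit.spec.scale_index])
    J = len(fit.cluster_ids)
    return np.exp(np.repeat(a[:, None], J, axis=1))


def cluster_variance(
    fit: FitResult, profile: ReferenceProfile | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Cluster residual variance at the reference profile.

    For specs without a scale effect the value is common to all
    clusters (``exp(alpha' xref)`` summarized over draws).
    """
    profile = profile or ReferenceProfile()
    draws = _variance_draws(fit, profile)
    s = _summarize(draws, level)
    return pd.DataFrame(
        {
            "cluster_id": fit.cluster_ids,
            "n_j": fit.n_j,
            **{f"variance_{k}": v for k, v in s.items()},
        }
    )


def total_adjusted_variance(
    fit: FitResult, profile: ReferenceProfile | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Decomposed per-cluster variance ``u1_j^2 * Var(x1) + sigma2_e,j``.

    The ``share`` column is the slope component's fraction of the total
    (exactly zero for specs without a random slope).
    """
    profile = profile or ReferenceProfile()
    if profile.var_x1 < 0:
        raise ValueError("profile var_x1 must be >= 0")
    resid = _variance_draws(fit, profile)
    if fit.spec.random_slope:
        E = _require_effects(fit)
        slope = E[:, :, 1] ** 2 * profile.var_x1
    else:
        slope = np.zeros_like(resid)
    total = slope + resid
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, slope / total, 0.0)
    out = {"cluster_id": fit.cluster_ids, "n_j": fit.n_j}
    for label, draws in (
        ("total", total),
        ("slope_component", slope),
        ("residual_component", resid),
        ("share", share),
    ):
        s = _summarize(draws, level)
        out[f"{label}_mean"] = s["mean"]
        if label == "total":
            out["total_lo"], out["total_hi"] = s["lo"], s["hi"]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------
# Scalar population summaries
# ---------------------------------------------------------------------

def pvr(
    center: float, variance: float, level: float = 0.95, scale: str = "identity"
) -> tuple[float, float]:
    """Plausible values range ``center +/- z * sqrt(variance)``.

    With ``scale="exp"`` the endpoints are exponentiated (for variance
    effects modeled on the log scale); this commutes with taking the
    identity-scale PVR first.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if scale not in ("identity", "exp"):
        raise ValueError("scale must be 'identity' or 'exp'")
    z = norm.ppf(0.5 * (1 + level))
    half = z * np.sqrt(variance)
    lo, hi = center - half, center + half
    if scale == "exp":
        return float(np.exp(lo)), float(np.exp(hi))
    return float(lo), float(hi)


def population_average_variance(alpha0: float, sigma_v2: float) -> float:
    """Population-averaged residual variance ``exp(alpha0 + sigma_v2/2)``.

    The mean of a log-normal variable whose log has mean ``alpha0`` and
    variance ``sigma_v2``.
    """
    if sigma_v2 < 0:
        raise ValueError("sigma_v2 must be >= 0")
    return float(np.exp(alpha0 + 0.5 * sigma_v2))


def within_cluster_range(variance: float, level: float = 0.95) -> float:
    """Spread between the upper and lower tail units of one cluster.

    ``2 * z * sqrt(variance)``: e.g. the gap in adjusted achievement
    between students at the 97.5th and 2.5th percentile within a school
    whose residual variance is ``variance``.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    z = norm.ppf(0.5 * (1 + level))
    return float(2.0 * z * np.sqrt(variance))


def variance_explained_and_vpc(sigma_u2: float, sigma_e2: float) -> tuple[float, float]:
    """Percent outcome variance explained, and the VPC, in percent.

    Assumes a standardized outcome (unit total variance), so the
    explained share is ``100 * (1 - (sigma_u2 + sigma_e2))`` and the
    variance partition coefficient is
    ``100 * sigma_u2 / (sigma_u2 + sigma_e2)``.
    """
    if sigma_u2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be >= 0")
    total = sigma_u2 + sigma_e2
    explained = 100.0 * (1.0 - total)
    if explained < 0:
        warnings.warn("total residual variance exceeds 1; clipping explained% at 0")
        explained = 0.0
    vpc = 100.0 * sigma_u2 / total if total > 0 else 0.0
    return float(explained), float(vpc)


# ---------------------------------------------------------------------
# Ranks and flags
# ---------------------------------------------------------------------

def rank_and_flag(
    summaries: pd.DataFrame,
    null_value: float,
    mean_col: str = "mean",
    lo_col: str = "lo",
    hi_col: str = "hi",
) -> pd.DataFrame:
    """Rank clusters by point estimate and flag separable ones.

    A cluster is flagged when its credible interval excludes the
    population-average comparator ``null_value`` (0 for mean effects;
    the population-averaged variance for variance effects).  Ranks are
    1..J ascending in the point estimate, ties broken by table order.
    """
    for col in (mean_col, lo_col, hi_col):
        if col not in summaries.columns:
            raise KeyError(f"summaries missing column {col!r}")
    out = summaries.copy()
    order = np.lexsort((np.arange(len(out)), out[mean_col].to_numpy()))
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    out["flag"] = (out[lo_col] > null_value) | (out[hi_col] < null_value)
    out["null_value"] = null_value
    return out


def caterpillar_data(ranked: pd.DataFrame, mean_col: str = "mean",
                     lo_col: str = "lo", hi_col: str = "hi") -> pd.DataFrame:
    """Plot-ready table sorted by rank (rank, point, lo, hi, flag)."""
    cols = ["cluster_id", "rank", mean_col, lo_col, hi_col, "flag"]
    cols = [c for c in cols if c in ranked.columns]
    return ranked.sort_values("rank")[cols].reset_index(drop=True)


def plot_caterpillar(ranked: pd.DataFrame, ax=None, **kwargs):
    """Render a caterpillar plot (requires matplotlib)."""
    import matplotlib.pyplot as plt

    data = caterpillar_data(ranked, **{k: v for k, v in kwargs.items() if k.endswith("_col")})
    if ax is None:
        _, ax = plt.subplots()
    mean_col = kwargs.get("mean_col", "mean")
    lo_col = kwargs.get("lo_col", "lo")
    hi_col = kwargs.get("hi_col", "hi")
    x = data["rank"]
    ax.errorbar(
        x,
        data[mean_col],
        yerr=[data[mean_col] - data[lo_col], data[hi_col] - data[mean_col]],
        fmt="o",
        ms=2,
        lw=0.5,
        alpha=0.7,
    )
    if "null_value" in ranked.columns:
        ax.axhline(float(ranked["null_value"].iloc[0]), color="k", ls="--", lw=0.8)
    ax.set_xlabel("rank")
    return ax
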