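"""Posterior sampling for mixed-effects location scale models.

The sampler is a Metropolis-Hastings-within-Gibbs scheme on the
complete-data posterior, vectorised across clusters:

* mean-function cluster effects ``(u0[, u1])`` — exact conjugate
  multivariate-normal draws given the scale effects (closed-form 1x1/2x2
  per-cluster solves, all clusters at once);
* scale effects ``v_j`` — per-cluster adaptive random-walk MH with
  Robbins-Monro step-size tuning toward 0.44 acceptance during burnin;
* regression coefficients ``beta`` — conjugate weighted-regression draw;
* variance-function coefficients ``alpha`` — block adaptive random-walk
  MH with a curvature-matched proposal, tuned toward 0.23 (0.44 when
  scalar) during burnin;
* random-effect covariance ``Sigma`` — conjugate inverse-Wishart;
* translation ("recentring") Gibbs moves along the ``(beta0, u0)``,
  ``(beta1, u1)`` and ``(alpha0, v)`` directions, which leave the
  likelihood invariant and decouple the fixed intercepts from the means
  of the random effects — the hierarchical-centering idea expressed as
  exact directional Gibbs steps.

All adaptation happens during burnin only and is frozen afterwards, so
the monitoring draws target the exact posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import invwishart

from .data_model import AnalysisTable, design_matrices
from .mels_core import ModelSpec, ParameterSet, PriorSpec

__all__ = [
    "McmcConfig",
    "FitResult",
    "fit",
    "gelman_rubin",
    "effective_sample_size",
    "dic",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration.

    Defaults follow common practice for these models: four chains with
    5,000 burnin and 10,000 monitoring iterations, overdispersed starts.
    ``init_dispersion`` scales the spread of the starting values around
    crude moment estimates.
    """

    chains: int = 4
    burnin: int = 5000
    iterations: int = 10000
    seed: int | None = None
    target_accept_scalar: float = 0.44
    target_accept_block: float = 0.23
    init_dispersion: float = 1.0
    store_effects: bool = True

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.iterations <= 0:
            raise ValueError("iterations must be > 0")
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")


@dataclass
class FitResult:
    """Posterior draws plus summaries for one fitted model.

    Draw arrays are shaped ``(chains, iterations, ...)`` and cover the
    monitoring period only.  ``effects`` may be ``None`` when effect
    storage was disabled.
    """

    spec: ModelSpec
    priors: PriorSpec
    config: McmcConfig
    cluster_ids: list[str]
    n_j: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    Sigma: np.ndarray
    deviance: np.ndarray
    effects: np.ndarray | None
    accept_v: np.ndarray
    accept_alpha: np.ndarray
    _data: dict = field(repr=False, default_factory=dict)

    # ---- naming ------------------------------------------------------
    @property
    def parameter_names(self) -> list[str]:
        names = [f"beta{k}" for k in range(self.beta.shape[-1])]
        names += [f"alpha{k}" for k in range(self.alpha.shape[-1])]
        eff = self.spec.effect_names
        names += [f"sigma2_{e}" for e in eff]
        names += [
            f"rho_{eff[a]}{eff[b]}"
            for a in range(len(eff))
            for b in range(a + 1, len(eff))
        ]
        return names

    def named_draws(self, name: str) -> np.ndarray:
        """Draws for one scalar parameter, shaped (chains, iterations)."""
        eff = self.spec.effect_names
        if name.startswith("beta"):
            return self.beta[..., int(name[4:])]
        if name.startswith("alpha"):
            return self.alpha[..., int(name[5:])]
        if name.startswith("sigma2_"):
            k = eff.index(name[7:])
            return self.Sigma[..., k, k]
        if name.startswith("rho_"):
            pair = name[4:]
            for a in range(len(eff)):
                if pair.startswith(eff[a]) and pair[len(eff[a]):] in eff:
                    b = eff.index(pair[len(eff[a]):])
                    den = np.sqrt(self.Sigma[..., a, a] * self.Sigma[..., b, b])
                    return self.Sigma[..., a, b] / den
        if name == "deviance":
            return self.deviance
        raise KeyError(f"unknown parameter {name!r}")

    # ---- summaries ---------------------------------------------------
    def summary(self, level: float = 0.95):
        """Posterior mean, SD, equal-tailed CI, split-R-hat and ESS."""
        import pandas as pd

        lo, hi = 50 * (1 - level), 50 * (1 + level)
        rows = []
        for name in self.parameter_names:
            d = self.named_draws(name)
            row = {
                "parameter": name,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                f"ci{lo:g}": float(np.percentile(d, lo)),
                f"ci{hi:g}": float(np.percentile(d, hi)),
                "ess": effective_sample_size(d),
            }
            row["rhat"] = gelman_rubin(d) if self.config.chains >= 2 else np.nan
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")

    @property
    def params_mean(self) -> ParameterSet:
        """Posterior means assembled into a ParameterSet."""
        return ParameterSet(
            self.beta.mean(axis=(0, 1)),
            self.alpha.mean(axis=(0, 1)),
            self.Sigma.mean(axis=(0, 1)),
        )

    @property
    def effects_mean(self) -> np.ndarray:
        if self.effects is None:
            raise ValueError("effect draws were not stored")
        return self.effects.mean(axis=(0, 1))

    @property
    def dic(self) -> float:
        return dic(self)

    def diagnostics_pass(self, rhat_max: float = 1.05, ess_min: float = 400.0) -> bool:
        s = self.summary()
        ok = bool((s["ess"] > ess_min).all())
        if self.config.chains >= 2:
            ok = ok and bool((s["rhat"] < rhat_max).all())
        return ok

    # ---- persistence -------------------------------------------------
    def save(self, path) -> None:
        """Save draws and metadata to an .npz archive."""
        import json

        meta = {
            "spec": {
                "mean_covariates": list(self.spec.mean_covariates),
                "variance_covariates": list(self.spec.variance_covariates),
                "random_slope": self.spec.random_slope,
                "random_scale": self.spec.random_scale,
            },
            "config": {
                "chains": self.config.chains,
                "burnin": self.config.burnin,
                "iterations": self.config.iterations,
                "seed": self.config.seed,
            },
            "cluster_ids": self.cluster_ids,
        }
        arrays = {
            "beta": self.beta,
            "alpha": self.alpha,
            "Sigma": self.Sigma,
            "deviance": self.deviance,
            "n_j": self.n_j,
            "accept_v": self.accept_v,
            "accept_alpha": self.accept_alpha,
            "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        }
        if self.effects is not None:
            arrays["effects"] = self.effects
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "FitResult":
        """Load a saved fit (derived summaries available; DIC is not
        recomputable without the data and is reported from the draws)."""
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            spec = ModelSpec(
                tuple(meta["spec"]["mean_covariates"]),
                tuple(meta["spec"]["variance_covariates"]),
                meta["spec"]["random_slope"],
                meta["spec"]["random_scale"],
            )
            config = McmcConfig(
                chains=meta["config"]["chains"],
                burnin=meta["config"]["burnin"],
                iterations=meta["config"]["iterations"],
                seed=meta["config"]["seed"],
            )
            return cls(
                spec=spec,
                priors=PriorSpec(),
                config=config,
                cluster_ids=list(meta["cluster_ids"]),
                n_j=z["n_j"],
                beta=z["beta"],
                alpha=z["alpha"],
                Sigma=z["Sigma"],
                deviance=z["deviance"],
                effects=z["effects"] if "effects" in z.files else None,
                accept_v=z["accept_v"],
                accept_alpha=z["accept_alpha"],
                _data={},
            )


# ---------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------

def _as_chain_array(draws) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("draws must be 1-D or (chains, iterations)")
    return arr


def gelman_rubin(draws, parameter: str | None = None) -> float:
    """Rank-normalised split-R-hat (via arviz); ~1 at convergence."""
    import arviz as az

    if isinstance(draws, FitResult):
        draws = draws.named_draws(parameter)
    arr = _as_chain_array(draws)
    if arr.shape[0] < 2:
        raise ValueError("Gelman-Rubin diagnostic needs >= 2 chains")
    return float(az.rhat(az.convert_to_dataset(arr))["x"].values)


def effective_sample_size(draws, parameter: str | None = None) -> float:
    """Autocorrelation-based effective sample size (arviz bulk ESS)."""
    import arviz as az

    if isinstance(draws, FitResult):
        draws = draws.named_draws(parameter)
    arr = _as_chain_array(draws)
    if np.ptp(arr) < 1e-14 * max(1.0, abs(float(arr.flat[0]))):
        warnings.warn("constant chain: effective sample size undefined, returning 0")
        return 0.0
    return float(az.ess(az.convert_to_dataset(arr))["x"].values)


def dic(fit: FitResult) -> float:
    """Deviance information criterion, conditional on cluster effects.

    ``DIC = Dbar + pD`` with ``pD = Dbar - D(posterior means)``, the
    deviance being ``-2 log p(y | params, effects)``.  The conditional
    (effects-in-focus) form matches the cluster-level focus of the
    analysis.
    """
    if not fit._data:
        raise ValueError("DIC needs the fitting data; it is unavailable on a loaded fit")
    if fit.deviance.size < 100:
        warnings.warn("fewer than 100 draws: DIC estimate will be noisy")
    dbar = float(fit.deviance.mean())
    d = fit._data
    p = fit.params_mean
    U = fit.effects_mean
    mu = d["X_mean"] @ p.beta + U[d["groups"], 0]
    if fit.spec.random_slope:
        mu = mu + U[d["groups"], 1] * d["x1"]
    lv = d["X_var"] @ p.alpha
    if fit.spec.random_scale:
        lv = lv + U[d["groups"], fit.spec.scale_index]
    dev_hat = float(np.sum(_LOG2PI + lv + (d["y"] - mu) ** 2 * np.exp(-lv)))
    return 2.0 * dbar - dev_hat


# ---------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------

def fit(
    table: AnalysisTable,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
) -> FitResult:
    """Fit a MELS model by MCMC; reproducible given ``config.seed``."""
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    X_mean, X_var = design_matrices(table, spec)
    y = table.data["y"].to_numpy(dtype=float)
    x1 = table.data["x1"].to_numpy(dtype=float)
    g = table.group_codes
    n_j = table.n_j
    if np.any(n_j < 1):
        raise ValueError("every cluster must have at least one unit")

    ss = np.random.SeedSequence(config.seed)
    chains = []
    for child in ss.spawn(config.chains):
        rng = np.random.default_rng(child)
        chains.append(
            _run_chain(y, X_mean, X_var, x1, g, n_j, spec, priors, config, rng)
        )

    stack = lambda key: np.stack([c[key] for c in chains])
    return FitResult(
        spec=spec,
        priors=priors,
        config=config,
        cluster_ids=table.cluster_ids,
        n_j=n_j,
        beta=stack("beta"),
        alpha=stack("alpha"),
        Sigma=stack("Sigma"),
        deviance=stack("deviance"),
        effects=stack("effects") if config.store_effects else None,
        accept_v=np.array([c["accept_v"] for c in chains]),
        accept_alpha=np.array([c["accept_alpha"] for c in chains]),
        _data={"y": y, "X_mean": X_mean, "X_var": X_var, "x1": x1, "groups": g},
    )


def _initial_state(y, X_mean, X_var, x1, g, n_j, spec, config, rng):
    """Overdispersed start around crude moment estimates."""
    disp = config.init_dispersion
    beta, *_ = np.linalg.lstsq(X_mean, y, rcond=None)
    resid = y - X_mean @ beta
    J = n_j.size
    cluster_mean = np.bincount(g, weights=resid, minlength=J) / n_j
    within = resid - cluster_mean[g]
    var_within = float(np.var(within, ddof=1))
    alpha = np.zeros(X_var.shape[1])
    alpha[0] = np.log(max(var_within, 1e-8))

    d = spec.n_effects
    diag = [max(float(np.var(cluster_mean, ddof=1)), 1e-3)]
    if spec.random_slope:
        diag.append(5e-3)
    if spec.random_scale:
        safe = n_j > 3
        lcv = np.log(
            np.maximum(np.bincount(g, weights=within**2, minlength=J) / n_j, 1e-8)
        )
        diag.append(max(float(np.var(lcv[safe], ddof=1)) - 2.0 / max(np.mean(n_j), 4), 0.02))
    Sigma = np.diag(diag)

    beta = beta + 0.1 * disp * rng.standard_normal(beta.size)
    alpha = alpha + 0.1 * disp * rng.standard_normal(alpha.size)
    Sigma = Sigma * np.exp(0.3 * disp * rng.standard_normal())
    U = np.zeros((J, d))
    return beta, alpha, Sigma, U


def _run_chain(y, X_mean, X_var, x1, g, n_j, spec, priors, config, rng):
    N = y.size
    J = n_j.size
    pm, pv = X_mean.shape[1], X_var.shape[1]
    d = spec.n_effects
    du = spec.n_mean_effects
    has_scale = spec.random_scale
    has_slope = spec.random_slope
    iv = spec.scale_index
    cv = priors.coef_variance
    df0 = priors.df(d)
    S0 = priors.scale_matrix(d)

    beta, alpha, Sigma, U = _initial_state(
        y, X_mean, X_var, x1, g, n_j, spec, config, rng
    )
    Omega = np.linalg.inv(Sigma)
    eta = X_var @ alpha

    # curvature-matched alpha proposal: Fisher info of a log-variance
    # regression is 0.5 * Xv'Xv
    info = 0.5 * X_var.T @ X_var + np.eye(pv) / cv
    L_prop = np.linalg.cholesky(np.linalg.inv(info))
    alpha_scale = 2.38 / np.sqrt(pv)
    alpha_target = (
        config.target_accept_scalar if pv == 1 else config.target_accept_block
    )
    v_step = 2.4 * np.sqrt(2.0 / np.maximum(n_j, 2))

    T = config.iterations
    out = {
        "beta": np.empty((T, pm)),
        "alpha": np.empty((T, pv)),
        "Sigma": np.empty((T, d, d)),
        "deviance": np.empty(T),
        "effects": np.empty((T, J, d)) if config.store_effects else None,
    }
    acc_v = 0.0
    acc_a = 0.0
    n_mon = 0

    total = config.burnin + T
    for t in range(total):
        adapting = t < config.burnin
        gamma = (t + 1.0) ** -0.6 if adapting else 0.0

        # --- conditional prior of the mean-effect block given v -------
        if has_scale:
            A = Sigma[:du, :du]
            Bv = Sigma[:du, iv]
            c_v = Sigma[iv, iv]
            cond_cov = A - np.outer(Bv, Bv) / c_v
            Q = np.linalg.inv(cond_cov)
            prior_mean = np.outer(U[:, iv], Bv / c_v)  # (J, du)
            v_g = U[g, iv]
        else:
            Q = np.linalg.inv(Sigma[:du, :du])
            prior_mean = np.zeros((J, du))
            v_g = 0.0

        # --- (1) conjugate draw of (u0[, u1]) per cluster -------------
        w = np.exp(-np.clip(eta + v_g, -40.0, 40.0))
        r = y - X_mean @ beta
        S11 = np.bincount(g, weights=w, minlength=J)
        b1 = np.bincount(g, weights=w * r, minlength=J)
        if du == 1:
            post_prec = S11 + Q[0, 0]
            h = b1 + Q[0, 0] * prior_mean[:, 0]
            mean_u = h / post_prec
            U[:, 0] = mean_u + rng.standard_normal(J) / np.sqrt(post_prec)
        else:
            S1x = np.bincount(g, weights=w * x1, minlength=J)
            Sxx = np.bincount(g, weights=w * x1 * x1, minlength=J)
            bx = np.bincount(g, weights=w * r * x1, minlength=J)
            P00 = S11 + Q[0, 0]
            P01 = S1x + Q[0, 1]
            P11 = Sxx + Q[1, 1]
            h0 = b1 + Q[0, 0] * prior_mean[:, 0] + Q[0, 1] * prior_mean[:, 1]
            h1 = bx + Q[1, 0] * prior_mean[:, 0] + Q[1, 1] * prior_mean[:, 1]
            det = P00 * P11 - P01**2
            L00 = np.sqrt(P00)
            L10 = P01 / L00
            L11 = np.sqrt(np.maximum(P11 - L10**2, 1e-12))
            z0 = rng.standard_normal(J)
            z1 = rng.standard_normal(J)
            t0 = h0 + L00 * z0
            t1 = h1 + L10 * z0 + L11 * z1
            U[:, 0] = (P11 * t0 - P01 * t1) / det
            U[:, 1] = (P00 * t1 - P01 * t0) / det

        # --- (2) per-cluster MH on v ----------------------------------
        if has_scale:
            mu = X_mean @ beta + U[g, 0]
            if has_slope:
                mu = mu + U[g, 1] * x1
            e2w = (y - mu) ** 2 * np.exp(-np.clip(eta, -40.0, 40.0))
            A_j = np.bincount(g, weights=e2w, minlength=J)
            k = np.linalg.solve(Sigma[:du, :du], Sigma[iv, :du])
            m_cond = U[:, :du] @ k
            tau2 = max(float(Sigma[iv, iv] - Sigma[iv, :du] @ k), 1e-12)
            v_cur = U[:, iv]
            v_prop = v_cur + v_step * rng.standard_normal(J)
            lt_cur = (
                -0.5 * (n_j * v_cur + A_j * np.exp(-np.clip(v_cur, -40, 40)))
                - 0.5 * (v_cur - m_cond) ** 2 / tau2
            )
            lt_prop = (
                -0.5 * (n_j * v_prop + A_j * np.exp(-np.clip(v_prop, -40, 40)))
                - 0.5 * (v_prop - m_cond) ** 2 / tau2
            )
            accept = np.log(rng.random(J)) < (lt_prop - lt_cur)
            U[accept, iv] = v_prop[accept]
            if adapting:
                v_step *= np.exp(
                    gamma * (accept.astype(float) - config.target_accept_scalar)
                )
            elif not adapting:
                acc_v += float(np.mean(accept))

        # --- (3) recentring (translation Gibbs) moves ------------------
        def _translate(col: int, coef: np.ndarray, idx: int):
            a = Omega[col, col]
            bsum = float(np.sum(U @ Omega[:, col]))
            prec = J * a + 1.0 / cv
            mean = (bsum - coef[idx] / cv) / prec
            delta = mean + rng.standard_normal() / np.sqrt(prec)
            coef[idx] += delta
            U[:, col] -= delta
            return delta

        _translate(0, beta, 0)
        if has_slope:
            _translate(1, beta, 1)
        if has_scale:
            delta = _translate(iv, alpha, 0)
            eta = eta + delta  # intercept column of X_var is 1

        # --- (4) conjugate beta ---------------------------------------
        v_g = U[g, iv] if has_scale else 0.0
        w = np.exp(-np.clip(eta + v_g, -40.0, 40.0))
        z = y - U[g, 0] - (U[g, 1] * x1 if has_slope else 0.0)
        Xw = X_mean * w[:, None]
        P = X_mean.T @ Xw + np.eye(pm) / cv
        h = Xw.T @ z
        cf = cho_factor(P, lower=True)
        beta = cho_solve(cf, h) + solve_triangular(
            cf[0].T, rng.standard_normal(pm), lower=False
        )

        # --- (5) block MH on alpha ------------------------------------
        mu = X_mean @ beta + U[g, 0]
        if has_slope:
            mu = mu + U[g, 1] * x1
        e2 = (y - mu) ** 2

        def alpha_logtarget(a_vec, eta_vec):
            lv = np.clip(eta_vec + v_g, -40.0, 40.0)
            return (
                -0.5 * float(np.sum(lv + e2 * np.exp(-lv)))
                - 0.5 * float(a_vec @ a_vec) / cv
            )

        lt_cur = alpha_logtarget(alpha, eta)
        step = alpha_scale * (L_prop @ rng.standard_normal(pv))
        alpha_prop = alpha + step
        eta_prop = eta + X_var @ step
        lt_prop = alpha_logtarget(alpha_prop, eta_prop)
        acc = np.log(rng.random()) < (lt_prop - lt_cur)
        if acc:
            alpha, eta = alpha_prop, eta_prop
        if adapting:
            alpha_scale *= np.exp(gamma * (float(acc) - alpha_target))
        else:
            acc_a += float(acc)

        # --- (6) conjugate inverse-Wishart for Sigma -------------------
        Sn = S0 + U.T @ U
        Sigma = invwishart.rvs(df=df0 + J, scale=Sn, random_state=rng)
        Sigma = np.atleast_2d(Sigma)
        try:
            Omega = np.linalg.inv(Sigma)
        except np.linalg.LinAlgError:
            Sigma = Sigma + 1e-10 * np.eye(d)
            Omega = np.linalg.inv(Sigma)
            warnings.warn("jittered a near-singular Sigma draw")

        # --- (7) record ------------------------------------------------
        if not adapting:
            lv = np.clip(eta + (U[g, iv] if has_scale else 0.0), -40.0, 40.0)
            dev = float(np.sum(_LOG2PI + lv + (y - mu) ** 2 * np.exp(-lv)))
            if not np.isfinite(dev):
                raise RuntimeError(
                    f"divergent state at iteration {t}: non-finite deviance"
                )
            i = t - config.burnin
            out["beta"][i] = beta
            out["alpha"][i] = alpha
            out["Sigma"][i] = Sigma
            out["deviance"][i] = dev
            if config.store_effects:
                out["effects"][i] = U
            n_mon += 1

    out["accept_v"] = acc_v / max(n_mon, 1) if has_scale else np.nan
    out["accept_alpha"] = acc_a / max(n_mon, 1)
    return out
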