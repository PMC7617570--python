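"""Model specification and probability computations for mixed-effects
location scale (MELS) regressions.

The model family covers a clustered continuous outcome ``y_ij`` (unit *i*
in cluster *j*) whose mean and log residual variance both carry fixed
covariate effects and cluster-level random effects::

    y_ij = beta' x_ij + u0_j (+ u1_j * x1_ij) + e_ij
    ln sigma2_e,ij = alpha' w_ij (+ v_j)
    (u0_j[, u1_j][, v_j]) ~ N(0, Sigma),   e_ij ~ N(0, sigma2_e,ij)

The canonical eight-model sequence used in school value-added work is
expressible through :class:`ModelSpec`:

=====  ==================  ===========  ======  ======
model  mean covariates     var. covs    slope   scale
=====  ==================  ===========  ======  ======
1      x1                  --           no      no
2      x1                  --           no      yes
3      x1                  x1           no      yes
4      x1                  --           yes     no
5      x1                  --           yes     yes
6      x1                  x1           yes     yes
7      x1 + student        x1 + student no      yes
8      7 + school          7 + school   no      yes
=====  ==================  ===========  ======  ======

The log link keeps every implied residual variance strictly positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp
from scipy.stats import invwishart, multivariate_normal

__all__ = [
    "STUDENT_COVARIATES",
    "SCHOOL_COVARIATES",
    "ModelSpec",
    "ParameterSet",
    "PriorSpec",
    "model_spec",
    "parameters_from_summaries",
    "mean_value",
    "logvar_value",
    "loglik_conditional",
    "logprior",
    "logposterior_complete",
    "marginal_loglik_quadrature",
]

#: Unit-level binary covariates in the order used by the full student model.
STUDENT_COVARIATES: tuple[str, ...] = (
    "summer_born",
    "girl",
    "eth_black",
    "eth_asian",
    "eth_chinese",
    "eth_mixed",
    "eth_other",
    "lang_not_english",
    "sen",
    "fsm",
)

#: Cluster-level binary covariates (dummy-coded school characteristics).
SCHOOL_COVARIATES: tuple[str, ...] = (
    "type_sponsored",
    "type_converter",
    "type_other",
    "adm_grammar",
    "adm_secondary_modern",
    "gender_boys",
    "gender_girls",
    "religious",
)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter each function and which random effects exist.

    Parameters
    ----------
    mean_covariates
        Ordered covariate names for the mean function; the prior score
        ``x1`` must come first (the random slope, when present, is on it).
    variance_covariates
        Ordered covariate names for the log residual-variance function;
        empty means an intercept-only variance function.
    random_slope
        Include a cluster random slope ``u1_j`` on ``x1``.
    random_scale
        Include a cluster random effect ``v_j`` in the variance function.
    """

    mean_covariates: tuple[str, ...] = ("x1",)
    variance_covariates: tuple[str, ...] = ()
    random_slope: bool = False
    random_scale: bool = False

    def __post_init__(self) -> None:
        if len(self.mean_covariates) == 0 or self.mean_covariates[0] != "x1":
            raise ValueError("mean_covariates must start with 'x1'")
        object.__setattr__(self, "mean_covariates", tuple(self.mean_covariates))
        object.__setattr__(self, "variance_covariates", tuple(self.variance_covariates))

    @property
    def n_mean_coef(self) -> int:
        return 1 + len(self.mean_covariates)

    @property
    def n_var_coef(self) -> int:
        return 1 + len(self.variance_covariates)

    @property
    def n_effects(self) -> int:
        """Dimension of the per-cluster random-effect vector."""
        return 1 + int(self.random_slope) + int(self.random_scale)

    @property
    def n_mean_effects(self) -> int:
        return 1 + int(self.random_slope)

    @property
    def effect_names(self) -> tuple[str, ...]:
        names = ["u0"]
        if self.random_slope:
            names.append("u1")
        if self.random_scale:
            names.append("v")
        return tuple(names)

    @property
    def scale_index(self) -> int | None:
        """Column of ``v`` in the effect vector, or ``None``."""
        return self.n_effects - 1 if self.random_scale else None


def model_spec(model: int) -> ModelSpec:
    """Return the spec for one of the eight canonical models (1..8)."""
    base = ("x1",)
    student = base + STUDENT_COVARIATES
    full = student + SCHOOL_COVARIATES
    table = {
        1: ModelSpec(base, (), False, False),
        2: ModelSpec(base, (), False, True),
        3: ModelSpec(base, base, False, True),
        4: ModelSpec(base, (), True, False),
        5: ModelSpec(base, (), True, True),
        6: ModelSpec(base, base, True, True),
        7: ModelSpec(student, student, False, True),
        8: ModelSpec(full, full, False, True),
    }
    if model not in table:
        raise ValueError(f"model must be in 1..8, got {model!r}")
    return table[model]


@dataclass
class ParameterSet:
    """Fixed coefficients and random-effect covariance of a MELS model.

    ``beta`` holds the mean-function coefficients (intercept first), and
    ``alpha`` the variance-function coefficients on the log scale.
    ``Sigma`` is the covariance of the cluster effects ordered
    ``(u0[, u1][, v])``; it must be symmetric positive definite.
    """

    beta: np.ndarray
    alpha: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))

    def validate(self, spec: ModelSpec) -> "ParameterSet":
        if self.beta.shape != (spec.n_mean_coef,):
            raise ValueError(
                f"beta has length {self.beta.size}, spec needs {spec.n_mean_coef}"
            )
        if self.alpha.shape != (spec.n_var_coef,):
            raise ValueError(
                f"alpha has length {self.alpha.size}, spec needs {spec.n_var_coef}"
            )
        d = spec.n_effects
        if self.Sigma.shape != (d, d):
            raise ValueError(f"Sigma is {self.Sigma.shape}, spec needs ({d}, {d})")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma) <= 0):
            raise ValueError("Sigma must be positive definite")
        return self

    # -- convenience accessors on the (u0[, u1][, v]) ordering --------
    @property
    def sigma2_u0(self) -> float:
        return float(self.Sigma[0, 0])

    def sigma2_u1(self, spec: ModelSpec) -> float:
        if not spec.random_slope:
            raise ValueError("spec has no random slope")
        return float(self.Sigma[1, 1])

    def sigma2_v(self, spec: ModelSpec) -> float:
        if not spec.random_scale:
            raise ValueError("spec has no random scale effect")
        return float(self.Sigma[spec.scale_index, spec.scale_index])

    def correlations(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.Sigma))
        return self.Sigma / np.outer(sd, sd)

    # -- serialization, labelled like the published results tables ----
    def to_dict(self, spec: ModelSpec) -> dict[str, float]:
        out: dict[str, float] = {}
        mean_names = ("intercept",) + spec.mean_covariates
        for k, name in enumerate(mean_names):
            out[f"beta{k}_{name}"] = float(self.beta[k])
        var_names = ("intercept",) + spec.variance_covariates
        for k, name in enumerate(var_names):
            out[f"alpha{k}_{name}"] = float(self.alpha[k])
        names = spec.effect_names
        corr = self.correlations()
        for a in range(len(names)):
            out[f"sigma2_{names[a]}"] = float(self.Sigma[a, a])
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                out[f"rho_{names[a]}{names[b]}"] = float(corr[a, b])
        return out

    def to_json(self, spec: ModelSpec) -> str:
        return json.dumps(self.to_dict(spec), indent=2)

    def named_values(self, spec: ModelSpec) -> dict[str, float]:
        """Scalar parameters keyed like fit summaries (beta0, alpha0, ...)."""
        out = {f"beta{k}": float(b) for k, b in enumerate(self.beta)}
        out |= {f"alpha{k}": float(a) for k, a in enumerate(self.alpha)}
        names = spec.effect_names
        corr = self.correlations()
        for a in range(len(names)):
            out[f"sigma2_{names[a]}"] = float(self.Sigma[a, a])
            for b in range(a + 1, len(names)):
                out[f"rho_{names[a]}{names[b]}"] = float(corr[a, b])
        return out

    @classmethod
    def from_dict(cls, d: dict[str, float], spec: ModelSpec) -> "ParameterSet":
        beta = [d[k] for k in sorted(d, key=_coef_key) if k.startswith("beta")]
        alpha = [d[k] for k in sorted(d, key=_coef_key) if k.startswith("alpha")]
        names = spec.effect_names
        variances = {n: d[f"sigma2_{n}"] for n in names}
        rhos = {
            (a, b): d.get(f"rho_{names[a]}{names[b]}", 0.0)
            for a in range(len(names))
            for b in range(a + 1, len(names))
        }
        Sigma = _assemble_covariance([variances[n] for n in names], rhos)
        return cls(np.array(beta), np.array(alpha), Sigma).validate(spec)


def _coef_key(name: str) -> tuple:
    head = name.split("_", 1)[0]
    digits = "".join(c for c in head if c.isdigit())
    return (int(digits) if digits else 0, name)


def _assemble_covariance(variances: list[float], rhos: dict) -> np.ndarray:
    d = len(variances)
    sd = np.sqrt(variances)
    Sigma = np.diag(np.asarray(variances, dtype=float))
    for (a, b), rho in rhos.items():
        Sigma[a, b] = Sigma[b, a] = rho * sd[a] * sd[b]
    return Sigma


def parameters_from_summaries(
    spec: ModelSpec,
    beta: list[float] | np.ndarray,
    alpha: list[float] | np.ndarray,
    variances: list[float],
    correlations: dict[str, float] | None = None,
) -> ParameterSet:
    """Build a :class:`ParameterSet` from variances and correlations.

    Results tables report random-effect variances and correlations (not
    covariances); this assembles the implied covariance matrix.  Keys of
    ``correlations`` pair effect names, e.g. ``"u0v"`` or ``"u0u1"``.
    """
    names = spec.effect_names
    idx = {n: k for k, n in enumerate(names)}
    rhos: dict[tuple[int, int], float] = {}
    for key, rho in (correlations or {}).items():
        for a in names:
            if key.startswith(a) and key[len(a):] in idx:
                rhos[(idx[a], idx[key[len(a):]])] = rho
                break
        else:
            raise ValueError(f"unknown correlation key {key!r}")
    Sigma = _assemble_covariance(list(variances), rhos)
    return ParameterSet(np.asarray(beta), np.asarray(alpha), Sigma).validate(spec)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the MCMC fit.

    Regression coefficients get independent diffuse normal priors with
    variance ``coef_variance``.  The random-effect covariance gets an
    inverse-Wishart prior; by default a minimally informative
    ``IW(d + 1, iw_scale * I)``.
    """

    coef_variance: float = 1.0e6
    iw_df: float | None = None
    iw_scale: float | np.ndarray = 0.1

    def df(self, d: int) -> float:
        df = (d + 1.0) if self.iw_df is None else float(self.iw_df)
        if df <= d - 1:
            raise ValueError(f"inverse-Wishart df must exceed d - 1 = {d - 1}")
        return df

    def scale_matrix(self, d: int) -> np.ndarray:
        S = np.asarray(self.iw_scale, dtype=float)
        if S.ndim == 0:
            S = float(S) * np.eye(d)
        if S.shape != (d, d):
            raise ValueError(f"iw_scale must be scalar or ({d}, {d})")
        if np.any(np.linalg.eigvalsh(S) <= 0):
            raise ValueError("iw_scale must be positive definite")
        return S


# ---------------------------------------------------------------------
# Pointwise model functions
# ---------------------------------------------------------------------

def _unit_vector(row, names: tuple[str, ...]) -> np.ndarray:
    """Covariate vector (with leading 1) from a mapping-like row."""
    return np.concatenate([[1.0], [float(row[n]) for n in names]])


def mean_value(params: ParameterSet, effects, row, spec: ModelSpec) -> float:
    """Mean function for one unit: ``beta'x + u0_j (+ u1_j * x1)``.

    ``effects`` is the cluster's effect vector ordered ``(u0[, u1][, v])``.
    """
    x = _unit_vector(row, spec.mean_covariates)
    effects = np.atleast_1d(np.asarray(effects, dtype=float))
    out = float(x @ params.beta) + float(effects[0])
    if spec.random_slope:
        out += float(effects[1]) * float(row["x1"])
    return out


def logvar_value(params: ParameterSet, effects, row, spec: ModelSpec) -> float:
    """Log residual variance for one unit: ``alpha'w (+ v_j)``.

    ``exp`` of the result is the unit's residual variance — strictly
    positive by construction of the log link.
    """
    w = _unit_vector(row, spec.variance_covariates)
    out = float(w @ params.alpha)
    if spec.random_scale:
        effects = np.atleast_1d(np.asarray(effects, dtype=float))
        out += float(effects[spec.scale_index])
    return out


# ---------------------------------------------------------------------
# Vectorised predictors used by the sampler and the generator
# ---------------------------------------------------------------------

def mean_predictor(
    beta: np.ndarray,
    X_mean: np.ndarray,
    U: np.ndarray,
    groups: np.ndarray,
    x1: np.ndarray,
    spec: ModelSpec,
) -> np.ndarray:
    """Row-wise mean function given designs and per-cluster effects."""
    mu = X_mean @ beta + U[groups, 0]
    if spec.random_slope:
        mu = mu + U[groups, 1] * x1
    return mu


def logvar_predictor(
    alpha: np.ndarray,
    X_var: np.ndarray,
    U: np.ndarray,
    groups: np.ndarray,
    spec: ModelSpec,
) -> np.ndarray:
    """Row-wise log residual variance given designs and effects."""
    lv = X_var @ alpha
    if spec.random_scale:
        lv = lv + U[groups, spec.scale_index]
    return lv


def normal_logpdf_sum(y: np.ndarray, mu: np.ndarray, logvar: np.ndarray) -> float:
    """Sum of heteroskedastic normal log densities (stable, no scipy loop)."""
    resid2 = (np.asarray(y) - np.asarray(mu)) ** 2
    return float(-0.5 * np.sum(_LOG2PI + logvar + resid2 * np.exp(-logvar)))


def loglik_conditional(table, params: ParameterSet, effects, spec: ModelSpec) -> float:
    """Conditional (given effects) log-likelihood over all units.

    ``table`` is an :class:`~melscale.data_model.AnalysisTable`;
    ``effects`` a ``(J, d)`` array aligned with ``table.cluster_ids``.
    """
    from .data_model import design_matrices

    params.validate(spec)
    U = np.atleast_2d(np.asarray(effects, dtype=float))
    if U.shape != (table.J, spec.n_effects):
        raise ValueError(f"effects must be ({table.J}, {spec.n_effects})")
    X_mean, X_var = design_matrices(table, spec)
    y = table.data["y"].to_numpy(dtype=float)
    x1 = table.data["x1"].to_numpy(dtype=float)
    g = table.group_codes
    mu = mean_predictor(params.beta, X_mean, U, g, x1, spec)
    lv = logvar_predictor(params.alpha, X_var, U, g, spec)
    out = normal_logpdf_sum(y, mu, lv)
    if not np.isfinite(out):
        raise FloatingPointError("non-finite conditional log-likelihood")
    return out


def logprior(params: ParameterSet, priors: PriorSpec, spec: ModelSpec) -> float:
    """Log prior density (normalising constants retained).

    Returns ``-inf`` when ``Sigma`` is not positive definite, so the
    sampler can reject such states instead of crashing.
    """
    d = spec.n_effects
    cv = priors.coef_variance
    coefs = np.concatenate([params.beta, params.alpha])
    lp = -0.5 * coefs.size * (_LOG2PI + np.log(cv)) - 0.5 * np.sum(coefs**2) / cv
    try:
        lp += float(
            invwishart.logpdf(params.Sigma, df=priors.df(d), scale=priors.scale_matrix(d))
        )
    except (np.linalg.LinAlgError, ValueError):
        return -np.inf
    if np.any(np.linalg.eigvalsh(params.Sigma) <= 0):
        return -np.inf
    return float(lp)


def logposterior_complete(
    table, params: ParameterSet, effects, priors: PriorSpec, spec: ModelSpec
) -> float:
    """Complete-data log posterior: likelihood + effects density + prior."""
    U = np.atleast_2d(np.asarray(effects, dtype=float))
    lp = logprior(params, priors, spec)
    if not np.isfinite(lp):
        return -np.inf
    lp += float(np.sum(multivariate_normal.logpdf(U, mean=np.zeros(spec.n_effects), cov=params.Sigma)))
    lp += loglik_conditional(table, params, effects, spec)
    return float(lp)


# ---------------------------------------------------------------------
# Adaptive Gauss-Hermite marginal likelihood (validation oracle)
# ---------------------------------------------------------------------

def marginal_loglik_quadrature(
    table, params: ParameterSet, spec: ModelSpec, n_nodes: int = 25
) -> float:
    """Marginal log-likelihood with the random effects integrated out.

    Supports random-intercept specs only (``d <= 2``: ``u0`` and optional
    ``v``); the integral per cluster is evaluated by adaptive
    Gauss-Hermite quadrature centred at the per-cluster posterior mode
    with curvature scaling.  Intended as a small-scale oracle, not an
    estimation route.
    """
    from .data_model import design_matrices

    if spec.random_slope:
        raise ValueError("quadrature oracle supports random-intercept specs only")
    params.validate(spec)
    d = spec.n_effects
    X_mean, X_var = design_matrices(table, spec)
    y = table.data["y"].to_numpy(dtype=float)
    g = table.group_codes
    xb = X_mean @ params.beta
    wa = X_var @ params.alpha
    Omega = np.linalg.inv(params.Sigma)
    _, logdetS = np.linalg.slogdet(params.Sigma)
    nodes, weights = hermgauss(n_nodes)
    if d == 1:
        Z = nodes[:, None]
        logw = np.log(weights)
    else:
        Z = np.array([[a, b] for a in nodes for b in nodes])
        logw = np.add.outer(np.log(weights), np.log(weights)).ravel()

    total = 0.0
    for j in range(table.J):
        mask = g == j
        yj, xbj, waj = y[mask], xb[mask], wa[mask]
        mode = _cluster_mode(yj, xbj, waj, Omega, d)
        H = -_cluster_hess(mode, yj, xbj, waj, Omega, d)
        L = np.linalg.cholesky(np.linalg.inv(H))
        pts = mode[None, :] + np.sqrt(2.0) * Z @ L.T
        gvals = np.array(
            [_cluster_logint(b, yj, xbj, waj, Omega, logdetS, d) for b in pts]
        )
        total += (
            0.5 * d * np.log(2.0)
            + np.log(np.abs(np.prod(np.diag(L))))
            + logsumexp(logw + np.sum(Z**2, axis=1) + gvals)
        )
    return float(total)


def _cluster_logint(b, y, xb, wa, Omega, logdetS, d) -> float:
    """log p(y_j | b) + log p(b) for effect vector b = (u[, v])."""
    u = b[0]
    v = b[1] if d == 2 else 0.0
    lv = wa + v
    ll = -0.5 * np.sum(_LOG2PI + lv + (y - xb - u) ** 2 * np.exp(-lv))
    lp = -0.5 * (d * _LOG2PI + logdetS + b @ Omega @ b)
    return float(ll + lp)


def _cluster_grad(b, y, xb, wa, Omega, d) -> np.ndarray:
    u = b[0]
    v = b[1] if d == 2 else 0.0
    r = y - xb - u
    w = np.exp(-(wa + v))
    gu = np.sum(r * w)
    grad = [gu]
    if d == 2:
        grad.append(np.sum(-0.5 + 0.5 * r**2 * w))
    return np.asarray(grad) - Omega @ b


def _cluster_hess(b, y, xb, wa, Omega, d) -> np.ndarray:
    u = b[0]
    v = b[1] if d == 2 else 0.0
    r = y - xb - u
    w = np.exp(-(wa + v))
    H = np.empty((d, d))
    H[0, 0] = -np.sum(w)
    if d == 2:
        H[0, 1] = H[1, 0] = -np.sum(r * w)
        H[1, 1] = -0.5 * np.sum(r**2 * w)
    return H - Omega


def _cluster_mode(y, xb, wa, Omega, d, tol: float = 1e-10) -> np.ndarray:
    """Damped Newton ascent of the per-cluster integrand; d <= 2."""
    b = np.zeros(d)
    f = _cluster_logint(b, y, xb, wa, Omega, 0.0, d)
    for _ in range(100):
        grad = _cluster_grad(b, y, xb, wa, Omega, d)
        H = _cluster_hess(b, y, xb, wa, Omega, d)
        step = np.linalg.solve(H, -grad)
        lam = 1.0
        for _ in range(30):
            cand = b + lam * step
            fc = _cluster_logint(cand, y, xb, wa, Omega, 0.0, d)
            if fc >= f - 1e-12:
                break
            lam *= 0.5
        if not np.all(np.isfinite(cand)):
            warnings.warn("mode search produced non-finite point; using last iterate")
            break
        moved = np.max(np.abs(cand - b))
        b, f = cand, fc
        if moved < tol:
            break
    return b
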