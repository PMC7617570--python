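"""Scikit-learn-style estimator facade over the MELS machinery.

:class:`MELSRegressor` wraps the Bayesian fit in the familiar
``fit``/``predict`` idiom so the model composes with sklearn pipelines
and model selection.  The grouped, hierarchical nature of the model
means the cluster labels travel as a ``groups`` argument (the same
convention sklearn uses for grouped cross-validation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .data_model import AnalysisTable
from .mcmc_engine import McmcConfig, fit as _fit
from .mels_core import ModelSpec, PriorSpec, model_spec
from .school_effects import ReferenceProfile, cluster_mean_adjusted, cluster_variance

__all__ = ["MELSRegressor"]


class MELSRegressor(BaseEstimator, RegressorMixin):
    """Mixed-effects location scale regression for clustered data.

    Parameters
    ----------
    model : int, default=2
        Which canonical model (1-8) to fit; ignored when ``spec`` given.
    spec : ModelSpec, optional
        Explicit model specification (overrides ``model``).
    priors : PriorSpec, optional
        Priors; defaults to diffuse normals and a minimally informative
        inverse-Wishart.
    chains, burnin, iterations, seed, init_dispersion, store_effects
        Sampler settings (see :class:`~melscale.mcmc_engine.McmcConfig`).

    Attributes
    ----------
    result_ : FitResult
        Full posterior draws and summaries.
    params_ : ParameterSet
        Posterior-mean parameters.
    dic_ : float
        Deviance information criterion.
    cluster_effects_ : DataFrame
        Shrunken per-cluster mean effects with credible intervals.
    cluster_variances_ : DataFrame
        Per-cluster residual variances at the reference profile.

    Examples
    --------
    >>> est = MELSRegressor(model=2, chains=2, burnin=200, iterations=400,
    ...                     seed=1)
    >>> est.fit(X, y, groups=school_ids)     # doctest: +SKIP
    >>> est.predict(X, groups=school_ids)    # doctest: +SKIP
    """

    def __init__(
        self,
        model: int = 2,
        spec: ModelSpec | None = None,
        priors: PriorSpec | None = None,
        chains: int = 4,
        burnin: int = 5000,
        iterations: int = 10000,
        seed: int | None = None,
        init_dispersion: float = 1.0,
        store_effects: bool = True,
    ):
        self.model = model
        self.spec = spec
        self.priors = priors
        self.chains = chains
        self.burnin = burnin
        self.iterations = iterations
        self.seed = seed
        self.init_dispersion = init_dispersion
        self.store_effects = store_effects

    # ------------------------------------------------------------------
    def _resolve_spec(self) -> ModelSpec:
        return self.spec if self.spec is not None else model_spec(self.model)

    def _build_table(self, X, y, groups, clusters=None) -> AnalysisTable:
        spec = self._resolve_spec()
        if groups is None:
            raise ValueError("groups (cluster labels, one per row) is required")
        groups = np.asarray(groups)
        if isinstance(X, pd.DataFrame):
            frame = X.copy()
            if "x1" not in frame.columns:
                raise ValueError("X must contain an 'x1' column")
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[1] < 1:
                raise ValueError("X needs at least the x1 column")
            names = ["x1"] + [f"c{k}" for k in range(1, X.shape[1])]
            frame = pd.DataFrame(X, columns=names)
        needed = set(spec.mean_covariates) | set(spec.variance_covariates)
        cluster_cols = set() if clusters is None else set(clusters.columns)
        missing = needed - set(frame.columns) - cluster_cols
        if missing:
            raise ValueError(f"covariates missing from X: {sorted(missing)}")
        frame = frame[[c for c in frame.columns if c in needed or c == "x1"]]
        frame.insert(0, "cluster_id", groups.astype(str))
        frame["y"] = np.asarray(y, dtype=float)
        return AnalysisTable(frame.reset_index(drop=True), clusters)

    # ------------------------------------------------------------------
    def fit(self, X, y, groups=None, clusters=None):
        """Fit the model.

        Parameters
        ----------
        X : DataFrame or ndarray
            Unit-level covariates; a DataFrame must contain ``x1`` plus
            any covariates the spec names, an ndarray's first column is
            taken as ``x1``.
        y : array-like
            Continuous outcome, one value per row of X.
        groups : array-like
            Cluster label per row (required).
        clusters : DataFrame, optional
            Cluster-level covariate table (``cluster_id`` + dummies).
        """
        table = self._build_table(X, y, groups, clusters)
        spec = self._resolve_spec()
        config = McmcConfig(
            chains=self.chains,
            burnin=self.burnin,
            iterations=self.iterations,
            seed=self.seed,
            init_dispersion=self.init_dispersion,
            store_effects=self.store_effects,
        )
        self.result_ = _fit(table, spec, self.priors or PriorSpec(), config)
        self.spec_ = spec
        self.params_ = self.result_.params_mean
        self.dic_ = self.result_.dic
        self.n_clusters_ = table.J
        self.cluster_index_ = {cid: k for k, cid in enumerate(table.cluster_ids)}
        profile = ReferenceProfile.from_table(table)
        self.reference_profile_ = profile
        self.cluster_effects_ = cluster_mean_adjusted(self.result_, profile)
        self.cluster_variances_ = cluster_variance(self.result_, profile)
        self.n_features_in_ = (
            X.shape[1] if hasattr(X, "shape") else len(X[0])
        )
        return self

    def predict(self, X, groups=None):
        """Posterior-mean prediction of the outcome.

        Fixed-effects prediction plus the shrunken cluster effect for
        clusters seen in training (zero for unseen or omitted groups).
        """
        if not hasattr(self, "result_"):
            raise AttributeError("call fit before predict")
        spec = self.spec_
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            names = ["x1"] + [f"c{k}" for k in range(1, X.shape[1])]
            frame = pd.DataFrame(X, columns=names)
        x = np.column_stack(
            [np.ones(len(frame))]
            + [frame[c].to_numpy(dtype=float) for c in spec.mean_covariates]
        )
        yhat = x @ self.params_.beta
        if groups is not None:
            U = self.result_.effects_mean
            idx = np.array(
                [self.cluster_index_.get(str(gid), -1) for gid in np.asarray(groups)]
            )
            seen = idx >= 0
            yhat[seen] += U[idx[seen], 0]
            if spec.random_slope:
                yhat[seen] += U[idx[seen], 1] * frame["x1"].to_numpy(dtype=float)[seen]
        return yhat

    def summary(self) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise AttributeError("call fit before summary")
        return self.result_.summary()
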