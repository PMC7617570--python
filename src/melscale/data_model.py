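"""Validated containers and I/O for clustered student/school data.

The analysis operates on a long-format table, one row per student, with a
cluster (school) identifier, a continuous outcome ``y`` (age-16 score), a
continuous prior score ``x1`` (age-11 score), binary student covariates,
and optional cluster-level dummy covariates supplied in a second table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .mels_core import ModelSpec

__all__ = [
    "AnalysisTable",
    "load_table",
    "read_schema",
    "standardize_scores",
    "design_matrices",
]

logger = logging.getLogger(__name__)

_CORE_COLUMNS = ("unit_id", "cluster_id", "y", "x1")


@dataclass
class AnalysisTable:
    """Unit rows plus cluster rows, validated and index-aligned.

    Attributes
    ----------
    data
        One row per unit with columns ``unit_id, cluster_id, y, x1`` and
        any number of 0/1 student covariate columns.
    clusters
        One row per cluster, keyed by ``cluster_id``, holding 0/1
        cluster covariate columns; ordered by first appearance in
        ``data`` (this order defines the internal cluster indexing used
        in all outputs).
    standardized
        Whether ``y`` and ``x1`` are z-scored on this sample.
    transform
        When standardized, the original means/SDs so predictions can be
        mapped back to the raw scale.
    """

    data: pd.DataFrame
    clusters: pd.DataFrame | None = None
    standardized: bool = False
    transform: dict[str, float] | None = None

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        if "unit_id" not in df.columns:
            df.insert(0, "unit_id", np.arange(len(df)))
        missing = [c for c in _CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"data is missing required columns: {missing}")
        n_before = len(df)
        df = df.dropna()
        if len(df) < n_before:
            logger.info("dropped %d rows with missing values", n_before - len(df))
        if len(df) == 0:
            raise ValueError("no complete rows")
        for col in ("y", "x1"):
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"column {col!r} contains non-finite values")
            df[col] = vals
        for col in self.unit_covariates(df):
            vals = df[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"student covariate {col!r} is not 0/1")
            df[col] = vals.astype(float)
        df["cluster_id"] = df["cluster_id"].astype(str)
        order = df["cluster_id"].drop_duplicates().tolist()

        if self.clusters is not None:
            cl = self.clusters.reset_index(drop=True).copy()
            if "cluster_id" not in cl.columns:
                raise ValueError("clusters table needs a cluster_id column")
            cl["cluster_id"] = cl["cluster_id"].astype(str)
            if cl["cluster_id"].duplicated().any():
                raise ValueError("duplicate cluster_id in clusters table")
            unknown = set(order) - set(cl["cluster_id"])
            if unknown:
                raise ValueError(
                    f"rows reference cluster_ids absent from clusters table: {sorted(unknown)[:5]}"
                )
            empty = set(cl["cluster_id"]) - set(order)
            if empty:
                raise ValueError(
                    f"clusters with no unit rows: {sorted(empty)[:5]}"
                )
            cl = cl.set_index("cluster_id").reindex(order).reset_index()
            for col in [c for c in cl.columns if c != "cluster_id"]:
                vals = cl[col].to_numpy()
                if not np.isin(vals, (0, 1)).all():
                    raise ValueError(f"cluster covariate {col!r} is not 0/1")
                cl[col] = vals.astype(float)
        else:
            cl = pd.DataFrame({"cluster_id": order})

        self.data = df.reset_index(drop=True)
        self.clusters = cl
        codes = pd.Categorical(df["cluster_id"], categories=order).codes
        self._group_codes = np.asarray(codes, dtype=np.intp)

    @staticmethod
    def unit_covariates(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c not in _CORE_COLUMNS]

    # -- shape accessors ----------------------------------------------
    @property
    def cluster_ids(self) -> list[str]:
        return self.clusters["cluster_id"].tolist()

    @property
    def J(self) -> int:
        return len(self.clusters)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_j(self) -> np.ndarray:
        return np.bincount(self._group_codes, minlength=self.J)

    @property
    def group_codes(self) -> np.ndarray:
        """Per-row cluster index into ``cluster_ids`` order."""
        return self._group_codes

    @property
    def covariate_names(self) -> list[str]:
        unit = self.unit_covariates(self.data)
        cl = [c for c in self.clusters.columns if c != "cluster_id"]
        return unit + cl

    def design_frame(self) -> pd.DataFrame:
        """Unit rows with cluster covariates merged in (row-aligned)."""
        if self.clusters.shape[1] == 1:
            return self.data
        return self.data.merge(self.clusters, on="cluster_id", how="left", sort=False)

    # -- I/O -----------------------------------------------------------
    def to_csv(self, data_path, clusters_path=None) -> None:
        self.data.to_csv(data_path, index=False)
        if clusters_path is not None:
            self.clusters.to_csv(clusters_path, index=False)

    @classmethod
    def from_csv(cls, data_path, clusters_path=None, **kwargs) -> "AnalysisTable":
        data = pd.read_csv(data_path)
        clusters = pd.read_csv(clusters_path) if clusters_path else None
        return cls(data, clusters, **kwargs)


def read_schema(path) -> dict:
    """Read a YAML or JSON column-mapping schema."""
    import json

    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _expand_categoricals(df: pd.DataFrame, categoricals: dict) -> pd.DataFrame:
    """Dummy-code categorical columns against stated reference levels."""
    for col, conf in (categoricals or {}).items():
        if col not in df.columns:
            raise KeyError(f"schema references missing column {col!r}")
        ref = conf["reference"]
        prefix = conf.get("prefix", col)
        levels = conf.get("levels")
        observed = df[col].astype(str)
        if levels is None:
            levels = sorted(observed.unique())
        unknown = set(observed.unique()) - set(map(str, levels)) - {str(ref)}
        if unknown:
            raise ValueError(f"column {col!r} has unlisted levels {sorted(unknown)}")
        for lvl in levels:
            if str(lvl) == str(ref):
                continue
            df[f"{prefix}_{lvl}"] = (observed == str(lvl)).astype(float)
        df = df.drop(columns=[col])
    return df


def load_table(path, schema: dict, clusters_path=None) -> AnalysisTable:
    """Load and validate a long-format CSV into an :class:`AnalysisTable`.

    ``schema`` maps roles to column names::

        {"cluster_id": "school", "y": "gcse", "x1": "ks2",
         "unit_id": "pupil",               # optional
         "dummies": ["girl", "fsm"],       # already-0/1 columns
         "categoricals": {"ethnicity": {"reference": "White",
                                        "prefix": "eth"}},
         "cluster_dummies": [...], "cluster_categoricals": {...}}
    """
    raw = pd.read_csv(path)
    for role in ("cluster_id", "y", "x1"):
        if role not in schema:
            raise KeyError(f"schema must name a column for {role!r}")
        if schema[role] not in raw.columns:
            raise KeyError(f"schema column {schema[role]!r} not found in {path}")
    cols = {schema[r]: r for r in ("cluster_id", "y", "x1")}
    if "unit_id" in schema:
        cols[schema["unit_id"]] = "unit_id"
    keep = list(cols) + list(schema.get("dummies", [])) + list(schema.get("categoricals", {}))
    missing = [c for c in keep if c not in raw.columns]
    if missing:
        raise KeyError(f"schema columns missing from {path}: {missing}")
    df = raw[keep].rename(columns=cols)
    df = _expand_categoricals(df, schema.get("categoricals"))

    clusters = None
    if clusters_path is not None:
        craw = pd.read_csv(clusters_path)
        ckey = schema.get("cluster_key", schema["cluster_id"])
        if ckey not in craw.columns:
            raise KeyError(f"cluster file missing key column {ckey!r}")
        ckeep = [ckey] + list(schema.get("cluster_dummies", [])) + list(
            schema.get("cluster_categoricals", {})
        )
        clusters = craw[ckeep].rename(columns={ckey: "cluster_id"})
        clusters = _expand_categoricals(clusters, schema.get("cluster_categoricals"))
    return AnalysisTable(df, clusters)


def standardize_scores(table: AnalysisTable) -> AnalysisTable:
    """Z-score ``y`` and ``x1`` on the analysis sample.

    Idempotent to numerical precision; the affine transform constants
    are retained for inverse mapping.  Raises on zero variance.
    """
    df = table.data.copy()
    transform: dict[str, float] = {}
    for col in ("y", "x1"):
        vals = df[col].to_numpy(dtype=float)
        mu, sd = float(np.mean(vals)), float(np.std(vals, ddof=0))
        if sd <= 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        df[col] = (vals - mu) / sd
        transform[f"{col}_mean"], transform[f"{col}_sd"] = mu, sd
    if table.standardized and table.transform is not None:
        # compose with the earlier transform so raw-scale recovery still works
        prev = table.transform
        for col in ("y", "x1"):
            transform[f"{col}_mean"] = (
                prev[f"{col}_mean"] + prev[f"{col}_sd"] * transform[f"{col}_mean"]
            )
            transform[f"{col}_sd"] = prev[f"{col}_sd"] * transform[f"{col}_sd"]
    return AnalysisTable(df, table.clusters.copy(), standardized=True, transform=transform)


def design_matrices(table: AnalysisTable, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Row-aligned mean and variance design matrices (leading intercept).

    The mean design always contains ``x1``; the variance design holds the
    spec's variance covariates (intercept-only when none).
    """
    frame = table.design_frame()
    available = set(frame.columns)
    for name in set(spec.mean_covariates) | set(spec.variance_covariates):
        if name not in available:
            raise KeyError(f"spec covariate {name!r} not present in table")
    n = len(frame)

    def build(names: tuple[str, ...]) -> np.ndarray:
        X = np.empty((n, 1 + len(names)))
        X[:, 0] = 1.0
        for k, name in enumerate(names, start=1):
            X[:, k] = frame[name].to_numpy(dtype=float)
        return X

    return build(spec.mean_covariates), build(spec.variance_covariates)
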