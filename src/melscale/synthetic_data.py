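"""Synthetic school/student data with the structure the analysis assumes.

The generator emulates a large urban secondary-school system: a few
hundred schools of mean size ~153 students (range 14-330), standardized
age-11 and age-16 scores correlated about 0.72, binary sociodemographic
covariates at realistic prevalences, a school-type mix including a small
selective (grammar) sector with upward-shifted intakes, and outcomes
drawn from any of the eight location-scale model variants.

All randomness flows from a single integer seed through spawned
`numpy.random.SeedSequence` streams, so the cluster, student, and outcome
stages are independently reproducible and a fixed seed yields
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import AnalysisTable
from .mels_core import (
    ModelSpec,
    ParameterSet,
    mean_predictor,
    logvar_predictor,
    model_spec,
    parameters_from_summaries,
)

__all__ = [
    "STUDENT_PREVALENCES",
    "SCHOOL_CATEGORICALS",
    "REFERENCE_ESTIMATES",
    "SyntheticScenario",
    "scenario",
    "generate_clusters",
    "generate_students",
    "simulate_outcomes",
]

#: Default marginal prevalence of each binary student covariate.
STUDENT_PREVALENCES: dict[str, float] = {
    "summer_born": 0.258,
    "girl": 0.505,
    "eth_black": 0.219,
    "eth_asian": 0.210,
    "eth_chinese": 0.006,
    "eth_mixed": 0.081,
    "eth_other": 0.090,
    "lang_not_english": 0.400,
    "sen": 0.142,
    "fsm": 0.348,
}

#: Default school categorical mix.  Each block maps level -> probability;
#: the reference level (no dummy) is listed too so blocks sum to one.
SCHOOL_CATEGORICALS: dict[str, dict[str, float]] = {
    "type": {"standard": 0.325, "sponsored": 0.200, "converter": 0.396, "other": 0.080},
    "admissions": {"comprehensive": 0.914, "grammar": 0.041, "secondary_modern": 0.045},
    "gender": {"mixed": 0.731, "boys": 0.108, "girls": 0.161},
    "religious": {"no": 0.750, "yes": 0.250},
}

_CATEGORY_DUMMIES = {
    ("type", "sponsored"): "type_sponsored",
    ("type", "converter"): "type_converter",
    ("type", "other"): "type_other",
    ("admissions", "grammar"): "adm_grammar",
    ("admissions", "secondary_modern"): "adm_secondary_modern",
    ("gender", "boys"): "gender_boys",
    ("gender", "girls"): "gender_girls",
    ("religious", "yes"): "religious",
}


def _reference_estimates() -> dict[int, ParameterSet]:
    """Reference posterior-mean parameter sets for Models 1-8.

    These are the reported estimates from the large-scale London
    application the generator emulates (71,321 students, 465 schools);
    they serve as realistic generating truths for recovery studies.
    """
    est = {
        1: parameters_from_summaries(
            model_spec(1), [-0.011, 0.678], [-0.870], [0.067]
        ),
        2: parameters_from_summaries(
            model_spec(2), [-0.011, 0.679], [-0.881], [0.067, 0.037], {"u0v": -0.472}
        ),
        3: parameters_from_summaries(
            model_spec(3), [-0.011, 0.679], [-0.881, 0.029], [0.067, 0.040], {"u0v": -0.484}
        ),
        4: parameters_from_summaries(
            model_spec(4), [-0.017, 0.675], [-0.877], [0.068, 0.004], {"u0u1": 0.278}
        ),
        5: parameters_from_summaries(
            model_spec(5),
            [-0.015, 0.673],
            [-0.889],
            [0.069, 0.004, 0.037],
            {"u0u1": 0.231, "u0v": -0.476, "u1v": -0.089},
        ),
        6: parameters_from_summaries(
            model_spec(6),
            [-0.015, 0.672],
            [-0.889, 0.036],
            [0.069, 0.004, 0.040],
            {"u0u1": 0.229, "u0v": -0.494, "u1v": -0.111},
        ),
        7: parameters_from_summaries(
            model_spec(7),
            [-0.129, 0.634, 0.045, 0.219, 0.015, 0.152, 0.296, 0.001, 0.089,
             0.162, -0.276, -0.193],
            [-0.948, 0.077, -0.044, -0.059, -0.154, -0.105, -0.088, -0.028,
             -0.014, -0.002, 0.204, 0.103],
            [0.050, 0.032],
            {"u0v": -0.409},
        ),
        8: parameters_from_summaries(
            model_spec(8),
            [-0.235, 0.632, 0.044, 0.218, 0.014, 0.150, 0.290, 0.000, 0.088,
             0.162, -0.276, -0.192, 0.055, 0.082, 0.023, 0.396, -0.118,
             0.053, 0.064, 0.139],
            [-0.889, 0.081, -0.045, -0.061, -0.156, -0.106, -0.080, -0.035,
             -0.015, -0.005, 0.203, 0.099, 0.011, -0.048, 0.053, -0.280,
             -0.068, 0.002, 0.015, -0.110],
            [0.037, 0.026],
            {"u0v": -0.282},
        ),
    }
    return est


REFERENCE_ESTIMATES: dict[int, ParameterSet] = _reference_estimates()


@dataclass
class SyntheticScenario:
    """Generative configuration for one synthetic dataset.

    School sizes follow a discretized log-normal matched to ``size_mean``
    and truncated to ``[size_min, size_max]``.  The prior score ``x1``
    is split into a between-school mean component (variance
    ``x1_icc``) and a within-school component (variance ``1 - x1_icc``)
    so its marginal variance is ~1; grammar schools get an upward intake
    shift of ``grammar_shift`` SD.  Binary covariates are drawn
    independently within school at the configured prevalences.
    """

    spec: ModelSpec
    truth: ParameterSet
    J: int = 465
    size_mean: float = 153.0
    size_min: int = 14
    size_max: int = 330
    size_sdlog: float = 0.4
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(STUDENT_PREVALENCES)
    )
    school_categoricals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in SCHOOL_CATEGORICALS.items()}
    )
    x1_icc: float = 0.2
    grammar_shift: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.truth.validate(self.spec)
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if not (self.size_min >= 1 and self.size_min <= self.size_mean <= self.size_max):
            raise ValueError("size bounds must satisfy 1 <= min <= mean <= max")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} must be in [0, 1]")
        if not 0.0 <= self.x1_icc < 1.0:
            raise ValueError("x1_icc must be in [0, 1)")

    def streams(self) -> tuple[np.random.Generator, ...]:
        ss = np.random.SeedSequence(self.seed)
        return tuple(np.random.default_rng(c) for c in ss.spawn(3))

    def generate(self, return_effects: bool = False):
        """Run all three stages and return the complete table."""
        rng_c, rng_s, rng_o = self.streams()
        clusters, sizes = generate_clusters(self, rng=rng_c)
        table = generate_students(self, clusters, sizes, rng=rng_s)
        return simulate_outcomes(
            table, self.spec, self.truth, rng=rng_o, return_effects=return_effects
        )


def scenario(model: int, **overrides) -> SyntheticScenario:
    """A ready-made scenario for one of Models 1-8 with the bundled
    reference estimates as generating truth."""
    truth = overrides.pop("truth", REFERENCE_ESTIMATES[model])
    return SyntheticScenario(spec=model_spec(model), truth=truth, **overrides)


def generate_clusters(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw school covariates and sizes.

    Returns the cluster table (dummy-coded) and an integer size vector.
    """
    if rng is None:
        rng = scenario.streams()[0]
    J = scenario.J
    meanlog = np.log(scenario.size_mean) - 0.5 * scenario.size_sdlog**2
    sizes = np.rint(rng.lognormal(meanlog, scenario.size_sdlog, size=J))
    sizes = np.clip(sizes, scenario.size_min, scenario.size_max).astype(int)

    cols: dict[str, np.ndarray] = {
        "cluster_id": np.array([f"school_{j:04d}" for j in range(J)])
    }
    for block, level_probs in scenario.school_categoricals.items():
        levels = list(level_probs)
        p = np.asarray([level_probs[l] for l in levels], dtype=float)
        p = p / p.sum()
        draws = rng.choice(len(levels), size=J, p=p)
        for k, lvl in enumerate(levels):
            dummy = _CATEGORY_DUMMIES.get((block, lvl))
            if dummy is not None:
                cols[dummy] = (draws == k).astype(float)
    return pd.DataFrame(cols), sizes


def generate_students(
    scenario: SyntheticScenario,
    clusters: pd.DataFrame,
    sizes: np.ndarray,
    rng: np.random.Generator | None = None,
) -> AnalysisTable:
    """Draw per-student prior scores and covariates (outcome left unset).

    The returned table carries ``y = NaN`` placeholders replaced by
    :func:`simulate_outcomes`; the table itself validates, so a zero
    column is used until outcomes are simulated.
    """
    if rng is None:
        rng = scenario.streams()[1]
    J = len(clusters)
    N = int(np.sum(sizes))
    groups = np.repeat(np.arange(J), sizes)

    icc = scenario.x1_icc
    m = rng.normal(0.0, np.sqrt(icc), size=J) if icc > 0 else np.zeros(J)
    if "adm_grammar" in clusters.columns:
        m = m + scenario.grammar_shift * clusters["adm_grammar"].to_numpy()
    x1 = m[groups] + rng.normal(0.0, np.sqrt(1.0 - icc), size=N)

    data = {
        "unit_id": np.arange(N),
        "cluster_id": clusters["cluster_id"].to_numpy()[groups],
        "y": np.zeros(N),
        "x1": x1,
    }
    for name, p in scenario.covariate_prevalences.items():
        data[name] = (rng.random(N) < p).astype(float)
    return AnalysisTable(pd.DataFrame(data), clusters.copy())


def simulate_outcomes(
    table: AnalysisTable,
    spec: ModelSpec,
    truth: ParameterSet,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_effects: bool = False,
):
    """Draw cluster effects and outcomes under the given model.

    Per cluster, ``(u0[, u1][, v])`` is drawn from ``N(0, Sigma)``;
    per unit, ``y ~ Normal(mean function, exp(variance function))``.
    """
    truth.validate(spec)
    if rng is None:
        rng = np.random.default_rng(seed)
    from .data_model import design_matrices

    X_mean, X_var = design_matrices(table, spec)
    g = table.group_codes
    x1 = table.data["x1"].to_numpy(dtype=float)

    L = np.linalg.cholesky(truth.Sigma)
    U = rng.standard_normal((table.J, spec.n_effects)) @ L.T
    mu = mean_predictor(truth.beta, X_mean, U, g, x1, spec)
    lv = logvar_predictor(truth.alpha, X_var, U, g, spec)
    y = mu + rng.standard_normal(table.n) * np.exp(0.5 * lv)

    data = table.data.copy()
    data["y"] = y
    out = AnalysisTable(data, table.clusters.copy())
    if return_effects:
        return out, U
    return out
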