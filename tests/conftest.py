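import numpy as np
import pandas as pd
import pytest

import melscale as m


@pytest.fixture
def tiny_table() -> m.AnalysisTable:
    """Two clusters of two units each, fixed by hand."""
    df = pd.DataFrame(
        {
            "unit_id": [0, 1, 2, 3],
            "cluster_id": ["a", "a", "b", "b"],
            "y": [0.1, -0.4, 0.9, 0.3],
            "x1": [0.5, -1.0, 1.2, 0.0],
            "girl": [1.0, 0.0, 1.0, 1.0],
        }
    )
    return m.AnalysisTable(df)


@pytest.fixture
def small_model2_table() -> m.AnalysisTable:
    scn = m.scenario(2, J=30, size_mean=40, size_min=20, size_max=70, seed=42)
    return scn.generate()


@pytest.fixture(scope="session")
def model2_recovery_fit():
    """One moderately large Model 2 fit reused across tests.

    Data simulated under the random-intercept location scale model with
    the bundled reference estimates as truth (200 schools of 100
    students), fitted with 2 chains of 1000 burnin + 2000 monitoring
    iterations.
    """
    scn = m.scenario(2, J=200, size_mean=100, size_min=100, size_max=100, seed=1)
    table = scn.generate()
    cfg = m.McmcConfig(chains=2, burnin=1000, iterations=2000, seed=2)
    fit = m.fit(table, scn.spec, m.PriorSpec(), cfg)
    return scn, table, fit


@pytest.fixture(scope="session")
def model1_fit_vs_lmm():
    """Model 1 fit plus the matching ML linear mixed model oracle."""
    import statsmodels.formula.api as smf

    scn = m.scenario(1, J=100, size_mean=50, size_min=50, size_max=50, seed=21)
    table = scn.generate()
    cfg = m.McmcConfig(chains=2, burnin=500, iterations=1500, seed=3)
    fit = m.fit(table, scn.spec, m.PriorSpec(), cfg)
    df = table.data
    lmm = smf.mixedlm("y ~ x1", df, groups=df["cluster_id"]).fit(reml=False)
    return table, fit, lmm
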