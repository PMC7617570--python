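"""Derived cluster summaries: PVRs, variances, shrinkage, ranks, flags."""

import numpy as np
import pandas as pd
import pytest

import melscale as m
from melscale.mcmc_engine import FitResult
from melscale.school_effects import ReferenceProfile, caterpillar_data


def _manual_fit(spec, beta_draws, alpha_draws, Sigma_draws, effect_draws,
                cluster_ids=None, n_j=None):
    """Assemble a FitResult from explicit draw arrays (1 chain)."""
    T = beta_draws.shape[0]
    J = effect_draws.shape[1]
    return FitResult(
        spec=spec,
        priors=m.PriorSpec(),
        config=m.McmcConfig(chains=1, burnin=0, iterations=T, seed=0),
        cluster_ids=cluster_ids or [f"c{j}" for j in range(J)],
        n_j=n_j if n_j is not None else np.full(J, 10),
        beta=beta_draws[None],
        alpha=alpha_draws[None],
        Sigma=Sigma_draws[None],
        deviance=np.zeros((1, T)),
        effects=effect_draws[None],
        accept_v=np.array([0.4]),
        accept_alpha=np.array([0.3]),
        _data={},
    )


class TestPvr:
    def test_school_mean_interval(self):
        lo, hi = m.pvr(-0.011, 0.067)
        assert (round(lo, 2), round(hi, 2)) == (-0.52, 0.50)
        assert lo == pytest.approx(-0.518, abs=5e-4)
        assert hi == pytest.approx(0.496, abs=5e-4)

    def test_school_slope_interval(self):
        lo, hi = m.pvr(0.675, 0.004)
        assert (round(lo, 2), round(hi, 2)) == (0.55, 0.80)

    def test_zero_variance_degenerates(self):
        assert m.pvr(1.3, 0.0) == (1.3, 1.3)

    def test_exp_scale_commutes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c, v = rng.normal(), rng.uniform(0, 0.5)
            lo_e, hi_e = m.pvr(c, v, scale="exp")
            lo_i, hi_i = m.pvr(c, v, scale="identity")
            assert lo_e == pytest.approx(np.exp(lo_i), rel=1e-12)
            assert hi_e == pytest.approx(np.exp(hi_i), rel=1e-12)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            m.pvr(0.0, 1.0, level=1.2)


class TestPopulationAverageVariance:
    def test_lognormal_mean(self):
        assert m.population_average_variance(-0.881, 0.037) == pytest.approx(
            0.422, abs=5e-4
        )

    def test_zero_scale_variance(self):
        assert m.population_average_variance(-0.5, 0.0) == pytest.approx(np.exp(-0.5))

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(1)
        alpha0, sv2 = -0.881, 0.037
        draws = np.exp(alpha0 + rng.normal(0, np.sqrt(sv2), 10_000_000))
        assert m.population_average_variance(alpha0, sv2) == pytest.approx(
            draws.mean(), abs=5e-4
        )


class TestWithinClusterRange:
    def test_most_variable_school(self):
        var = np.exp(-0.881 + 1.959964 * np.sqrt(0.037))
        assert round(m.within_cluster_range(var), 2) == 3.05

    def test_least_variable_school(self):
        var = np.exp(-0.881 - 1.959964 * np.sqrt(0.037))
        assert round(m.within_cluster_range(var), 2) == 2.09

    def test_unit_variance(self):
        assert m.within_cluster_range(1.0) == pytest.approx(3.92, abs=5e-3)


class TestVpc:
    def test_published_scale_values(self):
        explained, vpc = m.variance_explained_and_vpc(0.067, np.exp(-0.870))
        assert round(explained) == 51
        assert round(vpc) == 14

    def test_edge_cases(self):
        assert m.variance_explained_and_vpc(0.0, 0.4)[1] == 0.0
        assert m.variance_explained_and_vpc(0.3, 0.0)[1] == 100.0

    def test_overfull_total_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            explained, _ = m.variance_explained_and_vpc(0.6, 0.7)
        assert explained == 0.0


class TestClusterVariance:
    def test_zero_scale_draw_gives_exp_alpha0(self):
        spec = m.model_spec(2)
        T, J = 50, 4
        fitr = _manual_fit(
            spec,
            np.tile([0.0, 0.7], (T, 1)),
            np.full((T, 1), -0.881),
            np.tile(np.eye(2) * 0.05, (T, 1, 1)),
            np.zeros((T, J, 2)),
        )
        out = m.cluster_variance(fitr, ReferenceProfile())
        np.testing.assert_allclose(out["variance_mean"], np.exp(-0.881), rtol=1e-12)

    def test_full_covariate_profile_matches_dot_product(self):
        """Variance at a covariate profile equals the brute-force
        linear-predictor evaluation."""
        spec = m.model_spec(7)
        p = m.REFERENCE_ESTIMATES[7]
        profile_vals = {
            "x1": 0.258, "summer_born": 0.258, "girl": 0.505, "eth_black": 0.219,
            "eth_asian": 0.210, "eth_chinese": 0.006, "eth_mixed": 0.081,
            "eth_other": 0.090, "lang_not_english": 0.400, "sen": 0.142,
            "fsm": 0.348,
        }
        prof = ReferenceProfile(variance_covariates=profile_vals)
        T, J = 10, 3
        v = 0.1
        fitr = _manual_fit(
            spec,
            np.tile(p.beta, (T, 1)),
            np.tile(p.alpha, (T, 1)),
            np.tile(p.Sigma, (T, 1, 1)),
            np.full((T, J, 2), [0.0, v]),
        )
        out = m.cluster_variance(fitr, prof)
        eta = p.alpha[0] + sum(
            p.alpha[k + 1] * profile_vals[name]
            for k, name in enumerate(spec.variance_covariates)
        )
        np.testing.assert_allclose(out["variance_mean"], np.exp(eta + v), rtol=1e-12)

    def test_missing_profile_covariate_raises(self):
        spec = m.model_spec(3)
        fitr = _manual_fit(
            spec,
            np.zeros((5, 2)),
            np.zeros((5, 2)),
            np.tile(np.eye(2) * 0.1, (5, 1, 1)),
            np.zeros((5, 2, 2)),
        )
        with pytest.raises(KeyError, match="x1"):
            m.cluster_variance(fitr, ReferenceProfile())


class TestClusterMean:
    def _slope_fit(self):
        spec = m.model_spec(4)
        T, J = 40, 3
        rng = np.random.default_rng(5)
        E = rng.normal(size=(T, J, 2))
        return _manual_fit(
            spec,
            np.tile([0.0, 0.675], (T, 1)),
            np.full((T, 1), -0.877),
            np.tile(np.eye(2) * 0.05, (T, 1, 1)),
            E,
        ), E

    def test_at_zero_equals_intercept_summary(self):
        fitr, E = self._slope_fit()
        out = m.cluster_mean_adjusted(fitr, ReferenceProfile(mean_x1=0.0))
        np.testing.assert_allclose(out["mean_effect_mean"], E[:, :, 0].mean(0), atol=1e-12)

    def test_linearity_in_reference_point(self):
        fitr, E = self._slope_fit()
        hi = m.cluster_mean_adjusted(fitr, ReferenceProfile(mean_x1=1.0))
        lo = m.cluster_mean_adjusted(fitr, ReferenceProfile(mean_x1=-1.0))
        np.testing.assert_allclose(
            hi["mean_effect_mean"] - lo["mean_effect_mean"],
            2 * E[:, :, 1].mean(0),
            atol=1e-12,
        )


class TestTotalVariance:
    def test_slope_share_magnitude(self):
        """A typical slope SD contributes well under 1% of the total."""
        spec = m.model_spec(5)
        T, J = 30, 2
        E = np.zeros((T, J, 3))
        E[:, :, 1] = np.sqrt(0.004)
        fitr = _manual_fit(
            spec,
            np.tile([0.0, 0.675], (T, 1)),
            np.full((T, 1), np.log(0.42)),
            np.tile(np.eye(3) * 0.03, (T, 1, 1)),
            E,
        )
        out = m.total_adjusted_variance(fitr, ReferenceProfile(var_x1=0.83))
        share = 0.004 * 0.83 / (0.004 * 0.83 + 0.42)
        np.testing.assert_allclose(out["share_mean"], share, rtol=1e-10)
        assert (out["share_mean"] < 0.01).all()

    def test_no_slope_share_is_zero(self):
        spec = m.model_spec(2)
        fitr = _manual_fit(
            spec,
            np.zeros((5, 2)),
            np.zeros((5, 1)),
            np.tile(np.eye(2) * 0.05, (5, 1, 1)),
            np.zeros((5, 3, 2)),
        )
        out = m.total_adjusted_variance(fitr)
        assert (out["share_mean"] == 0.0).all()

    def test_share_tends_to_one_without_residual(self):
        spec = m.model_spec(5)
        T, J = 5, 2
        E = np.zeros((T, J, 3))
        E[:, :, 1] = 0.3
        E[:, :, 2] = -60.0  # residual variance exp(alpha0 + v) -> 0
        fitr = _manual_fit(
            spec,
            np.zeros((T, 2)),
            np.zeros((T, 1)),
            np.tile(np.eye(3) * 0.03, (T, 1, 1)),
            E,
        )
        out = m.total_adjusted_variance(fitr, ReferenceProfile(var_x1=1.0))
        assert (out["share_mean"] > 0.999).all()


class TestShrinkage:
    def test_small_cluster_shrinks_more(self):
        """Equal raw residual offsets: the 14-student school's posterior
        mean effect sits closer to zero than the 330-student school's."""
        rng = np.random.default_rng(8)
        sizes = [14, 330] + [60] * 18
        offsets = [0.3, 0.3] + [0.0] * 18
        rows = []
        for j, (nj, off) in enumerate(zip(sizes, offsets)):
            x1 = rng.normal(size=nj)
            e = rng.normal(0, np.sqrt(0.42), size=nj)
            e = e - e.mean()  # exact raw offset
            rows.append(
                pd.DataFrame(
                    {"cluster_id": f"s{j:02d}", "y": 0.7 * x1 + off + e, "x1": x1}
                )
            )
        table = m.AnalysisTable(pd.concat(rows, ignore_index=True))
        fit = m.fit(
            table, m.model_spec(1),
            config=m.McmcConfig(chains=2, burnin=300, iterations=600, seed=4),
        )
        eff = m.shrunken_effects(fit)
        small = eff.loc[eff.cluster_id == "s00", "u0_mean"].item()
        large = eff.loc[eff.cluster_id == "s01", "u0_mean"].item()
        assert 0 < small < large

    def test_total_shrinkage_when_no_cluster_variation(self):
        truth = m.parameters_from_summaries(
            m.model_spec(1), [0.0, 0.7], [-0.87], [1e-8]
        )
        scn = m.scenario(1, J=40, size_mean=50, size_min=30, size_max=80,
                         seed=19, truth=truth)
        table = scn.generate()
        fit = m.fit(
            table, m.model_spec(1),
            priors=m.PriorSpec(iw_scale=0.01),
            config=m.McmcConfig(chains=2, burnin=300, iterations=600, seed=5),
        )
        eff = m.shrunken_effects(fit)
        # raw per-cluster mean residuals for comparison
        resid = table.data["y"] - 0.7 * table.data["x1"]
        g = table.group_codes
        raw = np.bincount(g, weights=resid) / table.n_j
        raw = raw - raw.mean()
        assert np.abs(eff["u0_mean"]).mean() < 0.4 * np.abs(raw).mean()
        assert np.abs(eff["u0_mean"]).max() < 0.1

    def test_posterior_mean_effects_center_near_zero(self, model2_recovery_fit):
        _, _, fit = model2_recovery_fit
        eff = m.shrunken_effects(fit)
        assert abs(eff["u0_mean"].mean()) < 0.01


class TestRankAndFlag:
    def _summaries(self):
        return pd.DataFrame(
            {
                "cluster_id": ["a", "b", "c"],
                "mean": [0.5, -0.4, 0.1],
                "lo": [0.2, -0.7, -0.2],
                "hi": [0.8, -0.1, 0.4],
            }
        )

    def test_ranks_follow_point_estimates(self):
        out = m.rank_and_flag(self._summaries(), 0.0)
        assert dict(zip(out.cluster_id, out["rank"])) == {"b": 1, "c": 2, "a": 3}

    def test_flags_use_interval_exclusion(self):
        out = m.rank_and_flag(self._summaries(), 0.0)
        assert dict(zip(out.cluster_id, out.flag)) == {"a": True, "b": True, "c": False}

    def test_ties_broken_by_table_order(self):
        df = self._summaries()
        df["mean"] = [0.1, 0.1, 0.1]
        out = m.rank_and_flag(df, 0.0)
        assert list(out["rank"]) == [1, 2, 3]

    def test_caterpillar_data_sorted(self):
        out = caterpillar_data(m.rank_and_flag(self._summaries(), 0.0))
        assert list(out["rank"]) == [1, 2, 3]
        assert list(out["cluster_id"]) == ["b", "c", "a"]

    def test_detection_improves_with_cluster_size(self):
        """At fixed true effects, larger clusters are flagged more often."""
        rng = np.random.default_rng(12)
        J_half = 20
        sizes = np.array([20] * J_half + [200] * J_half)
        u = rng.normal(0, np.sqrt(0.067), size=2 * J_half)
        rows = []
        for j, (nj, uj) in enumerate(zip(sizes, u)):
            x1 = rng.normal(size=nj)
            rows.append(
                pd.DataFrame(
                    {
                        "cluster_id": f"s{j:02d}",
                        "y": 0.7 * x1 + uj + rng.normal(0, np.sqrt(0.42), nj),
                        "x1": x1,
                    }
                )
            )
        table = m.AnalysisTable(pd.concat(rows, ignore_index=True))
        fit = m.fit(
            table, m.model_spec(1),
            config=m.McmcConfig(chains=2, burnin=300, iterations=600, seed=6),
        )
        eff = m.cluster_mean_adjusted(fit)
        ranked = m.rank_and_flag(
            eff, 0.0, "mean_effect_mean", "mean_effect_lo", "mean_effect_hi"
        )
        small_rate = ranked.flag.to_numpy()[:J_half].mean()
        large_rate = ranked.flag.to_numpy()[J_half:].mean()
        assert large_rate > small_rate


class TestReferenceProfile:
    def test_from_table_defaults(self, small_model2_table):
        prof = ReferenceProfile.from_table(small_model2_table)
        x1 = small_model2_table.data["x1"]
        assert prof.mean_x1 == pytest.approx(float(x1.mean()))
        assert prof.var_x1 > 0
        assert "x1" in prof.variance_covariates

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="var_x1"):
            ReferenceProfile(var_x1=-1.0)
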