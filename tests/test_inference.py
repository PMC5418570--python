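"""Estimators, tests and aggregate statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from contestlearn import features, game, inference
from contestlearn.errors import ConfigError, EstimationError
from contestlearn.errors import TestError as StatTestError
from conftest import constant_trajectory


def small_fixture(n=40, seed=3):
    """Deterministic 40-row feature table with two clusters per pair id."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "pair_id": np.repeat(np.arange(8), n // 8),
            "subject_id": np.arange(n),
            "treatment": np.where(np.repeat(np.arange(8), n // 8) % 2, "Info", "NoInfo"),
            "period": rng.integers(3, 600, n),
            "copy_up": rng.integers(0, 2, n),
            "copy_down": 0,
            "wclr": rng.integers(0, 2, n),
            "br": rng.integers(0, 2, n),
            "at_boundary": 0,
            "wclr_const_profit": 0,
        }
    )
    table["copy_down"] = np.where(table.copy_up == 0, rng.integers(0, 2, n), 0)
    table["info"] = (table.treatment == "Info").astype(int)
    table["phase"] = features.assign_phase(table["period"].to_numpy())
    # outcome with known structure plus noise
    table["change"] = (
        (0.3 + 0.4 * table.copy_up - 0.2 * table.copy_down + rng.uniform(0, 1, n)) > 0.8
    ).astype(int)
    return table


class TestFitLpm:
    def test_matches_normal_equations_oracle(self):
        table = small_fixture()
        res = inference.fit_lpm(table, regressors=inference.MAIN_EFFECT_REGRESSORS)
        X = np.column_stack(
            [np.ones(len(table)), table.copy_up, table.copy_down, table.wclr, table.br]
        ).astype(float)
        y = table.change.to_numpy(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)
        # residual orthogonality to the design
        resid = y - X @ res.params.to_numpy()
        assert np.max(np.abs(X.T @ resid)) < 1e-8

    def test_perfect_fit_when_outcome_equals_regressor(self):
        table = small_fixture()
        table["change"] = table["copy_up"]
        res = inference.fit_lpm(table, regressors=("copy_up",))
        assert res.coef("copy_up") == pytest.approx(1.0, abs=1e-10)
        assert res.coef("const") == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_rank_deficiency_names_collinear_columns(self):
        table = small_fixture()
        table["wclr"] = table["copy_up"]  # duplicate column content
        with pytest.raises(EstimationError, match="wclr"):
            inference.fit_lpm(table, regressors=("copy_up", "wclr", "br"))

    def test_singleton_clusters_equal_hc1(self):
        import statsmodels.api as sm

        table = small_fixture()
        table["pair_id"] = np.arange(len(table))  # one observation per cluster
        res = inference.fit_lpm(table, regressors=inference.MAIN_EFFECT_REGRESSORS)
        X = np.column_stack(
            [np.ones(len(table)), table.copy_up, table.copy_down, table.wclr, table.br]
        ).astype(float)
        hc1 = sm.OLS(table.change.to_numpy(float), X).fit(cov_type="HC1")
        assert np.allclose(res.bse.to_numpy(), hc1.bse, rtol=1e-8)

    def test_phase_subsets_restrict_rows(self, default_features):
        table, _ = default_features
        naive = inference.fit_lpm(table, periods=(1, 25))
        assert naive.nobs == len(table[(table.period >= 1) & (table.period <= 25)])

    def test_cluster_count_reported(self, default_features):
        table, _ = default_features
        res = inference.fit_lpm(table, periods=(26, 600))
        assert res.n_clusters == 36

    def test_clustered_se_grow_with_injected_within_pair_correlation(self):
        rng = np.random.default_rng(12)
        n_pairs, per = 30, 40
        pair = np.repeat(np.arange(n_pairs), per)
        x = rng.integers(0, 2, n_pairs * per)
        # outcome with a strong pair-level random effect shared within clusters
        effect = np.repeat(rng.uniform(-0.35, 0.35, n_pairs), per)
        ylat = 0.5 + 0.0 * x + effect + rng.normal(0, 0.1, n_pairs * per)
        table = pd.DataFrame(
            {
                "pair_id": pair,
                "change": (ylat > 0.5).astype(int),
                "copy_up": x,
                "period": 100,
                "at_boundary": 0,
                "phase": "learning",
            }
        )
        import statsmodels.api as sm

        res = inference.fit_lpm(table, regressors=("copy_up",))
        X = np.column_stack([np.ones(len(table)), x]).astype(float)
        iid = sm.OLS(table.change.to_numpy(float), X).fit()
        assert res.se("const") > iid.bse[0]

    def test_logit_estimator_agrees_in_sign(self, default_features):
        table, _ = default_features
        ols = inference.fit_lpm(table, periods=(26, 600))
        logit = inference.fit_lpm(table, periods=(26, 600), estimator="logit")
        for name in ("copy_up", "copy_down", "wclr", "br"):
            if abs(ols.coef(name)) > 2 * ols.se(name):
                assert np.sign(logit.coef(name)) == np.sign(ols.coef(name))


class TestWald:
    def test_single_coefficient_equals_squared_t_ratio(self, default_features):
        table, _ = default_features
        res = inference.fit_lpm(table, periods=(26, 600))
        out = inference.wald_combination(res, {"wclr": 1.0})
        assert out.statistic == pytest.approx(
            (res.coef("wclr") / res.se("wclr")) ** 2, rel=1e-10
        )

    def test_weight_vector_and_mapping_agree(self, default_features):
        table, _ = default_features
        res = inference.fit_lpm(table, periods=(26, 600))
        w = np.zeros(len(res.params))
        w[list(res.params.index).index("br")] = 1.0
        w[list(res.params.index).index("br:info")] = 1.0
        a = inference.wald_combination(res, w)
        b = inference.wald_combination(res, {"br": 1.0, "br:info": 1.0})
        assert a.statistic == pytest.approx(b.statistic)

    def test_zero_weights_rejected(self, default_features):
        table, _ = default_features
        res = inference.fit_lpm(table, periods=(26, 600))
        with pytest.raises(ConfigError):
            inference.wald_combination(res, np.zeros(len(res.params)))


class TestMannWhitney:
    def test_extreme_separation_matches_exact_enumeration(self, params):
        trajs = [
            constant_trajectory(params, v, pair_id=i, treatment="NoInfo")
            for i, v in enumerate([1.0, 2.0, 3.0])
        ] + [
            constant_trajectory(params, v, pair_id=i + 3, treatment="Info")
            for i, v in enumerate([4.0, 5.0, 6.0])
        ]
        res = inference.mann_whitney_treatments(trajs, "naive")
        # U = 0; exact two-sided p = 2 / C(6,3) = 0.1
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self, params):
        trajs = [
            constant_trajectory(params, 2.0, pair_id=i, treatment=tr)
            for tr in ("NoInfo", "Info")
            for i in range(3)
        ]
        res = inference.mann_whitney_treatments(trajs, "naive")
        assert res.pvalue == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, params):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.5, 5.5, 8)
        trajs = [
            constant_trajectory(params, v, pair_id=i,
                                treatment="NoInfo" if i < 4 else "Info")
            for i, v in enumerate(vals)
        ]
        trans = [
            constant_trajectory(params, np.sqrt(v), pair_id=i,
                                treatment="NoInfo" if i < 4 else "Info")
            for i, v in enumerate(vals)
        ]
        a = inference.mann_whitney_treatments(trajs, "naive")
        b = inference.mann_whitney_treatments(trans, "naive")
        assert a.statistic == b.statistic and a.pvalue == b.pvalue

    def test_too_few_units_raise(self, params):
        trajs = [
            constant_trajectory(params, 2.0, pair_id=0, treatment="NoInfo"),
            constant_trajectory(params, 3.0, pair_id=1, treatment="Info"),
        ]
        with pytest.raises(StatTestError):
            inference.mann_whitney_treatments(trajs, "naive")


class TestTTest:
    def test_hand_computed_fixture(self, params):
        trajs = [
            constant_trajectory(params, v, pair_id=i, treatment="NoInfo")
            for i, v in enumerate([2.0, 2.2, 1.8])
        ]
        res = inference.t_test_vs_nash(trajs, "NoInfo", "naive")
        x = np.array([2.0, 2.2, 1.8])
        expected_t = (x.mean() - 3.0) / (x.std(ddof=1) / np.sqrt(3))
        assert res.statistic == pytest.approx(expected_t, rel=1e-10)
        expected_p = 2 * scipy.stats.t.sf(abs(expected_t), df=2)
        assert res.pvalue == pytest.approx(expected_p, rel=1e-10)

    def test_all_at_nash_gives_p_one(self, params):
        trajs = [
            constant_trajectory(params, 3.0, pair_id=i, treatment="Info")
            for i in range(4)
        ]
        res = inference.t_test_vs_nash(trajs, "Info", "naive")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_zero_variance_off_null_raises(self, params):
        trajs = [
            constant_trajectory(params, 2.0, pair_id=i, treatment="Info")
            for i in range(4)
        ]
        with pytest.raises(StatTestError):
            inference.t_test_vs_nash(trajs, "Info", "naive")


class TestAggregates:
    def test_bins_constant_dataset(self, params):
        trajs = [constant_trajectory(params, 2.5, horizon=600)]
        bins = inference.median_action_bins(trajs)
        assert (bins.median_action == 2.5).all()
        assert len(bins) == 28  # 5 bins of 5 periods + 23 bins of 25

    def test_bin_edges_for_horizon_600(self, default_experiment):
        bins = inference.median_action_bins(default_experiment)
        noinfo = bins[bins.treatment == "NoInfo"]
        assert len(noinfo) == 28
        assert list(noinfo["bin"][:6]) == ["1-5", "6-10", "11-15", "16-20", "21-25", "26-50"]

    def test_phase_summary_constant(self, params):
        trajs = [constant_trajectory(params, 2.0, horizon=600)]
        out = inference.phase_summary(trajs)
        assert (out["mean"] == 2.0).all()
        assert (out.sd == 0.0).all()

    def test_phase_summary_matches_two_pass_oracle(self, default_experiment):
        out = inference.phase_summary(default_experiment)
        # recompute one cell by brute force
        pooled = np.concatenate(
            [t.actions[300:600].ravel() for t in default_experiment if t.treatment == "Info"]
        )
        row = out[(out.treatment == "Info") & (out.phase == "longrun")].iloc[0]
        assert row["mean"] == pytest.approx(pooled.mean(), rel=1e-12)
        assert row["sd"] == pytest.approx(pooled.std(ddof=1), rel=1e-12)
        assert row["median"] == pytest.approx(np.median(pooled), rel=1e-12)


class TestEarnings:
    def test_nash_play_for_a_phase(self, params):
        trajs = [constant_trajectory(params, 3.0, horizon=600)]
        per_subject, medians = inference.earnings(trajs, phase="longrun")
        # 300 periods x 40 points / 2000 points-per-euro
        assert medians["NoInfo"] == pytest.approx(6.0, rel=1e-9)

    def test_cooperative_play_for_a_phase(self, params):
        trajs = [constant_trajectory(params, 0.1, horizon=600)]
        _, medians = inference.earnings(trajs, phase="longrun")
        assert medians["NoInfo"] == pytest.approx(10.35, rel=1e-9)

    def test_show_up_fee_only_added_on_request(self, params):
        trajs = [constant_trajectory(params, 3.0, horizon=600)]
        _, base = inference.earnings(trajs, phase="longrun")
        _, topped = inference.earnings(trajs, phase="longrun", show_up_euro=5.0)
        assert topped["NoInfo"] == pytest.approx(base["NoInfo"] + 5.0)

    def test_no_phase_filter_sums_everything(self, params):
        trajs = [constant_trajectory(params, 3.0, horizon=600)]
        _, medians = inference.earnings(trajs)
        assert medians["NoInfo"] == pytest.approx(12.0, rel=1e-9)
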