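"""Regression engine, fluctuation solver, and nuisance estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

import misscausal as mc
from misscausal.nuisance import (
    NuisanceSpecs,
    RegressionSpec,
    estimate_nuisances_ia,
    estimate_nuisances_ib,
    fit_weighted_regression,
    solve_fluctuation,
)


def _random_frame(rng, n=200):
    return pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.integers(0, 2, n).astype(float),
    })


class TestFitWeightedRegression:
    def test_identity_link_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        df = _random_frame(rng)
        y = 0.5 + 1.2 * df["x1"] - 0.7 * df["x2"] + rng.normal(size=len(df))
        fit = fit_weighted_regression(df, y, RegressionSpec(link="identity"), ["x1", "x2"])
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coef_, beta, atol=1e-10)

    def test_duplicated_row_equals_doubled_weight(self):
        rng = np.random.default_rng(1)
        df = _random_frame(rng, 80)
        y = (rng.random(80) < expit(df["x1"])).astype(float)
        w = np.ones(80)
        w[3] = 2.0
        dup = pd.concat([df, df.iloc[[3]]], ignore_index=True)
        y_dup = np.append(y, y[3])
        f_w = fit_weighted_regression(df, y, RegressionSpec(), ["x1", "x2"], weights=w)
        f_d = fit_weighted_regression(dup, y_dup, RegressionSpec(), ["x1", "x2"])
        assert np.allclose(f_w.coef_, f_d.coef_, atol=1e-7)

    def test_logit_saturated_design_recovers_stratum_means(self):
        # a single binary covariate: the parametric logistic fit is saturated
        df = pd.DataFrame({"x": [0.0] * 40 + [1.0] * 60})
        y = np.array([1.0] * 10 + [0.0] * 30 + [1.0] * 45 + [0.0] * 15)
        fit = fit_weighted_regression(df, y, RegressionSpec(), ["x"])
        pred = fit.predict(pd.DataFrame({"x": [0.0, 1.0]}))
        assert np.allclose(pred, [0.25, 0.75], atol=1e-8)

    def test_saturated_flavor_equals_groupby_means(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"b1": rng.integers(0, 2, 300).astype(float),
                           "b2": rng.integers(0, 2, 300).astype(float)})
        y = rng.random(300)
        fit = fit_weighted_regression(df, y, RegressionSpec(flavor="saturated"), ["b1", "b2"])
        expect = pd.Series(y).groupby([df.b1, df.b2]).mean()
        pred = fit.predict(df)
        for (b1, b2), m in expect.items():
            assert pred[(df.b1 == b1) & (df.b2 == b2)][0] == pytest.approx(m, abs=1e-12)

    def test_matches_statsmodels_glm_with_weights_and_offset(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        df = _random_frame(rng, 500)
        off = 0.3 * df["x1"].to_numpy()
        w = rng.uniform(0.5, 2.0, 500)
        y = (rng.random(500) < expit(-0.2 + 0.8 * df["x1"] + off)).astype(float)
        fit = fit_weighted_regression(df, y, RegressionSpec(), ["x1", "x2"],
                                      weights=w, offset=off)
        X = np.column_stack([np.ones(500), df["x1"], df["x2"]])
        ref = sm.GLM(y, X, family=sm.families.Binomial(), offset=off, var_weights=w).fit()
        assert np.allclose(fit.coef_, ref.params, atol=1e-6)

    def test_unseen_stratum_raises_positivity(self):
        df = pd.DataFrame({"b": [0.0, 0.0, 0.0]})
        fit = fit_weighted_regression(df, [1.0, 0.0, 1.0], RegressionSpec(flavor="saturated"), ["b"])
        with pytest.raises(mc.PositivityError, match="unseen"):
            fit.predict(pd.DataFrame({"b": [1.0]}))

    def test_zero_sample_and_bad_weights_rejected(self):
        df = pd.DataFrame({"x": []})
        with pytest.raises(mc.PositivityError):
            fit_weighted_regression(df, [], RegressionSpec(), ["x"])
        df = pd.DataFrame({"x": [1.0, 0.0]})
        with pytest.raises(ValueError):
            fit_weighted_regression(df, [1.0, 0.0], RegressionSpec(), ["x"], weights=[0.0, 0.0])

    def test_learner_hook(self):
        from sklearn.ensemble import GradientBoostingRegressor

        rng = np.random.default_rng(4)
        df = _random_frame(rng, 300)
        y = (rng.random(300) < expit(df["x1"])).astype(float)
        spec = RegressionSpec(flavor="learner",
                              learner=GradientBoostingRegressor(n_estimators=20, random_state=0))
        fit = fit_weighted_regression(df, y, spec, ["x1", "x2"])
        pred = fit.predict(df)
        assert pred.shape == (300,) and (pred >= 0).all() and (pred <= 1).all()


class TestSolveFluctuation:
    def test_fixed_point_gives_zero_epsilon(self):
        y = np.array([0.3, 0.7, 0.5])
        res = solve_fluctuation(y, logit(y), np.ones(3))
        assert res.epsilon == pytest.approx(0.0, abs=1e-10)
        assert res.converged

    def test_closed_form_root(self):
        y = np.array([1.0, 0.0, 1.0])
        off = np.full(3, logit(0.4))
        res = solve_fluctuation(y, off, np.ones(3))
        assert res.epsilon == pytest.approx(logit(2 / 3) - logit(0.4), abs=1e-9)

    def test_all_ones_clamps_at_bound_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            res = solve_fluctuation(np.ones(5), np.zeros(5), np.ones(5))
        assert res.epsilon == 10.0 and not res.converged

    def test_identity_link_weighted_mean_residual(self):
        y = np.array([1.0, 2.0, 4.0])
        off = np.array([0.5, 1.5, 3.0])
        w = np.array([1.0, 2.0, 1.0])
        res = solve_fluctuation(y, off, w, link="identity")
        assert res.epsilon == pytest.approx(np.sum(w * (y - off)) / w.sum())

    @settings(max_examples=100, deadline=None)
    @given(data=st.lists(
        st.tuples(st.floats(0.02, 0.98), st.floats(-2, 2), st.floats(0.1, 5)),
        min_size=2, max_size=20))
    def test_root_property(self, data):
        y, off, w = (np.array(v) for v in zip(*data))
        res = solve_fluctuation(y, off, w)
        if res.converged:
            assert abs(np.sum(w * (y - expit(off + res.epsilon)))) < 1e-7


class TestNuisanceEstimation:
    def test_fully_observed_reduces_to_propensity(self, roles):
        rng = np.random.default_rng(5)
        n = 400
        df = pd.DataFrame({
            "y": rng.integers(0, 2, n).astype(float),
            "a": rng.integers(0, 2, n).astype(float),
            "l_o": rng.integers(0, 2, n).astype(float),
            "l_m1": rng.integers(0, 2, n).astype(float),
            "l_m2": rng.integers(0, 2, n).astype(float),
        })
        table = mc.ObservedTable.from_dataframe(df, roles)
        fit = estimate_nuisances_ia(table, NuisanceSpecs.saturated(0.01), 1.0)
        assert np.allclose(fit.pi_rl[0], 1.0)
        assert np.allclose(fit.pi_ra, 1.0)
        strata = df.groupby(["l_o", "l_m1", "l_m2"])["a"].mean()
        for key, m in strata.items():
            mask = (df.l_o == key[0]) & (df.l_m1 == key[1]) & (df.l_m2 == key[2])
            assert fit.pi_a[mask.to_numpy()][0] == pytest.approx(max(m, 0.01), abs=1e-10)

    def test_saturated_fits_equal_empirical_frequencies(self, sim_table_ii, sat_specs):
        fit = estimate_nuisances_ia(sim_table_ii, sat_specs, 1.0)
        t = sim_table_ii
        rl = t.r_l_joint == 1
        df = t.frame()
        # spot-check pi_rl on one stratum
        for lo in (0.0, 1.0):
            mask = df["l_o"].to_numpy() == lo
            emp = rl[mask].mean()
            assert fit.pi_rl[0][mask][0] == pytest.approx(emp, abs=1e-12)

    def test_scenario_ii_predictions_within_bounds_with_diagnostics(self, sim_table_ii):
        specs = NuisanceSpecs.saturated(truncation=0.01)
        fit = estimate_nuisances_ia(sim_table_ii, specs, 1.0)
        for name, arr in (("pi_a", fit.pi_a), ("pi_ra", fit.pi_ra), ("pi_rl", fit.pi_rl[0])):
            assert (arr >= 0.01).all() and (arr <= 1.0).all()
        assert "pred_range" in fit.diagnostics

    def test_ib_with_q1_matches_ia(self, sim_table_ii, sat_specs):
        # restrict to a single partially observed covariate
        roles1 = mc.VariableRoles("y", "a", ("l_o",), ("l_m1",))
        df = sim_table_ii.frame().drop(columns=["l_m2"])
        t1 = mc.ObservedTable.from_dataframe(df, roles1)
        f_ia = estimate_nuisances_ia(t1, sat_specs, 1.0)
        f_ib = estimate_nuisances_ib(t1, sat_specs, 1.0, ["l_m1"])
        assert np.allclose(f_ia.pi_rl[0], f_ib.pi_rl[0])
        assert np.allclose(f_ia.pi_ra, f_ib.pi_ra)
        assert np.allclose(f_ia.pi_a, f_ib.pi_a)
        assert np.allclose(f_ia.t_init, f_ib.t_init, equal_nan=True)

    def test_ordering_lets_later_missingness_depend_on_earlier_covariate(
        self, sim_table_iii, sat_specs
    ):
        work = mc.coarsen_monotone(sim_table_iii, ["l_m1", "l_m2"])
        fit = estimate_nuisances_ib(work, sat_specs, 1.0, ["l_m1", "l_m2"])
        # the second-stage missingness model conditions on l_m1, and in
        # Scenario III the dependence is real
        df = work.frame()
        obs1 = work.r_l[:, 0] == 1
        p_by_lm1 = [fit.pi_rl[1][obs1 & (df["l_m1"].to_numpy() == v)][0] for v in (0.0, 1.0)]
        assert abs(p_by_lm1[1] - p_by_lm1[0]) > 0.05

    def test_nonmonotone_table_rejected_for_ib(self, small_table, sat_specs):
        with pytest.raises(ValueError, match="monotone"):
            estimate_nuisances_ib(small_table, sat_specs, 1.0, ["l_m1", "l_m2"])
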