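"""Linear engine: design construction, OLS, cluster-robust variance."""

import numpy as np
import pandas as pd
import pytest

from staggerdid import (ModelSpec, PolicySchedule, build_treatment_indicator,
                        fit_linear, validate_panel, wald_interval)


def _toy_panel(x, y, region=None):
    n = len(x)
    return pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(n)],
        "region_id": region if region is not None else ["r0"] * n,
        "wave": [2011] * n,
        "y": y, "x": x,
    })


PLAIN = ModelSpec(outcome="y", treatment_terms=("x",),
                  include_treated_main=False, time_fe=None, cluster=None)


class TestTreatmentIndicator:
    WAVES = (2011, 2013, 2015, 2018)

    def _panel(self):
        return pd.DataFrame({
            "individual_id": ["a"] * 4 + ["b"] * 4,
            "region_id": ["pilot"] * 4 + ["other"] * 4,
            "wave": list(self.WAVES) * 2,
            "cancer": [0] * 8,
        })

    def test_mid_rollout_adoption(self):
        sched = PolicySchedule({"pilot": 2014}, regions=("pilot", "other"))
        out = build_treatment_indicator(self._panel(), sched)
        pilot = out[out.region_id == "pilot"].sort_values("wave")
        assert pilot["cetp_post"].tolist() == [0, 0, 1, 1]

    def test_never_treated_all_zero(self):
        sched = PolicySchedule({"pilot": 2014}, regions=("pilot", "other"))
        out = build_treatment_indicator(self._panel(), sched)
        assert (out.loc[out.region_id == "other", "cetp_post"] == 0).all()
        assert (out.loc[out.region_id == "other", "treated"] == 0).all()

    def test_adoption_year_boundary_inclusive(self):
        sched = PolicySchedule({"pilot": 2013}, regions=("pilot", "other"))
        out = build_treatment_indicator(self._panel(), sched)
        pilot = out[out.region_id == "pilot"].sort_values("wave")
        assert pilot["cetp_post"].tolist() == [0, 1, 1, 1]

    def test_region_missing_from_schedule_never_treated(self, caplog):
        sched = PolicySchedule({"pilot": 2013}, regions=("pilot",))
        with caplog.at_level("INFO", logger="staggerdid.panel"):
            out = build_treatment_indicator(self._panel(), sched)
        assert (out.loc[out.region_id == "other", "cetp_post"] == 0).all()
        assert "never-treated" in caplog.text


class TestFitLinear:
    def test_four_point_toy_closed_form(self):
        """x = (0,0,1,1), y = (0,2,3,5): normal equations give slope 3,
        intercept 1."""
        res = fit_linear(_toy_panel([0, 0, 1, 1], [0, 2, 3, 5]), PLAIN)
        assert res.params["x"] == pytest.approx(3.0, abs=1e-12)
        assert res.params["_cons"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_outcome(self):
        res = fit_linear(_toy_panel([0.0, 1, 2, 3], [5.0, 5, 5, 5]), PLAIN)
        assert res.params["x"] == pytest.approx(0.0, abs=1e-10)
        assert res.params["_cons"] == pytest.approx(5.0, abs=1e-10)
        assert res.rsquared == pytest.approx(0.0, abs=1e-12)

    def test_matches_pseudoinverse_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 60))
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            y = rng.normal(size=n)
            panel = _toy_panel(x1, y)
            panel["x2"] = x2
            res = fit_linear(panel, PLAIN.replace(treatment_terms=("x", "x2")))
            X = np.column_stack([np.ones(n), x1, x2])
            beta = np.linalg.pinv(X.T @ X) @ X.T @ y
            got = res.params[["_cons", "x", "x2"]].to_numpy()
            assert np.allclose(got, beta, rtol=1e-10, atol=1e-12)

    def test_singleton_clusters_equal_hc1(self, rng):
        """With one observation per cluster the textbook cluster sandwich
        reduces to the HC1 heteroskedasticity-robust covariance."""
        n = 40
        x = rng.normal(size=n)
        y = 2 * x + rng.normal(size=n) * (1 + x**2)
        panel = _toy_panel(x, y, region=[f"r{k}" for k in range(n)])
        res = fit_linear(panel, PLAIN.replace(cluster="region_id",
                                              cov_method="cr1"))
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        u = y - X @ beta
        xtxi = np.linalg.inv(X.T @ X)
        hc1 = n / (n - 2) * xtxi @ (X.T * u**2) @ X @ xtxi
        assert np.allclose(res.cov.to_numpy()[np.ix_([1, 0], [1, 0])],
                           hc1[np.ix_([1, 0], [1, 0])], rtol=1e-8)

    def test_cr1_matches_manual_sandwich(self, rng):
        """Textbook cluster covariance: G/(G-1) * (N-1)/(N-K) times the
        score-outer-product sandwich, computed by hand."""
        n, G = 60, 12
        x = rng.normal(size=n)
        region = [f"r{k % G}" for k in range(n)]
        y = 1 + 2 * x + rng.normal(size=n) + rng.normal(size=G)[
            [k % G for k in range(n)]]
        panel = _toy_panel(x, y, region=region)
        res = fit_linear(panel, PLAIN.replace(cluster="region_id",
                                              cov_method="cr1"))
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        u = y - X @ beta
        xtxi = np.linalg.inv(X.T @ X)
        meat = np.zeros((2, 2))
        for g in range(G):
            idx = np.array([k % G == g for k in range(n)])
            s = X[idx].T @ u[idx]
            meat += np.outer(s, s)
        V = G / (G - 1) * (n - 1) / (n - 2) * xtxi @ meat @ xtxi
        got = res.cov.loc[["_cons", "x"], ["_cons", "x"]].to_numpy()
        assert np.allclose(got, V, rtol=1e-8)
        assert res.df_inference == G - 1

    def test_cr2_matches_dense_reference(self, rng):
        """Bias-reduced cluster covariance equals the direct
        (I - H_gg)^(-1/2) construction via fractional matrix powers."""
        import scipy.linalg

        n, G = 48, 8
        x = rng.normal(size=n)
        codes = np.repeat(np.arange(G), n // G)
        y = 1 - x + rng.normal(size=n) + rng.normal(size=G)[codes]
        panel = _toy_panel(x, y, region=[f"r{c}" for c in codes])
        res = fit_linear(panel, PLAIN.replace(cluster="region_id"))
        X = np.column_stack([np.ones(n), x])
        M = np.linalg.inv(X.T @ X)
        u = y - X @ (M @ X.T @ y)
        meat = np.zeros((2, 2))
        for g in range(G):
            idx = codes == g
            Xg = X[idx]
            A = np.real(scipy.linalg.fractional_matrix_power(
                np.eye(int(idx.sum())) - Xg @ M @ Xg.T, -0.5))
            s = Xg.T @ A @ u[idx]
            meat += np.outer(s, s)
        ref = M @ meat @ M
        got = res.cov.loc[["_cons", "x"], ["_cons", "x"]].to_numpy()
        assert np.allclose(got, ref, rtol=1e-8)
        # Satterthwaite dfs are per-term and bounded by the cluster count
        assert (res.df_inference > 0).all()

    def test_rank_deficiency_names_columns(self):
        panel = _toy_panel([0.0, 1, 2, 3], [1.0, 2, 3, 4])
        panel["x_dup"] = panel["x"]
        with pytest.raises(ValueError, match="x_dup|x"):
            fit_linear(panel, PLAIN.replace(treatment_terms=("x", "x_dup")))

    def test_fewer_than_two_clusters_errors(self):
        panel = _toy_panel([0.0, 1, 2, 3], [1.0, 2, 3, 4])
        with pytest.raises(ValueError, match="clusters"):
            fit_linear(panel, PLAIN.replace(cluster="region_id"))

    def test_weighted_fit_downweights(self):
        """WLS with weight ~0 on an outlier reproduces the fit without it."""
        panel = _toy_panel([0.0, 1, 2, 3, 10], [0.0, 1, 2, 3, 50])
        panel["w"] = [1.0, 1, 1, 1, 1e-10]
        res_w = fit_linear(panel, PLAIN.replace(weight="w"))
        res_drop = fit_linear(panel.iloc[:4], PLAIN)
        assert res_w.params["x"] == pytest.approx(res_drop.params["x"], abs=1e-6)


class TestFixedEffectAbsorption:
    def test_dummy_absorption_equals_demeaning(self, small_panel, small_schedule):
        """Wave-FE dummies give the same treatment coefficient as within-
        wave demeaning of outcome and regressors (Frisch-Waugh)."""
        spec = ModelSpec(covariates=("female", "age"), cluster=None)
        res = fit_linear(small_panel, spec)
        cols = ["cancer", "cetp_post", "treated", "female", "age"]
        dm = small_panel[cols + ["wave"]].copy()
        dm[cols] = dm[cols] - dm.groupby("wave")[cols].transform("mean")
        X = dm[["cetp_post", "treated", "female", "age"]].to_numpy()
        beta, *_ = np.linalg.lstsq(X, dm["cancer"].to_numpy(), rcond=None)
        assert res.params["cetp_post"] == pytest.approx(beta[0], abs=1e-8)


class TestWaldInterval:
    def test_zero_se_degenerate_interval(self):
        res = fit_linear(_toy_panel([0.0, 1, 2, 3], [0.0, 2, 4, 6]), PLAIN)
        lo, hi = res.wald_interval("x")
        assert lo == pytest.approx(2.0, abs=1e-8)
        assert hi == pytest.approx(2.0, abs=1e-8)

    def test_wider_level_contains_narrower(self, small_panel, demo_spec,
                                           small_schedule):
        res = fit_linear(small_panel, demo_spec.replace(outcome="cancer"))
        lo95, hi95 = wald_interval(res, "cetp_post", 0.95)
        lo999, hi999 = wald_interval(res, "cetp_post", 0.999)
        assert lo999 < lo95 < hi95 < hi999

    def test_unknown_term_errors(self, small_panel, demo_spec):
        res = fit_linear(small_panel, demo_spec)
        with pytest.raises(ValueError, match="unknown term"):
            res.wald_interval("not_a_term")

    def test_interval_consistent_with_table(self, small_panel, demo_spec):
        res = fit_linear(small_panel, demo_spec)
        lo, hi = res.wald_interval("cetp_post")
        assert lo == pytest.approx(res.conf_int.loc["cetp_post", "low"])
        assert hi == pytest.approx(res.conf_int.loc["cetp_post", "high"])


class TestPanelValidation:
    def test_duplicate_keys_rejected(self):
        panel = _toy_panel([0, 1], [0, 1000])
        panel["individual_id"] = ["a", "a"]
        panel["cancer"] = [0, 1000]
        with pytest.raises(ValueError, match="duplicated"):
            validate_panel(panel)

    def test_outcome_coding_enforced(self):
        panel = _toy_panel([0, 1], [0, 1])
        panel["cancer"] = [0, 1]  # 0/1 coding instead of 0/1000
        with pytest.raises(ValueError, match="0, 1000"):
            validate_panel(panel)

    def test_valid_panel_passes(self, small_panel):
        assert validate_panel(small_panel) is small_panel


class TestSummary:
    def test_summary_layout(self, small_panel, small_schedule, demo_spec):
        res = fit_linear(small_panel, demo_spec)
        text = res.summary(title="Model 1")
        lines = text.splitlines()
        assert lines[0] == "Model 1"
        # treatment term first, then covariates, constant last before footer
        assert lines[3].startswith("cetp_post")
        assert any(ln.startswith("_cons") for ln in lines)
        assert any(ln.startswith("r2") for ln in lines)
        assert any(ln.startswith("N") for ln in lines)

    def test_json_round_trip(self, small_panel, demo_spec, tmp_path):
        import json

        res = fit_linear(small_panel, demo_spec)
        path = tmp_path / "fit.json"
        res.to_json(path)
        data = json.loads(path.read_text())
        assert data["params"]["cetp_post"] == pytest.approx(
            res.params["cetp_post"])
        assert data["nobs"] == res.nobs
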