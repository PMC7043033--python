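"""Model families: stepwise OLS, single-harmonic Fourier, cubic surface, metrics."""

import numpy as np
import pandas as pd
import pytest

from leafskew import (DegenerateInputError, FittedModel, InputError,
                      PUBLISHED_MODELS, evaluate, fit_fourier1,
                      fit_poly_surface, predict_published, stepwise_ols)
from leafskew.modeling import FULL_POLY33_POWERS


class TestStepwise:
    def test_planted_single_predictor(self):
        """y = 2 x1 + small noise among 19 pure-noise candidates -> exactly {x1}."""
        rng = np.random.default_rng(1)
        n = 200
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(1, 21)})
        y = 2.0 * X["x1"] + rng.normal(0, 0.05, n)
        model, trace = stepwise_ols(X, y)
        assert model.predictors == ("x1",)
        se = 0.05 / np.sqrt(n)  # approximate slope SE at unit predictor variance
        assert abs(model.coefficients["x1"] - 2.0) < 3 * se * 2

    def test_constant_target_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        model, trace = stepwise_ols(X, np.full(50, 7.0))
        assert model.predictors == ()
        assert model.coefficients["Intercept"] == pytest.approx(7.0)

    def test_orthogonal_pair_selected_in_two_steps(self):
        n = 64
        t = np.arange(n)
        x1 = np.cos(2 * np.pi * t / n)
        x2 = np.sin(2 * np.pi * t / n)  # orthogonal to x1
        X = pd.DataFrame({"x1": x1, "x2": x2})
        y = x1 + x2
        model, trace = stepwise_ols(X, y)
        assert set(model.predictors) == {"x1", "x2"}
        assert len(trace.steps) == 2 and all(s.action == "enter" for s in trace.steps)
        assert model.coefficients["x1"] == pytest.approx(1.0, abs=1e-8)

    def test_matches_best_subset_on_strong_signal(self):
        """Final selection equals exhaustive best-subset choice on a small pool."""
        import itertools
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        n = 120
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(6)})
        y = 3.0 * X["x0"] - 2.0 * X["x3"] + rng.normal(0, 0.1, n)
        model, _ = stepwise_ols(X, y)
        # brute force: smallest subset in which every member is significant
        # and no excluded variable would be
        def fits(sub):
            res = sm.OLS(y, sm.add_constant(X[list(sub)])).fit()
            return res
        best = None
        for k in range(0, 4):
            for sub in itertools.combinations(X.columns, k):
                res = fits(sub)
                if sub and max(res.pvalues[list(sub)]) > 0.10:
                    continue
                aic = res.aic
                if best is None or aic < best[0]:
                    best = (aic, set(sub))
        assert set(model.predictors) == best[1] == {"x0", "x3"}

    def test_constant_column_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"flat": np.ones(40), "x": rng.normal(size=40)})
        y = X["x"].to_numpy() + rng.normal(0, 0.01, 40)
        with pytest.warns(UserWarning, match="constant"):
            model, _ = stepwise_ols(X, y)
        assert model.predictors == ("x",)

    def test_collinear_candidate_skipped(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        X = pd.DataFrame({"x": x, "x_copy": x * 2.0, "z": rng.normal(size=60)})
        y = x + rng.normal(0, 0.01, 60)
        with pytest.warns(UserWarning, match="collinear"):
            model, _ = stepwise_ols(X, y)
        assert "x_copy" not in model.predictors


class TestFourier:
    REF = {"a0": 19.38, "a1": 7.972, "b1": -6.747, "w": 1.314}

    def test_recovers_published_curve_parameters(self):
        x = np.linspace(90, 160, 100)
        c = self.REF
        y = c["a0"] + c["a1"] * np.cos(c["w"] * x) + c["b1"] * np.sin(c["w"] * x)
        m = fit_fourier1(x, y)
        for k, v in c.items():
            assert m.coefficients[k] == pytest.approx(v, abs=1e-6)

    def test_constant_target(self):
        x = np.linspace(0, 10, 30)
        m = fit_fourier1(x, np.full(30, 4.5))
        assert m.coefficients["a0"] == pytest.approx(4.5, abs=1e-8)
        assert abs(m.coefficients["a1"]) < 1e-8 and abs(m.coefficients["b1"]) < 1e-8

    def test_fixed_frequency_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 20, 80)
        y = rng.normal(size=80)
        w = 0.73
        m = fit_fourier1(x, y, w=w)
        design = np.column_stack([np.ones_like(x), np.cos(w * x), np.sin(w * x)])
        ref = np.linalg.solve(design.T @ design, design.T @ y)
        assert m.coefficients["a0"] == pytest.approx(ref[0], abs=1e-10)
        assert m.coefficients["a1"] == pytest.approx(ref[1], abs=1e-10)
        assert m.coefficients["b1"] == pytest.approx(ref[2], abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sse_never_worse_than_intercept_only(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 50, 60)
        y = rng.normal(10, 3, 60)
        m = fit_fourier1(x, y)
        sse = float(np.sum((m.predict(pd.DataFrame({"x": x})) - y) ** 2))
        sse0 = float(np.sum((y - y.mean()) ** 2))
        assert sse <= sse0 + 1e-9

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            fit_fourier1(np.full(10, 3.0), np.arange(10.0))


class TestSurface:
    def test_recovers_published_surface_coefficients(self):
        g1, g2 = np.meshgrid(np.linspace(90, 160, 20), np.linspace(-0.7, 0.6, 20))
        f4 = PUBLISHED_MODELS["F4"]
        y = f4.predict(pd.DataFrame({"R_Mean": g1.ravel(), "R_Skewness": g2.ravel()}))
        m = fit_poly_surface(g1.ravel(), g2.ravel(), y, terms="exact",
                             predictors=("R_Mean", "R_Skewness"))
        assert m.surface_powers == f4.surface_powers
        for got, want in zip(m.surface_coefficients, f4.surface_coefficients):
            assert got == pytest.approx(want, abs=1e-6)

    def test_planar_target_in_full_basis(self):
        rng = np.random.default_rng(6)
        x1, x2 = rng.uniform(-2, 2, (2, 100))
        m = fit_poly_surface(x1, x2, x1.copy(), terms="full")
        coefs = dict(zip(m.surface_powers, m.surface_coefficients))
        assert coefs[(1, 0)] == pytest.approx(1.0, abs=1e-8)
        for p, c in coefs.items():
            if p != (1, 0):
                assert abs(c) < 1e-8

    def test_full_basis_is_ten_terms(self):
        assert len(FULL_POLY33_POWERS) == 10
        assert all(i + j <= 3 for i, j in FULL_POLY33_POWERS)

    def test_nested_r2_ordering(self):
        """Cubic surface fits at least as well as a line in x1, on any data."""
        rng = np.random.default_rng(7)
        x1 = rng.uniform(90, 160, 150)
        x2 = rng.uniform(-0.7, 0.6, 150)
        y = 30 - 0.2 * x1 + 5 * x2 + rng.normal(0, 2, 150)
        surf = fit_poly_surface(x1, x2, y, terms="full")
        line = np.polyval(np.polyfit(x1, y, 1), x1)
        sse_surf = np.sum((surf.predict(pd.DataFrame({"x1": x1, "x2": x2})) - y) ** 2)
        sse_line = np.sum((line - y) ** 2)
        assert sse_surf <= sse_line + 1e-9

    def test_rank_deficiency_names_terms(self):
        x1 = np.linspace(0, 1, 30)
        x2 = np.zeros(30)  # x2 powers all collapse
        with pytest.raises(Exception, match="deficient|zero design"):
            fit_poly_surface(x1, x2, x1, terms="full")


class TestPublishedModels:
    def test_f1_at_forty_day_mean(self):
        assert predict_published("F1", {"R_Mean": 98.64}) == pytest.approx(29.75, abs=0.005)

    def test_intercepts(self):
        assert predict_published(
            "F2", {"R_Mean": 0.0, "Y_Skewness": 0.0, "G_Kurtosis": 0.0}
        ) == pytest.approx(76.134, abs=1e-9)
        assert predict_published(
            "F4", {"R_Mean": 0.0, "R_Skewness": 0.0}) == pytest.approx(0.3344, abs=1e-9)

    def test_f3_uses_radians(self):
        # at R_Median = 0: a0 + a1
        assert predict_published("F3", {"R_Median": 0.0}) == pytest.approx(
            19.38 + 7.972, abs=1e-9)

    def test_missing_feature_named_in_error(self):
        with pytest.raises(InputError, match="Y_Skewness"):
            predict_published("F2", {"R_Mean": 100.0, "G_Kurtosis": 0.0})

    def test_stateless_and_bit_identical(self):
        rec = {"R_Mean": 123.4, "R_Skewness": -0.2}
        assert predict_published("F4", rec) == predict_published("F4", rec)

    def test_unknown_id_rejected(self):
        with pytest.raises(InputError):
            predict_published("F9", {})

    def test_json_round_trip(self):
        for mid, model in PUBLISHED_MODELS.items():
            again = FittedModel.from_json(model.to_json())
            assert again == model


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([10.0, 20.0, 30.0])
        ev = evaluate(y, y, n_params=1)
        assert ev.sse == 0 and ev.rmse == 0 and ev.r2 == 1 and ev.accuracy_mean == 100

    def test_accuracy_footnote_formula(self):
        """(predicted 30, measured 25): accuracy = (1 - 5/25)*100 = 80%."""
        ev = evaluate([30.0, 25.0], [25.0, 25.0], n_params=1)
        assert ev.accuracy_mean == pytest.approx((80.0 + 100.0) / 2)

    def test_adjusted_r2_hand_value(self):
        """R2=0.5, n=12, p=1 -> adjusted R2 = 1 - 0.5*11/10 = 0.45."""
        rng = np.random.default_rng(0)
        y = rng.uniform(10, 30, 12)
        sst = np.sum((y - y.mean()) ** 2)
        # craft predictions with SSE = SST/2: residuals = sqrt(0.5)*(y - mean)
        yhat = y - np.sqrt(0.5) * (y - y.mean())
        ev = evaluate(yhat, y, n_params=1)
        assert ev.r2 == pytest.approx(0.5, abs=1e-9)
        assert ev.adjusted_r2 == pytest.approx(0.45, abs=1e-9)
        assert ev.adjusted_r2 <= ev.r2
        assert ev.rmse == pytest.approx(np.sqrt(ev.sse / ev.n), abs=1e-12)

    def test_outlier_rule_removes_and_reports(self):
        y = np.array([10.0] * 20)
        yhat = y.copy()
        yhat[0] = 30.0  # one wild residual
        ev = evaluate(yhat, y, n_params=1, outlier_k=3.0)
        assert ev.n_removed == 1 and ev.n == 19 and ev.sse == 0

    def test_zero_measured_is_undefined_metric(self):
        with pytest.raises(DegenerateInputError):
            evaluate([1.0, 2.0], [0.0, 2.0], n_params=1)

    def test_sd_scale_switch(self):
        ev_frac = evaluate([30.0, 25.0], [25.0, 25.0], n_params=1)
        ev_pct = evaluate([30.0, 25.0], [25.0, 25.0], n_params=1, sd_scale="percent")
        assert ev_pct.accuracy_sd == pytest.approx(100 * ev_frac.accuracy_sd)
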