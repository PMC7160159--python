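"""Size-model fitting, AIC selection, prediction and residual comparison."""

import itertools
import math

import numpy as np
import pytest

import otodiet as od
from otodiet.size_models import (Form, Predictor, Response, SelectionRationale,
                                 aic_least_squares, fit_curve)

from conftest import make_reference


def _reference_from_curve(model, x, response="FTL", species=None):
    """Noise-free reference rows lying exactly on a model curve."""
    y = od.predict_size(model, x)
    rows = []
    for i, (xi, yi) in enumerate(zip(x, y)):
        kw = {"ftl": yi} if response == "FTL" else {"fw": yi}
        rows.append(make_reference(f"f{i}", species or model.species.value,
                                   ol=xi, sl=0.8 * xi, cl=0.4 * xi, **kw))
    return rows


class TestFitCurve:
    def test_linear_recovery_from_published_line(self):
        m = od.packaged_model("croaker", "OL", "FTL")
        x = np.round(np.linspace(4, 14, 60), 2)
        rows = _reference_from_curve(m, x)
        fit = od.fit_model(rows, "croaker", "OL", "FTL", "linear")
        assert fit.params["b0"] == pytest.approx(-25.51784, abs=1e-6)
        assert fit.params["b1"] == pytest.approx(24.410412, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_logistic_recovery(self):
        m = od.packaged_model("croaker", "OL", "FW")
        x = np.linspace(5, 16, 80)
        params, r2, _ = fit_curve(x, od.predict_size(m, x), Form.LOGISTIC)
        true = np.array([286.38443, 0.6072569, 10.473646])
        assert np.max(np.abs(params - true) / true) < 1e-4

    def test_constant_response_degenerates_cleanly(self):
        x = np.linspace(1, 10, 20)
        params, r2, _ = fit_curve(x, np.full_like(x, 7.0), Form.LINEAR)
        assert params[1] == 0.0 and r2 == 0.0

    def test_fit_model_requires_ten_rows(self):
        m = od.packaged_model("spot", "OL", "FTL")
        rows = _reference_from_curve(m, np.linspace(4, 9, 5))
        with pytest.raises(ValueError):
            od.fit_model(rows, "spot", "OL", "FTL", "logistic")


class TestSelectModel:
    def _table(self, *rows):
        return {p: dict(zip(Form, r)) for p, r in zip(Predictor, rows)}

    def test_linear_preferred_within_two_aic(self):
        sel = od.select_model("croaker", "FTL", self._table(
            (101.5, 100.0, 103.0), (90.0, 95.0, 96.0), (90.0, 95.0, 96.0)))
        assert sel.chosen[Predictor.OL] is Form.LINEAR
        assert sel.rationale[Predictor.OL] is SelectionRationale.LINEAR_WITHIN_2

    def test_majority_form_imposed_on_all_predictors(self):
        # OL and SL resolve to logistic, CL to linear -> all logistic
        sel = od.select_model("spotted_seatrout", "FTL", self._table(
            (110.0, 100.0, 105.0), (110.0, 100.0, 105.0), (90.0, 100.0, 105.0)))
        assert all(f is Form.LOGISTIC for f in sel.chosen.values())
        assert sel.rationale[Predictor.CL] is SelectionRationale.MAJORITY_FORM
        assert sel.majority_applied

    def test_unanimous_lowest_aic(self):
        sel = od.select_model("spot", "FW", self._table(
            (90.0, 95.0, 96.0), (90.0, 95.0, 96.0), (90.0, 95.0, 96.0)))
        assert all(f is Form.LINEAR for f in sel.chosen.values())
        assert not sel.majority_applied

    def test_missing_cell_is_an_error(self):
        table = self._table((90.0, 95.0, 96.0), (90.0, 95.0, 96.0),
                            (90.0, 95.0, 96.0))
        del table[Predictor.CL][Form.GOMPERTZ]
        with pytest.raises(ValueError):
            od.select_model("spot", "FW", table)


class TestPredictSize:
    def test_linear_intercept_at_zero(self):
        m = od.packaged_model("croaker", "OL", "FTL")
        assert od.predict_size(m, 0.0, strict=False) == pytest.approx(-25.51784)

    def test_logistic_asymptote_and_midpoint(self):
        m = od.packaged_model("croaker", "OL", "FW")
        assert od.predict_size(m, 1e6) == pytest.approx(286.38443)
        assert od.predict_size(m, m.params["x0"]) == pytest.approx(286.38443 / 2)

    def test_rejects_nonpositive_predictor(self):
        m = od.packaged_model("croaker", "OL", "FTL")
        with pytest.raises(ValueError):
            od.predict_size(m, -1.0)

    def test_inverse_round_trip(self, packaged_models):
        for m in packaged_models:
            y = od.predict_size(m, 9.0)
            if m.form is not Form.LINEAR and not 0 < y < m.params["A"]:
                continue
            assert od.invert_size_model(m, y) == pytest.approx(9.0, rel=1e-9)


class TestPackagedModels:
    def test_full_catalogue(self, packaged_models):
        assert len(packaged_models) == 24
        keys = {(m.species, m.predictor, m.response) for m in packaged_models}
        assert len(keys) == 24

    def test_published_parameter_spot_checks(self):
        m = od.packaged_model("weakfish", "CL", "FW")
        assert m.form is Form.LOGISTIC and m.params["A"] == pytest.approx(5377.982)
        m2 = od.packaged_model("spot", "OL", "FTL")
        assert m2.form is Form.LOGISTIC and m2.params["A"] == pytest.approx(380.79763)

    def test_sigmoid_shape_invariants(self, packaged_models):
        """Sigmoids rise monotonically to A; y(x0) is A/2 (logistic) or
        A/e (gompertz)."""
        for m in packaged_models:
            if m.form is Form.LINEAR:
                continue
            a, x0 = m.params["A"], m.params["x0"]
            assert m.params["k"] > 0 and a > 0
            mid = od.predict_size(m, x0, strict=False)
            expected = a / 2 if m.form is Form.LOGISTIC else a / math.e
            assert mid == pytest.approx(expected, rel=1e-12)
            grid = np.linspace(0.5, x0 + 5 / m.params["k"], 50)
            y = od.predict_size(m, grid)
            assert np.all(np.diff(y) > 0) and np.all(y < a)


def test_generating_form_wins_aic_under_noise():
    """Refitting noisy draws from a sigmoid keeps its AIC best (or linear
    within 2) in at least 90% of seeded replicates."""
    m = od.packaged_model("croaker", "OL", "FW")
    x = np.linspace(5.5, 15.5, 100)
    y0 = od.predict_size(m, x)
    scale = 0.05 * float(np.ptp(y0))
    wins = 0
    n_rep = 100
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        y = y0 + rng.normal(0, scale, size=x.size)
        aics = {f: fit_curve(x, y, f, seed=rep)[2] for f in Form}
        best = min(aics, key=aics.get)
        ok = best is Form.LOGISTIC or (aics[Form.LINEAR] - aics[best] <= 2)
        wins += ok
    assert wins >= 0.90 * n_rep


class TestMeasuredMinusPredicted:
    def _models_and_rows(self):
        # linear models chosen so all three predictors predict identically
        models = {}
        for pred, slope in (("OL", 10.0), ("SL", 12.5), ("CL", 25.0)):
            models[pred] = od.SizeModel(species="croaker", predictor=pred,
                                        response="FTL", form="linear",
                                        params={"b0": 0.0, "b1": slope})
        rows = [make_reference(f"f{i}", "croaker", ol=x, sl=0.8 * x,
                               cl=0.4 * x, ftl=10.0 * x + d)
                for i, (x, d) in enumerate([(5, 3), (7, -2), (9, 1),
                                            (11, 0), (13, -4)])]
        return models, rows

    def test_identical_predictions_give_null_result(self):
        models, rows = self._models_and_rows()
        table, test = od.measured_minus_predicted(models, rows, b=500, seed=0)
        for diff in test.pairwise_diff.values():
            assert diff == pytest.approx(0.0, abs=1e-9)
        assert test.global_p > 0.9

    def test_mean_differences_match_hand_computation(self):
        models, rows = self._models_and_rows()
        # perturb the CL model so residuals differ by a known constant
        models["CL"] = od.SizeModel(species="croaker", predictor="CL",
                                    response="FTL", form="linear",
                                    params={"b0": -6.0, "b1": 25.0})
        table, test = od.measured_minus_predicted(models, rows, b=500, seed=0)
        # measured - predicted: CL residuals exceed OL residuals by exactly 6
        assert test.pairwise_diff[("OL", "CL")] == pytest.approx(-6.0)
        assert test.means["CL"] - test.means["OL"] == pytest.approx(6.0)

    def test_permutation_p_matches_exact_enumeration(self):
        """On 4 fish the 6^4 within-fish label arrangements can be fully
        enumerated; the Monte-Carlo p must agree within sampling error."""
        rng = np.random.default_rng(7)
        mat = rng.normal(0, 1, size=(4, 3)) + np.array([0.0, 0.4, 0.8])
        conditions = ["OL", "SL", "CL"]
        from otodiet._stats import within_unit_permutation

        mc = within_unit_permutation(mat, conditions, b=20000, seed=1)

        # independent enumeration
        pairs = [(0, 1), (0, 2), (1, 2)]
        obs = mat.mean(axis=0)
        obs_global = max(abs(obs[i] - obs[j]) for i, j in pairs)
        ge = total = 0
        for assign in itertools.product(
                itertools.permutations(range(3)), repeat=4):
            perm = np.stack([mat[i, list(assign[i])] for i in range(4)])
            mean = perm.mean(axis=0)
            stat = max(abs(mean[i] - mean[j]) for i, j in pairs)
            ge += stat >= obs_global - 1e-12
            total += 1
        exact = ge / total
        assert mc.global_p == pytest.approx(exact, abs=3 * math.sqrt(
            exact * (1 - exact) / 20000) + 1e-4)

    def test_warns_on_tiny_permutation_count(self):
        models, rows = self._models_and_rows()
        with pytest.warns(UserWarning):
            od.measured_minus_predicted(models, rows, b=50, seed=0)


def test_aic_formula_matches_definition():
    rss, n, p = 123.4, 50, 3
    assert aic_least_squares(rss, n, p) == pytest.approx(
        n * math.log(rss / n) + 2 * (p + 1))
    assert aic_least_squares(rss, n, p, corrected=True) > aic_least_squares(rss, n, p)
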