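"""Dose-response-level evaluation, bootstrap SD and Wilcoxon comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ec50ml.data import DoseResponseSet, Measurement
from ec50ml.evaluate import (
    EvaluationReport,
    bootstrap_rmse_sd,
    evaluate_on_dose_response,
    wilcoxon_compare,
)
from ec50ml.hill import HillParameters, hill_response
from ec50ml.models import ModelSpec, TrainedModel

from conftest import make_set


class _StubEstimator:
    """Predicts a fixed LogEC50 per row (keyed by the first feature value)."""

    def __init__(self, mapping):
        self.mapping = mapping

    def predict(self, X):
        return np.array([self.mapping[x0] for x0 in np.asarray(X)[:, 0]])


def stub_model(mapping):
    return TrainedModel(
        spec=ModelSpec("RF", {}),
        estimator=_StubEstimator(mapping),
        n_training_molecules=len(mapping),
        n_features=1,
    )


def report_from_errors(errors):
    """Report with the given residuals; observations are shared zeros so two
    such reports cover identical measurements (as paired comparisons require)."""
    err = np.asarray(errors, dtype=float)
    return EvaluationReport(
        pairs=pd.DataFrame(
            {
                "molecule_id": [f"m{i}" for i in range(len(err))],
                "log_concentration": np.arange(len(err), dtype=float),
                "observed": np.zeros(len(err)),
                "predicted": -err,
            }
        )
    )


class TestEvaluateOnDoseResponse:
    def test_exact_model_on_noiseless_slope1_data_has_zero_rmse(self):
        sets = [make_set(f"m{i}", t, slope=1.0) for i, t in enumerate([-1.0, 0.0, 0.7])]
        feats = {s.molecule_id: np.array([float(i)]) for i, s in enumerate(sets)}
        model = stub_model({0.0: -1.0, 1.0: 0.0, 2.0: 0.7})
        rep = evaluate_on_dose_response(model, sets, feats)
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_three_measurement_rmse(self):
        # predicted LogEC50 = 0, slope 1: responses at X=-1,0,1 are
        # 100/11, 50, 100/1.1; observed 0, 50, 100
        s = DoseResponseSet(
            "m", [Measurement(0.1, 0.0), Measurement(1.0, 50.0), Measurement(10.0, 100.0)]
        )
        model = stub_model({0.0: 0.0})
        rep = evaluate_on_dose_response(model, [s], {"m": np.zeros(1)})
        r1 = 100.0 / 11.0
        r3 = 100.0 - 100.0 / 1.1
        expected = np.sqrt((r1**2 + 0.0 + r3**2) / 3.0)
        assert rep.rmse == pytest.approx(expected, rel=1e-12)

    def test_constant_50_observed_with_midpoint_predictions(self):
        # predicting LogEC50 == X for a measurement makes the predicted
        # response exactly 50
        sets = [
            DoseResponseSet(f"m{i}", [Measurement(10.0**x, 50.0)])
            for i, x in enumerate([-1.0, 0.5, 2.0])
        ]
        model = stub_model({0.0: -1.0, 1.0: 0.5, 2.0: 2.0})
        feats = {f"m{i}": np.array([float(i)]) for i in range(3)}
        rep = evaluate_on_dose_response(model, sets, feats)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)

    def test_observed_responses_are_clipped(self):
        s = DoseResponseSet("m", [Measurement(1.0, 150.0)])
        model = stub_model({0.0: 0.0})
        rep = evaluate_on_dose_response(model, [s], {"m": np.zeros(1)})
        assert rep.pairs["observed"].item() == 100.0

    def test_missing_features_named(self):
        s = make_set("mA", 0.0)
        with pytest.raises(KeyError, match="mA"):
            evaluate_on_dose_response(stub_model({}), [s], {"other": np.zeros(1)})

    def test_rmse_recomputable_from_stored_pairs(self):
        sets = [make_set(f"m{i}", 0.2, sigma=20.0, seed=i) for i in range(5)]
        feats = {s.molecule_id: np.array([0.0]) for s in sets}
        model = stub_model({0.0: 0.5})
        rep = evaluate_on_dose_response(model, sets, feats)
        by_hand = np.sqrt(
            np.mean((rep.pairs["observed"] - rep.pairs["predicted"]) ** 2)
        )
        assert rep.rmse == pytest.approx(by_hand, abs=1e-12)

    def test_inhibition_direction_uses_decreasing_curve(self):
        s = make_set("m", 0.0, slope=1.0, direction="inhibition")
        model = stub_model({0.0: 0.0})
        rep = evaluate_on_dose_response(model, [s], {"m": np.zeros(1)})
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)


class TestBootstrapSD:
    def test_identical_residual_magnitudes_give_zero_sd(self):
        rep = report_from_errors([5.0, -5.0, 5.0, -5.0])
        assert bootstrap_rmse_sd(rep, n_boot=100, seed=0) == 0.0

    def test_deterministic_given_seed(self):
        rep = report_from_errors([1.0, 3.0, -2.0, 0.5])
        a = bootstrap_rmse_sd(rep, n_boot=500, seed=42)
        b = bootstrap_rmse_sd(rep, n_boot=500, seed=42)
        assert a == b

    def test_two_point_enumeration_oracle(self):
        # residuals {0, r}: resamples are (0,0), (0,r), (r,0), (r,r) with
        # equal probability -> RMSEs {0, r/sqrt(2), r/sqrt(2), r}
        r = 2.0
        rep = report_from_errors([0.0, r])
        outcomes = [
            np.sqrt(np.mean(np.array(c) ** 2))
            for c in itertools.product([0.0, r], repeat=2)
        ]
        expected_sd = np.std(outcomes)
        got = bootstrap_rmse_sd(rep, n_boot=200_000, seed=1)
        assert got == pytest.approx(expected_sd, rel=0.01)


class TestWilcoxonCompare:
    def test_identical_reports_not_significant(self):
        rep = report_from_errors([1.0, 2.0, 3.0])
        res = wilcoxon_compare(rep, rep)
        assert res.p_value == 1.0
        assert not res.significant
        assert res.direction == "tied"

    def test_uniformly_better_model_significant(self):
        rng = np.random.default_rng(0)
        errs = rng.uniform(1, 2, 30)
        rep_a = report_from_errors(errs)
        rep_b = report_from_errors(errs + rng.uniform(0.5, 1.0, 30))
        res = wilcoxon_compare(rep_a, rep_b)
        assert res.p_value < 0.001
        assert res.significant
        assert res.direction == "a_better"

    def test_swapping_reports_flips_direction(self):
        rng = np.random.default_rng(1)
        rep_a = report_from_errors(rng.uniform(0, 1, 20))
        rep_b = report_from_errors(rng.uniform(1, 2, 20))
        fwd = wilcoxon_compare(rep_a, rep_b)
        rev = wilcoxon_compare(rep_b, rep_a)
        assert fwd.direction == "a_better" and rev.direction == "b_better"
        assert not rev.significant

    def test_exact_null_enumeration_small_n(self):
        # brute-force one-sided signed-rank p-value over all sign assignments
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, 12)
        b = rng.uniform(0, 1, 12)
        res = wilcoxon_compare(report_from_errors(a), report_from_errors(b))
        assert res.method == "exact"

        d = a**2 - b**2  # the comparison is on per-measurement squared errors
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_plus = ranks[d > 0].sum()
        count = 0
        for signs in itertools.product([0, 1], repeat=12):
            if np.sum(ranks * np.array(signs)) <= w_plus:
                count += 1
        assert res.p_value == pytest.approx(count / 2**12, abs=1e-12)

    def test_mismatched_measurements_rejected(self):
        rep_a = report_from_errors([1.0, 2.0])
        rep_b = report_from_errors([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="identical"):
            wilcoxon_compare(rep_a, rep_b)


def test_report_requires_columns_and_rows():
    with pytest.raises(ValueError, match="missing columns"):
        EvaluationReport(pairs=pd.DataFrame({"observed": [1.0]}))
    with pytest.raises(ValueError, match="empty"):
        report_from_errors([])
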