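"""Published equation, online estimation loop and baselines."""

import numpy as np
import pytest

from paco2est import (AveragedSample, BloodGasRecord, CandidateDescriptor,
                      FittedModel, OnlineConfig, centred_average,
                      etco2_baseline, offset_baseline, predict,
                      published_model, run_online)
from paco2est.estimator import METHOD_ETCO2, METHOD_RLR

from conftest import WORKED_VALUE, constant_trial


class TestPublishedModel:
    def test_term_count_and_logvte_coefficient(self):
        model = published_model()
        assert len(model.coefficients) == 5
        assert model.intercept == 31.8164
        assert model.coefficients[CandidateDescriptor("Vte", "log")] == -5.2879

    def test_worked_covariate_vector(self, worked_sample):
        assert predict(published_model(), worked_sample) == pytest.approx(
            WORKED_VALUE, abs=1e-9)
        assert predict(published_model(), worked_sample) == pytest.approx(
            45.689, abs=1e-3)

    def test_intercept_only_when_terms_vanish(self):
        s = AveragedSample("t", 0.0, {"etCO2": 0.0, "O2diff": 0.0,
                                      "%Spont": 0.0, "Pmean": 0.0,
                                      "Vte": 1.0})
        assert predict(published_model(), s) == pytest.approx(31.8164)

    def test_missing_covariate_signals(self, worked_sample):
        del worked_sample.values["SpO2"]
        assert predict(published_model(), worked_sample) is None


class TestRunOnline:
    def test_constant_covariates_give_constant_stream(self, worked_sample):
        trial = constant_trial(300.0)
        records = run_online(trial, published_model())
        expected = predict(published_model(),
                           AveragedSample("c", 0.0,
                                          {k: trial.channels[k][1][0]
                                           for k in trial.channels}))
        values = [r.value for r in records if not r.withheld]
        # first ticks lack a full window only if coverage drops; 20-s
        # windows are filled from t=20 onwards
        assert len(values) >= 70
        assert np.allclose(values, expected)
        assert all(r.method == METHOD_RLR for r in records)

    def test_low_vte_withholding_follows_window_arithmetic(self):
        trial = constant_trial(600.0)
        t, v = trial.channels["Vte"]
        v = v.copy()
        v[(t >= 100.0) & (t < 160.0)] = 10.0   # 60-s dip to 10 mL
        trial.channels["Vte"] = (t, v)
        cfg = OnlineConfig()
        records = run_online(trial, published_model(), cfg)
        for r in records:
            mask = (t > r.time - cfg.window) & (t <= r.time)
            expected_low = v[mask].mean() < cfg.vte_min
            assert (r.withheld_reason == "low_vte") == expected_low

    def test_causality_future_perturbation_invariance(self):
        trial = constant_trial(300.0)
        records = run_online(trial, published_model())
        t, v = trial.channels["etCO2"]
        v2 = v.copy()
        v2[t > 200.0] = 60.0
        trial.channels["etCO2"] = (t, v2)
        perturbed = run_online(trial, published_model())
        for a, b in zip(records, perturbed):
            if a.time <= 200.0:
                assert a == b

    def test_missing_channel_withholds(self):
        trial = constant_trial(100.0)
        del trial.channels["SpO2"]
        records = run_online(trial, published_model())
        assert all(r.withheld_reason == "missing_parameters" for r in records)

    def test_out_of_validated_range_flagged(self):
        trial = constant_trial(100.0, overrides={"etCO2": 69.0, "Vte": 13.0,
                                                 "Pmean": 17.0})
        records = run_online(trial, published_model())
        emitted = [r for r in records if not r.withheld]
        assert emitted and all(r.value > 75.0 and r.out_of_validated_range
                               for r in emitted)


class TestEtco2Baseline:
    def test_constant_etco2(self):
        records = etco2_baseline(constant_trial(200.0))
        values = [r.value for r in records if not r.withheld]
        assert np.allclose(values, 44.0)
        assert all(r.method == METHOD_ETCO2 for r in records)

    def test_equals_online_with_identity_model(self):
        trial = constant_trial(200.0)
        identity = FittedModel(intercept=0.0, coefficients={
            CandidateDescriptor("etCO2", "identity"): 1.0}, scale=1.0)
        via_model = run_online(trial, identity)
        baseline = etco2_baseline(trial)
        assert [r.value for r in via_model] == [r.value for r in baseline]


def make_bga(minute: float, paco2: float) -> BloodGasRecord:
    return BloodGasRecord("const", minute, paco2, 7.3, 50.0)


class TestOffsetBaseline:
    def test_offset_anchors_to_blood_gas(self):
        trial = constant_trial(600.0)     # etCO2 constant 44
        records = offset_baseline(trial, [make_bga(300.0, 50.0)])
        for r in records:
            if r.withheld:
                continue
            if r.time < 360.0:            # result available at minute end
                assert r.value == pytest.approx(44.0)
            else:
                assert r.value == pytest.approx(50.0)

    def test_estimates_inside_documented_minute_use_previous_offset(self):
        trial = constant_trial(600.0)
        records = offset_baseline(trial, [make_bga(300.0, 50.0)])
        inside = [r for r in records if 300.0 <= r.time < 360.0]
        assert inside and all(r.value == pytest.approx(44.0) for r in inside)

    def test_two_blood_gases_piecewise_constant(self):
        trial = constant_trial(900.0)
        records = offset_baseline(trial, [make_bga(300.0, 50.0),
                                          make_bga(600.0, 40.0)])
        values = {r.time: r.value for r in records if not r.withheld}
        assert values[300.0] == pytest.approx(44.0)
        assert values[400.0] == pytest.approx(50.0)
        assert values[660.0] == pytest.approx(40.0)


class TestZeroNoiseConsistency:
    def test_model_exact_and_etco2_gap_on_constant_trial(self, worked_sample):
        trial = constant_trial(600.0)
        constants = {k: trial.channels[k][1][0] for k in trial.channels}
        sample = AveragedSample("const", 0.0, constants)
        truth = predict(published_model(), sample)
        bga = make_bga(300.0, truth)
        rlr = run_online(trial, published_model())
        etco2 = etco2_baseline(trial)
        rlr_at = [r for r in rlr if 300.0 <= r.time < 360.0][-1]
        etco2_at = [r for r in etco2 if 300.0 <= r.time < 360.0][-1]
        assert rlr_at.value == pytest.approx(truth, abs=1e-9)
        assert abs(etco2_at.value - truth) == pytest.approx(
            abs(constants["etCO2"] - truth), abs=1e-9)

    def test_design_phase_error_zero_on_population(self, small_population):
        from paco2est.agreement import design_phase_pairs

        for trial, bgas in small_population:
            samples = [centred_average(trial, b) for b in bgas]
            for s, b in zip(samples, bgas):
                s.paco2 = b.paco2
            pairs = design_phase_pairs(samples, published_model())
            diffs = np.array([e - r for e, r in pairs])
            assert np.allclose(diffs, 0.0, atol=1e-9)
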