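import numpy as np
import pytest

import synergait as sg
from synergait.errors import DegenerateSynergyError, InvalidParameterError
from synergait.impairment import (
    METRIC_NAMES,
    ImpairmentReport,
    TemplateReconstruction,
    activation_duration,
    activation_metric,
    classify_impairment,
    max_circular_xcorr,
    normative_thresholds,
    similarity,
    t_lag_metric,
)

# published pre-treatment metric values for the two reference stroke
# patients, with the cohort thresholds (similarity / correlation / t_lag /
# activation per synergy WA, PO, FC, LD)
PATIENT_S1 = {
    "WA": {"similarity": 0.67, "correlation": 0.95, "t_lag": 0.94, "activation": 0.85},
    "PO": {"similarity": 0.97, "correlation": 0.89, "t_lag": 0.96, "activation": 0.71},
    "FC": {"similarity": 0.95, "correlation": 0.77, "t_lag": 0.61, "activation": 0.65},
    "LD": {"similarity": 0.91, "correlation": 0.92, "t_lag": 0.99, "activation": 0.77},
}
PATIENT_S2 = {
    "WA": {"similarity": 0.90, "correlation": 0.96, "t_lag": 0.96, "activation": 0.99},
    "PO": {"similarity": 0.93, "correlation": 0.93, "t_lag": 0.98, "activation": 0.83},
    "FC": {"similarity": 0.80, "correlation": 0.79, "t_lag": 0.99, "activation": 0.97},
    "LD": {"similarity": 0.98, "correlation": 0.85, "t_lag": 0.99, "activation": 0.99},
}
THRESHOLDS = {"similarity": 0.79, "correlation": 0.90, "t_lag": 0.96, "activation": 0.82}


class TestSimilarity:
    def test_identical_vectors(self, rng):
        v = rng.uniform(0.1, 1, 8)
        assert similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        assert similarity([1, 0, 0], [0, 2, 3]) == pytest.approx(0.0)

    def test_scale_invariant(self, rng):
        v = rng.uniform(0.1, 1, 5)
        assert similarity(v, 2 * v) == pytest.approx(1.0)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateSynergyError):
            similarity([0, 0], [1, 1])


class TestTimingMetrics:
    def test_shift_construction(self, template):
        h = template.H[2]
        r, lag = max_circular_xcorr(h, np.roll(h, 10))
        assert r == pytest.approx(1.0) and lag == 10

    @pytest.mark.parametrize("lag,expected", [(0, 1.0), (-39, 0.61), (50, 0.5), (13, 0.87)])
    def test_t_lag_values(self, lag, expected):
        assert t_lag_metric(lag) == pytest.approx(expected)

    def test_t_lag_out_of_range_raises(self):
        with pytest.raises(InvalidParameterError):
            t_lag_metric(51)

    def test_zero_variance_profile_raises(self):
        with pytest.raises(DegenerateSynergyError):
            max_circular_xcorr(np.ones(100), np.arange(100.0))


class TestActivationDuration:
    def test_square_pulse(self):
        h = np.zeros(100)
        h[10:40] = 1.0  # threshold 0.2: exactly the 30 ones exceed it
        assert activation_duration(h) == 30

    def test_flat_profile_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert activation_duration(np.full(100, 0.7)) == 0.0

    def test_raised_cosine_matches_brute_force_scan(self, template):
        for h in template.H:
            thr = h.min() + 0.2 * (h.max() - h.min())
            brute = sum(1 for v in h if v > thr)
            assert activation_duration(h) == brute

    @pytest.mark.parametrize("dp,dh,expected", [(50, 50, 1.0), (50, 30, 0.8), (100, 0, 0.0)])
    def test_activation_metric(self, dp, dh, expected):
        assert activation_metric(dp, dh) == pytest.approx(expected)

    def test_activation_metric_range_check(self):
        with pytest.raises(InvalidParameterError):
            activation_metric(120, 50)


class TestThresholds:
    def test_equal_values_threshold_is_value(self):
        thr = normative_thresholds({m: np.full(10, 0.9) for m in METRIC_NAMES})
        assert all(v == pytest.approx(0.9) for v in thr.values())

    def test_two_value_example(self):
        thr = normative_thresholds({
            "similarity": np.array([0.9, 1.0]),
            "correlation": np.array([0.9, 1.0]),
            "t_lag": np.array([0.9, 1.0]),
            "activation": np.array([0.9, 1.0]),
        })
        assert thr["similarity"] == pytest.approx(0.95 - 2 * np.std([0.9, 1.0], ddof=1))
        assert thr["similarity"] == pytest.approx(0.8086, abs=5e-4)

    def test_matches_independent_recompute(self, rng):
        values = {m: rng.uniform(0.5, 1.0, size=52) for m in METRIC_NAMES}
        thr = normative_thresholds(values)
        for m in METRIC_NAMES:
            xs = list(values[m])
            mean = sum(xs) / len(xs)
            sd = (sum((x - mean) ** 2 for x in xs) / (len(xs) - 1)) ** 0.5
            assert thr[m] == pytest.approx(mean - 2 * sd, abs=1e-12)

    def test_single_value_raises(self):
        with pytest.raises(InvalidParameterError):
            normative_thresholds({"similarity": np.array([1.0])})


class TestClassification:
    def test_reference_patient_s1_all_four_impaired(self):
        flags = classify_impairment(PATIENT_S1, THRESHOLDS)
        assert flags == {"WA": True, "PO": True, "FC": True, "LD": True}

    def test_reference_patient_s2_exactly_fc_and_ld(self):
        flags = classify_impairment(PATIENT_S2, THRESHOLDS)
        assert flags == {"WA": False, "PO": False, "FC": True, "LD": True}

    def test_boundary_equality_is_not_impaired(self):
        # S2's WA t_lag equals the 0.96 threshold exactly: strict < passes it
        assert PATIENT_S2["WA"]["t_lag"] == THRESHOLDS["t_lag"]
        flags = classify_impairment({"WA": PATIENT_S2["WA"]}, THRESHOLDS)
        assert flags["WA"] is False

    def test_perfect_metrics_never_impaired(self):
        perfect = {lab: {m: 1.0 for m in METRIC_NAMES} for lab in ("WA", "PO")}
        assert classify_impairment(perfect, THRESHOLDS) == {"WA": False, "PO": False}

    def test_missing_metric_raises(self):
        with pytest.raises(InvalidParameterError):
            classify_impairment({"WA": {"similarity": 1.0}}, THRESHOLDS)


class TestReconstructionPipeline:
    def test_healthy_like_patient_not_impaired(self, template, built):
        tmpl, thresholds, _ = built
        patient = sg.make_stroke_patient(template, config=sg.SynthConfig(seed=77))
        report = sg.assess_patient(patient, tmpl, thresholds, seed=2, max_iter=500)
        assert report.impaired_labels == []
        assert report.vaf_fixed_w > 0.9

    def test_merged_weights_trip_similarity(self, template, built):
        tmpl, thresholds, _ = built
        patient = sg.make_stroke_patient(
            template, merge_pairs=[("WA", "LD")], config=sg.SynthConfig(seed=78)
        )
        report = sg.assess_patient(patient, tmpl, thresholds, seed=2, max_iter=500)
        assert set(report.impaired_labels) & {"WA", "LD"}
        assert (
            report.metrics["WA"]["similarity"] < thresholds["similarity"]
            or report.metrics["LD"]["similarity"] < thresholds["similarity"]
        )

    def test_shifted_po_trips_timing(self, template, built):
        tmpl, thresholds, _ = built
        patient = sg.make_stroke_patient(
            template, lag_shift={"PO": -15}, config=sg.SynthConfig(seed=79)
        )
        report = sg.assess_patient(patient, tmpl, thresholds, seed=2, max_iter=500)
        assert report.metrics["PO"]["lag"] <= -10
        assert "PO" in report.impaired_labels

    def test_metric_values_within_bounds(self, template, built, rng):
        tmpl, _, _ = built
        patient = sg.make_stroke_patient(
            template, duration_scale={"FC": 1.5}, config=sg.SynthConfig(seed=80)
        )
        recon = TemplateReconstruction(patient, tmpl).fit(seed=4, max_iter=400)
        for m in recon.metrics().values():
            assert 0 <= m["similarity"] <= 1
            assert -1 <= m["correlation"] <= 1
            assert 0.5 <= m["t_lag"] <= 1
            assert 0 <= m["activation"] <= 1

    def test_report_json_roundtrip_and_table(self, template, built):
        tmpl, thresholds, _ = built
        patient = sg.make_stroke_patient(template, config=sg.SynthConfig(seed=81))
        report = sg.assess_patient(patient, tmpl, thresholds, seed=1, max_iter=300)
        back = ImpairmentReport.from_json(report.to_json())
        assert back.impaired == report.impaired
        df = report.to_frame()
        assert list(df.columns) == ["WA", "PO", "FC", "LD", "threshold"]
        assert list(df.index) == list(METRIC_NAMES)
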