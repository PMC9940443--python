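"""ST-segment geometry, the slope formula, and the derived dataset features
(oldpeak regression, restecg classification, thalach)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiorisk.ecg import ECGSignal, RPeakSet, detect_r_peaks
from cardiorisk.errors import ConfigurationError, InvalidInputError
from cardiorisk.st_features import (
    STSegment,
    categorize_slope,
    compute_st_slope,
    compute_thalach,
    extract_st_segments,
    fit_oldpeak_regressor,
    fit_restecg_classifier,
    summarize_slopes,
)

FS = 350.0


def _signal(n=4000):
    return ECGSignal(np.arange(n, dtype=float) / n, FS)


class TestSegmentExtraction:
    def test_default_window_is_20_plus_42_samples_at_350hz(self):
        raw = _signal()
        peaks = RPeakSet(np.array([100, 800, 1500]), FS)
        segments = extract_st_segments(raw, peaks)
        assert len(segments) == 3
        for seg, r in zip(segments, peaks.indices):
            assert seg.start_index == r + 20
            assert seg.n == 42

    def test_boundary_peak_is_skipped(self):
        raw = _signal(1000)
        peaks = RPeakSet(np.array([100, 970]), FS)  # 30 samples of tail
        segments = extract_st_segments(raw, peaks)
        assert len(segments) == 1
        assert segments[0].start_index == 120

    def test_empty_peak_set_gives_empty_list(self):
        assert extract_st_segments(_signal(), RPeakSet(np.array([]), FS)) == []

    def test_segment_count_never_exceeds_peak_count(self):
        raw = _signal(500)
        peaks = RPeakSet(np.array([10, 200, 430, 460]), FS)
        segments = extract_st_segments(raw, peaks)
        assert len(segments) <= len(peaks)

    def test_bad_window_parameters_raise(self):
        raw = _signal()
        peaks = RPeakSet(np.array([100]), FS)
        with pytest.raises(InvalidInputError):
            extract_st_segments(raw, peaks, offset_ms=0)
        with pytest.raises(InvalidInputError):
            extract_st_segments(raw, peaks, length_ms=-5)


class TestSlope:
    def test_flat_segment_has_zero_slope(self):
        seg = STSegment(0, np.full(42, 0.3))
        assert compute_st_slope(seg) == 0.0

    def test_printed_arithmetic_example(self):
        samples = np.zeros(42)
        samples[-1] = 0.42
        assert compute_st_slope(STSegment(0, samples)) == pytest.approx(0.01)

    @pytest.mark.parametrize("k,n", [(0.5, 42), (-2.0, 10), (0.013, 7)])
    def test_linear_segment_recovers_k_times_n_minus_1_over_n(self, k, n):
        seg = STSegment(0, k * np.arange(n, dtype=float))
        assert compute_st_slope(seg) == pytest.approx(k * (n - 1) / n)

    def test_too_short_segment_raises(self):
        with pytest.raises(InvalidInputError):
            compute_st_slope(STSegment(0, np.array([1.0])))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(offset=st.floats(-10, 10, allow_nan=False), seed=st.integers(0, 99))
    def test_slope_invariant_to_constant_offset(self, offset, seed):
        rng = np.random.default_rng(seed)
        samples = rng.normal(size=42)
        base = compute_st_slope(STSegment(0, samples))
        shifted = compute_st_slope(STSegment(0, samples + offset))
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_summary_mean_and_median(self):
        slopes = [0.01, 0.02, 0.06]
        assert summarize_slopes(slopes).summary == pytest.approx(0.03)
        assert summarize_slopes(slopes, "median").summary == pytest.approx(0.02)
        with pytest.raises(InvalidInputError):
            summarize_slopes([])

    def test_injected_ramp_recovered_through_pipeline(self, long_ecg):
        """Mean tan-theta within 15 % of the injected slope at zero noise."""
        peaks = detect_r_peaks(long_ecg.signal)
        segments = extract_st_segments(long_ecg.signal, peaks)
        result = summarize_slopes([compute_st_slope(s) for s in segments])
        target = long_ecg.params["st_slope"]
        assert abs(result.summary - target) / target < 0.15

    def test_categorize_slope_bands(self):
        assert categorize_slope(0.01) == 1    # upsloping
        assert categorize_slope(0.0) == 2     # flat
        assert categorize_slope(-0.001) == 2
        assert categorize_slope(-0.01) == 3   # downsloping
        with pytest.raises(InvalidInputError):
            categorize_slope(float("nan"))


class TestThalach:
    def test_max_of_20_readings(self):
        assert compute_thalach(list(range(60, 80))) == 79
        assert compute_thalach([72] * 20) == 72

    def test_wrong_count_raises(self):
        with pytest.raises(InvalidInputError):
            compute_thalach(list(range(60, 79)))

    def test_out_of_range_strict_and_clamped(self):
        readings = [72] * 19 + [300]
        with pytest.raises(InvalidInputError):
            compute_thalach(readings)
        with pytest.warns(UserWarning):
            assert compute_thalach(readings, strict=False) == 250.0


class TestFeatureCompletion:
    @staticmethod
    def _oldpeak_table(n, seed):
        rng = np.random.default_rng(seed)
        f1 = rng.uniform(0, 8, n)
        noise_col = rng.normal(size=n)
        oldpeak = 0.5 * f1 + rng.normal(0, 0.05, n)
        return pd.DataFrame({"f1": f1, "distractor": noise_col,
                             "oldpeak": np.clip(oldpeak, 0, 6.2)})

    def test_oldpeak_parameter_recovery(self):
        train = self._oldpeak_table(400, 0)
        test = self._oldpeak_table(200, 1)
        model = fit_oldpeak_regressor(train, correlation_threshold=0.2)
        assert "f1" in model.features
        assert "distractor" not in model.features
        pred = model.predict(test)
        ss_res = np.sum((test["oldpeak"] - pred) ** 2)
        ss_tot = np.sum((test["oldpeak"] - test["oldpeak"].mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.9

    def test_oldpeak_predictions_within_hard_range(self):
        train = self._oldpeak_table(300, 2)
        model = fit_oldpeak_regressor(train)
        wild = pd.DataFrame({"f1": [-100.0, 0.0, 1000.0]})
        pred = model.predict(wild)
        assert np.all(pred >= 0.0) and np.all(pred <= 6.2)

    def test_oldpeak_missing_predictor_raises(self):
        model = fit_oldpeak_regressor(self._oldpeak_table(200, 3))
        with pytest.raises(InvalidInputError):
            model.predict(pd.DataFrame({"distractor": [0.1]}))

    def test_no_feature_passing_threshold_reports_correlations(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"f1": rng.normal(size=200),
                              "f2": rng.normal(size=200),
                              "oldpeak": rng.uniform(0, 6.2, 200)})
        with pytest.raises(ConfigurationError, match="correlations"):
            fit_oldpeak_regressor(table, correlation_threshold=0.5)

    @staticmethod
    def _restecg_table(n, seed):
        rng = np.random.default_rng(seed)
        restecg = rng.integers(0, 3, n)
        f1 = restecg * 2.0 + rng.normal(0, 0.2, n)
        f2 = -restecg + rng.normal(0, 0.2, n)
        return pd.DataFrame({"f1": f1, "f2": f2, "restecg": restecg})

    def test_restecg_cluster_recovery(self):
        train = self._restecg_table(300, 0)
        test = self._restecg_table(150, 1)
        model = fit_restecg_classifier(train)
        pred = model.predict(test)
        assert set(np.unique(pred)) <= {0, 1, 2}
        assert np.mean(pred == test["restecg"].to_numpy()) >= 0.9

    def test_restecg_single_class_raises(self):
        table = pd.DataFrame({"f1": np.arange(30.0), "restecg": np.zeros(30)})
        with pytest.raises(InvalidInputError):
            fit_restecg_classifier(table)

    def test_restecg_out_of_domain_labels_raise(self):
        table = pd.DataFrame({"f1": np.arange(30.0),
                              "restecg": np.arange(30) % 4})
        with pytest.raises(InvalidInputError):
            fit_restecg_classifier(table)
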