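"""Tests of gait/statistical features, normalization and aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from trunkrun import GaitFeatureExtractor, SignalParams, simulate_run_signal
from trunkrun.features import (
    FeatureDef,
    FeatureTable,
    aggregate_to_subject,
    attach_questionnaire,
    detect_steps,
    impact,
    regularity,
    remove_constant_features,
    rms_ratio,
    sample_entropy,
    statistical_bank,
    step_time,
    subject_minmax_normalize,
)
from trunkrun.preprocessing import CohortRecord, RunningStage, estimate_tilt, tilt_correct

FS = 100.0


def corrected_vt(params):
    trace = simulate_run_signal(params)
    full = RunningStage(0, len(trace))
    vt, _, _ = tilt_correct(trace, full, estimate_tilt(trace, full))
    return vt


class TestStepDetection:
    def test_noiseless_window_counts_steps(self, clean_run):
        vt = clean_run.vt[: int(10 * FS)]
        events = detect_steps(vt, FS)
        assert abs(len(events) - 28) <= 1

    def test_noisy_window_count_close_to_cadence_times_duration(self):
        p = SignalParams(duration_s=10.0, fs=FS, cadence_hz=2.8, seed=12,
                         tilt_ap_deg=0.0, drift_deg=0.0)
        vt = corrected_vt(p)
        events = detect_steps(vt, FS)
        assert abs(len(events) - 2.8 * 10) <= 2

    def test_flat_signal_unusable(self):
        events = detect_steps(np.zeros(1000), FS)
        assert len(events) < 4


class TestStepTime:
    def test_constant_interval(self):
        events = np.arange(0, 3570 * 5, 357)
        assert step_time(events, 1000.0) == pytest.approx(0.357)

    def test_two_events_single_interval(self):
        assert step_time(np.array([100, 400]), 1000.0) == pytest.approx(0.3)

    def test_fewer_than_two_events_missing(self):
        assert math.isnan(step_time(np.array([5]), 1000.0))

    def test_synthetic_window_recovers_cadence(self):
        p = SignalParams(duration_s=20.0, fs=FS, cadence_hz=3.0, seed=13,
                         tilt_ap_deg=0.0, drift_deg=0.0)
        vt = corrected_vt(p)
        events = detect_steps(vt, FS)
        assert step_time(events, FS) == pytest.approx(1 / 3.0, rel=0.05)


class TestRmsRatio:
    def test_single_axis_signal(self):
        vt = np.sin(np.linspace(0, 20 * np.pi, 1000))
        zeros = np.zeros(1000)
        res = np.sqrt(vt**2 + zeros**2 + zeros**2)
        assert rms_ratio(vt, res) == pytest.approx(1.0)
        assert rms_ratio(zeros, res) == pytest.approx(0.0)

    def test_equal_power_axes_give_inverse_sqrt_three(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.standard_normal((3, 200_000))
        res = np.sqrt(a**2 + b**2 + c**2)
        for axis in (a, b, c):
            assert rms_ratio(axis, res) == pytest.approx(1 / np.sqrt(3), rel=0.01)

    def test_ratio_bounded_by_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b, c = rng.standard_normal((3, 256))
            res = np.sqrt(a**2 + b**2 + c**2)
            assert 0.0 <= rms_ratio(a, res) <= 1.0


class TestRegularity:
    def test_pure_periodic_signal_fully_regular(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 2.8 * t)
        step_reg, stride_reg = regularity(x, FS)
        assert step_reg >= 0.99 and stride_reg >= 0.99

    def test_alternating_amplitude_makes_stride_beat_step(self):
        # brute-force oracle: construct alternating-amplitude impulse train and
        # evaluate the unbiased normalized autocorrelation directly
        period = 36  # samples per step
        n = 3600
        x = np.zeros(n)
        for k, i in enumerate(range(0, n, period)):
            x[i] = 1.3 if k % 2 == 0 else 0.7
        step_reg, stride_reg = regularity(x, FS)
        assert stride_reg > step_reg

        def brute_ac(x, lag):
            xc = x - x.mean()
            num = np.sum(xc[:-lag] * xc[lag:]) / (len(x) - lag)
            return num / (np.sum(xc**2) / len(x))

        assert step_reg == pytest.approx(np.clip(brute_ac(x, period), -1, 1), abs=1e-9)
        assert stride_reg == pytest.approx(np.clip(brute_ac(x, 2 * period), -1, 1), abs=1e-9)

    def test_white_noise_has_no_regularity(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2000)
        step_reg, stride_reg = regularity(x, FS)
        assert abs(step_reg) <= 0.2 and abs(stride_reg) <= 0.2


def brute_force_sampen(x, m, r):
    """O(N^2) reference implementation with explicit loops."""
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


class TestSampleEntropy:
    def test_constant_signal_missing(self):
        assert math.isnan(sample_entropy(np.ones(100)))

    def test_matches_brute_force_on_short_series(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], float)
        expected = brute_force_sampen(x, 2, 0.5 * np.std(x))
        assert sample_entropy(x, m=2, r_factor=0.5) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(60)
        expected = brute_force_sampen(x, 2, 0.2 * np.std(x))
        assert sample_entropy(x, m=2, r_factor=0.2) == pytest.approx(expected, abs=1e-12)

    def test_noise_more_entropic_than_sine(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 10, 0.01)
        sine = np.sin(2 * np.pi * 1.0 * t)
        noise = rng.standard_normal(len(t)) * np.std(sine)
        assert sample_entropy(noise) > sample_entropy(sine)

    def test_decimation_path_reduces_to_target_rate(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(10_000)  # 10 s at 1000 Hz
        v = sample_entropy(x, fs=1000.0)
        assert np.isfinite(v) and v > 0


class TestImpact:
    def test_constructed_impacts_recovered_exactly(self):
        x = np.zeros(1000)
        events = np.array([100, 400, 700])
        x[events + 3] = 3.0
        assert impact(x, events, FS) == pytest.approx(3.0)

    def test_no_events_missing(self):
        assert math.isnan(impact(np.ones(100), np.array([]), FS))

    def test_synthetic_impact_recovered_within_ten_percent(self):
        p = SignalParams(duration_s=20.0, fs=FS, step_impact_g=3.0, seed=14,
                         tilt_ap_deg=0.0, drift_deg=0.0, asymmetry=0.0)
        vt = corrected_vt(p)
        events = detect_steps(vt, FS)
        assert impact(vt, events, FS) == pytest.approx(3.0, rel=0.10)


class TestStatisticalBank:
    def test_constant_signal_degenerate_values(self):
        out = statistical_bank(np.full(500, 2.5), FS)
        assert out["sd"] == 0.0 and out["range"] == 0.0
        assert math.isnan(out["skewness"]) and math.isnan(out["kurtosis"])
        assert out["mean"] == 2.5

    def test_standard_normal_sd_within_sampling_error(self):
        rng = np.random.default_rng(7)
        out = statistical_bank(rng.standard_normal(12_000), FS)
        se = 1 / np.sqrt(2 * 12_000)
        assert abs(out["sd"] - 1.0) <= 3 * se

    def test_pure_sine_dominant_frequency(self):
        t = np.arange(0, 20, 1 / FS)
        out = statistical_bank(np.sin(2 * np.pi * 2.8 * t), FS)
        assert out["dominant_freq"] == pytest.approx(2.8, abs=1 / 20)
        assert out["power_0_3"] == pytest.approx(1.0, abs=0.01)

    def test_band_powers_sum_to_at_most_one(self):
        rng = np.random.default_rng(8)
        out = statistical_bank(rng.standard_normal(1000), FS)
        total = out["power_0_3"] + out["power_3_10"] + out["power_10_30"]
        assert 0.0 < total <= 1.0 + 1e-9


class TestNormalization:
    def test_reference_windows_map_to_unit_interval(self):
        df = pd.DataFrame({"f": [3.0, 1.0, 2.0, 5.0, 4.0, 2.5, 9.0, 0.0]})
        out = subject_minmax_normalize(df)
        ref = out["f"].iloc[:6]
        assert ref.min() == 0.0 and ref.max() == 1.0
        assert out["f"].iloc[6] == pytest.approx((9 - 1) / 4)   # above 1 is allowed
        assert out["f"].iloc[7] == pytest.approx(-0.25)         # below 0 is allowed

    def test_constant_feature_maps_to_zero(self):
        df = pd.DataFrame({"f": [2.0] * 8})
        out = subject_minmax_normalize(df)
        assert (out["f"] == 0.0).all()

    def test_exempt_column_untouched(self):
        df = pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 6], "angle": [0.1] * 6})
        out = subject_minmax_normalize(df, exempt=["angle"])
        assert (out["angle"] == 0.1).all()

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="subwindows"):
            subject_minmax_normalize(pd.DataFrame({"f": [1.0, 2.0]}))


class TestAggregation:
    def test_identical_windows_mean_equals_value_and_sd_zero(self):
        df = pd.DataFrame({"sample_entropy_VT": [1.4] * 6, "stat_mean_VT": [0.2] * 6})
        row = aggregate_to_subject(df)
        assert row["sample_entropy_VT"] == pytest.approx(1.4)
        assert row["sample_entropy_VT_sd"] == pytest.approx(0.0, abs=1e-12)
        assert "stat_mean_VT_sd" not in row

    def test_single_window_sd_missing(self):
        row = aggregate_to_subject(pd.DataFrame({"impact_VT": [2.0]}))
        assert row["impact_VT"] == 2.0 and math.isnan(row["impact_VT_sd"])

    def test_three_window_toy_matches_arithmetic(self):
        vals = [0.1, 0.5, 0.9]
        df = pd.DataFrame({"impact_ML": vals, "step_regularity_ML": [0.8, 0.6, 0.7]})
        row = aggregate_to_subject(df)
        assert row["impact_ML"] == pytest.approx(0.5)
        assert row["impact_ML_sd"] == pytest.approx(np.std(vals, ddof=1))
        assert row["step_regularity_ML"] == pytest.approx(0.7)

    def test_missing_subwindow_values_ignored(self):
        df = pd.DataFrame({"impact_AP": [1.0, np.nan, 3.0]})
        row = aggregate_to_subject(df)
        assert row["impact_AP"] == pytest.approx(2.0)


class TestTableOperations:
    @staticmethod
    def table(values):
        defs = {c: FeatureDef(c, "VT", "stat") for c in values.columns}
        return FeatureTable(values=values, defs=defs)

    def test_constant_column_removed_and_logged(self):
        values = pd.DataFrame({"stat_a_VT": [1.0, 2.0, 3.0], "stat_c_VT": [5.0, 5.0, 5.0]},
                              index=["s1", "s2", "s3"])
        out, removed = remove_constant_features(self.table(values))
        assert removed == ["stat_c_VT"]
        assert list(out.values.columns) == ["stat_a_VT"]

    def test_near_constant_column_kept(self):
        values = pd.DataFrame({"stat_a_VT": [5.0, 5.0 + 1e-12, 5.0]}, index=["s1", "s2", "s3"])
        _, removed = remove_constant_features(self.table(values))
        assert removed == []

    def test_single_subject_rejected(self):
        values = pd.DataFrame({"stat_a_VT": [1.0]}, index=["s1"])
        with pytest.raises(ValueError):
            remove_constant_features(self.table(values))

    def test_questionnaire_attached_verbatim(self):
        values = pd.DataFrame({"stat_a_VT": [1.0, 2.0]}, index=["s1", "s2"])
        records = [
            CohortRecord(subject_id="s1", gender="male", mass_kg=70.0, height_cm=180.0,
                         prev_injury=True, insoles=False, distance_m=3000.0, status="none"),
            CohortRecord(subject_id="s2", gender="female", mass_kg=None, height_cm=165.0,
                         prev_injury=False, insoles=True, distance_m=2500.0, status="LLOI"),
        ]
        out = attach_questionnaire(self.table(values), records)
        assert out.values.shape[1] == 1 + 6
        assert out.values.loc["s1", "mass_kg"] == 70.0
        assert out.values.loc["s1", "gender"] == "male"
        assert np.isnan(out.values.loc["s2", "mass_kg"])  # missing -> exclusion fodder
        assert records[1].has_missing()
        assert out.defs["distance_m"].ftype == "quest"
        assert out.defs["gender"].direction == "ND"


@pytest.fixture(scope="module")
def asymmetric_pair():
    """Two short runs differing only in left/right asymmetry."""
    traces = []
    for asym in (0.0, 0.35):
        p = SignalParams(duration_s=200.0, fs=50.0, seed=20, asymmetry=asym,
                         tilt_ap_deg=3.0, drift_deg=1.0, noise_sd_g=0.08)
        t = simulate_run_signal(p)
        t.subject_id = f"asym{asym}"
        traces.append(t)
    ex = GaitFeatureExtractor().fit()
    return ex.transform(traces), ex


class TestExtractor:

    def test_higher_asymmetry_lowers_step_vs_stride_regularity(self, asymmetric_pair):
        table, _ = asymmetric_pair
        gap = table.values["stride_regularity_VT"] - table.values["step_regularity_VT"]
        assert gap.loc["asym0.35"] > gap.loc["asym0.0"]

    def test_every_feature_has_one_tag(self, asymmetric_pair):
        table, _ = asymmetric_pair
        assert set(table.values.columns) == set(table.defs)
        for d in table.defs.values():
            assert d.direction in ("VT", "ML", "AP", "Res", "ND")
            assert d.ftype in ("sport", "stat", "quest")

    def test_running_time_and_window_counts_recorded(self, asymmetric_pair):
        _, ex = asymmetric_pair
        assert ex.running_time_s_["asym0.0"] == pytest.approx(200.0, rel=0.05)
        assert ex.n_windows_["asym0.0"] == 1  # 200 s - 70 s crop -> one 2-min window

    def test_single_window_leaves_angle_change_missing(self, asymmetric_pair):
        table, _ = asymmetric_pair
        assert table.values["angle_change_AP"].isna().all()

    def test_transform_deterministic(self, asymmetric_pair):
        table, _ = asymmetric_pair
        p = SignalParams(duration_s=200.0, fs=50.0, seed=20, asymmetry=0.0,
                         tilt_ap_deg=3.0, drift_deg=1.0, noise_sd_g=0.08)
        t = simulate_run_signal(p)
        t.subject_id = "asym0.0"
        again = GaitFeatureExtractor().fit().transform([t])
        a = table.values.loc[["asym0.0"]]
        pd.testing.assert_frame_equal(a, again.values, check_exact=True)
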