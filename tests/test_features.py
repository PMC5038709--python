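"""Feature-extraction checks: filtering, smoothing, detectors and the
round-trip recovery of generator ground truth."""

import numpy as np
import pytest

from psychstate.config import GeneratorConfig
from psychstate.features import (
    FEATURE_GROUPS,
    bandpass_filter,
    build_feature_vector,
    bvp_features,
    detect_r_peaks,
    ecg_features,
    eda_features,
    emg_features,
    moving_average,
)
from psychstate.synthetic import (
    generate_cohort,
    synthesize_bvp,
    synthesize_ecg,
)


def _rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestBandpass:
    def test_stop_band_attenuation(self):
        t = np.arange(0, 10, 1 / 250)
        x = np.sin(2 * np.pi * 50 * t)
        y = bandpass_filter(x, 250, 0.5, 40)
        assert _rms(y) < 0.05 * _rms(x)

    def test_pass_band_preservation(self):
        t = np.arange(0, 10, 1 / 250)
        x = np.sin(2 * np.pi * 10 * t)
        y = bandpass_filter(x, 250, 0.5, 40)
        assert _rms(y) == pytest.approx(_rms(x), rel=0.05)

    def test_dc_offset_removed(self):
        x = np.full(2500, 5.0)
        y = bandpass_filter(x, 250, 0.5, 40)
        assert abs(y.mean()) < 0.05

    def test_filtering_twice_is_nearly_idempotent_in_band(self):
        t = np.arange(0, 10, 1 / 250)
        x = np.sin(2 * np.pi * 10 * t)
        once = bandpass_filter(x, 250, 0.5, 40)
        twice = bandpass_filter(once, 250, 0.5, 40)
        assert _rms(twice) == pytest.approx(_rms(once), rel=0.01)

    @pytest.mark.parametrize("low,high", [(40, 0.5), (0.5, 200), (-1, 40)])
    def test_invalid_band_edges_rejected(self, low, high):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), 250, low, high)


class TestMovingAverage:
    def test_constant_preserved(self):
        np.testing.assert_allclose(moving_average(np.full(40, 3.3), 15), 3.3)

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_trailing_ramp_value(self):
        x = np.arange(1.0, 31.0)
        out = moving_average(x, 15)
        assert out[14] == pytest.approx(8.0)  # mean of 1..15

    def test_edge_truncation(self):
        x = np.arange(1.0, 31.0)
        out = moving_average(x, 15)
        assert out[0] == 1.0
        assert out[2] == pytest.approx(2.0)  # mean of 1..3


class TestRPeaks:
    def test_all_zero_signal_yields_empty(self):
        assert detect_r_peaks(np.zeros(1000), 250.0).size == 0

    def test_two_beats_half_second_apart(self, default_effects):
        effects = {**default_effects, "heart_rate_bpm": {"N": 120.0},
                   "rr_jitter_sd_s": {"N": 0.0}}
        sig = synthesize_ecg("N", 2.0, 250.0, effects, seed=0, noise_sd=0.0)
        peaks = detect_r_peaks(sig.samples, 250.0)
        assert len(peaks) >= 2
        assert abs(int(np.diff(peaks)[0]) - 125) <= 1

    def test_peaks_strictly_increasing_with_refractory(self, default_effects):
        sig = synthesize_ecg("E", 30.0, 250.0, default_effects, seed=4)
        peaks = detect_r_peaks(bandpass_filter(sig.samples, 250, 0.5, 40), 250.0)
        assert np.all(np.diff(peaks) >= int(0.2 * 250))


class TestECGFeatures:
    def test_bazett_correction_consistency(self, default_effects):
        sig = synthesize_ecg("N", 30.0, 250.0, default_effects, seed=2)
        f = ecg_features(sig.samples, 250.0, (0, len(sig.samples)))
        assert f["qtc"] == pytest.approx(f["qt"] / np.sqrt(f["rr_mean"]), rel=1e-9)

    def test_unit_rr_means_qtc_equals_qt(self, default_effects):
        effects = {**default_effects, "heart_rate_bpm": {"N": 60.0},
                   "rr_jitter_sd_s": {"N": 0.0}}
        sig = synthesize_ecg("N", 20.0, 250.0, effects, seed=0, noise_sd=0.0)
        f = ecg_features(sig.samples, 250.0, (0, len(sig.samples)))
        assert f["rr_mean"] == pytest.approx(1.0, abs=0.01)
        assert f["qtc"] == pytest.approx(f["qt"], rel=0.01)
        assert f["qt"] == pytest.approx(sig.truth["qt_s"], abs=2 / 250)

    def test_constant_rr_zero_variance_and_derivative(self, default_effects):
        effects = {**default_effects, "rr_jitter_sd_s": {"N": 0.0}}
        sig = synthesize_ecg("N", 20.0, 250.0, effects, seed=0, noise_sd=0.0)
        f = ecg_features(sig.samples, 250.0, (0, len(sig.samples)))
        assert f["rr_var"] == pytest.approx(0.0, abs=1e-4)
        assert f["rr_d1"] == pytest.approx(0.0, abs=0.01)

    def test_too_few_beats_flagged_missing(self):
        f = ecg_features(np.zeros(2500), 250.0, (0, 2500))
        assert all(np.isnan(v) for v in f.values())


class TestEDAFeatures:
    def test_tonic_only_signal(self):
        x = np.full(16 * 60, 2.0)
        f = eda_features(x, 16.0, (0, len(x)))
        assert f["scl_mean"] == pytest.approx(2.0, rel=0.01)
        assert f["scr_count"] == 0

    def test_five_injected_scrs_give_five_per_minute(self):
        fs, dur = 16.0, 60.0
        t = np.arange(int(fs * dur)) / fs
        x = np.full(len(t), 2.0)
        from psychstate.synthetic import _scr_shape

        for t0 in (5.0, 15.0, 25.0, 35.0, 45.0):
            x += 0.5 * _scr_shape(t - t0)
        f = eda_features(x, fs, (0, len(x)))
        assert f["scr_count"] == 5
        assert f["scr_freq_per_min"] == pytest.approx(5.0, rel=1e-6)

    def test_mean_amplitude_recovers_injected_values(self):
        fs, dur = 16.0, 120.0
        t = np.arange(int(fs * dur)) / fs
        x = np.full(len(t), 2.0)
        from psychstate.synthetic import _scr_shape

        for t0, amp in [(10.0, 0.2), (40.0, 0.4), (70.0, 0.2), (100.0, 0.4)]:
            x += amp * _scr_shape(t - t0)
        f = eda_features(x, fs, (0, len(x)))
        assert f["scr_amp_mean"] == pytest.approx(0.3, rel=0.1)


class TestBVPFeatures:
    def test_60bpm_mm_interval(self, default_effects):
        effects = {**default_effects, "heart_rate_bpm": {"N": 60.0},
                   "rr_jitter_sd_s": {"N": 0.0}}
        sig = synthesize_bvp("N", 30.0, 64.0, effects, seed=0, noise_sd=0.0)
        f = bvp_features(sig.samples, 64.0, (0, len(sig.samples)))
        assert f["mm_interval_mean"] == pytest.approx(1.0, abs=2 / 64)
        assert f["mm_interval_sd"] == pytest.approx(0.0, abs=2 / 64)

    def test_augmentation_index_recovery(self, default_effects):
        effects = {**default_effects, "augmentation_index": {"N": 0.5}}
        sig = synthesize_bvp("N", 60.0, 64.0, effects, seed=1, noise_sd=0.0)
        f = bvp_features(sig.samples, 64.0, (0, len(sig.samples)))
        assert f["augmentation_index_mean"] == pytest.approx(0.5, rel=0.05)

    def test_zero_diastolic_flags_mq_missing(self, default_effects):
        effects = {**default_effects, "augmentation_index": {"N": 0.0}}
        sig = synthesize_bvp("N", 20.0, 64.0, effects, seed=0, noise_sd=0.0)
        f = bvp_features(sig.samples, 64.0, (0, len(sig.samples)))
        assert np.isnan(f["mq_interval_mean"])


class TestEMGFeatures:
    def test_flat_band_median_frequency(self, rng):
        # white noise band-limited to 20-200 Hz: median near the midpoint
        from scipy import signal as sps

        fs = 1000.0
        x = rng.normal(size=int(fs * 30))
        sos = sps.butter(8, [20, 200], btype="band", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
        f = emg_features(x, fs, (0, len(x)))
        assert f["emg_median_freq"] == pytest.approx(110.0, rel=0.1)

    def test_gap_rate_matches_schedule(self, default_effects):
        from psychstate.synthetic import synthesize_emg

        sig = synthesize_emg("N", 60.0, 1000.0, default_effects, seed=1)
        f = emg_features(sig.samples, 1000.0, (0, len(sig.samples)))
        assert f["emg_gaps_per_min"] == pytest.approx(sig.truth["gap_count"], abs=1)

    def test_no_gap_signal_has_zero_gap_percentage(self, default_effects):
        effects = {**default_effects, "emg_gaps_per_min": {"N": 0.0}}
        from psychstate.synthetic import synthesize_emg

        sig = synthesize_emg("N", 30.0, 1000.0, effects, seed=0)
        f = emg_features(sig.samples, 1000.0, (0, len(sig.samples)))
        assert f["emg_gap_pct"] == 0.0


class TestFeatureVector:
    def test_every_sensor_group_represented(self, small_cohort):
        fv = build_feature_vector(small_cohort[0], 0)
        groups = set(fv.groups.values())
        for g in ("ECG", "EDA", "BVP", "EMG", "BDI", "FH"):
            assert g in groups
        assert set(fv.groups.values()) <= set(FEATURE_GROUPS.values())

    def test_missing_channel_flags_only_its_features(self, small_cohort):
        import copy

        rec = copy.copy(small_cohort[0])
        rec.channels = {k: v for k, v in rec.channels.items() if k != "EMG"}
        fv = build_feature_vector(rec, 0)
        assert all(f in fv.missing for f, g in fv.groups.items() if g == "EMG")
        assert np.isfinite(fv.values["scl_mean"])

    def test_history_flags_encoded_as_binary(self, small_cohort):
        rec = small_cohort[0]
        fv = build_feature_vector(rec, 0)
        assert fv.values["family_suicide_history"] == float(
            rec.history["family_suicide_history"]
        )

    def test_slot_locality(self, small_cohort):
        """Corrupting samples outside a slot leaves its features unchanged."""
        import copy

        rec = small_cohort[1]
        before = build_feature_vector(rec, 3).values
        corrupted = copy.copy(rec)
        corrupted.channels = {k: v.copy() for k, v in rec.channels.items()}
        for ch, fs in rec.fs.items():
            hi = int(2 * rec.tau_seconds * fs)  # slots 0-1 only
            corrupted.channels[ch][:hi] = 99.0
        after = build_feature_vector(corrupted, 3).values
        for name, value in before.items():
            if np.isnan(value):
                assert np.isnan(after[name])
            else:
                assert after[name] == value


def test_feature_table_shape_and_truth_column(small_cohort, small_features):
    n_slots = sum(rec.n_slots for rec in small_cohort)
    assert len(small_features) == n_slots
    assert set(small_features["true_state"].unique()) <= {"N", "A", "E"}
    assert all(name in small_features.columns for name in FEATURE_GROUPS)
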