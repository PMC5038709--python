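"""Per-slot psychophysiological feature extraction.

Each observation slot of duration tau is reduced to a named feature
vector: band-pass filtered ECG yields R-R/QRS/QT descriptors, EDA yields
tonic level and skin-conductance-response statistics, BVP yields pulse
morphology (systolic/diastolic amplitudes, augmentation and stiffness
indices), and EMG yields amplitude, spectral and gap statistics.  The
sensor features are fused with the subject's rating-scale scores and
history flags into one :class:`FeatureVector` per slot.

Extraction is strictly slot-local: every feature of slot ``i`` is computed
from the raw samples of slot ``i`` alone (filtering included), so samples
outside the slot can never leak into its features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import minimum_filter1d

from .synthetic import RawRecording

__all__ = [
    "FeatureVector",
    "bandpass_filter",
    "moving_average",
    "detect_r_peaks",
    "ecg_features",
    "eda_features",
    "bvp_features",
    "emg_features",
    "build_feature_vector",
    "features_table",
    "FEATURE_GROUPS",
    "SENSOR_BANDS",
]

# conventional clinical pass-bands per channel; low = 0 means low-pass
SENSOR_BANDS: dict[str, tuple[float, float]] = {
    "ECG": (0.5, 40.0),
    "BVP": (0.5, 8.0),
    "EDA": (0.0, 1.0),
    "EMG": (20.0, 450.0),
}

SMOOTHING_WINDOW = 15  # samples, applied to EDA and detector energy series

SCR_AMPLITUDE_THRESHOLD_US = 0.05
SCR_MIN_SEPARATION_S = 1.0
EMG_GAP_ENVELOPE_FRACTION = 0.10  # of slot RMS
EMG_GAP_MIN_DURATION_S = 0.20
STIFFNESS_HEIGHT_M = 1.75  # nominal subject height proxy
R_REFRACTORY_S = 0.20

# rating scales entering the feature vector; the HRSD (total and suicide
# item) defines the state label itself and is deliberately excluded to
# avoid circularity between label and feature.
SCALE_FEATURES: dict[str, str] = {
    "BDI": "BDI",
    "SSI": "SSI",
    "BHS": "BHS",
    "SCST": "SCST",
    "BIS": "BIS",
    "BPAQ": "BPAQ",
    "BDHI": "BDHI",
    "PHQ9": "PHQ",
    "GAD7": "PHQ",
}

HISTORY_FEATURES: dict[str, str] = {
    "family_suicide_history": "FH",
    "medical_history": "MH",
    "personal_trait": "PT",
}

_ECG_NAMES = (
    "rr_mean", "rr_var", "rr_d1", "rr_d2", "qrs_amplitude", "qrs_duration",
    "qt", "qtc", "rs_ratio", "r_peak_amplitude",
)
_EDA_NAMES = ("scl_mean", "scr_count", "scr_freq_per_min", "scr_amp_mean",
              "scr_duration_mean")
_BVP_NAMES = tuple(
    f"{base}_{stat}"
    for base in ("mm_interval", "pulse_width", "pulse_area", "mq_interval",
                 "pulse_interval", "systolic_amp", "diastolic_amp",
                 "augmentation_index", "stiffness_index")
    for stat in ("mean", "sd")
)
_EMG_NAMES = ("emg_mean_amp", "emg_mean_freq", "emg_median_freq",
              "emg_gaps_per_min", "emg_gap_pct")

#: provenance group of every feature name
FEATURE_GROUPS: dict[str, str] = {}
FEATURE_GROUPS.update({n: "ECG" for n in _ECG_NAMES})
FEATURE_GROUPS.update({n: "EDA" for n in _EDA_NAMES})
FEATURE_GROUPS.update({n: "BVP" for n in _BVP_NAMES})
FEATURE_GROUPS.update({n: "EMG" for n in _EMG_NAMES})
FEATURE_GROUPS.update(SCALE_FEATURES)
FEATURE_GROUPS.update(HISTORY_FEATURES)


@dataclass
class FeatureVector:
    """Named features for one observation slot.

    ``missing`` lists features that could not be computed (too few beats,
    absent channel, ...); their ``values`` entry is NaN, never a silent 0.
    """

    slot_index: int
    values: dict[str, float] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)

    def set(self, name: str, value: float, group: str) -> None:
        if name in self.values:
            raise ValueError(f"duplicate feature name {name!r}")
        self.groups[name] = group
        if value is None or not np.isfinite(value):
            self.values[name] = np.nan
            self.missing.add(name)
        else:
            self.values[name] = float(value)


# ---------------------------------------------------------------------------
# preprocessing


def bandpass_filter(
    signal: np.ndarray, fs: float, low: float, high: float
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (low-pass when ``low`` is 0)."""
    if not 0 <= low < high < fs / 2:
        raise ValueError(
            f"invalid band edges ({low}, {high}) for fs={fs}: need 0 <= low < high < fs/2"
        )
    x = np.asarray(signal, dtype=float)
    order = 8  # steep roll-off; zero-phase application doubles it again
    # cascade of separate low-pass and high-pass stages: running the
    # low-pass first keeps stop-band edge kinks from ringing the slow
    # high-pass modes
    out = x
    lp = sps.butter(order, high, btype="low", fs=fs, output="sos")
    padlen = min(len(x) - 1, 3 * (2 * order + 1))
    if padlen < 1:
        return x.copy()
    out = sps.sosfiltfilt(lp, out, padlen=padlen, padtype="even")
    if low > 0:
        hp = sps.butter(order, low, btype="high", fs=fs, output="sos")
        hp_pad = min(len(x) - 1, max(3 * (2 * order + 1), int(2 * fs / low)))
        out = sps.sosfiltfilt(hp, out, padlen=hp_pad, padtype="even")
    return out


def moving_average(signal: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Trailing moving average with edge truncation.

    ``out[i]`` averages the last ``window`` samples up to and including
    ``i``; near the start the effective window shrinks, so the output has
    the input's length and a constant input maps to itself.
    """
    x = np.asarray(signal, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(x):
        raise ValueError("window exceeds signal length")
    if window == 1:
        return x.copy()
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(1, len(x) + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


# ---------------------------------------------------------------------------
# ECG


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Derivative-energy R-peak detector with a 200 ms refractory period.

    The squared first difference is smoothed and thresholded at a fraction
    of its maximum; detections are refined to the local ECG maximum.  A
    flat (or empty) trace yields an empty index array.
    """
    x = np.asarray(ecg, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int)
    energy = np.diff(x) ** 2
    win = max(3, int(0.030 * fs))
    energy = moving_average(energy, min(win, len(energy)))
    peak_e = energy.max()
    if peak_e <= 1e-12:
        return np.array([], dtype=int)
    distance = max(1, int(R_REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(energy, height=0.20 * peak_e, distance=distance)
    half = max(1, int(0.05 * fs))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    peaks: list[int] = []
    for r in sorted(set(refined)):
        if not peaks or r - peaks[-1] >= distance:
            peaks.append(r)
        elif x[r] > x[peaks[-1]]:
            peaks[-1] = r
    return np.array(peaks, dtype=int)


def _nan_dict(names) -> dict[str, float]:
    return {n: np.nan for n in names}


def ecg_features(
    ecg: np.ndarray, fs: float, slot_bounds: tuple[int, int]
) -> dict[str, float]:
    """R-R statistics, QRS/QT morphology and beat-series derivatives.

    QTc uses Bazett's correction QT/sqrt(RR).  The "first/second
    derivative" features are the means of the successive-difference and
    second-difference series of the R-R intervals.  Fewer than two beats
    in the slot flags every ECG feature missing.
    """
    lo, hi = slot_bounds
    seg = bandpass_filter(np.asarray(ecg, dtype=float)[lo:hi], fs, *SENSOR_BANDS["ECG"])
    peaks = detect_r_peaks(seg, fs)
    if len(peaks) < 2:
        return _nan_dict(_ECG_NAMES)
    rr = np.diff(peaks) / fs
    out = {
        "rr_mean": rr.mean(),
        "rr_var": rr.var(),
        "rr_d1": np.diff(rr).mean() if len(rr) > 1 else 0.0,
        "rr_d2": np.diff(rr, 2).mean() if len(rr) > 2 else 0.0,
    }
    q_win = max(1, int(0.060 * fs))
    t_lo, t_hi = int(0.12 * fs), int(0.35 * fs)
    qrs_amp, qrs_dur, qts, rs_ratio, r_amp = [], [], [], [], []
    for r in peaks:
        if r - q_win < 0 or r + t_hi >= len(seg):
            continue
        q_rel = int(np.argmin(seg[r - q_win : r])) + r - q_win
        s_rel = int(np.argmin(seg[r + 1 : r + q_win + 1])) + r + 1
        t_rel = int(np.argmax(seg[r + t_lo : r + t_hi])) + r + t_lo
        qrs_amp.append(seg[r] - seg[s_rel])
        qrs_dur.append((s_rel - q_rel) / fs)
        qts.append((t_rel - q_rel) / fs)
        rs_ratio.append(seg[r] / abs(seg[s_rel]) if abs(seg[s_rel]) > 1e-9 else np.nan)
        r_amp.append(seg[r])
    if not qts:
        out.update(_nan_dict(_ECG_NAMES[4:]))
        return out
    qt = float(np.mean(qts))
    out.update(
        qrs_amplitude=float(np.mean(qrs_amp)),
        qrs_duration=float(np.mean(qrs_dur)),
        qt=qt,
        qtc=qt / np.sqrt(rr.mean()),
        rs_ratio=float(np.nanmean(rs_ratio)),
        r_peak_amplitude=float(np.mean(r_amp)),
    )
    return out


# ---------------------------------------------------------------------------
# EDA


def eda_features(
    eda: np.ndarray, fs: float, slot_bounds: tuple[int, int]
) -> dict[str, float]:
    """Tonic level and phasic skin-conductance-response statistics.

    The phasic component is the excursion above a rolling-minimum
    baseline; an SCR is a phasic peak of at least 0.05 uS with at least
    1 s separation.  Frequency is reported per minute.
    """
    lo, hi = slot_bounds
    seg = np.asarray(eda, dtype=float)[lo:hi]
    seg = bandpass_filter(seg, fs, *SENSOR_BANDS["EDA"])
    seg = moving_average(seg, min(SMOOTHING_WINDOW, len(seg)))
    baseline_win = max(1, int(4.0 * fs))
    baseline = minimum_filter1d(seg, size=baseline_win, mode="nearest")
    phasic = seg - baseline
    distance = max(1, int(SCR_MIN_SEPARATION_S * fs))
    peaks, props = sps.find_peaks(
        phasic, height=SCR_AMPLITUDE_THRESHOLD_US, distance=distance
    )
    minutes = len(seg) / fs / 60.0
    out = {
        "scl_mean": float(seg.mean()),
        "scr_count": float(len(peaks)),
        "scr_freq_per_min": len(peaks) / minutes if minutes > 0 else np.nan,
    }
    if len(peaks) == 0:
        out["scr_amp_mean"] = np.nan
        out["scr_duration_mean"] = np.nan
    else:
        widths = sps.peak_widths(phasic, peaks, rel_height=0.5)[0] / fs
        out["scr_amp_mean"] = float(props["peak_heights"].mean())
        out["scr_duration_mean"] = float(widths.mean())
    return out


# ---------------------------------------------------------------------------
# BVP


def bvp_features(
    bvp: np.ndarray, fs: float, slot_bounds: tuple[int, int]
) -> dict[str, float]:
    """Pulse-wave morphology statistics per slot.

    Systolic peaks (M) are the dominant maxima; the diastolic peak (Q) is
    the secondary maximum after the dicrotic notch.  The augmentation
    index is the diastolic/systolic amplitude ratio; the stiffness index
    divides a nominal height constant by the M-Q interval.
    """
    lo, hi = slot_bounds
    seg = bandpass_filter(np.asarray(bvp, dtype=float)[lo:hi], fs, *SENSOR_BANDS["BVP"])
    out = _nan_dict(_BVP_NAMES)
    if len(seg) < 8:
        return out
    m_peaks, _ = sps.find_peaks(
        seg, height=0.5 * seg.max(), distance=max(1, int(0.35 * fs)),
        prominence=0.25 * (seg.max() - seg.min()),
    )
    if len(m_peaks) < 2:
        return out
    mm = np.diff(m_peaks) / fs
    widths = sps.peak_widths(seg, m_peaks, rel_height=0.5)[0] / fs

    feet, q_idx, sys_amp, dia_amp, mq, areas = [], [], [], [], [], []
    for i, m in enumerate(m_peaks):
        f_lo = m_peaks[i - 1] if i > 0 else max(0, m - int(0.4 * fs))
        foot = f_lo + int(np.argmin(seg[f_lo:m])) if m > f_lo else m
        feet.append(foot)
        sys_amp.append(seg[m] - seg[foot])
        nxt = m_peaks[i + 1] if i + 1 < len(m_peaks) else len(seg)
        q_lo = m + max(1, int(0.12 * fs))
        q_hi = min(nxt - max(1, int(0.05 * fs)), m + int(0.5 * fs))
        if q_hi > q_lo:
            # require a genuine local maximum after the notch, not filter ripple
            q_cands, _ = sps.find_peaks(
                seg[q_lo:q_hi], prominence=0.03 * (seg.max() - seg.min())
            )
            if len(q_cands):
                q = q_lo + q_cands[np.argmax(seg[q_lo + q_cands])]
                q_idx.append(q)
                dia_amp.append(seg[q] - seg[foot])
                mq.append((q - m) / fs)
    for i in range(len(feet) - 1):
        window = seg[feet[i] : feet[i + 1]]
        areas.append(float(np.trapezoid(window - seg[feet[i]], dx=1.0 / fs)))
    pulse_interval = np.diff(feet) / fs if len(feet) > 1 else np.array([])

    def put(base: str, arr) -> None:
        arr = np.asarray(arr, dtype=float)
        if arr.size:
            out[f"{base}_mean"] = float(np.mean(arr))
            out[f"{base}_sd"] = float(np.std(arr))

    put("mm_interval", mm)
    put("pulse_width", widths)
    put("pulse_area", areas)
    put("pulse_interval", pulse_interval)
    put("systolic_amp", sys_amp)
    if mq:
        put("mq_interval", mq)
        put("diastolic_amp", dia_amp)
        sys_for_q = np.asarray(sys_amp[: len(dia_amp)], dtype=float)
        aug = np.asarray(dia_amp) / np.where(sys_for_q > 1e-9, sys_for_q, np.nan)
        put("augmentation_index", aug[np.isfinite(aug)])
        put("stiffness_index", STIFFNESS_HEIGHT_M / np.asarray(mq))
    return out


# ---------------------------------------------------------------------------
# EMG


def emg_features(
    emg: np.ndarray, fs: float, slot_bounds: tuple[int, int]
) -> dict[str, float]:
    """Amplitude, spectral and gap statistics of the muscle-activity trace.

    A gap is a stretch where the RMS envelope stays below 10% of the
    slot RMS for at least 200 ms; reported as gaps/min and as the
    percentage of slot time spent in gaps.
    """
    lo, hi = slot_bounds
    x = np.asarray(emg, dtype=float)[lo:hi]
    band_hi = min(SENSOR_BANDS["EMG"][1], 0.45 * fs)
    seg = bandpass_filter(x, fs, SENSOR_BANDS["EMG"][0], band_hi)
    out = _nan_dict(_EMG_NAMES)
    if len(seg) < 16:
        return out
    out["emg_mean_amp"] = float(np.mean(np.abs(seg)))
    nperseg = min(1024, len(seg))
    f, pxx = sps.welch(seg, fs=fs, nperseg=nperseg)
    total = pxx.sum()
    if total > 0:
        out["emg_mean_freq"] = float((f * pxx).sum() / total)
        cum = np.cumsum(pxx)
        out["emg_median_freq"] = float(f[np.searchsorted(cum, 0.5 * cum[-1])])
    env_win = max(3, int(0.05 * fs))
    envelope = np.sqrt(moving_average(seg**2, min(env_win, len(seg))))
    slot_rms = np.sqrt(np.mean(seg**2))
    below = envelope < EMG_GAP_ENVELOPE_FRACTION * slot_rms if slot_rms > 0 else (
        np.zeros(len(seg), dtype=bool)
    )
    min_len = int(EMG_GAP_MIN_DURATION_S * fs)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], below.astype(int), [0]])))
    starts, ends = edges[::2], edges[1::2]
    runs = [(s, e) for s, e in zip(starts, ends) if e - s >= min_len]
    minutes = len(seg) / fs / 60.0
    out["emg_gaps_per_min"] = len(runs) / minutes if minutes > 0 else np.nan
    out["emg_gap_pct"] = (
        100.0 * sum(e - s for s, e in runs) / len(seg) if len(seg) else np.nan
    )
    return out


# ---------------------------------------------------------------------------
# fusion


_SENSOR_EXTRACTORS = {
    "ECG": (ecg_features, _ECG_NAMES),
    "EDA": (eda_features, _EDA_NAMES),
    "BVP": (bvp_features, _BVP_NAMES),
    "EMG": (emg_features, _EMG_NAMES),
}


def build_feature_vector(recording: RawRecording, slot_index: int) -> FeatureVector:
    """Fuse sensor, rating-scale and history features for one slot."""
    if not 0 <= slot_index < recording.n_slots:
        raise IndexError(f"slot_index {slot_index} outside 0..{recording.n_slots - 1}")
    fv = FeatureVector(slot_index=slot_index)
    for channel, (extractor, names) in _SENSOR_EXTRACTORS.items():
        if channel in recording.channels:
            fs = recording.fs[channel]
            lo = int(round(slot_index * recording.tau_seconds * fs))
            hi = int(round((slot_index + 1) * recording.tau_seconds * fs))
            feats = extractor(recording.channels[channel], fs, (lo, hi))
        else:
            feats = _nan_dict(names)
        for name in names:
            fv.set(name, feats.get(name, np.nan), channel)
    for inst, group in SCALE_FEATURES.items():
        fv.set(inst, recording.scale_scores.get(inst, np.nan), group)
    for flag, group in HISTORY_FEATURES.items():
        value = recording.history.get(flag)
        fv.set(flag, np.nan if value is None else float(bool(value)), group)
    return fv


def features_table(recordings: list[RawRecording]) -> pd.DataFrame:
    """One row per subject x slot: features, group-taggable by name.

    Columns: ``subject``, ``slot``, ``true_state``, then every feature
    name in :data:`FEATURE_GROUPS` order.  Missing features are NaN.
    """
    rows = []
    for rec in recordings:
        for slot in range(rec.n_slots):
            fv = build_feature_vector(rec, slot)
            row = {"subject": rec.subject_id, "slot": slot,
                   "true_state": rec.true_states[slot]}
            row.update(fv.values)
            rows.append(row)
    return pd.DataFrame(rows)
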