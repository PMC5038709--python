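"""State-conditioned synthetic cohort generator.

Real recordings of psychiatric consultations with parallel biosensor
streams are not publicly available, so every downstream stage of the
package is exercised on synthetic subjects whose four channels (ECG, EDA,
BVP, EMG), rating-scale scores and history flags carry the class structure
the prediction method assumes:

* a latent first-order Markov chain over (N, A, E) at slot resolution tau;
* ECG built from a sum-of-Gaussians P-QRS-T template repeated at a
  state-dependent heart rate with state-dependent R-R jitter;
* EDA as a slowly drifting tonic level plus Poisson-arriving skin
  conductance responses (rapid rise, exponential decay);
* BVP as a two-Gaussian systolic/diastolic pulse locked to the ECG beats;
* EMG as band-limited noise whose envelope alternates active tone with
  state-dependent rest gaps.

Every synthesized fiducial (R peaks, SCR events, pulse peaks, EMG gaps) is
returned as ground truth so feature extractors can be validated by
round-trip recovery rather than by eyeballing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as sps

from .config import (
    GeneratorConfig,
    HRSD_ITEM3_MAPPING,
    SCALE_RANGES,
)
from .states import STATES, STATE_INDEX

__all__ = [
    "SynthSignal",
    "RawRecording",
    "sample_state_trajectory",
    "synthesize_ecg",
    "synthesize_eda",
    "synthesize_bvp",
    "synthesize_emg",
    "sample_scale_scores",
    "sample_history",
    "generate_cohort",
]

# per-channel nominal measurement-noise sd, scaled by GeneratorConfig.noise_sd
CHANNEL_NOISE_SD = {"ECG": 0.02, "EDA": 0.01, "BVP": 0.02, "EMG": 0.002}

# ECG template: (time offset from R in s, Gaussian width s, amplitude mV)
ECG_WAVES = {
    "P": (-0.200, 0.025, 0.15),
    "Q": (-0.035, 0.010, -0.12),
    "R": (0.000, 0.012, 1.00),
    "S": (0.035, 0.010, -0.25),
    "T": (0.220, 0.045, 0.35),
}

# BVP template offsets from the pulse foot (systolic valley S)
BVP_SYSTOLIC_OFFSET_S = 0.15
BVP_SYSTOLIC_WIDTH_S = 0.055
BVP_DIASTOLIC_OFFSET_S = 0.40
BVP_DIASTOLIC_WIDTH_S = 0.085

SCR_RISE_S = 0.75
SCR_DECAY_S = 3.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SynthSignal:
    """Synthesized channel: samples plus generator ground truth."""

    samples: np.ndarray
    fs: float
    truth: dict[str, Any] = field(default_factory=dict)


@dataclass
class RawRecording:
    """One synthetic subject: four channels, scores, history, true states."""

    subject_id: str
    channels: dict[str, np.ndarray]
    fs: dict[str, float]
    scale_scores: dict[str, int]
    history: dict[str, bool]
    true_states: list[str]
    tau_seconds: float
    dominant_label: str
    truth: dict[str, dict[str, Any]] = field(default_factory=dict)

    @property
    def n_slots(self) -> int:
        return len(self.true_states)

    def validate(self) -> None:
        for name, samples in self.channels.items():
            expected = int(round(self.n_slots * self.tau_seconds * self.fs[name]))
            if len(samples) != expected:
                raise ValueError(
                    f"channel {name}: {len(samples)} samples, expected {expected}"
                )
        for inst, score in self.scale_scores.items():
            lo, hi = SCALE_RANGES[inst]
            if not lo <= score <= hi:
                raise ValueError(f"{inst} score {score} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# latent state dynamics


def sample_state_trajectory(
    transition_matrix: np.ndarray,
    n_slots: int,
    initial_state: str,
    seed,
) -> list[str]:
    """Sample a first-order Markov chain over the state alphabet.

    The next state depends only on the current one; rows of
    ``transition_matrix`` are the conditional next-state distributions in
    (N, A, E) order.
    """
    T = np.asarray(transition_matrix, dtype=float)
    if T.shape != (len(STATES), len(STATES)) or np.any(T < 0) or not np.allclose(
        T.sum(axis=1), 1.0, atol=1e-9
    ):
        raise ValueError("transition matrix must be row-stochastic over the 3 states")
    if n_slots < 1:
        raise ValueError("n_slots must be >= 1")
    rng = _as_rng(seed)
    state = STATE_INDEX[initial_state]
    out = [STATES[state]]
    for _ in range(n_slots - 1):
        state = rng.choice(len(STATES), p=T[state])
        out.append(STATES[state])
    return out


def _biased_matrix(T: np.ndarray, dominant: str, boost: float) -> np.ndarray:
    """Shift probability mass toward the dominant state and renormalize."""
    B = T.copy()
    B[:, STATE_INDEX[dominant]] += boost
    return B / B.sum(axis=1, keepdims=True)


def _dominant_trajectory(
    config: GeneratorConfig, dominant: str, rng: np.random.Generator
) -> list[str]:
    """Trajectory whose dominant-state share is at least config.dominant_fraction.

    The subject's chain is biased toward its assigned class and resampled a
    bounded number of times; if the share target is still unmet the deficit
    slots are overwritten in place (deterministically under the rng).
    """
    n = config.n_slots
    B = _biased_matrix(config.transition_matrix, dominant, config.dominant_boost)
    need = int(np.ceil(config.dominant_fraction * n))
    traj: list[str] = []
    for _ in range(20):
        traj = sample_state_trajectory(B, n, dominant, rng)
        if traj.count(dominant) >= need:
            return traj
    other = [i for i, s in enumerate(traj) if s != dominant]
    deficit = need - traj.count(dominant)
    for i in rng.permutation(other)[:deficit]:
        traj[i] = dominant
    return traj


# ---------------------------------------------------------------------------
# waveform synthesis


def _slot_of(t: float, tau: float, n_slots: int) -> int:
    return min(int(t // tau), n_slots - 1)


def _beat_times(
    duration_s: float,
    hr_bpm: float,
    jitter_sd_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """R-peak times: mean period 60/HR with additive Gaussian R-R jitter."""
    mean_rr = 60.0 / hr_bpm
    n_max = int(np.ceil(duration_s / mean_rr)) + 8
    rr = np.full(n_max, mean_rr)
    if jitter_sd_s > 0:
        rr += rng.normal(0.0, jitter_sd_s, size=n_max)
    rr = np.clip(rr, 0.3, None)  # refractory floor
    times = 0.35 + np.cumsum(np.concatenate([[0.0], rr[:-1]]))
    return times[times < duration_s - 0.05]


def _beat_times_piecewise(
    slot_states: list[str],
    tau: float,
    effects: dict[str, dict[str, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Beat times whose instantaneous rate follows the slot-state sequence."""
    duration = len(slot_states) * tau
    times: list[float] = []
    cursor = 0.35
    while cursor < duration - 0.05:
        times.append(cursor)
        s = slot_states[_slot_of(cursor, tau, len(slot_states))]
        rr = 60.0 / effects["heart_rate_bpm"][s]
        jit = effects["rr_jitter_sd_s"][s]
        if jit > 0:
            rr += rng.normal(0.0, jit)
        cursor += max(rr, 0.3)
    return np.array(times)

def _add_gaussians(
    out: np.ndarray, fs: float, centers: np.ndarray, width_s: float, amp: float | np.ndarray
) -> None:
    """Accumulate Gaussian bumps into ``out`` using local windows only."""
    half = int(np.ceil(4 * width_s * fs))
    amps = np.broadcast_to(np.asarray(amp, dtype=float), centers.shape)
    n = len(out)
    for c, a in zip(centers, amps):
        ci = int(round(c * fs))
        lo, hi = max(0, ci - half), min(n, ci + half + 1)
        if lo >= hi:
            continue
        t = np.arange(lo, hi) / fs - c
        out[lo:hi] += a * np.exp(-0.5 * (t / width_s) ** 2)


def _state_param(effects: dict[str, dict[str, float]], param: str, state: str) -> float:
    return effects[param][state]


def synthesize_ecg(
    state: str,
    duration_s: float,
    fs: float,
    effects: dict[str, dict[str, float]],
    seed,
    noise_sd: float = CHANNEL_NOISE_SD["ECG"],
    beat_times: np.ndarray | None = None,
) -> SynthSignal:
    """ECG from a sum-of-Gaussians P-QRS-T template.

    Beats repeat at the state's heart rate with Gaussian R-R jitter
    standing in for heart-rate variability.  Ground truth carries the
    exact P/Q/R/S/T wave times of every beat.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs < 100:
        raise ValueError("fs below 100 Hz cannot resolve the QRS complex")
    rng = _as_rng(seed)
    if beat_times is None:
        beat_times = _beat_times(
            duration_s,
            _state_param(effects, "heart_rate_bpm", state),
            _state_param(effects, "rr_jitter_sd_s", state),
            rng,
        )
    n = int(round(duration_s * fs))
    samples = np.zeros(n)
    wave_times: dict[str, np.ndarray] = {}
    for wave, (offset, width, amp) in ECG_WAVES.items():
        centers = beat_times + offset
        wave_times[wave] = centers
        _add_gaussians(samples, fs, centers, width, amp)
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, size=n)
    truth = {
        "r_times": beat_times.copy(),
        "wave_times": wave_times,
        "qt_s": ECG_WAVES["T"][0] - ECG_WAVES["Q"][0],
        "qrs_duration_s": ECG_WAVES["S"][0] - ECG_WAVES["Q"][0],
        "r_amplitude": ECG_WAVES["R"][2],
        "rs_ratio": abs(ECG_WAVES["R"][2] / ECG_WAVES["S"][2]),
    }
    return SynthSignal(samples, fs, truth)


def synthesize_bvp(
    state: str,
    duration_s: float,
    fs: float,
    effects: dict[str, dict[str, float]],
    seed,
    noise_sd: float = CHANNEL_NOISE_SD["BVP"],
    beat_times: np.ndarray | None = None,
    slot_states: list[str] | None = None,
    tau_seconds: float | None = None,
) -> SynthSignal:
    """Blood-volume pulse: systolic + diastolic Gaussians per beat.

    The pulse train is locked to the same beat times as the subject's ECG
    when ``beat_times`` is supplied.  The diastolic component amplitude is
    ``augmentation_index`` times the systolic amplitude, so the extractor
    can be checked by recovering that ratio.  With ``slot_states`` the
    amplitudes follow each beat's slot state instead of a constant state.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _as_rng(seed)
    if beat_times is None:
        beat_times = _beat_times(
            duration_s,
            _state_param(effects, "heart_rate_bpm", state),
            _state_param(effects, "rr_jitter_sd_s", state),
            rng,
        )
    if slot_states is not None:
        if tau_seconds is None:
            raise ValueError("slot_states requires tau_seconds")
        per_beat = [
            slot_states[_slot_of(t, tau_seconds, len(slot_states))] for t in beat_times
        ]
        sys_amp = np.array(
            [_state_param(effects, "pulse_amplitude", s) for s in per_beat]
        )
        dia_amp = sys_amp * np.array(
            [_state_param(effects, "augmentation_index", s) for s in per_beat]
        )
    else:
        sys_amp = np.full(len(beat_times), _state_param(effects, "pulse_amplitude", state))
        dia_amp = sys_amp * _state_param(effects, "augmentation_index", state)
    n = int(round(duration_s * fs))
    samples = np.zeros(n)
    m_times = beat_times + BVP_SYSTOLIC_OFFSET_S
    q_times = beat_times + BVP_DIASTOLIC_OFFSET_S
    has_dia = np.any(dia_amp > 0)
    _add_gaussians(samples, fs, m_times, BVP_SYSTOLIC_WIDTH_S, sys_amp)
    if has_dia:
        _add_gaussians(samples, fs, q_times, BVP_DIASTOLIC_WIDTH_S, dia_amp)
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, size=n)
    with np.errstate(divide="ignore", invalid="ignore"):
        aug = np.where(sys_amp > 0, dia_amp / np.where(sys_amp > 0, sys_amp, 1.0), np.nan)
    truth = {
        "foot_times": beat_times.copy(),
        "m_times": m_times,
        "q_times": q_times if has_dia else np.array([]),
        "systolic_amplitude": sys_amp,
        "diastolic_amplitude": dia_amp,
        "augmentation_index": aug,
        "mq_interval_s": BVP_DIASTOLIC_OFFSET_S - BVP_SYSTOLIC_OFFSET_S,
    }
    return SynthSignal(samples, fs, truth)


def _scr_shape(t: np.ndarray) -> np.ndarray:
    """Biexponential SCR kernel normalized to unit peak."""
    raw = np.exp(-t / SCR_DECAY_S) - np.exp(-t / SCR_RISE_S)
    t_peak = (
        SCR_RISE_S
        * SCR_DECAY_S
        / (SCR_DECAY_S - SCR_RISE_S)
        * np.log(SCR_DECAY_S / SCR_RISE_S)
    )
    peak = np.exp(-t_peak / SCR_DECAY_S) - np.exp(-t_peak / SCR_RISE_S)
    return np.where(t >= 0, raw / peak, 0.0)


def synthesize_eda(
    state: str,
    duration_s: float,
    fs: float,
    effects: dict[str, dict[str, float]],
    seed,
    noise_sd: float = CHANNEL_NOISE_SD["EDA"],
    slot_states: list[str] | None = None,
    tau_seconds: float | None = None,
) -> SynthSignal:
    """Electrodermal activity: tonic drift plus Poisson SCR events.

    The tonic skin conductance level and the SCR arrival rate both rise
    with arousal state.  With ``slot_states`` the inhomogeneous Poisson
    rate and the (smoothed) tonic level follow the slot sequence.  Event
    times and amplitudes are ground truth.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _as_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    if slot_states is not None:
        if tau_seconds is None:
            raise ValueError("slot_states requires tau_seconds")
        slot_idx = np.minimum((t // tau_seconds).astype(int), len(slot_states) - 1)
        tonic_per_slot = np.array(
            [_state_param(effects, "scl_tonic_us", s) for s in slot_states]
        )
        tonic_track = tonic_per_slot[slot_idx]
        # smooth tonic transitions over ~10 s so the level drifts, not steps
        width = max(1, int(10.0 * fs))
        kernel = np.ones(width) / width
        tonic_track = np.convolve(
            np.pad(tonic_track, (width, width), mode="edge"), kernel, mode="same"
        )[width:-width]
        rate_fn = lambda tt: _state_param(  # noqa: E731
            effects, "scr_rate_per_min",
            slot_states[_slot_of(tt, tau_seconds, len(slot_states))],
        )
        amp_fn = lambda tt: _state_param(  # noqa: E731
            effects, "scr_amplitude_us",
            slot_states[_slot_of(tt, tau_seconds, len(slot_states))],
        )
        max_rate = max(
            _state_param(effects, "scr_rate_per_min", s) for s in set(slot_states)
        )
    else:
        rate = _state_param(effects, "scr_rate_per_min", state)
        if rate < 0:
            raise ValueError("SCR rate must be non-negative")
        tonic_track = np.full(n, _state_param(effects, "scl_tonic_us", state))
        rate_fn = lambda tt: rate  # noqa: E731
        amp_fn = lambda tt: _state_param(effects, "scr_amplitude_us", state)  # noqa: E731
        max_rate = rate
    if max_rate < 0:
        raise ValueError("SCR rate must be non-negative")

    samples = tonic_track + 0.10 * np.sin(2 * np.pi * t / 300.0)

    # inhomogeneous Poisson arrivals by thinning at the maximum rate
    event_times: list[float] = []
    if max_rate > 0:
        max_per_s = max_rate / 60.0
        cursor = rng.exponential(1.0 / max_per_s)
        while cursor < duration_s - 1.0:
            if rng.random() < rate_fn(cursor) / max_rate:
                event_times.append(cursor)
            cursor += rng.exponential(1.0 / max_per_s)
    amplitudes = np.array(
        [
            max(0.08, rng.normal(amp_fn(t0), 0.3 * amp_fn(t0)))
            for t0 in event_times
        ]
    )
    for t0, amp in zip(event_times, amplitudes):
        i0 = int(t0 * fs)
        hi = min(n, i0 + int(6 * SCR_DECAY_S * fs))
        samples[i0:hi] += amp * _scr_shape(t[i0:hi] - t0)
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, size=n)
    truth = {
        "tonic_us": float(tonic_track.mean()),
        "event_times": np.array(event_times),
        "event_amplitudes": amplitudes,
    }
    return SynthSignal(samples, fs, truth)


def _emg_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to the surface-EMG band."""
    raw = rng.normal(0.0, 1.0, size=n)
    high = min(450.0, 0.45 * fs)
    sos = sps.butter(4, [20.0, high], btype="band", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, raw)
    rms = np.sqrt(np.mean(carrier**2))
    return carrier / rms if rms > 0 else carrier


def synthesize_emg(
    state: str,
    duration_s: float,
    fs: float,
    effects: dict[str, dict[str, float]],
    seed,
    noise_sd: float = CHANNEL_NOISE_SD["EMG"],
    rest_fraction: float = 0.05,
    gap_duration_s: float = 1.0,
    slot_states: list[str] | None = None,
    tau_seconds: float | None = None,
) -> SynthSignal:
    """Surface EMG: band-limited noise with an active/rest envelope.

    Sustained muscle tension (fewer, shorter rest gaps) marks higher
    arousal, so the gap schedule is state-dependent and returned as ground
    truth.  During a gap the envelope drops to ``rest_fraction`` of the
    active tone.  With ``slot_states`` the tone and the gap rate follow
    each slot's state.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _as_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    if slot_states is not None:
        if tau_seconds is None:
            raise ValueError("slot_states requires tau_seconds")
        slot_idx = np.minimum((t // tau_seconds).astype(int), len(slot_states) - 1)
        tone_track = np.array(
            [_state_param(effects, "emg_tone_mv", s) for s in slot_states]
        )[slot_idx]
        gaps: list[tuple[float, float]] = []
        for k, s in enumerate(slot_states):
            rate = _state_param(effects, "emg_gaps_per_min", s)
            if rate < 0:
                raise ValueError("gap rate must be non-negative")
            for _ in range(rng.poisson(rate * tau_seconds / 60.0)):
                dur = max(0.3, rng.normal(gap_duration_s, 0.2 * gap_duration_s))
                start = k * tau_seconds + rng.uniform(
                    0.0, max(tau_seconds - dur, 1e-6)
                )
                if all(start + dur < a or start > a + d for a, d in gaps):
                    gaps.append((start, dur))
        gaps.sort()
        mean_tone = float(tone_track.mean())
    else:
        tone = _state_param(effects, "emg_tone_mv", state)
        gaps_per_min = _state_param(effects, "emg_gaps_per_min", state)
        if gaps_per_min < 0:
            raise ValueError("gap rate must be non-negative")
        tone_track = np.full(n, tone)
        n_gaps = rng.poisson(gaps_per_min * duration_s / 60.0)
        gaps = []
        for _ in range(200):
            if len(gaps) >= n_gaps:
                break
            dur = max(0.3, rng.normal(gap_duration_s, 0.2 * gap_duration_s))
            start = rng.uniform(0.0, max(duration_s - dur, 1e-6))
            if all(start + dur < a or start > a + d for a, d in gaps):
                gaps.append((start, dur))
        gaps.sort()
        mean_tone = float(tone_track.mean())

    envelope = tone_track.copy()
    for start, dur in gaps:
        i0, i1 = int(start * fs), min(n, int((start + dur) * fs))
        envelope[i0:i1] *= rest_fraction
    samples = envelope * _emg_carrier(n, fs, rng)
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, size=n)
    truth = {
        "gap_intervals": gaps,
        "gap_count": len(gaps),
        "tone_mv": mean_tone,
        "rest_level_mv": mean_tone * rest_fraction,
    }
    return SynthSignal(samples, fs, truth)


# ---------------------------------------------------------------------------
# psychometric scores and history


def sample_scale_scores(state: str, config: GeneratorConfig, seed) -> dict[str, int]:
    """Draw one integer score per instrument from a truncated rounded normal.

    Scores are clamped to each instrument's published range.  The HRSD
    suicide item (item 3) is drawn from the score set mapped to the state
    label, so the label definition and the questionnaire stay consistent.
    """
    rng = _as_rng(seed)
    scores: dict[str, int] = {}
    for inst, by_state in config.scale_score_means.items():
        mean, sd = by_state[state]
        lo, hi = SCALE_RANGES[inst]
        value = mean if sd == 0 else rng.normal(mean, sd)
        scores[inst] = int(np.clip(round(value), lo, hi))
    scores["HRSD_item3"] = int(rng.choice(HRSD_ITEM3_MAPPING[state]))
    return scores


def sample_history(state: str, config: GeneratorConfig, seed) -> dict[str, bool]:
    rng = _as_rng(seed)
    return {
        flag: bool(rng.random() < by_state[state])
        for flag, by_state in config.history_probs.items()
    }


# ---------------------------------------------------------------------------
# cohort assembly


def _class_labels(config: GeneratorConfig) -> list[str]:
    labels: list[str] = []
    for s in ("E", "A", "N"):
        labels.extend([s] * config.class_counts.get(s, 0))
    return labels


def generate_cohort(config: GeneratorConfig) -> list[RawRecording]:
    """Generate the full labelled cohort described by ``config``.

    Deterministic for a fixed config (including seed): every subject and
    channel draws from its own child stream of the cohort seed.
    """
    config.validate()
    effects = config.effective_effects()
    duration = config.n_slots * config.tau_seconds
    recordings: list[RawRecording] = []
    for idx, dominant in enumerate(_class_labels(config)):
        sub_rng = {
            key: np.random.default_rng([config.seed, idx, code])
            for code, key in enumerate(
                ["traj", "ECG", "BVP", "EDA", "EMG", "scores", "history"]
            )
        }
        states = _dominant_trajectory(config, dominant, sub_rng["traj"])
        tau = config.tau_seconds
        noise = config.noise_sd
        beats = _beat_times_piecewise(states, tau, effects, sub_rng["ECG"])
        ecg = synthesize_ecg(
            dominant, duration, config.fs_per_sensor["ECG"], effects,
            sub_rng["ECG"], noise_sd=noise * CHANNEL_NOISE_SD["ECG"],
            beat_times=beats,
        )
        bvp = synthesize_bvp(
            dominant, duration, config.fs_per_sensor["BVP"], effects,
            sub_rng["BVP"], noise_sd=noise * CHANNEL_NOISE_SD["BVP"],
            beat_times=beats, slot_states=states, tau_seconds=tau,
        )
        eda = synthesize_eda(
            dominant, duration, config.fs_per_sensor["EDA"], effects,
            sub_rng["EDA"], noise_sd=noise * CHANNEL_NOISE_SD["EDA"],
            slot_states=states, tau_seconds=tau,
        )
        emg = synthesize_emg(
            dominant, duration, config.fs_per_sensor["EMG"], effects,
            sub_rng["EMG"], noise_sd=noise * CHANNEL_NOISE_SD["EMG"],
            slot_states=states, tau_seconds=tau,
        )
        rec = RawRecording(
            subject_id=f"S{idx:03d}",
            channels={
                "ECG": ecg.samples, "BVP": bvp.samples,
                "EDA": eda.samples, "EMG": emg.samples,
            },
            fs=dict(config.fs_per_sensor),
            scale_scores=sample_scale_scores(dominant, config, sub_rng["scores"]),
            history=sample_history(dominant, config, sub_rng["history"]),
            true_states=states,
            tau_seconds=config.tau_seconds,
            dominant_label=dominant,
            truth={"ECG": ecg.truth, "BVP": bvp.truth, "EDA": eda.truth, "EMG": emg.truth},
        )
        rec.validate()
        recordings.append(rec)
    return recordings
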