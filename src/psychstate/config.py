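"""Cohort generator configuration.

:class:`GeneratorConfig` collects every knob of the synthetic cohort: cohort
composition, slot/window geometry, sensor sampling rates, the latent Markov
dynamics, per-state physiological effects, and per-state rating-scale score
distributions.  Defaults describe a 55-subject cohort (14 Emergency,
16 Atypical, 25 Normal) observed in 15-second slots over one 15-minute
prediction window, with wearable-typical sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml

from .states import STATES

# ---------------------------------------------------------------------------
# rating-scale instruments: published score ranges

SCALE_RANGES: dict[str, tuple[int, int]] = {
    "BDI": (0, 63),
    "SSI": (0, 38),
    "BHS": (0, 20),
    "SCST": (0, 40),
    "BIS": (30, 120),
    "BPAQ": (29, 145),
    "BDHI": (0, 75),
    "PHQ9": (0, 27),
    "GAD7": (0, 21),
    "HRSD": (0, 52),
    "HRSD_item3": (0, 4),
}

# per-state (mean, sd) for each instrument; higher scores = more symptomatic
DEFAULT_SCALE_SCORE_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "BDI": {"N": (8, 4), "A": (22, 6), "E": (38, 8)},
    "SSI": {"N": (2, 2), "A": (10, 4), "E": (24, 6)},
    "BHS": {"N": (3, 2), "A": (9, 3), "E": (15, 3)},
    "SCST": {"N": (10, 4), "A": (20, 5), "E": (30, 5)},
    "BIS": {"N": (55, 8), "A": (70, 10), "E": (85, 10)},
    "BPAQ": {"N": (55, 10), "A": (80, 12), "E": (105, 12)},
    "BDHI": {"N": (15, 6), "A": (30, 8), "E": (50, 8)},
    "PHQ9": {"N": (4, 2), "A": (12, 4), "E": (21, 4)},
    "GAD7": {"N": (3, 2), "A": (10, 3), "E": (17, 3)},
    "HRSD": {"N": (5, 3), "A": (15, 4), "E": (30, 5)},
}

#: HRSD suicide item (item 3) scores compatible with each state label
HRSD_ITEM3_MAPPING: dict[str, tuple[int, ...]] = {
    "N": (0,),
    "A": (1, 2),
    "E": (3, 4),
}

# ---------------------------------------------------------------------------
# per-state signal effects.  Arousal raises heart rate, suppresses
# beat-to-beat variability, multiplies skin-conductance responses, raises
# muscle tone and shortens EMG rest gaps, and attenuates the peripheral
# pulse (vasoconstriction).

DEFAULT_STATE_EFFECTS: dict[str, dict[str, float]] = {
    "heart_rate_bpm": {"N": 65.0, "A": 76.0, "E": 90.0},
    "rr_jitter_sd_s": {"N": 0.050, "A": 0.038, "E": 0.024},
    "scr_rate_per_min": {"N": 2.0, "A": 4.0, "E": 8.0},
    "scl_tonic_us": {"N": 2.0, "A": 3.0, "E": 4.5},
    "scr_amplitude_us": {"N": 0.25, "A": 0.40, "E": 0.60},
    "emg_tone_mv": {"N": 0.050, "A": 0.080, "E": 0.125},
    "emg_gaps_per_min": {"N": 6.0, "A": 3.0, "E": 1.0},
    "pulse_amplitude": {"N": 1.00, "A": 0.88, "E": 0.72},
    "augmentation_index": {"N": 0.50, "A": 0.44, "E": 0.38},
}

# probability each history flag is set, per state
DEFAULT_HISTORY_PROBS: dict[str, dict[str, float]] = {
    "family_suicide_history": {"N": 0.05, "A": 0.20, "E": 0.45},
    "medical_history": {"N": 0.20, "A": 0.45, "E": 0.65},
    "personal_trait": {"N": 0.15, "A": 0.45, "E": 0.70},
}

DEFAULT_TRANSITION = (
    (0.92, 0.06, 0.02),
    (0.08, 0.86, 0.06),
    (0.04, 0.10, 0.86),
)

DEFAULT_FS = {"ECG": 250.0, "BVP": 64.0, "EDA": 16.0, "EMG": 1000.0}


def _scaled_effects(
    effects: dict[str, dict[str, float]], scale: float
) -> dict[str, dict[str, float]]:
    """Scale per-state offsets away from the Normal baseline by ``scale``."""
    out: dict[str, dict[str, float]] = {}
    for param, by_state in effects.items():
        base = by_state["N"]
        # every physiological parameter here is non-negative by nature
        out[param] = {
            s: max(0.0, base + scale * (v - base)) for s, v in by_state.items()
        }
    return out


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Parameters
    ----------
    n_subjects:
        Cohort size; must equal the sum of ``class_counts``.
    class_counts:
        Number of subjects whose dominant state is E / A / N.
    tau_seconds:
        Duration of one observation slot (the resolution at which the
        latent state is labelled and features are extracted).
    window_w:
        Number of slots per prediction window; a window spans
        ``window_w * tau_seconds`` seconds.
    duration_s:
        Recording length per subject.  The default equals one prediction
        window (15 min), so the default cohort yields exactly one
        window-level prediction per subject.
    fs_per_sensor:
        Sampling rate in Hz for each of the four channels.
    transition_matrix:
        Row-stochastic 3x3 latent dynamics over (N, A, E).
    dominant_boost / dominant_fraction:
        Per-subject chains are biased toward the subject's assigned class
        and resampled until at least ``dominant_fraction`` of slots carry
        the class label.
    effect_scale:
        Multiplier on all state-effect offsets relative to the Normal
        baseline; 1.0 is the nominal cohort, 0 removes all class signal.
    noise_sd:
        Global multiplier on additive measurement noise per channel.
    """

    n_subjects: int = 55
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"E": 14, "A": 16, "N": 25}
    )
    tau_seconds: float = 15.0
    window_w: int = 60
    duration_s: float = 900.0
    fs_per_sensor: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FS))
    transition_matrix: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_TRANSITION)
    )
    dominant_boost: float = 0.30
    dominant_fraction: float = 0.60
    state_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STATE_EFFECTS.items()}
    )
    effect_scale: float = 1.0
    scale_score_means: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCALE_SCORE_MEANS.items()}
    )
    history_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HISTORY_PROBS.items()}
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        T = self.transition_matrix
        if T.shape != (len(STATES), len(STATES)):
            raise ValueError(f"transition_matrix must be {len(STATES)}x{len(STATES)}")
        if np.any(T < 0):
            raise ValueError("transition_matrix entries must be non-negative")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_matrix rows must sum to 1 (tol 1e-9)")
        if sum(self.class_counts.get(s, 0) for s in STATES) != self.n_subjects:
            raise ValueError("class_counts must sum to n_subjects")
        if self.tau_seconds <= 0:
            raise ValueError("tau_seconds must be positive")
        if self.window_w < 1:
            raise ValueError("window_w must be >= 1")
        if self.duration_s < self.tau_seconds:
            raise ValueError("duration_s must cover at least one slot")
        if not 0.0 < self.dominant_fraction <= 1.0:
            raise ValueError("dominant_fraction must be in (0, 1]")
        for name, fs in self.fs_per_sensor.items():
            if fs <= 0:
                raise ValueError(f"sampling rate for {name} must be positive")

    # -- derived quantities -------------------------------------------------
    @property
    def n_slots(self) -> int:
        return int(self.duration_s // self.tau_seconds)

    def effective_effects(self) -> dict[str, dict[str, float]]:
        """State effects after applying :attr:`effect_scale`."""
        return _scaled_effects(self.state_effects, self.effect_scale)

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["transition_matrix"] = self.transition_matrix.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown GeneratorConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "scale_score_means" in d:
            d["scale_score_means"] = {
                inst: {s: tuple(v) for s, v in by_state.items()}
                for inst, by_state in d["scale_score_means"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
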