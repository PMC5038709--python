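"""Window-level state prediction by a three-candidate ensemble.

A decoded slot-level state sequence is summarized into one prediction per
observation window by majority vote over three candidates:

* LRL — the state holding the Longest Run Length (maximal consecutive
  run); run-length ties resolve to the most recent tied run;
* HFC — the state with the Highest Frequency Count over the whole
  sequence; count ties resolve to the clinically more severe state;
* MRS — the Most Recent State (last slot of the window).

A 1-1-1 vote splits to the most severe candidate, so an emergency signal
is never out-voted by recency alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import HMMParams, viterbi_decode
from .states import STATES, most_severe, validate_states

__all__ = [
    "PredictionResult",
    "longest_run_candidate",
    "highest_frequency_candidate",
    "most_recent_state",
    "majority_vote",
    "predict_window",
]


@dataclass
class PredictionResult:
    """Full audit trail of one window prediction."""

    decoded: list[str]
    lrl_candidate: tuple[str, int]
    hfc_candidate: tuple[str, int]
    mrs_candidate: str
    ensemble: tuple[str, str, str]
    predicted: str
    vote_counts: dict[str, int]
    log_probability: float = np.nan
    floored: bool = False

    def class_scores(self) -> dict[str, float]:
        """Per-class posterior proxy: vote share scaled by the per-slot
        geometric-mean path probability."""
        T = max(len(self.decoded), 1)
        conf = float(np.exp(np.clip(self.log_probability / T, -700, 0)))
        return {s: self.vote_counts.get(s, 0) / 3.0 * conf for s in STATES}


def _runs(q: list[str]) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for s in q:
        if runs and runs[-1][0] == s:
            runs[-1] = (s, runs[-1][1] + 1)
        else:
            runs.append((s, 1))
    return runs


def longest_run_candidate(q) -> tuple[str, int]:
    """State with the longest consecutive run; ties go to the latest run."""
    q = validate_states(q)
    if not q:
        raise ValueError("empty state sequence")
    best_state, best_len = q[0], 0
    for state, length in _runs(q):
        if length >= best_len:  # >= : most recent tied run wins
            best_state, best_len = state, length
    return best_state, best_len


def highest_frequency_candidate(q) -> tuple[str, int]:
    """State occurring most often; count ties go to the more severe state."""
    q = validate_states(q)
    if not q:
        raise ValueError("empty state sequence")
    counts = {s: q.count(s) for s in STATES}
    top = max(counts.values())
    state = most_severe([s for s, c in counts.items() if c == top])
    return state, top


def most_recent_state(q) -> str:
    """The state of the last (most recent) slot."""
    q = validate_states(q)
    if not q:
        raise ValueError("empty state sequence")
    return q[-1]


def majority_vote(ensemble) -> tuple[str, int]:
    """State with the maximum multiplicity; a 1-1-1 split is resolved to
    the most severe candidate."""
    ensemble = validate_states(ensemble)
    if len(ensemble) != 3:
        raise ValueError("ensemble must hold exactly three candidate states")
    counts = {s: ensemble.count(s) for s in set(ensemble)}
    top = max(counts.values())
    winner = most_severe([s for s, c in counts.items() if c == top])
    return winner, top


def summarize_sequence(
    decoded: list[str], log_probability: float = np.nan, floored: bool = False
) -> PredictionResult:
    """Apply the candidate extractors and the vote to a decoded sequence."""
    lrl = longest_run_candidate(decoded)
    hfc = highest_frequency_candidate(decoded)
    mrs = most_recent_state(decoded)
    ensemble = (lrl[0], hfc[0], mrs)
    predicted, _ = majority_vote(ensemble)
    votes = {s: ensemble.count(s) for s in STATES}
    return PredictionResult(
        decoded=list(decoded),
        lrl_candidate=lrl,
        hfc_candidate=hfc,
        mrs_candidate=mrs,
        ensemble=ensemble,
        predicted=predicted,
        vote_counts=votes,
        log_probability=log_probability,
        floored=floored,
    )


def predict_window(params: HMMParams, obs: np.ndarray) -> PredictionResult:
    """Decode one observation window and fuse the three candidates."""
    decoded, logp, floored = viterbi_decode(params, obs)
    return summarize_sequence(decoded, logp, floored)
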