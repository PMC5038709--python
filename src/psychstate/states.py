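"""Psychiatric state alphabet.

Three hidden states are modelled: Normal (N), Atypical (A) and Emergency (E).
State order everywhere in the package is ``N < A < E``; this fixes both the
index convention of probability vectors/matrices and the deterministic
tie-break used by the Viterbi decoder (lowest index wins).  Clinical severity
runs the other way, ``E > A > N``, and is used to break ties where a
conservative choice (prefer flagging an emergency) is appropriate.
"""

from __future__ import annotations

STATES: tuple[str, ...] = ("N", "A", "E")
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

#: severity rank, higher = more severe
SEVERITY: dict[str, int] = {"N": 0, "A": 1, "E": 2}


def validate_states(seq) -> list[str]:
    """Check every label is in the state alphabet; return as a list."""
    seq = list(seq)
    for s in seq:
        if s not in STATE_INDEX:
            raise ValueError(f"unknown state label {s!r}; expected one of {STATES}")
    return seq


def most_severe(states) -> str:
    """Return the clinically most severe state among ``states``."""
    states = validate_states(states)
    if not states:
        raise ValueError("empty state collection")
    return max(states, key=lambda s: SEVERITY[s])


def dominant_state(seq) -> str:
    """Most frequent state in ``seq``; frequency ties resolve to higher severity."""
    seq = validate_states(seq)
    if not seq:
        raise ValueError("empty state sequence")
    counts = {s: 0 for s in STATES}
    for s in seq:
        counts[s] += 1
    best = max(counts.values())
    return most_severe([s for s, c in counts.items() if c == best])
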