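"""On-disk cohort layout.

One directory per subject containing:

* ``signals.csv`` — long format with columns channel, t_seconds, value;
* ``meta.json`` — per-channel sampling rates, scale scores, history
  flags, slot duration and dominant label;
* ``states.csv`` — slot_index, state (one of N/A/E).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import RawRecording

__all__ = ["write_cohort", "read_cohort"]


def write_cohort(recordings: list[RawRecording], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        sub = out / rec.subject_id
        sub.mkdir(exist_ok=True)
        frames = []
        for channel, samples in sorted(rec.channels.items()):
            fs = rec.fs[channel]
            frames.append(
                pd.DataFrame(
                    {
                        "channel": channel,
                        "t_seconds": np.arange(len(samples)) / fs,
                        "value": samples,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(sub / "signals.csv", index=False)
        meta = {
            "subject_id": rec.subject_id,
            "fs": rec.fs,
            "scale_scores": rec.scale_scores,
            "history": rec.history,
            "tau_seconds": rec.tau_seconds,
            "dominant_label": rec.dominant_label,
        }
        with open(sub / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        pd.DataFrame(
            {"slot_index": range(rec.n_slots), "state": rec.true_states}
        ).to_csv(sub / "states.csv", index=False)


def read_cohort(in_dir: str | Path) -> list[RawRecording]:
    root = Path(in_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"cohort directory not found: {root}")
    recordings = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        meta_path = sub / "meta.json"
        if not meta_path.exists():
            continue
        with open(meta_path) as fh:
            meta = json.load(fh)
        signals = pd.read_csv(sub / "signals.csv")
        channels = {
            ch: grp.sort_values("t_seconds")["value"].to_numpy(dtype=float)
            for ch, grp in signals.groupby("channel")
        }
        states = pd.read_csv(sub / "states.csv").sort_values("slot_index")
        recordings.append(
            RawRecording(
                subject_id=meta["subject_id"],
                channels=channels,
                fs={k: float(v) for k, v in meta["fs"].items()},
                scale_scores={k: int(v) for k, v in meta["scale_scores"].items()},
                history={k: bool(v) for k, v in meta["history"].items()},
                true_states=states["state"].tolist(),
                tau_seconds=float(meta["tau_seconds"]),
                dominant_label=meta.get("dominant_label", ""),
            )
        )
    if not recordings:
        raise FileNotFoundError(f"no subject directories under {root}")
    return recordings
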