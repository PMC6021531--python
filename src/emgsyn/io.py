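"""Reading and writing simulated sessions: delimited trial files + manifest."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import RawTrial
from .simulate import GroundTruth

__all__ = ["save_session", "load_session"]


def save_session(
    trials: list[RawTrial],
    out_dir: str | Path,
    ground_truth: GroundTruth | None = None,
    extra: dict | None = None,
) -> Path:
    """Write one CSV per trial (time + channel columns) and a YAML manifest.

    The manifest records sampling rate, channel names, per-trial direction
    vectors and, when given, the full planted ground truth (for test
    oracles).  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "sampling_rate": float(trials[0].sampling_rate),
        "channel_names": list(trials[0].channel_names or []),
        "trials": [],
    }
    for i, t in enumerate(trials):
        name = f"trial_{i:03d}.csv"
        time = np.arange(t.n_samples) / t.sampling_rate
        df = pd.DataFrame(t.signal, columns=list(t.channel_names))
        df.insert(0, "time", time)
        df.to_csv(out / name, index=False, float_format="%.6g")
        manifest["trials"].append(
            {
                "file": name,
                "direction": None if t.direction is None else [float(v) for v in t.direction],
            }
        )
    if ground_truth is not None:
        manifest["ground_truth"] = {
            "weights": ground_truth.weights.tolist(),
            "preferred_directions": ground_truth.preferred_directions.tolist(),
            "tuning_gain": ground_truth.tuning_gain.tolist(),
            "fatigue_decay": ground_truth.fatigue_decay.tolist(),
            "spectral_compression": float(ground_truth.spectral_compression),
        }
    if extra:
        manifest.update(extra)
    path = out / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def load_session(session_dir: str | Path) -> tuple[list[RawTrial], dict]:
    """Load trials and manifest written by :func:`save_session`."""
    session = Path(session_dir)
    with open(session / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    fs = manifest["sampling_rate"]
    names = manifest["channel_names"]
    trials = []
    for entry in manifest["trials"]:
        df = pd.read_csv(session / entry["file"])
        direction = entry.get("direction")
        trials.append(
            RawTrial(
                signal=df[names].to_numpy(),
                sampling_rate=fs,
                channel_names=names,
                direction=None if direction is None else np.asarray(direction, dtype=float),
            )
        )
    return trials, manifest
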