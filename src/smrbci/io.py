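"""Serialization: compressed columnar recordings, trial tables, ground
truth sidecars, YAML configs, and optional EDF/BDF reading through MNE.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .containers import EEGRecording, TrialTable
from .synthetic import GroundTruth, SimulationConfig

__all__ = ["save_recording", "load_recording", "save_trials", "load_trials",
           "save_ground_truth", "save_config", "load_config", "read_edf"]


def save_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a compressed .npz with a JSON metadata entry."""
    np.savez_compressed(
        Path(path), data=rec.data, rate=np.array(rec.rate),
        channel_labels=np.array(rec.channel_labels, dtype=object),
        meta=np.frombuffer(json.dumps(rec.meta, default=str).encode(),
                           dtype=np.uint8))


def load_recording(path: str | Path) -> EEGRecording:
    with np.load(Path(path), allow_pickle=True) as z:
        meta = json.loads(bytes(z["meta"]).decode()) if "meta" in z else {}
        return EEGRecording(z["data"], float(z["rate"]),
                            [str(c) for c in z["channel_labels"]], meta)


def save_trials(trials: TrialTable, path: str | Path) -> None:
    trials.to_csv(Path(path), index=False)


def load_trials(path: str | Path) -> TrialTable:
    import pandas as pd

    return TrialTable(pd.read_csv(Path(path)))


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """JSON sidecar with the programmed trajectories and event log."""
    d = {"run_index": truth.run_index, "separability": truth.separability,
         "drift_power": truth.drift_power,
         "drift_rotation": truth.drift_rotation,
         "blink_events": [list(e) for e in truth.blink_events],
         "trials": truth.trials.to_dict(orient="records")}
    Path(path).write_text(json.dumps(d, indent=2))


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """YAML dump of the scalar configuration fields (callables are noted
    by name only; reload them programmatically)."""
    d = {}
    for f in dataclasses.fields(config):
        val = getattr(config, f.name)
        if callable(val):
            d[f.name] = f"<callable {getattr(val, '__name__', 'fn')}>"
        else:
            d[f.name] = val
    Path(path).write_text(yaml.safe_dump(d, default_flow_style=None))


def load_config(path: str | Path, **overrides) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    d = {k: v for k, v in d.items()
         if not (isinstance(v, str) and v.startswith("<callable"))}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    clean = {}
    for k, v in d.items():
        if k not in known:
            continue
        if isinstance(v, list) and k in ("trial_duration", "inter_trial"):
            v = tuple(v)
        if k == "channel_topography" and isinstance(v, dict):
            v = {c: [tuple(t) for t in feats] for c, feats in v.items()}
        clean[k] = v
    clean.update(overrides)
    return SimulationConfig(**clean)


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/BDF file through MNE (optional dependency)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional path
        raise ImportError("reading EDF/BDF requires the 'mne' package") from err
    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data.T, float(raw.info["sfreq"]),
                        list(raw.ch_names), {"source": str(path)})
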