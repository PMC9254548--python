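"""The 14-channel sensorimotor montage and its Laplacian neighborhoods.

Neighbor sets are the orthogonal (cross-shaped) nearest neighbors on the
10-20 grid restricted to the 14 recorded channels; edge channels use
whatever orthogonal neighbors exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEG_CHANNELS", "EOG_CHANNELS", "Montage", "default_montage",
           "channel_positions"]

EEG_CHANNELS = ["Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
                "C3", "C1", "Cz", "C2", "C4", "CP1", "CPz", "CP2"]
EOG_CHANNELS = ["EOG_Fp1", "EOG_Fp2"]

# (x, y) grid coordinates; x lateral (left negative), y anterior positive
_POSITIONS = {
    "Fz": (0.0, 2.0),
    "FC3": (-1.5, 1.0), "FC1": (-0.5, 1.0), "FCz": (0.0, 1.0),
    "FC2": (0.5, 1.0), "FC4": (1.5, 1.0),
    "C3": (-1.5, 0.0), "C1": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C2": (0.5, 0.0), "C4": (1.5, 0.0),
    "CP1": (-0.5, -1.0), "CPz": (0.0, -1.0), "CP2": (0.5, -1.0),
}

_NEIGHBORS = {
    "Fz": ["FCz"],
    "FC3": ["FC1", "C3"],
    "FC1": ["FC3", "FCz", "C1"],
    "FCz": ["Fz", "FC1", "FC2", "Cz"],
    "FC2": ["FCz", "FC4", "C2"],
    "FC4": ["FC2", "C4"],
    "C3": ["FC3", "C1"],
    "C1": ["C3", "Cz", "FC1", "CP1"],
    "Cz": ["C1", "C2", "FCz", "CPz"],
    "C2": ["Cz", "C4", "FC2", "CP2"],
    "C4": ["C2", "FC4"],
    "CP1": ["C1", "CPz"],
    "CPz": ["CP1", "CP2", "Cz"],
    "CP2": ["CPz", "C2"],
}


def channel_positions(labels: list[str] | None = None) -> np.ndarray:
    """Grid coordinates, (n, 2), for the requested EEG labels."""
    labels = EEG_CHANNELS if labels is None else labels
    return np.array([_POSITIONS[c] for c in labels], dtype=float)


@dataclass
class Montage:
    """Per-channel neighbor lists used by the Laplacian spatial filter."""

    neighbors: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _NEIGHBORS.items()})

    def __post_init__(self) -> None:
        chans = set(self.neighbors)
        for ch, nbrs in self.neighbors.items():
            for nb in nbrs:
                if nb not in chans:
                    raise ValueError(f"neighbor {nb} of {ch} not in montage")
                if ch not in self.neighbors[nb]:
                    raise ValueError(
                        f"neighbor relation not symmetric: {ch}<->{nb}")

    @property
    def channels(self) -> list[str]:
        return list(self.neighbors)


def default_montage() -> Montage:
    return Montage()
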