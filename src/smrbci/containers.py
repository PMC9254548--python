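"""In-memory containers shared across the pipeline.

``EEGRecording`` holds a continuous multichannel segment (time x channel,
microvolts) together with its sampling rate, channel labels and free-form
session metadata.  ``PSDFrame`` holds the sliding-window Welch spectra the
decoder and the channels'-domain learning metrics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["EEGRecording", "PSDFrame", "TrialTable"]

#: canonical class labels (both-hands / both-feet motor imagery)
CLASSES = ("both_hands", "both_feet")


@dataclass
class EEGRecording:
    """Continuous EEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal in microvolts.
    rate : float
        Sampling rate in Hz (512 in the reference setup).
    channel_labels : list of str
        10-20 labels, EOG channels included at the end when present.
    meta : dict
        Session date, run index, run type, etc.
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in recording") from err

    def get(self, labels: list[str]) -> np.ndarray:
        """Column view for the requested channels (samples x len(labels))."""
        idx = [self.channel_index(c) for c in labels]
        return self.data[:, idx]

    def select(self, labels: list[str]) -> "EEGRecording":
        return EEGRecording(self.get(labels).copy(), self.rate, list(labels),
                            dict(self.meta))

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.rate,
                            list(self.channel_labels), dict(self.meta))


class TrialTable(pd.DataFrame):
    """Trial metadata: one row per cue with columns
    ``cue_onset`` (s), ``task_onset`` (s), ``trial_end`` (s), ``label``.

    A plain DataFrame subclass so pandas I/O and indexing behave as usual.
    """

    @property
    def _constructor(self):
        return TrialTable


@dataclass
class PSDFrame:
    """Sliding-window Welch spectra.

    ``power`` is (n_windows, n_channels, n_bins) with non-negative entries;
    ``freqs`` are the one-sided bin centers on a 2 Hz grid; ``times`` are
    window *start* times in seconds; ``labels`` holds the class label of
    windows fully inside a task interval (``None`` elsewhere);
    ``artifact_mask`` is True for windows overlapping an EOG suppression
    interval (those windows are excluded from every downstream metric).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    labels: np.ndarray | None = None
    artifact_mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be (windows, channels, bins)")
        if self.power.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match labels")
        if self.power.shape[2] != self.freqs.size:
            raise ValueError("frequency axis does not match bins")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.n_windows, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)

    @property
    def n_windows(self) -> int:
        return self.power.shape[0]

    def clean(self) -> "PSDFrame":
        """Frame restricted to artifact-free windows."""
        keep = ~self.artifact_mask
        return PSDFrame(
            self.power[keep], self.freqs, self.times[keep],
            list(self.channel_labels),
            None if self.labels is None else self.labels[keep],
            np.zeros(int(keep.sum()), dtype=bool), dict(self.meta))

    def labelled(self, klass: str | None = None) -> "PSDFrame":
        """Artifact-free windows carrying a class label (optionally one class)."""
        if self.labels is None:
            raise ValueError("frame has no labels")
        keep = ~self.artifact_mask
        if klass is None:
            keep &= np.array([l is not None for l in self.labels])
        else:
            keep &= np.array([l == klass for l in self.labels])
        return PSDFrame(
            self.power[keep], self.freqs, self.times[keep],
            list(self.channel_labels), self.labels[keep],
            np.zeros(int(keep.sum()), dtype=bool), dict(self.meta))
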