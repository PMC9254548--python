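"""Spatial filtering, band-pass filtering and sliding-window Welch spectra.

Mirrors the online pipeline: Laplacian re-referencing with the adjacent
electrodes of the 14-channel sensorimotor montage, then 1 s Hamming windows
sliding every 62.5 ms, each summarized by a one-sided Welch PSD on a 2 Hz
frequency grid (256-sample sub-segments with 50% overlap at 512 Hz).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .containers import EEGRecording, PSDFrame, TrialTable
from .montage import Montage, default_montage

__all__ = ["laplacian_filter", "sliding_windows", "window_view", "welch_psd",
           "bandpass", "compute_psd_frame", "MU_BAND", "BETA_BAND"]

MU_BAND = (8.0, 12.0)
BETA_BAND = (16.0, 26.0)
BANDS_DEFAULT = {"mu": MU_BAND, "beta": BETA_BAND}

WINDOW_S = 1.0
HOP_S = 0.0625


def laplacian_filter(rec: EEGRecording, montage: Montage | None = None
                     ) -> EEGRecording:
    """Subtract from each montage channel the mean of its neighbors.

    Channels absent from the montage (e.g. EOG) and channels with an empty
    neighbor list pass through unchanged.  Raises ``KeyError`` when a
    montage channel is missing from the recording.
    """
    montage = montage or default_montage()
    out = rec.data.copy()
    idx = {c: rec.channel_index(c) for c in montage.channels}
    for ch, nbrs in montage.neighbors.items():
        if not nbrs:
            continue
        nb_idx = [idx[n] for n in nbrs]
        out[:, idx[ch]] = rec.data[:, idx[ch]] - rec.data[:, nb_idx].mean(axis=1)
    return EEGRecording(out, rec.rate, list(rec.channel_labels), dict(rec.meta))


def sliding_windows(n_samples: int, rate: float, length: float = WINDOW_S,
                    hop: float = HOP_S) -> np.ndarray:
    """Start indices of fully-contained windows.

    The count follows floor((duration - length)/hop) + 1; an empty array is
    returned when the segment is shorter than one window.
    """
    win = int(round(length * rate))
    step = int(round(hop * rate))
    if n_samples < win:
        return np.array([], dtype=int)
    n = (n_samples - win) // step + 1
    return np.arange(n) * step


def window_view(data: np.ndarray, rate: float, length: float = WINDOW_S,
                hop: float = HOP_S) -> tuple[np.ndarray, np.ndarray]:
    """(n_windows, win_samples, n_channels) strided view plus start times."""
    win = int(round(length * rate))
    step = int(round(hop * rate))
    starts = sliding_windows(data.shape[0], rate, length, hop)
    if starts.size == 0:
        return np.empty((0, win, data.shape[1])), np.array([])
    view = sliding_window_view(data, win, axis=0)[::step]  # (n, ch, win)
    view = np.swapaxes(view[: starts.size], 1, 2)
    return view, starts / rate


def welch_psd(window: np.ndarray, rate: float, *,
              detrend: str = "constant") -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD at 2 Hz resolution.

    ``window`` is (..., n_samples, n_channels); sub-segments are rate/2
    samples with 50% overlap under a Hamming taper, so the bin spacing is
    exactly 2 Hz.  Returns (freqs, power) with power shaped
    (..., n_channels, n_bins).
    """
    x = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in window")
    nperseg = int(round(rate / 2))
    freqs, pxx = sps.welch(np.moveaxis(x, -2, -1), fs=rate,
                           window="hamming", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend=detrend, axis=-1)
    return freqs, pxx


def bandpass(rec: EEGRecording, band: tuple[float, float], order: int = 4,
             channels: list[str] | None = None) -> EEGRecording:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    lo, hi = band
    if not (0 < lo < hi < rec.rate / 2):
        raise ValueError(f"invalid band {band} at rate {rec.rate}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.rate,
                     output="sos")
    out = rec.data.copy()
    cols = (slice(None) if channels is None
            else [rec.channel_index(c) for c in channels])
    out[:, cols] = sps.sosfiltfilt(sos, rec.data[:, cols], axis=0)
    return EEGRecording(out, rec.rate, list(rec.channel_labels), dict(rec.meta))


def _window_labels(times: np.ndarray, length: float,
                   trials: TrialTable | None) -> np.ndarray | None:
    """Class label for windows fully inside a task interval, else None."""
    if trials is None:
        return None
    labels = np.full(times.size, None, dtype=object)
    ends = times + length
    for _, tr in trials.iterrows():
        inside = (times >= tr["task_onset"]) & (ends <= tr["trial_end"])
        labels[inside] = tr["label"]
    return labels


def compute_psd_frame(rec: EEGRecording, *, montage: Montage | None = None,
                      trials: TrialTable | None = None,
                      length: float = WINDOW_S, hop: float = HOP_S,
                      apply_laplacian: bool = True,
                      channels: list[str] | None = None,
                      artifact_mask: np.ndarray | None = None) -> PSDFrame:
    """End-to-end feature extraction for one recording.

    Laplacian (optional) -> sliding windows -> Welch PSD; windows fully
    inside a cue's task interval inherit its class label.  ``artifact_mask``
    may be supplied per window (see :mod:`smrbci.artifact`).
    """
    montage = montage or default_montage()
    work = laplacian_filter(rec, montage) if apply_laplacian else rec
    channels = channels or [c for c in montage.channels
                            if c in rec.channel_labels]
    data = work.get(channels)
    wins, times = window_view(data, rec.rate, length, hop)
    if wins.shape[0] == 0:
        freqs = np.arange(0, rec.rate / 2 + 1, 2.0)
        return PSDFrame(np.empty((0, len(channels), freqs.size)), freqs,
                        times, channels, None, None, dict(rec.meta))
    freqs, power = welch_psd(wins, rec.rate)
    labels = _window_labels(times, length, trials)
    return PSDFrame(power, freqs, times, list(channels), labels,
                    artifact_mask, dict(rec.meta))


def band_power(frame: PSDFrame, band: tuple[float, float]) -> np.ndarray:
    """Per-window per-channel PSD averaged over the 2 Hz bins inside band."""
    lo, hi = band
    sel = (frame.freqs >= lo) & (frame.freqs <= hi)
    if not sel.any():
        raise ValueError(f"no PSD bins inside band {band}")
    return frame.power[:, :, sel].mean(axis=2)
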