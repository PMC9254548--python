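"""EOG artifact gating.

Two frontal electrodes (~Fp1/Fp2) are combined into horizontal and vertical
EOG components (HEOG = Fp1 - Fp2, VEOG = (Fp1 + Fp2)/2).  Low-frequency
content is isolated with a zero-lag second-order Butterworth filter in the
1-10 Hz band (signal mirroring at the edges avoids boundary transients);
amplitudes are the absolute value of the filtered components.  Whenever the
amplitude in a 32-sample frame (62.5 ms at 512 Hz) exceeds the threshold
(30 uV by default), command output is suppressed for the next 2 s.

The guard never cleans the signal: it only gates commands, and downstream
metrics drop every analysis window overlapping a suppression interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import EEGRecording
from .montage import EOG_CHANNELS

__all__ = ["eog_components", "lowfreq_envelope", "EOGGuard",
           "scan_recording", "mask_windows"]

FRAME_SAMPLES = 32
EOG_BAND = (1.0, 10.0)


def eog_components(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical EOG components, sample-wise.

    ``frame`` is (n_samples, 2) ordered (Fp1, Fp2).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 2:
        raise ValueError("frame must be (n_samples, 2): (Fp1, Fp2)")
    heog = frame[:, 0] - frame[:, 1]
    veog = (frame[:, 0] + frame[:, 1]) / 2.0
    return heog, veog


def _eog_sos(rate: float) -> np.ndarray:
    return sps.butter(2, EOG_BAND, btype="bandpass", fs=rate, output="sos")


def lowfreq_envelope(signal: np.ndarray, rate: float) -> np.ndarray:
    """|zero-lag 1-10 Hz Butterworth| of a 1-D signal with mirrored edges."""
    x = np.asarray(signal, dtype=float)
    if x.size < 4:
        raise ValueError("signal too short to filter")
    pad = min(x.size - 1, int(rate))
    mirrored = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]])
    filtered = sps.sosfiltfilt(_eog_sos(rate), mirrored, padtype=None)
    return np.abs(filtered[pad:pad + x.size])


@dataclass
class EOGGuard:
    """Streaming frame-wise detector with a trailing buffer.

    Each incoming 32-sample EOG frame is appended to a 1 s trailing buffer;
    the buffer is mirrored at both edges, band-pass filtered forward and
    backward (zero lag), and the amplitude of the frame's own samples is
    compared against the threshold.  Detection is therefore causal at frame
    granularity: a flag depends only on the frame and its look-back buffer.

    A flag suppresses command output until frame end + ``freeze_s``;
    overlapping flags extend the interval.  Whether the evidence integrator
    is merely frozen (default) or reset during suppression is a pipeline
    flag, not the guard's concern.
    """

    threshold: float = 30.0
    freeze_s: float = 2.0
    rate: float = 512.0
    buffer_s: float = 1.0
    frozen_until: float = -np.inf
    _buffer: np.ndarray = field(default=None, repr=False)  # type: ignore

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.freeze_s < 0:
            raise ValueError("freeze horizon must be non-negative")
        if self._buffer is None:
            self._buffer = np.empty((0, 2), dtype=float)

    def scan_frame(self, frame: np.ndarray, t_end: float) -> bool:
        """Process one (32, 2) frame ending at ``t_end`` s; return the flag."""
        frame = np.asarray(frame, dtype=float)
        if frame.shape != (FRAME_SAMPLES, 2):
            raise ValueError(f"frame must be ({FRAME_SAMPLES}, 2)")
        max_len = int(round(self.buffer_s * self.rate))
        self._buffer = np.vstack([self._buffer, frame])[-max_len:]
        if self._buffer.shape[0] < 4 * FRAME_SAMPLES:
            return False  # undecidable: buffer too short, treated as clean
        heog, veog = eog_components(self._buffer)
        amp_h = lowfreq_envelope(heog, self.rate)[-FRAME_SAMPLES:]
        amp_v = lowfreq_envelope(veog, self.rate)[-FRAME_SAMPLES:]
        flag = bool(max(amp_h.max(), amp_v.max()) > self.threshold)
        if flag:
            self.frozen_until = max(self.frozen_until, t_end + self.freeze_s)
        return flag

    def suppressed(self, t: float) -> bool:
        return t < self.frozen_until


def scan_recording(rec: EEGRecording, *, threshold: float = 30.0,
                   freeze_s: float = 2.0,
                   eog_labels: tuple[str, str] = tuple(EOG_CHANNELS),
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Offline batch scan of a whole recording.

    Equivalent to running the streaming guard over consecutive frames but
    filtering the full signal once.  Returns ``(frame_times, flags,
    suppression)`` where ``frame_times`` are frame end times, ``flags`` the
    per-frame detections and ``suppression`` (n, 2) merged intervals
    [start, end) during which commands are suppressed.
    """
    try:
        eog = rec.get(list(eog_labels))
    except KeyError as err:
        raise ValueError("recording lacks the two frontal EOG channels") from err
    n_frames = eog.shape[0] // FRAME_SAMPLES
    heog, veog = eog_components(eog[: n_frames * FRAME_SAMPLES])
    amp_h = lowfreq_envelope(heog, rec.rate)
    amp_v = lowfreq_envelope(veog, rec.rate)
    amp = np.maximum(amp_h, amp_v).reshape(n_frames, FRAME_SAMPLES)
    flags = amp.max(axis=1) > threshold
    frame_times = (np.arange(1, n_frames + 1) * FRAME_SAMPLES) / rec.rate
    intervals: list[list[float]] = []
    for t in frame_times[flags]:
        start, end = t - FRAME_SAMPLES / rec.rate, t + freeze_s
        if intervals and start <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], end)
        else:
            intervals.append([start, end])
    return frame_times, flags, np.array(intervals).reshape(-1, 2)


def mask_windows(window_times: np.ndarray, window_length: float,
                 suppression: np.ndarray) -> np.ndarray:
    """True for analysis windows overlapping any suppression interval."""
    times = np.asarray(window_times, dtype=float)
    mask = np.zeros(times.size, dtype=bool)
    for start, end in np.asarray(suppression).reshape(-1, 2):
        mask |= (times < end) & (times + window_length > start)
    return mask
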