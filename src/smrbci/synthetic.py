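"""Synthetic EEG sessions with programmable learning dynamics.

The generator emulates the statistical structure the longitudinal analysis
assumes, so every pipeline stage can be verified against a known ground
truth:

* spatially correlated pink background noise over the 14-channel 10-20
  sensorimotor montage (so the Laplacian filter does nontrivial work);
* baseline mu (8-12 Hz) and beta (16-26 Hz) rhythms realized as
  band-limited Gaussian-noise sources mixed into the channels through
  band-specific spatial patterns (amplitude-modulated noise carriers, not
  pure sines, so PSD features have realistic variance);
* class-dependent band-power modulation during motor-imagery trials:
  both-hands trials modulate lateral channels (C3/C4), both-feet trials
  medial ones (Cz/FCz/CPz), with a contrast that scales with the
  programmed separability g(r) of run r;
* within-class drift d(r) per band, decomposed into a slow multiplicative
  shift of baseline band power (what the channels'-domain metrics see) and
  a slow rotation of the band's spatial mixing (what the Riemannian
  covariance metrics see), plus day-to-day lognormal power jitter;
* an optional long break: after the break run, the power shift restarts
  from its day-one level for every band, while the mixing rotation is kept
  for "retained" bands and restarted for the others — giving the
  channels-domain/Riemann-domain dissociation a generative counterpart;
* EOG blink and saccade artifacts on two frontal channels with a small
  bleed into the frontal EEG channels.

Sessions follow the calibration-run template: 15 cued trials per class,
each lasting 4.5-5.5 s, with the first 0.5 s after the cue excluded from
task labelling.  Everything is deterministic given (seed, run index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .containers import CLASSES, EEGRecording, TrialTable
from .montage import EEG_CHANNELS, EOG_CHANNELS, channel_positions
from .preprocessing import BANDS_DEFAULT

__all__ = ["SimulationConfig", "GroundTruth", "SessionSet",
           "simulate_session", "simulate_training_history", "inject_eog",
           "linear_ramp", "growth_history_config", "break_history_config"]


def linear_ramp(start: float, stop: float, n_runs: int
                ) -> Callable[[int], float]:
    """Trajectory helper: linear from ``start`` (run 1) to ``stop`` (run n)."""
    def traj(r: int) -> float:
        if n_runs <= 1:
            return float(stop)
        frac = (r - 1) / (n_runs - 1)
        return float(start + (stop - start) * min(max(frac, 0.0), 1.0))
    return traj


def _default_topography() -> dict[str, list[tuple[str, str, float]]]:
    return {
        "both_hands": [("C3", "mu", 0.5), ("C4", "mu", 0.5),
                       ("C3", "beta", 0.8), ("C4", "beta", 0.8)],
        "both_feet": [("Cz", "mu", 0.5), ("FCz", "mu", 0.5),
                      ("Cz", "beta", 0.8), ("CPz", "beta", 0.8)],
    }


@dataclass
class SimulationConfig:
    """Generative parameters of one synthetic training history.

    Amplitudes are in microvolts RMS.  ``separability_trajectory`` maps the
    run index to the class-contrast gain g(r) >= 0;
    ``drift_trajectory`` maps it to a per-band drift magnitude d(r), which
    acts on baseline band power with gain ``drift_power_gain`` and on the
    band's spatial mixing rotation with gain ``drift_rotation_gain``
    (radians at d = 1).  ``break_spec`` is (break run index,
    {band: retained}) — see the module docstring for its semantics.
    """

    rate: float = 512.0
    trial_duration: tuple[float, float] = (4.5, 5.5)
    trials_per_class: int = 15
    inter_trial: tuple[float, float] = (1.5, 2.5)
    cue_latency: float = 0.5
    lead_in: float = 3.0
    channel_topography: dict[str, list[tuple[str, str, float]]] = field(
        default_factory=_default_topography)
    separability_trajectory: Callable[[int], float] = lambda r: 1.0
    drift_trajectory: Callable[[int], dict[str, float]] = (
        lambda r: {"mu": 0.0, "beta": 0.0})
    break_spec: tuple[int, dict[str, bool]] | None = None
    blink_rate: float = 6.0            # events/min
    blink_amplitude: float = 150.0     # uV peak on the EOG channels
    saccade_rate: float = 2.0          # events/min
    pink_exponent: float = 1.0
    spatial_scale: float = 1.5         # grid units of the correlation kernel
    background_rms: float = 8.0
    eog_rms: float = 5.0
    band_amplitude: dict[str, float] = field(
        default_factory=lambda: {"mu": 3.0, "beta": 2.5})
    n_band_sources: int = 3
    task_amplitude: float = 3.0
    drift_power_gain: dict[str, float] = field(
        default_factory=lambda: {"mu": 0.9, "beta": 0.15})
    drift_rotation_gain: dict[str, float] = field(
        default_factory=lambda: {"mu": 1.0, "beta": 1.2})
    rotation_wobble: float = 0.08      # per-run random rotation (radians)
    run_jitter_sd: float = 0.12        # lognormal sigma of day-to-day power
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for cls, feats in self.channel_topography.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r} in topography")
            for ch, band, depth in feats:
                if ch not in EEG_CHANNELS:
                    raise ValueError(f"unknown channel {ch!r} in topography")
                if band not in BANDS_DEFAULT:
                    raise ValueError(f"unknown band {band!r} in topography")
                if depth < 0:
                    raise ValueError("modulation depths must be >= 0")


@dataclass
class GroundTruth:
    """Programmed quantities of one generated run (the recovery oracle)."""

    run_index: int
    separability: float
    drift_power: dict[str, float]
    drift_rotation: dict[str, float]
    trials: TrialTable
    blink_events: list[tuple[float, float, float, str]] = field(
        default_factory=list)   # (onset s, duration s, amplitude uV, kind)


# ---------------------------------------------------------------------------
# run-invariant generative structure
# ---------------------------------------------------------------------------

def _structure(config: SimulationConfig) -> dict:
    """Mixing patterns and kernels shared by every run of one history."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0x5EED]))
    pos = channel_positions()
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * config.spatial_scale ** 2))
    L_bg = np.linalg.cholesky(K + 1e-9 * np.eye(len(EEG_CHANNELS)))
    out = {"L_bg": L_bg, "patterns": {}, "skew": {}, "amp_spread": {}}
    k = config.n_band_sources
    for band in BANDS_DEFAULT:
        P = rng.standard_normal((len(EEG_CHANNELS), k))
        P, _ = np.linalg.qr(P)
        S = rng.standard_normal((len(EEG_CHANNELS),) * 2)
        S = S - S.T
        S /= np.linalg.norm(S, 2)
        out["patterns"][band] = P[:, :k]
        out["skew"][band] = S
        out["amp_spread"][band] = np.linspace(1.3, 0.7, k)
    return out


def _effective_drift(config: SimulationConfig, run_index: int
                     ) -> tuple[dict[str, float], dict[str, float]]:
    """Per-band (power drift, rotation drift) honoring the break semantics.

    After the break every band's power shift restarts from the trajectory's
    day-one level; the mixing rotation restarts only for non-retained bands.
    """
    def d_at(r: int) -> dict[str, float]:
        d = config.drift_trajectory(max(r, 1))
        for band, val in d.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite drift for band {band} run {r}")
        return d

    d_now = d_at(run_index)
    if config.break_spec is None:
        return dict(d_now), dict(d_now)
    b_run, retained = config.break_spec
    if run_index <= b_run:
        return dict(d_now), dict(d_now)
    d_restart = d_at(run_index - b_run)
    power = {band: d_restart[band] for band in d_now}
    rot = {band: (d_now[band] if retained.get(band, False)
                  else d_restart[band]) for band in d_now}
    return power, rot


def _band_carrier(rng: np.random.Generator, n: int, rate: float,
                  band: tuple[float, float], shape: tuple[int, ...] = ()
                  ) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, shape (*shape, n)."""
    white = rng.standard_normal(shape + (n,))
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    return x / np.maximum(rms, 1e-12)


def _pink(rng: np.random.Generator, n: int, n_ch: int, exponent: float
          ) -> np.ndarray:
    """Unit-variance 1/f^exponent noise, (n, n_ch)."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x.T


def _make_trials(config: SimulationConfig, rng: np.random.Generator
                 ) -> TrialTable:
    labels = np.repeat(np.array(CLASSES, dtype=object),
                       config.trials_per_class)
    rng.shuffle(labels)
    rows = []
    t = config.lead_in
    for lab in labels:
        dur = rng.uniform(*config.trial_duration)
        rows.append({"cue_onset": t, "task_onset": t + config.cue_latency,
                     "trial_end": t + dur, "label": lab})
        t = t + dur + rng.uniform(*config.inter_trial)
    return TrialTable(rows)


def simulate_session(config: SimulationConfig, run_index: int
                     ) -> tuple[EEGRecording, TrialTable, GroundTruth]:
    """Generate one calibration-style run (15 cued trials per class).

    Deterministic given (config.seed, run_index): the same pair yields
    byte-identical arrays.
    """
    if run_index < 1:
        raise ValueError("run_index must be >= 1")
    g = float(config.separability_trajectory(run_index))
    if not np.isfinite(g) or g < 0:
        raise ValueError(f"invalid separability gain {g} at run {run_index}")
    power_d, rot_d = _effective_drift(config, run_index)
    struct = _structure(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(run_index)]))

    trials = _make_trials(config, rng)
    total = float(trials["trial_end"].iloc[-1]) + config.lead_in
    n = int(round(total * config.rate))
    n_eeg = len(EEG_CHANNELS)

    # background: spatially correlated pink noise + independent EOG noise
    eeg = (_pink(rng, n, n_eeg, config.pink_exponent) @ struct["L_bg"].T
           ) * config.background_rms
    eog = _pink(rng, n, 2, config.pink_exponent) * config.eog_rms

    # baseline band rhythms with drifted power and rotated mixing
    for band, rng_band in BANDS_DEFAULT.items():
        k = config.n_band_sources
        src = _band_carrier(rng, n, config.rate, rng_band, (k,))
        theta = config.drift_rotation_gain[band] * rot_d[band]
        S = struct["skew"][band].copy()
        if config.rotation_wobble > 0:
            W = rng.standard_normal((n_eeg, n_eeg))
            W = W - W.T
            W /= np.linalg.norm(W, 2)
            S_eff = theta * S + config.rotation_wobble * W
        else:
            S_eff = theta * S
        R = sla.expm(S_eff)
        mix = R @ struct["patterns"][band]
        jitter = float(np.exp(rng.normal(0.0, config.run_jitter_sd)))
        amp = (config.band_amplitude[band]
               * np.sqrt(1.0 + config.drift_power_gain[band] * power_d[band])
               * jitter)
        eeg += amp * (mix @ (struct["amp_spread"][band][:, None] * src)).T

    # class-dependent task modulation (contrast scales with g(run))
    ramp_n = int(round(0.2 * config.rate))
    for _, tr in trials.iterrows():
        feats = config.channel_topography.get(tr["label"], [])
        i0 = int(round(tr["task_onset"] * config.rate))
        i1 = min(int(round(tr["trial_end"] * config.rate)), n)
        seg = i1 - i0
        if seg <= 2 * ramp_n:
            continue
        env = np.ones(seg)
        env[:ramp_n] = np.hanning(2 * ramp_n)[:ramp_n]
        env[-ramp_n:] = np.hanning(2 * ramp_n)[-ramp_n:]
        for ch, band, depth in feats:
            carrier = _band_carrier(rng, seg, config.rate, BANDS_DEFAULT[band])
            ci = EEG_CHANNELS.index(ch)
            eeg[i0:i1, ci] += config.task_amplitude * depth * g * carrier * env

    data = np.hstack([eeg, eog])
    rec = EEGRecording(data, config.rate, EEG_CHANNELS + EOG_CHANNELS,
                       {"run_index": run_index, "run_type": "calibration",
                        "seed": int(config.seed)})
    truth = GroundTruth(run_index, g, power_d, rot_d, trials)
    if config.blink_rate > 0 or config.saccade_rate > 0:
        rec, truth = inject_eog(rec, truth, config.blink_rate,
                                config.blink_amplitude,
                                saccade_rate=config.saccade_rate,
                                seed=int(config.seed) * 100003 + run_index)
    return rec, trials, truth


def inject_eog(recording: EEGRecording, truth: GroundTruth,
               blink_rate: float, amplitude: float, *,
               saccade_rate: float = 0.0, seed: int = 0,
               frontal_bleed: float = 0.12
               ) -> tuple[EEGRecording, GroundTruth]:
    """Add blink and saccade templates to the two frontal EOG channels.

    Blinks are 150-400 ms raised-cosine bumps with the configured peak
    amplitude and the same sign on both EOG channels; horizontal saccades
    are opposite-sign.  A fraction ``frontal_bleed`` of the blink waveform
    bleeds into the frontal EEG channels.  Events are appended to
    ``truth.blink_events``; a zero rate leaves the recording unchanged.
    """
    for ch in EOG_CHANNELS:
        if ch not in recording.channel_labels:
            raise ValueError(f"recording lacks EOG channel {ch}")
    if blink_rate == 0 and saccade_rate == 0:
        return recording, truth
    rng = np.random.default_rng(np.random.SeedSequence([0xE06, int(seed)]))
    rec = recording.copy()
    dur_total = rec.duration
    i_fp1 = rec.channel_index(EOG_CHANNELS[0])
    i_fp2 = rec.channel_index(EOG_CHANNELS[1])
    bleed_targets = [(c, frontal_bleed if c in ("Fz", "FCz") else
                      frontal_bleed / 2.0)
                     for c in ("Fz", "FCz", "FC1", "FC2")
                     if c in rec.channel_labels]
    events: list[tuple[float, float, float, str]] = []

    def _add(kind: str, rate_per_min: float, dur_range: tuple[float, float],
             amp: float) -> None:
        n_ev = rng.poisson(rate_per_min / 60.0 * dur_total)
        for _ in range(n_ev):
            dur = rng.uniform(*dur_range)
            onset = rng.uniform(0.5, max(dur_total - dur - 0.5, 0.6))
            i0 = int(round(onset * rec.rate))
            i1 = min(i0 + int(round(dur * rec.rate)), rec.n_samples)
            bump = amp * np.hanning(i1 - i0)
            if kind == "blink":
                rec.data[i0:i1, i_fp1] += bump
                rec.data[i0:i1, i_fp2] += bump
                for ch, scale in bleed_targets:
                    rec.data[i0:i1, rec.channel_index(ch)] += scale * bump
            else:  # saccade: opposite sign on the two EOG channels
                sign = rng.choice([-1.0, 1.0])
                rec.data[i0:i1, i_fp1] += sign * bump
                rec.data[i0:i1, i_fp2] -= sign * bump
            events.append((onset, dur, amp, kind))

    _add("blink", blink_rate, (0.15, 0.40), amplitude)
    _add("saccade", saccade_rate, (0.20, 0.50), 0.6 * amplitude)
    events.sort()
    truth = replace(truth, blink_events=list(truth.blink_events) + events)
    return rec, truth


@dataclass
class SessionSet:
    """Lazy ordered collection of the runs of one training history."""

    config: SimulationConfig
    n_runs: int

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("a history needs at least 2 runs")
        if self.config.break_spec is not None:
            b_run, _ = self.config.break_spec
            if not 1 <= b_run <= self.n_runs:
                raise ValueError(
                    f"break run {b_run} outside [1, {self.n_runs}]")

    def __len__(self) -> int:
        return self.n_runs

    def session(self, run_index: int
                ) -> tuple[EEGRecording, TrialTable, GroundTruth]:
        if not 1 <= run_index <= self.n_runs:
            raise IndexError(f"run {run_index} outside [1, {self.n_runs}]")
        return simulate_session(self.config, run_index)

    def __iter__(self):
        for r in range(1, self.n_runs + 1):
            yield (r, *self.session(r))

    def programmed(self):
        """DataFrame of the programmed g(r) and per-band drifts."""
        import pandas as pd

        rows = []
        for r in range(1, self.n_runs + 1):
            power_d, rot_d = _effective_drift(self.config, r)
            rows.append({"run": r,
                         "g": float(self.config.separability_trajectory(r)),
                         **{f"power_d_{b}": power_d[b] for b in power_d},
                         **{f"rot_d_{b}": rot_d[b] for b in rot_d}})
        return pd.DataFrame(rows)

    def period(self, run_index: int) -> str:
        """'2019' before/at the break run, '2020' after (no break: '2019')."""
        if (self.config.break_spec is not None
                and run_index > self.config.break_spec[0]):
            return "2020"
        return "2019"


def simulate_training_history(config: SimulationConfig, n_runs: int
                              ) -> SessionSet:
    """Ordered multi-run history with monotone-programmed g(r) and d(r)."""
    sset = SessionSet(config, n_runs)
    for r in (1, n_runs):  # fail fast on bad trajectories
        _effective_drift(config, r)
        g = config.separability_trajectory(r)
        if not np.isfinite(g):
            raise ValueError(f"non-finite separability at run {r}")
    return sset


# ---------------------------------------------------------------------------
# study-condition templates
# ---------------------------------------------------------------------------

def growth_history_config(seed: int, n_runs: int = 30) -> SimulationConfig:
    """First-training-period template: class separability and within-class
    drift grow linearly over the whole history (no break)."""
    ramp = linear_ramp(0.0, 1.0, n_runs)
    return SimulationConfig(
        seed=seed,
        separability_trajectory=linear_ramp(0.2, 0.9, n_runs),
        drift_trajectory=lambda r: {"mu": ramp(r), "beta": ramp(r)})


def break_history_config(seed: int, n_pre: int = 18, n_post: int = 10,
                         saturate_run: int = 10
                         ) -> tuple[SimulationConfig, int]:
    """Two-period template with a long break after run ``n_pre``.

    Separability and drift ramp up and plateau by ``saturate_run`` (skill
    consolidates before the first competition); across the break the beta
    band's generative covariance rotation is retained while the mu band
    resets entirely, and every band's power shift restarts.  Returns the
    config and the break run index; the total history has
    ``n_pre + n_post`` runs.
    """
    ramp = linear_ramp(0.0, 1.0, saturate_run)
    return SimulationConfig(
        seed=seed,
        separability_trajectory=linear_ramp(0.3, 1.0, saturate_run),
        drift_trajectory=lambda r: {"mu": ramp(r), "beta": ramp(r)},
        break_spec=(n_pre, {"beta": True, "mu": False})), n_pre
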