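"""End-to-end longitudinal experiment harness.

Reproduces the three-stage protocol on synthetic histories: calibration
runs from the first day train the decoder, subsequent runs are decoded
online-style (with the EOG guard gating the integrator), races are
simulated from the per-run decoding accuracy, learning curves (accuracy,
rejection, bcDist/wcDist x {channels, riemann} x {mu, beta}) are computed
per run, and the statistical battery (per-period trends, first/last-15
group comparisons, per-section race-time comparisons) is applied.  The
re-calibration policy refits the decoder, carrying over its previous
features, whenever online accuracy drops below the configured floor.

``replay`` runs the identical analysis path on provided recordings and
trial tables, for archived or externally recorded data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import artifact, game, metrics, stats
from .containers import CLASSES, EEGRecording, TrialTable
from .decoder import (FeatureMask, GaussianClassifier, cva_rank_features,
                      extract_features, fit_gaussian_classifier,
                      select_features)
from .metrics import BANDS, RunDistribution
from .preprocessing import band_power, bandpass, compute_psd_frame
from .riemann import sample_covariance
from .synthetic import SessionSet, SimulationConfig, simulate_training_history

__all__ = ["ExperimentConfig", "LongitudinalReport",
           "run_longitudinal_experiment", "analyze_session", "replay",
           "fit_decoder", "compute_learning_curves"]


@dataclass
class ExperimentConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_runs: int = 10
    n_calibration_runs: int = 3          # first-day runs used to calibrate
    n_features: int = 5
    recalibration_floor: float = 75.0    # online accuracy % triggering a refit
    carryover_score_floor: float = 0.0
    log_features: bool = False
    analysis_hop: float = 0.0625         # s between analysis windows
    n_races_per_run: int = 1
    pilot_reaction_s: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.recalibration_floor < 100:
            raise ValueError("accuracy floor must be in (0, 100)")
        if self.n_calibration_runs >= self.n_runs:
            raise ValueError("need more runs than calibration runs")


@dataclass
class LongitudinalReport:
    """Results bundle of one longitudinal experiment."""

    curves: pd.DataFrame            # run, period, metric, band, domain, value
    trends: pd.DataFrame            # per metric/band/domain/period trend stats
    group_tests: dict
    section_tests: pd.DataFrame | None
    races: pd.DataFrame | None
    recalibrations: list[int]
    window_accounting: pd.DataFrame
    config: ExperimentConfig | None = None

    def curve(self, metric: str, band: str | None = None,
              domain: str | None = None) -> pd.DataFrame:
        sel = self.curves[self.curves["metric"] == metric]
        if band is not None:
            sel = sel[sel["band"] == band]
        if domain is not None:
            sel = sel[sel["domain"] == domain]
        return sel.sort_values("run").reset_index(drop=True)

    def summary(self) -> str:
        lines = ["Longitudinal experiment summary", "=" * 32]
        lines.append(f"runs analysed: {self.curves['run'].nunique()}, "
                     f"re-calibrations at runs {self.recalibrations or '—'}")
        for _, row in self.trends.iterrows():
            lines.append(
                f"{row['metric']:<10} {str(row['band']):<5} "
                f"{str(row['domain']):<9} {row['period']}: "
                f"r={row['r']:+.3f} p={row['p']:.2e} n={int(row['n'])}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.curves.to_csv(out / "learning_curves.csv", index=False)
        self.trends.to_csv(out / "trend_tests.csv", index=False)
        self.window_accounting.to_csv(out / "window_accounting.csv",
                                      index=False)
        if self.races is not None:
            self.races.to_csv(out / "races.csv", index=False)
        if self.section_tests is not None:
            self.section_tests.to_csv(out / "section_time_tests.csv")
        payload = {
            "recalibrations": self.recalibrations,
            "group_tests": {
                "|".join(map(str, key)):
                    {"h": comp.h_statistic, "p": comp.p_omnibus,
                     "groups": comp.groups,
                     "pairwise_p": (None if comp.pairwise_p is None
                                    else comp.pairwise_p.to_dict())}
                for key, comp in self.group_tests.items()},
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=2))


def fit_decoder(frames, *, k: int = 5, carryover: FeatureMask | None = None,
                carryover_floor: float = 0.0, log_transform: bool = False,
                seed: int = 0) -> GaussianClassifier:
    """Rank features by CVA over pooled calibration frames and fit the
    Gaussian prototype classifier on the selected mask."""
    pooled = _pool_frames(frames)
    ranked = cva_rank_features(pooled, log_transform=log_transform)
    mask = select_features(ranked, k, carryover, carryover_floor)
    sub = pooled.labelled()
    X = extract_features(sub, mask, log_transform)
    model = fit_gaussian_classifier(X, sub.labels, mask=mask,
                                    log_transform=log_transform, seed=seed)
    return model


def _pool_frames(frames):
    from .containers import PSDFrame

    frames = list(frames)
    first = frames[0]
    return PSDFrame(
        np.concatenate([f.power for f in frames]),
        first.freqs,
        np.concatenate([f.times for f in frames]),
        list(first.channel_labels),
        np.concatenate([f.labels for f in frames]),
        np.concatenate([f.artifact_mask for f in frames]),
        dict(first.meta))


def analyze_session(rec: EEGRecording, trials: TrialTable, *,
                    hop: float = 0.0625,
                    model: GaussianClassifier | None = None) -> dict:
    """Per-run analysis shared by the simulated and replay paths.

    Returns the PSD frame (artifact-masked), per-band/per-class channel- and
    Riemann-domain distributions, decoding performance under ``model`` and
    the window accounting.
    """
    _, _, suppression = artifact.scan_recording(rec)
    frame = compute_psd_frame(rec, trials=trials, hop=hop)
    frame.artifact_mask = artifact.mask_windows(frame.times, 1.0, suppression)

    dists: dict[tuple[str, str, str], RunDistribution] = {}
    run = int(rec.meta.get("run_index", 0))
    for band, rng_band in BANDS.items():
        filtered = bandpass(rec, rng_band)
        for klass in CLASSES:
            dists[("channels", band, klass)] = (
                metrics.channel_domain_distribution(frame, band, klass, run))
            scms = _class_scms(filtered, frame, klass)
            dists[("riemann", band, klass)] = RunDistribution(
                scms, "riemann", band, klass, run)

    out = {"frame": frame, "distributions": dists, "run": run}
    labelled = np.array([l is not None for l in frame.labels])
    out["accounting"] = {
        "run": run, "n_windows": frame.n_windows,
        "n_labelled": int(labelled.sum()),
        "n_artifact": int((frame.artifact_mask & labelled).sum()),
    }
    if model is not None:
        acc, rej = metrics.decoding_performance(frame, model)
        out["accuracy"], out["rejection"] = acc, rej
        sub = frame.labelled()
        post = model.posterior(
            extract_features(sub, model.mask, model.log_transform))
        accepted = int((post.max(axis=1) >= model.th_rej).sum())
        out["accounting"]["n_accepted"] = accepted
        out["accounting"]["n_rejected"] = (out["accounting"]["n_labelled"]
                                           - out["accounting"]["n_artifact"]
                                           - accepted)
    return out


def _class_scms(filtered: EEGRecording, frame, klass: str) -> np.ndarray:
    from .montage import EEG_CHANNELS
    from .preprocessing import window_view

    data = filtered.get(EEG_CHANNELS)
    win = int(round(1.0 * filtered.rate))
    keep = (~frame.artifact_mask
            & np.array([l == klass for l in frame.labels]))
    starts = np.round(frame.times[keep] * filtered.rate).astype(int)
    scms = np.empty((starts.size, len(EEG_CHANNELS), len(EEG_CHANNELS)))
    for j, s in enumerate(starts):
        scms[j] = sample_covariance(data[s:s + win].T)
    return scms


def compute_learning_curves(history: SessionSet, *, hop: float = 0.0625
                            ) -> pd.DataFrame:
    """bcDist and class-averaged wcDist per run, band and domain, without
    any decoder in the loop (the metric-only analysis path)."""
    rows = []
    first_dists = None
    for run_index, rec, trials, _truth in history:
        res = analyze_session(rec, trials, hop=hop)
        if first_dists is None:
            first_dists = res["distributions"]
        period = history.period(run_index)
        for domain in ("channels", "riemann"):
            for band in BANDS:
                pair = {c: res["distributions"][(domain, band, c)]
                        for c in CLASSES}
                first = {c: first_dists[(domain, band, c)] for c in CLASSES}
                rows.append({"run": run_index, "period": period,
                             "metric": "bcDist", "band": band,
                             "domain": domain,
                             "value": metrics.bc_dist(pair[CLASSES[0]],
                                                      pair[CLASSES[1]])})
                rows.append({"run": run_index, "period": period,
                             "metric": "wcDist", "band": band,
                             "domain": domain,
                             "value": metrics.wc_dist_class_averaged(
                                 pair, first)})
    return pd.DataFrame(rows)


def run_longitudinal_experiment(config: ExperimentConfig
                                ) -> LongitudinalReport:
    """Simulate and analyse a full training history (see module docstring)."""
    history = simulate_training_history(config.sim, config.n_runs)
    return _run_history(history, config)


def _run_history(history: SessionSet, config: ExperimentConfig
                 ) -> LongitudinalReport:
    rng = np.random.default_rng(config.master_seed)
    calib_frames = []
    model: GaussianClassifier | None = None
    recalibrations: list[int] = []
    rows, accounting, race_rows = [], [], []
    first_dists: dict[tuple[str, str, str], RunDistribution] | None = None

    for run_index, rec, trials, _truth in history:
        is_calibration = run_index <= config.n_calibration_runs
        res = analyze_session(rec, trials, hop=config.analysis_hop,
                              model=None if is_calibration else model)
        accounting.append(res["accounting"])
        period = history.period(run_index)
        if first_dists is None:
            first_dists = res["distributions"]
        if is_calibration:
            calib_frames.append(res["frame"])
            if run_index == config.n_calibration_runs:
                model = fit_decoder(
                    calib_frames, k=config.n_features,
                    log_transform=config.log_features,
                    seed=config.master_seed)
        else:
            rows.append({"run": run_index, "period": period,
                         "metric": "accuracy", "band": None, "domain": None,
                         "value": res["accuracy"]})
            rows.append({"run": run_index, "period": period,
                         "metric": "rejection", "band": None, "domain": None,
                         "value": res["rejection"]})
        for domain in ("channels", "riemann"):
            for band in BANDS:
                pair = {c: res["distributions"][(domain, band, c)]
                        for c in CLASSES}
                first = {c: first_dists[(domain, band, c)] for c in CLASSES}
                bc = metrics.bc_dist(pair[CLASSES[0]], pair[CLASSES[1]])
                wc = metrics.wc_dist_class_averaged(pair, first)
                rows.append({"run": run_index, "period": period,
                             "metric": "bcDist", "band": band,
                             "domain": domain, "value": bc})
                rows.append({"run": run_index, "period": period,
                             "metric": "wcDist", "band": band,
                             "domain": domain, "value": wc})

        if is_calibration:
            continue

        # re-calibration policy: accuracy floor with feature carryover
        if (res["accuracy"] is not None
                and res["accuracy"] < config.recalibration_floor):
            model = fit_decoder([res["frame"]], k=config.n_features,
                                carryover=model.mask,
                                carryover_floor=config.carryover_score_floor,
                                log_transform=config.log_features,
                                seed=config.master_seed + run_index)
            recalibrations.append(run_index)

        # race simulation driven by the measured decoding accuracy
        if config.n_races_per_run > 0 and res["accuracy"] is not None:
            for j in range(config.n_races_per_run):
                seed = int(rng.integers(2 ** 31))
                track = game.generate_track(seed)
                result = game.simulate_race(
                    track, game.Kinematics(reaction_s=config.pilot_reaction_s),
                    accuracy=res["accuracy"] / 100.0, seed=seed)
                race_rows.append({
                    "run": run_index, "period": period, "race": j,
                    "time": result.completion_time,
                    "completed": result.completed,
                    **{f"t_{sec}": float(np.sum(
                        result.section_times[
                            np.array(track.sections) == sec]))
                       for sec in game.SECTION_TYPES}})

    curves = pd.DataFrame(rows)
    trends = _trend_table(curves)
    group_tests = _group_tests(curves)
    races = pd.DataFrame(race_rows) if race_rows else None
    section_tests = _section_tests(races) if races is not None else None
    return LongitudinalReport(curves, trends, group_tests, section_tests,
                              races, recalibrations,
                              pd.DataFrame(accounting), config)


def _trend_table(curves: pd.DataFrame) -> pd.DataFrame:
    rows = []
    keys = ["metric", "band", "domain"]
    for (metric, band, domain), sub in curves.groupby(keys, dropna=False):
        for period, per in sub.groupby("period"):
            per = per.dropna(subset=["value"]).sort_values("run")
            if len(per) < 3:
                continue
            tr = stats.pearson_trend(per["run"].to_numpy(),
                                     per["value"].to_numpy())
            rows.append({"metric": metric, "band": band, "domain": domain,
                         "period": period, "r": tr.r, "p": tr.p, "n": tr.n,
                         "slope": tr.slope, "degenerate": tr.degenerate})
    return pd.DataFrame(rows)


def _group_tests(curves: pd.DataFrame, n_group: int = 15) -> dict:
    out = {}
    keys = ["metric", "band", "domain"]
    for (metric, band, domain), sub in curves.groupby(keys, dropna=False):
        groups = {}
        for period, per in sub.groupby("period"):
            per = per.dropna(subset=["value"]).sort_values("run")
            vals = per["value"].to_numpy()
            m = min(n_group, len(vals) // 2)
            if m >= 2:
                groups[f"first-{m}-{period}"] = vals[:m]
                groups[f"last-{m}-{period}"] = vals[-m:]
        if len(groups) >= 2:
            out[(metric, str(band), str(domain))] = (
                stats.first_last_comparison(groups))
    return out


def _section_tests(races: pd.DataFrame, n_group: int = 15
                   ) -> pd.DataFrame | None:
    races = races.sort_values("run")
    m = min(n_group, len(races) // 2)
    if m < 2:
        return None
    cols = {sec: f"t_{sec}" for sec in game.SECTION_TYPES}
    first = {sec: races[col].to_numpy()[:m] for sec, col in cols.items()}
    last = {sec: races[col].to_numpy()[-m:] for sec, col in cols.items()}
    return stats.section_time_comparison(first, last)


def replay(sessions, model: GaussianClassifier | None = None, *,
           hop: float = 0.0625) -> dict:
    """Offline re-analysis of provided (recording, trial table) pairs.

    Produces the same per-run metric outputs as the simulated path; runs
    that fail to parse are skipped and itemized in the error manifest.
    """
    results, errors = {}, {}
    for item in sessions:
        run_key = None
        try:
            rec, trials = item
            run_key = rec.meta.get("run_index", len(results) + 1)
            results[run_key] = analyze_session(rec, trials, hop=hop,
                                               model=model)
        except Exception as err:  # noqa: BLE001 — itemized error report
            errors[run_key if run_key is not None else len(errors)] = str(err)
    return {"results": results, "errors": errors}
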