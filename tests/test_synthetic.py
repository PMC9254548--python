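"""Generator contracts: determinism, programmed class contrast, artifact
injection bookkeeping, break/trajectory validation."""

import numpy as np
import pytest
from scipy import stats as sst

from smrbci.montage import EEG_CHANNELS, EOG_CHANNELS
from smrbci.preprocessing import band_power, compute_psd_frame
from smrbci.synthetic import (GroundTruth, SimulationConfig, inject_eog,
                              linear_ramp, simulate_session,
                              simulate_training_history)
from smrbci.containers import TrialTable


class TestDeterminism:
    def test_same_seed_byte_identical(self, short_config):
        a, _, _ = simulate_session(short_config, 3)
        b, _, _ = simulate_session(short_config, 3)
        assert a.data.tobytes() == b.data.tobytes()

    def test_runs_differ(self, short_config):
        a, _, _ = simulate_session(short_config, 1)
        b, _, _ = simulate_session(short_config, 2)
        assert not np.array_equal(a.data, b.data)

    def test_seeds_differ(self, short_config):
        import dataclasses
        other = dataclasses.replace(short_config, seed=short_config.seed + 1)
        a, _, _ = simulate_session(short_config, 1)
        b, _, _ = simulate_session(other, 1)
        assert not np.array_equal(a.data, b.data)


class TestSessionStructure:
    def test_channel_layout_and_trials(self, short_session, short_config):
        rec, trials, truth = short_session
        assert rec.channel_labels == EEG_CHANNELS + EOG_CHANNELS
        assert len(trials) == 2 * short_config.trials_per_class
        assert set(trials["label"]) == {"both_hands", "both_feet"}
        durations = trials["trial_end"] - trials["cue_onset"]
        assert durations.between(*short_config.trial_duration).all()
        assert np.allclose(trials["task_onset"] - trials["cue_onset"],
                           short_config.cue_latency)

    def test_invalid_run_index(self, short_config):
        with pytest.raises(ValueError):
            simulate_session(short_config, 0)

    def test_non_finite_trajectory_is_config_error(self):
        cfg = SimulationConfig(separability_trajectory=lambda r: np.nan)
        with pytest.raises(ValueError):
            simulate_session(cfg, 1)


class TestProgrammedContrast:
    def test_band_power_contrast_tracks_separability(self, short_config):
        # beta power at C4 differs between classes when g > 0, not when g = 0
        import dataclasses

        def contrast(g):
            cfg = dataclasses.replace(
                short_config, trials_per_class=10,
                separability_trajectory=lambda r: g,
                blink_rate=0.0, saccade_rate=0.0)
            rec, trials, _ = simulate_session(cfg, 1)
            frame = compute_psd_frame(rec, trials=trials, hop=0.25,
                                      apply_laplacian=False)
            bp = band_power(frame, (16.0, 26.0))
            ci = EEG_CHANNELS.index("C4")
            bh = np.array([l == "both_hands" for l in frame.labels])
            bf = np.array([l == "both_feet" for l in frame.labels])
            return bp[bh, ci].mean() / bp[bf, ci].mean()

        assert contrast(0.0) == pytest.approx(1.0, abs=0.25)
        assert contrast(1.0) > 1.5


class TestInjectEOG:
    def _clean_session(self, short_config):
        import dataclasses
        cfg = dataclasses.replace(short_config, blink_rate=0.0,
                                  saccade_rate=0.0)
        return simulate_session(cfg, 1)

    def test_zero_rate_unchanged(self, short_config):
        rec, trials, truth = self._clean_session(short_config)
        rec2, truth2 = inject_eog(rec, truth, 0.0, 150.0)
        assert np.array_equal(rec.data, rec2.data)
        assert truth2.blink_events == truth.blink_events

    def test_events_logged_and_on_eog_channels(self, short_config):
        rec, _, truth = self._clean_session(short_config)
        rec2, truth2 = inject_eog(rec, truth, 10.0, 150.0, seed=4)
        blinks = [e for e in truth2.blink_events if e[3] == "blink"]
        assert blinks
        i1 = rec.channel_index("EOG_Fp1")
        onset, dur, amp, _ = blinks[0]
        sl = slice(int(onset * rec.rate), int((onset + dur) * rec.rate))
        assert (rec2.data[sl, i1] - rec.data[sl, i1]).max() == pytest.approx(
            amp, rel=0.01)

    def test_event_count_poisson_consistent(self, short_config):
        rec, _, truth = self._clean_session(short_config)
        rate = 20.0
        counts = []
        for seed in range(8):
            _, t2 = inject_eog(rec, truth, rate, 150.0, seed=seed)
            counts.append(len([e for e in t2.blink_events
                               if e[3] == "blink"]))
        lam = rate / 60.0 * rec.duration
        total = np.sum(counts)
        lo, hi = sst.poisson.interval(0.999, 8 * lam)
        assert lo <= total <= hi

    def test_missing_eog_channels_structural_error(self, rng):
        from conftest import make_recording
        rec = make_recording(rng.standard_normal((1024, 14)),
                             labels=EEG_CHANNELS)
        truth = GroundTruth(1, 0.0, {}, {}, TrialTable())
        with pytest.raises(ValueError):
            inject_eog(rec, truth, 5.0, 150.0)


class TestHistory:
    def test_break_outside_range_rejected(self, short_config):
        import dataclasses
        cfg = dataclasses.replace(short_config,
                                  break_spec=(50, {"beta": True}))
        with pytest.raises(ValueError):
            simulate_training_history(cfg, 10)

    def test_needs_two_runs(self, short_config):
        with pytest.raises(ValueError):
            simulate_training_history(short_config, 1)

    def test_programmed_table_reflects_break(self, short_config):
        import dataclasses
        ramp = linear_ramp(0.0, 1.0, 6)
        cfg = dataclasses.replace(
            short_config,
            drift_trajectory=lambda r: {"mu": ramp(r), "beta": ramp(r)},
            break_spec=(6, {"beta": True, "mu": False}))
        hist = simulate_training_history(cfg, 9)
        tab = hist.programmed().set_index("run")
        # power restarts for every band after the break
        assert tab.loc[7, "power_d_mu"] < tab.loc[6, "power_d_mu"]
        assert tab.loc[7, "power_d_beta"] < tab.loc[6, "power_d_beta"]
        # rotation is retained for beta, restarted for mu
        assert tab.loc[7, "rot_d_beta"] == tab.loc[6, "rot_d_beta"]
        assert tab.loc[7, "rot_d_mu"] < tab.loc[6, "rot_d_mu"]
        assert hist.period(6) == "2019" and hist.period(7) == "2020"

    def test_null_history_has_no_metric_trend(self, short_config):
        # flat g and d: bcDist trend stays non-significant for most seeds
        import dataclasses
        from smrbci.orchestrator import analyze_session
        from smrbci import metrics
        from smrbci.containers import CLASSES
        from smrbci.stats import pearson_trend

        hits = 0
        n_seeds = 4
        for seed in range(n_seeds):
            cfg = dataclasses.replace(short_config, seed=100 + seed,
                                      trials_per_class=4, blink_rate=0.0,
                                      saccade_rate=0.0)
            hist = simulate_training_history(cfg, 6)
            vals = []
            for _, rec, trials, _t in hist:
                d = analyze_session(rec, trials, hop=0.5)["distributions"]
                pair = [d[("channels", "beta", c)] for c in CLASSES]
                vals.append(metrics.bc_dist(*pair))
            tr = pearson_trend(np.arange(len(vals)), np.array(vals))
            hits += tr.p < 0.05
        assert hits <= 1
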