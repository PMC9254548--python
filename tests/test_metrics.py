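"""Fisher score, bcDist/wcDist algebra in both domains, topographic maps
and sample-wise decoding performance."""

import numpy as np
import pytest

from smrbci.containers import PSDFrame
from smrbci.decoder import fit_gaussian_classifier
from smrbci.metrics import (RunDistribution, bc_dist, fisher_score,
                            topographic_discriminancy, wc_dist,
                            decoding_performance, wc_dist_class_averaged)
from smrbci.riemann import sample_covariance

from conftest import random_spd


class TestFisherScore:
    def test_identical_sets_zero(self, rng):
        x = rng.standard_normal(50)
        assert fisher_score(x, x) == 0.0

    def test_closed_form(self, rng):
        a = rng.standard_normal(5000) + 2.0
        b = rng.standard_normal(5000)
        assert fisher_score(a, b) == pytest.approx(np.sqrt(2), abs=0.05)

    def test_matches_direct_recomputation(self, rng):
        for _ in range(20):
            a = rng.standard_normal(30) * rng.uniform(0.5, 3)
            b = rng.standard_normal(40) + rng.uniform(-2, 2)
            expected = abs(a.mean() - b.mean()) / np.sqrt(
                a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2)
            assert fisher_score(a, b) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_variances(self):
        assert fisher_score([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert fisher_score([1.0, 1.0], [2.0, 2.0]) == np.inf


def _chan_dist(data, band="beta", klass="both_hands", run=1):
    return RunDistribution(np.asarray(data, dtype=float), "channels", band,
                           klass, run)


class TestBcDist:
    def test_same_distribution_near_zero(self, rng):
        a = _chan_dist(rng.standard_normal((500, 14)))
        b = _chan_dist(rng.standard_normal((500, 14)), klass="both_feet")
        assert bc_dist(a, b) < 0.1

    def test_one_dimensional_equals_fisher_under_sd_convention(self, rng):
        # 100 random instances, exact to 1e-12
        for _ in range(100):
            x1 = rng.standard_normal((20, 1)) * rng.uniform(0.5, 2)
            x2 = rng.standard_normal((25, 1)) + rng.uniform(-3, 3)
            a = _chan_dist(x1)
            b = _chan_dist(x2, klass="both_feet")
            fs = fisher_score(x1[:, 0], x2[:, 0])
            assert bc_dist(a, b, convention="fisher-sd") == pytest.approx(
                fs, abs=1e-12)

    def test_homogeneity_in_mean_separation(self, rng):
        base = rng.standard_normal((300, 14))
        shift = rng.standard_normal(14)
        a = _chan_dist(base)
        b1 = _chan_dist(base + shift, klass="both_feet")
        b2 = _chan_dist(base + 2 * shift, klass="both_feet")
        # doubling the separation at fixed dispersion doubles bcDist
        assert bc_dist(a, b2) == pytest.approx(2 * bc_dist(a, b1), rel=0.02)

    def test_requires_two_classes(self, rng):
        a = _chan_dist(rng.standard_normal((10, 3)))
        with pytest.raises(ValueError):
            bc_dist(a, a)


class TestWcDist:
    def test_zero_against_itself(self, rng):
        a = _chan_dist(rng.standard_normal((100, 14)))
        assert wc_dist(a, a) == 0.0

    def test_shifted_copy_closed_form(self, rng):
        # symmetric +/- v pairs make the mean-distance dispersion exactly |v|
        v = np.zeros(14)
        v[3] = 2.0
        base = np.concatenate([np.tile(v, (50, 1)), np.tile(-v, (50, 1))])
        shift = rng.standard_normal(14)
        a = _chan_dist(base, run=1)
        b = _chan_dist(base + shift, run=5)
        delta = np.linalg.norm(shift)
        sigma = np.linalg.norm(v)
        assert wc_dist(b, a) == pytest.approx(delta / (2 * sigma), abs=1e-10)

    def test_riemann_affine_invariance(self, rng):
        X1 = rng.standard_normal((6, 14, 256))
        X2 = rng.standard_normal((6, 14, 256)) * 1.5
        W = rng.standard_normal((14, 14)) + 3 * np.eye(14)
        def scms(X, mix=None):
            out = []
            for x in X:
                xm = x if mix is None else mix @ x
                out.append(sample_covariance(xm))
            return np.stack(out)
        a = RunDistribution(scms(X1), "riemann", "beta", "both_hands", 1)
        b = RunDistribution(scms(X2), "riemann", "beta", "both_hands", 2)
        am = RunDistribution(scms(X1, W), "riemann", "beta", "both_hands", 1)
        bm = RunDistribution(scms(X2, W), "riemann", "beta", "both_hands", 2)
        assert wc_dist(bm, am) == pytest.approx(wc_dist(b, a), abs=1e-6)

    def test_class_and_domain_guards(self, rng):
        a = _chan_dist(rng.standard_normal((10, 3)))
        b = _chan_dist(rng.standard_normal((10, 3)), klass="both_feet")
        with pytest.raises(ValueError):
            wc_dist(a, b)

    def test_class_average(self, rng):
        mk = lambda k: {k2: _chan_dist(rng.standard_normal((20, 4)) + o,
                                       klass=k2, run=k)
                        for o, k2 in enumerate(("both_hands", "both_feet"))}
        r1, r2 = mk(1), mk(2)
        avg = wc_dist_class_averaged(r2, r1)
        vals = [wc_dist(r2[c], r1[c]) for c in ("both_hands", "both_feet")]
        assert avg == pytest.approx(np.mean(vals))


def _toy_frame(rng, n=120, modulated="C4"):
    from smrbci.montage import EEG_CHANNELS

    freqs = np.arange(0.0, 50.0, 2.0)
    power = rng.chisquare(4, (n, 14, freqs.size))
    labels = np.array(["both_hands", "both_feet"] * (n // 2), dtype=object)
    ci = EEG_CHANNELS.index(modulated)
    sel = (freqs >= 16) & (freqs <= 26)
    bh = labels == "both_hands"
    power[np.ix_(bh, [ci], np.where(sel)[0])] *= 8.0
    return PSDFrame(power, freqs, np.arange(n) * 0.0625, EEG_CHANNELS,
                    labels)


class TestTopographicMap:
    def test_null_map_near_zero(self, rng):
        frame = _toy_frame(rng, modulated="C4")
        frame.power = rng.chisquare(4, frame.power.shape)  # remove effect
        topo = topographic_discriminancy(frame)
        assert topo.max() < 0.35

    def test_modulated_channel_is_argmax(self, rng):
        topo = topographic_discriminancy(_toy_frame(rng, modulated="C4"))
        assert topo.idxmax() == "C4"

    def test_values_follow_channel_labels(self, rng):
        frame = _toy_frame(rng, modulated="C3")
        topo = topographic_discriminancy(frame)
        perm = list(range(14))[::-1]
        frame2 = PSDFrame(frame.power[:, perm, :], frame.freqs, frame.times,
                          [frame.channel_labels[i] for i in perm],
                          frame.labels)
        topo2 = topographic_discriminancy(frame2)
        assert np.allclose(topo.sort_index().values,
                           topo2.sort_index().values)

    def test_empty_band_rejected(self, rng):
        with pytest.raises(ValueError):
            topographic_discriminancy(_toy_frame(rng), band=(100.0, 110.0))


class TestDecodingPerformance:
    def _frame_and_model(self, rng, sep=8.0):
        frame = _toy_frame(rng, n=200, modulated="C4")
        model_X = np.vstack([
            frame.power[:, 10, 10],  # C4, 20 Hz
            frame.power[:, 10, 11]]).T
        model = fit_gaussian_classifier(model_X, frame.labels,
                                        mask=[("C4", 20.0), ("C4", 22.0)],
                                        seed=0)
        return frame, model

    def test_separable_simulation_high_accuracy(self, rng):
        frame, model = self._frame_and_model(rng)
        acc, rej = decoding_performance(frame, model)
        assert acc > 95.0
        assert rej < 20.0

    def test_flipped_labels_mirror_accuracy(self, rng):
        frame, model = self._frame_and_model(rng)
        acc, rej = decoding_performance(frame, model)
        flipped = PSDFrame(frame.power, frame.freqs, frame.times,
                           frame.channel_labels,
                           np.where(frame.labels == "both_hands",
                                    "both_feet", "both_hands"))
        acc_f, rej_f = decoding_performance(flipped, model)
        assert acc_f == pytest.approx(100.0 - acc, abs=1e-9)
        assert rej_f == pytest.approx(rej)

    def test_all_rejected_flags_undefined_accuracy(self, rng):
        frame, model = self._frame_and_model(rng)
        model.th_rej = 1.01  # nothing can be accepted
        acc, rej = decoding_performance(frame, model)
        assert acc is None
        assert rej == 100.0
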