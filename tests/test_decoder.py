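"""Feature ranking, Gaussian classification with rejection, and the
evidence integrator against closed forms and brute-force Bayes oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from smrbci.decoder import (FROZEN, REJECTED, GaussianClassifier, Integrator,
                            _cva_rank, apply_rejection, classify,
                            fit_gaussian_classifier, select_features)
from smrbci.metrics import fisher_score


def _named(n_features):
    return [(f"ch{j}", 2.0 * (j + 2)) for j in range(n_features)]


class TestCVARanking:
    def test_disjoint_feature_ranked_first(self, rng):
        n = 200
        X = rng.standard_normal((2 * n, 6))
        y = np.array(["both_hands"] * n + ["both_feet"] * n, dtype=object)
        X[:n, 3] += 10.0  # disjoint class supports on feature 3
        ranked = _cva_rank(X, y, _named(6))
        assert ranked.iloc[0]["channel"] == "ch3"

    def test_null_scores_near_zero(self, rng):
        n = 500
        X = rng.standard_normal((n, 20))
        y = np.array(["both_hands", "both_feet"] * (n // 2), dtype=object)
        ranked = _cva_rank(X, y, _named(20))
        assert ranked["score"].max() < 0.05

    def test_agrees_with_fisher_ranking_on_diagonal_features(self, rng):
        # diagonal-covariance classes: top-5 sets of CVA and Fisher ranking
        # overlap on >= 90% of instances
        overlaps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            n, f = 400, 10
            shifts = np.zeros(f)
            shifts[:5] = [2.0, 1.5, 1.2, 0.9, 0.7]
            X = r.standard_normal((n, f))
            y = np.array(["both_hands"] * (n // 2)
                         + ["both_feet"] * (n // 2), dtype=object)
            X[: n // 2] += shifts
            ranked = _cva_rank(X, y, _named(f))
            top_cva = set(ranked.head(5)["channel"])
            fs = [fisher_score(X[: n // 2, j], X[n // 2:, j])
                  for j in range(f)]
            top_fs = {f"ch{j}" for j in np.argsort(fs)[::-1][:5]}
            overlaps.append(len(top_cva & top_fs) / 5.0)
        assert np.mean(overlaps) >= 0.9

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array(["both_hands"] * 20, dtype=object)
        with pytest.raises(ValueError):
            _cva_rank(X, y, _named(3))


class TestSelectFeatures:
    def _ranked(self):
        return pd.DataFrame({
            "channel": ["C3", "C4", "Cz", "CPz", "FCz"],
            "freq": [20.0, 20.0, 12.0, 22.0, 10.0],
            "score": [0.9, 0.7, 0.5, 0.3, 0.1]})

    def test_plain_topk_without_carryover(self):
        assert select_features(self._ranked(), 2) == [("C3", 20.0),
                                                      ("C4", 20.0)]

    def test_carryover_forced_in_when_above_floor(self):
        mask = select_features(self._ranked(), 2,
                               carryover=[("CPz", 22.0)], floor=0.2)
        assert ("CPz", 22.0) in mask and len(mask) == 2

    def test_infinite_floor_ignores_carryover(self):
        mask = select_features(self._ranked(), 2,
                               carryover=[("CPz", 22.0)], floor=np.inf)
        assert mask == [("C3", 20.0), ("C4", 20.0)]

    def test_truncates_with_warning(self):
        with pytest.warns(UserWarning):
            mask = select_features(self._ranked(), 10)
        assert len(mask) == 5


def _two_blob_data(rng, n=400, sep=6.0):
    X = rng.standard_normal((n, 2))
    y = np.array(["both_hands"] * (n // 2) + ["both_feet"] * (n // 2),
                 dtype=object)
    X[n // 2:, 0] += sep
    return X, y


class TestGaussianClassifier:
    def test_separated_classes_high_accuracy(self, rng):
        X, y = _two_blob_data(rng)
        model = fit_gaussian_classifier(X, y, seed=0)
        acc = (model.predict(X) == y).mean()
        assert acc > 0.95

    def test_posterior_half_on_bisector(self):
        means = np.array([[[0.0, 0.0]], [[4.0, 0.0]]])
        model = GaussianClassifier([], means, np.zeros((2, 1, 2)),
                                   np.ones((2, 1)))
        post = classify(model, np.array([2.0, 3.7]))
        assert post[0] == pytest.approx(0.5, abs=1e-12)

    def test_shuffled_labels_chance_level(self, rng):
        X, y = _two_blob_data(rng, n=2000)
        y_shuf = y.copy()
        rng.shuffle(y_shuf)
        model = fit_gaussian_classifier(X, y_shuf, seed=0)
        acc = (model.predict(X) == y_shuf).mean()
        assert abs(acc - 0.5) < 0.05

    def test_posterior_matches_bayes_oracle(self, rng):
        # mixture posterior equals a direct density-sum computation
        M, f = 3, 4
        means = rng.standard_normal((2, M, f))
        log_vars = rng.uniform(-1, 1, (2, M, f))
        w = rng.dirichlet(np.ones(M), size=2)
        model = GaussianClassifier([], means, log_vars, w)
        for _ in range(100):
            x = rng.standard_normal(f) * 2
            dens = np.zeros(2)
            for c in range(2):
                for m in range(M):
                    dens[c] += w[c, m] * np.prod(sst.norm.pdf(
                        x, means[c, m], np.exp(log_vars[c, m] / 2)))
            expected = dens / dens.sum()
            assert np.allclose(classify(model, x), expected, atol=1e-10)

    def test_posteriors_normalized(self, rng):
        X, y = _two_blob_data(rng, n=100)
        model = fit_gaussian_classifier(X, y, seed=0)
        post = model.posterior(rng.standard_normal((50, 2)) * 10)
        assert np.allclose(post.sum(axis=1), 1.0)
        assert np.all((post >= 0) & (post <= 1))

    def test_far_prototype_saturates_posterior(self):
        means = np.array([[[0.0]], [[30.0]]])
        model = GaussianClassifier([], means, np.zeros((2, 1, 1)),
                                   np.ones((2, 1)))
        assert classify(model, np.array([0.0]))[0] > 0.999

    def test_roundtrip_json(self, rng):
        X, y = _two_blob_data(rng, n=100)
        model = fit_gaussian_classifier(X, y, mask=[("C3", 20.0)], seed=0)
        clone = GaussianClassifier.from_json(model.to_json())
        x = rng.standard_normal((5, 2))
        assert np.allclose(model.posterior(x), clone.posterior(x))
        assert clone.mask == model.mask


class TestRejection:
    @pytest.mark.parametrize("post,accepted", [
        ((0.59, 0.41), False),
        ((0.60, 0.40), True),   # boundary inclusive
        ((0.5, 0.5), False),
        ((0.95, 0.05), True)])
    def test_boundary_convention(self, post, accepted):
        assert apply_rejection(np.array(post)) is accepted


class TestIntegrator:
    HOP = 0.0625

    def _drive(self, integ, evidence, n):
        cmds = []
        for i in range(n):
            cmd = integ.step(evidence, i * self.HOP)
            if cmd:
                cmds.append((i, cmd))
        return cmds

    def test_inc_state_under_rejection(self):
        integ = Integrator()
        cmds = self._drive(integ, REJECTED, 200)
        assert cmds == []
        assert np.allclose(integ.y, [0.5, 0.5])

    def test_closed_form_frames_to_command(self):
        # under constant (1, 0) evidence y_n = 1 - 0.5 * 0.9^n; the command
        # fires at the smallest n with y_n >= 1 - eps_cmd
        alpha, eps = 0.1, 0.025
        n_star = int(np.ceil(np.log(2 * eps) / np.log(1 - alpha)))
        assert 1 - 0.5 * (1 - alpha) ** n_star >= 1 - eps
        assert 1 - 0.5 * (1 - alpha) ** (n_star - 1) < 1 - eps
        integ = Integrator(alpha=alpha, eps_cmd=eps)
        cmds = self._drive(integ, np.array([1.0, 0.0]), 60)
        assert cmds[0] == (n_star - 1, "both_hands")  # 0-based frame index
        assert n_star * self.HOP == pytest.approx(n_star * 0.0625)

    def test_refractory_suppresses_second_burst(self):
        integ = Integrator(alpha=0.5, eps_cmd=0.025, refractory_s=1.0)
        t, cmds = 0.0, []
        # two evidence bursts 0.4 s apart, each strong enough to trigger
        for burst_start in (0.0, 0.4):
            for i in range(6):
                cmd = integ.step(np.array([1.0, 0.0]),
                                 burst_start + i * self.HOP)
                if cmd:
                    cmds.append(cmd)
        assert len(cmds) == 1

    def test_uniform_evidence_never_commands(self):
        for alpha in (0.05, 0.2, 0.8, 1.0):
            integ = Integrator(alpha=alpha)
            assert self._drive(integ, np.array([0.5, 0.5]), 500) == []

    def test_time_to_command_monotone_in_alpha_and_evidence(self):
        def frames(alpha, p):
            integ = Integrator(alpha=alpha)
            cmds = self._drive(integ, np.array([p, 1 - p]), 2000)
            return cmds[0][0] if cmds else np.inf

        for p in (0.99, 1.0):
            times = [frames(a, p) for a in (0.05, 0.1, 0.2, 0.4)]
            assert all(a >= b for a, b in zip(times, times[1:]))
        for alpha in (0.1, 0.3):
            times = [frames(alpha, p) for p in (0.98, 0.99, 1.0)]
            assert all(a >= b for a, b in zip(times, times[1:]))

    def test_state_stays_probability_vector(self, rng):
        integ = Integrator(alpha=0.3)
        t = 0.0
        for _ in range(300):
            ev = rng.dirichlet([1, 1]) if rng.random() < 0.8 else REJECTED
            integ.step(ev, t)
            assert np.all(integ.y >= 0) and np.all(integ.y <= 1)
            assert integ.y.sum() == pytest.approx(1.0)
            t += self.HOP

    def test_frozen_sentinel_freezes_state(self):
        integ = Integrator()
        integ.step(np.array([0.9, 0.1]), 0.0)
        y_before = integ.y.copy()
        integ.step(FROZEN, 0.0625)
        assert np.array_equal(integ.y, y_before)

    def test_non_monotone_timestamps_rejected(self):
        integ = Integrator()
        integ.step(np.array([0.6, 0.4]), 1.0)
        with pytest.raises(ValueError):
            integ.step(np.array([0.6, 0.4]), 0.5)
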