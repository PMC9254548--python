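"""User-learning metrics: Fisher-score discriminancy, between-class and
within-class distances in the channels' and Riemann domains, topographic
discriminancy maps, and sample-wise decoding performance.

Two geometrical views of the neural patterns are tracked run by run:

* channels' domain — each 1 s window is the 14-vector of per-channel PSD
  averaged over the mu (8-12 Hz) or beta (16-26 Hz) band; distances are
  Euclidean between arithmetic means.
* Riemann domain — each window is the sample covariance matrix of the
  band-passed channels; distances are affine-invariant geodesics between
  geometric (Karcher) means.

The between-class distance bcDist = delta(mean_bh, mean_bf) /
(sigma_bh + sigma_bf) measures how separable the two imagery classes are
within a run; the within-class distance wcDist = delta(mean_1, mean_r) /
(sigma_1 + sigma_r) measures how far class activity in run r has moved from
the first recorded run.  The denominator is, by default, the sum of the
mean distances of the windows around their class means ("mean-distance"
convention); an alternative "fisher-sd" convention uses quadrature-combined
sample standard deviations, under which the one-dimensional channels'-domain
bcDist reduces exactly to the Fisher score |m1-m2|/sqrt(s1^2+s2^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import riemann
from .containers import CLASSES, PSDFrame
from .decoder import GaussianClassifier, extract_features
from .preprocessing import BETA_BAND, MU_BAND, band_power

__all__ = ["fisher_score", "RunDistribution", "bc_dist", "wc_dist",
           "topographic_discriminancy", "decoding_performance",
           "channel_domain_distribution", "riemann_domain_distribution",
           "BANDS"]

BANDS = {"mu": MU_BAND, "beta": BETA_BAND}


def fisher_score(samples1: np.ndarray, samples2: np.ndarray) -> float:
    """FS = |m1 - m2| / sqrt(s1^2 + s2^2) with sample standard deviations.

    With both variances zero the score is 0 for equal means and +inf
    otherwise (flagged by the infinite value itself).
    """
    a = np.asarray(samples1, dtype=float)
    b = np.asarray(samples2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per set")
    num = abs(a.mean() - b.mean())
    den = np.sqrt(a.var(ddof=1) + b.var(ddof=1))
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / den)


@dataclass
class RunDistribution:
    """Per-window features of one run, one class, one domain, one band.

    ``data`` is (n_windows, 14) band-power vectors in the channels' domain
    or (n_windows, C, C) SPD covariance stacks in the Riemann domain.
    Artifact-masked windows must be excluded before construction.
    """

    data: np.ndarray
    domain: str                 # 'channels' | 'riemann'
    band: str                   # 'mu' | 'beta'
    klass: str
    run: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.domain not in ("channels", "riemann"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 windows per distribution")

    def mean(self) -> np.ndarray:
        if self.domain == "channels":
            return self.data.mean(axis=0)
        # band-passed window SCMs are badly conditioned; give the damped
        # fixed point more room than the generic default
        return riemann.geometric_mean(self.data, max_iter=150)

    def dispersion(self, center: np.ndarray | None = None,
                   convention: str = "mean-distance") -> float:
        center = self.mean() if center is None else center
        if self.domain == "riemann":
            return riemann.dispersion(self.data, center)
        d = np.linalg.norm(self.data - center[None, :], axis=1)
        if convention == "mean-distance":
            return float(d.mean())
        if convention == "fisher-sd":
            # per-axis sample SD combined in quadrature (n-1 normalization)
            return float(np.sqrt(self.data.var(axis=0, ddof=1).sum()))
        raise ValueError(f"unknown dispersion convention {convention!r}")


def _normalized_distance(da: RunDistribution, db: RunDistribution,
                         convention: str) -> float:
    ma, mb = da.mean(), db.mean()
    if da.domain == "riemann":
        num = riemann.geodesic_distance(ma, mb)
        den = da.dispersion(ma) + db.dispersion(mb)
    else:
        num = float(np.linalg.norm(ma - mb))
        sa = da.dispersion(ma, convention)
        sb = db.dispersion(mb, convention)
        if convention == "fisher-sd":
            den = float(np.sqrt(sa ** 2 + sb ** 2))
        else:
            den = sa + sb
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return num / den


def bc_dist(dist_bh: RunDistribution, dist_bf: RunDistribution,
            convention: str = "mean-distance") -> float:
    """Between-class distance of one run (discriminability of the classes)."""
    if dist_bh.domain != dist_bf.domain or dist_bh.band != dist_bf.band:
        raise ValueError("distributions must share domain and band")
    if dist_bh.klass == dist_bf.klass:
        raise ValueError("bc_dist needs the two different classes")
    return _normalized_distance(dist_bh, dist_bf, convention)


def wc_dist(dist_r: RunDistribution, dist_1: RunDistribution,
            convention: str = "mean-distance") -> float:
    """Within-class distance of run r from the first recorded run."""
    if dist_r.domain != dist_1.domain or dist_r.band != dist_1.band:
        raise ValueError("distributions must share domain and band")
    if dist_r.klass != dist_1.klass:
        raise ValueError("wc_dist compares the same class across runs")
    return _normalized_distance(dist_1, dist_r, convention)


def wc_dist_class_averaged(dists_r: dict[str, RunDistribution],
                           dists_1: dict[str, RunDistribution],
                           convention: str = "mean-distance") -> float:
    """wcDist averaged across the two classes (the reported curve)."""
    vals = [wc_dist(dists_r[c], dists_1[c], convention) for c in CLASSES]
    return float(np.mean(vals))


def channel_domain_distribution(frame: PSDFrame, band: str, klass: str,
                                run: int) -> RunDistribution:
    """Band-power vectors of one class's artifact-free windows."""
    sub = frame.labelled(klass)
    return RunDistribution(band_power(sub, BANDS[band]), "channels", band,
                           klass, run)


def riemann_domain_distribution(scms: np.ndarray, band: str, klass: str,
                                run: int) -> RunDistribution:
    return RunDistribution(scms, "riemann", band, klass, run)


def topographic_discriminancy(frame: PSDFrame,
                              band: tuple[float, float] = BETA_BAND,
                              log_transform: bool = False) -> pd.Series:
    """Per-channel Fisher score of the PSD bins inside ``band``, averaged
    over bins — the topographic discriminancy map."""
    sub = frame.labelled()
    sel = (sub.freqs >= band[0]) & (sub.freqs <= band[1])
    if not sel.any():
        raise ValueError(f"no PSD bins inside band {band}")
    y = sub.labels.astype(str)
    masks = [y == c for c in CLASSES]
    if min(m.sum() for m in masks) < 2:
        raise ValueError("need at least 2 windows per class")
    P = sub.power[:, :, sel]
    if log_transform:
        P = np.log10(np.maximum(P, 1e-12))
    vals = np.empty(len(sub.channel_labels))
    for ci in range(len(sub.channel_labels)):
        fs = [fisher_score(P[masks[0], ci, bi], P[masks[1], ci, bi])
              for bi in range(int(sel.sum()))]
        vals[ci] = np.mean(fs)
    return pd.Series(vals, index=sub.channel_labels, name="fisher_score")


def decoding_performance(frame: PSDFrame, model: GaussianClassifier
                         ) -> tuple[float | None, float]:
    """Sample-by-sample (accuracy %, rejection %) of the raw classifier.

    Computed on labelled artifact-free windows, before any integration:
    rejection is the share of samples whose maximum posterior falls below
    the model's rejection threshold; accuracy is computed over the accepted
    samples only and is None when everything is rejected.
    """
    sub = frame.labelled()
    if sub.n_windows == 0:
        raise ValueError("no labelled artifact-free windows")
    X = extract_features(sub, model.mask, model.log_transform)
    post = model.posterior(X)
    accepted = post.max(axis=1) >= model.th_rej
    rejection = 100.0 * (1.0 - accepted.mean())
    if not accepted.any():
        return None, float(rejection)
    pred = np.asarray(model.classes, dtype=object)[post.argmax(axis=1)]
    correct = pred[accepted] == sub.labels[accepted]
    return float(100.0 * correct.mean()), float(rejection)
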