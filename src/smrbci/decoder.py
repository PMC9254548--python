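"""Feature selection, Gaussian classification with rejection, and
evidence integration.

The online decoder ranks (channel, 2 Hz bin) PSD features by canonical
variate analysis, trains a two-class Gaussian prototype classifier
(self-organizing-map initialization refined by gradient descent), rejects
uncertain samples whose maximum posterior falls below ``th_rej`` (0.6), and
accumulates accepted posteriors with an exponential evidence integrator:
a command is delivered when the integrated probability of a class reaches 1
(within a small numerical band), after which the integrator resets to the
uniform distribution and a 1 s refractory period starts.  With no decisive
evidence the integrator idles near uniform — the intentional non-control
(INC) state — and no command is ever sent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASSES, PSDFrame

__all__ = ["cva_rank_features", "select_features", "FeatureMask",
           "GaussianClassifier", "fit_gaussian_classifier", "classify",
           "apply_rejection", "Integrator", "REJECTED", "FROZEN",
           "extract_features"]

#: sentinel evidence values for the integrator
REJECTED = "rejected"
FROZEN = "frozen"

FeatureMask = list[tuple[str, float]]  # (channel label, bin center Hz)

FEATURE_BAND = (4.0, 48.0)


# ---------------------------------------------------------------------------
# feature ranking / selection
# ---------------------------------------------------------------------------

def _frame_matrix(frame: PSDFrame, log_transform: bool
                  ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, float]]]:
    """Flatten labelled artifact-free windows to (n, features)."""
    sub = frame.labelled()
    lo, hi = FEATURE_BAND
    sel = (sub.freqs >= lo) & (sub.freqs <= hi)
    X = sub.power[:, :, sel].reshape(sub.n_windows, -1)
    if log_transform:
        X = np.log10(np.maximum(X, 1e-12))
    names = [(ch, float(f)) for ch in sub.channel_labels
             for f in sub.freqs[sel]]
    y = np.asarray(sub.labels, dtype=object)
    return X, y, names


def cva_rank_features(frame: PSDFrame, *, log_transform: bool = False,
                      ridge: float = 1e-6) -> pd.DataFrame:
    """Rank (channel, bin) features by two-class canonical variate analysis.

    With two classes there is a single canonical axis (the regularized
    within-class-whitened mean difference).  Each feature's discriminant
    power is its squared canonical loading (correlation with the canonical
    scores) times the canonical correlation.  Ties break deterministically
    by (channel order, bin frequency).

    Returns a DataFrame (channel, freq, score) sorted by descending score.
    """
    X, y, names = _frame_matrix(frame, log_transform)
    return _cva_rank(X, y, names, ridge)


def _cva_rank(X: np.ndarray, y: np.ndarray,
              names: list[tuple[str, float]],
              ridge: float = 1e-6) -> pd.DataFrame:
    classes = np.unique(y.astype(str))
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    masks = [np.asarray(y).astype(str) == c for c in classes]
    if min(m.sum() for m in masks) < 2:
        raise ValueError("need at least 2 windows per class")
    m1, m2 = (X[m].mean(axis=0) for m in masks)
    Sw = sum(np.cov(X[m], rowvar=False, bias=False) * (m.sum() - 1)
             for m in masks) / (X.shape[0] - 2)
    Sw = np.atleast_2d(Sw)
    Sw_reg = Sw + ridge * (np.trace(Sw) / Sw.shape[0] + 1e-30) * np.eye(Sw.shape[0])
    w = np.linalg.solve(Sw_reg, m1 - m2)
    scores_axis = X @ w
    yy = masks[0].astype(float)
    rho = abs(_safe_corr(scores_axis, yy))
    sd_u = scores_axis.std(ddof=1)
    loadings = np.array([_safe_corr(X[:, j], scores_axis) if sd_u > 0 else 0.0
                         for j in range(X.shape[1])])
    disc = loadings ** 2 * rho
    out = pd.DataFrame({"channel": [n[0] for n in names],
                        "freq": [n[1] for n in names],
                        "score": disc})
    chan_order = {c: i for i, c in enumerate(dict.fromkeys(out["channel"]))}
    out["_c"] = out["channel"].map(chan_order)
    out = (out.sort_values(["score", "_c", "freq"],
                           ascending=[False, True, True], kind="mergesort")
              .drop(columns="_c").reset_index(drop=True))
    return out


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_features(ranked: pd.DataFrame, k: int,
                    carryover: FeatureMask | None = None,
                    floor: float = 0.0) -> FeatureMask:
    """Top-k features with a carryover stability policy.

    Features used by the previous decoder (``carryover``) are force-included
    when their current score is at least ``floor``; the remaining slots fill
    by rank order.  Mirrors the practice of keeping the previous decoder's
    features in each re-calibration when possible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    avail = [(row.channel, float(row.freq)) for row in ranked.itertuples()]
    scores = {(row.channel, float(row.freq)): float(row.score)
              for row in ranked.itertuples()}
    if k > len(avail):
        warnings.warn(f"requested {k} features, only {len(avail)} available",
                      UserWarning, stacklevel=2)
        k = len(avail)
    chosen: FeatureMask = []
    for feat in (carryover or []):
        feat = (feat[0], float(feat[1]))
        if feat in scores and scores[feat] >= floor and feat not in chosen:
            chosen.append(feat)
    for feat in avail:
        if len(chosen) >= k:
            break
        if feat not in chosen:
            chosen.append(feat)
    return chosen[:k]


def extract_features(frame: PSDFrame, mask: FeatureMask,
                     log_transform: bool = False) -> np.ndarray:
    """(n_windows, len(mask)) feature matrix for a PSD frame."""
    cols = []
    for ch, f in mask:
        ci = frame.channel_labels.index(ch)
        bi = int(np.argmin(np.abs(frame.freqs - f)))
        if abs(frame.freqs[bi] - f) > 1e-6:
            raise KeyError(f"bin {f} Hz not on the frequency grid")
        cols.append(frame.power[:, ci, bi])
    X = np.column_stack(cols) if cols else np.empty((frame.n_windows, 0))
    if log_transform:
        X = np.log10(np.maximum(X, 1e-12))
    return X


# ---------------------------------------------------------------------------
# Gaussian prototype classifier
# ---------------------------------------------------------------------------

@dataclass
class GaussianClassifier:
    """Two-class Gaussian prototype classifier with rejection.

    Each class is modelled by ``n_prototypes`` diagonal-covariance Gaussian
    prototypes with uniform within-class weights; the posterior is the
    normalized class-conditional mixture likelihood under equal priors.
    """

    mask: FeatureMask
    means: np.ndarray          # (2, M, f)
    log_vars: np.ndarray       # (2, M, f)
    weights: np.ndarray        # (2, M), rows sum to 1
    th_rej: float = 0.6
    log_transform: bool = False
    classes: tuple[str, str] = CLASSES

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.log_vars = np.asarray(self.log_vars, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            raise ValueError("prototype weights must sum to 1 per class")

    # -- inference ---------------------------------------------------------
    def _log_mixture(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) log class-conditional mixture likelihoods."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature vector")
        d = X[:, None, None, :] - self.means[None]          # (n, 2, M, f)
        var = np.exp(self.log_vars)[None]
        log_norm = -0.5 * (self.log_vars.sum(axis=-1)
                           + self.means.shape[-1] * np.log(2 * np.pi))
        log_comp = log_norm[None] - 0.5 * (d * d / var).sum(axis=-1)
        log_comp = log_comp + np.log(self.weights)[None]
        m = log_comp.max(axis=-1, keepdims=True)
        return (m[..., 0] + np.log(np.exp(log_comp - m).sum(axis=-1)))

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) posterior over (both_hands, both_feet), equal priors."""
        logf = self._log_mixture(X)
        m = logf.max(axis=1, keepdims=True)
        p = np.exp(logf - m)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        post = self.posterior(X)
        return np.asarray(self.classes, dtype=object)[post.argmax(axis=1)]

    # -- persistence -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "mask": [[c, f] for c, f in self.mask],
            "means": self.means.tolist(),
            "log_vars": self.log_vars.tolist(),
            "weights": self.weights.tolist(),
            "th_rej": self.th_rej,
            "log_transform": self.log_transform,
            "classes": list(self.classes)})

    @classmethod
    def from_json(cls, text: str) -> "GaussianClassifier":
        d = json.loads(text)
        return cls([(c, float(f)) for c, f in d["mask"]],
                   np.array(d["means"]), np.array(d["log_vars"]),
                   np.array(d["weights"]), d["th_rej"], d["log_transform"],
                   tuple(d["classes"]))


def _som_init(X: np.ndarray, n_prototypes: int, rng: np.random.Generator,
              epochs: int = 200) -> np.ndarray:
    """1-D ring SOM over one class's feature vectors (batch updates)."""
    n, f = X.shape
    qs = np.linspace(0.2, 0.8, n_prototypes)
    protos = np.quantile(X, qs, axis=0) + 1e-6 * rng.standard_normal(
        (n_prototypes, f)) * (X.std(axis=0) + 1e-12)
    ring = np.arange(n_prototypes)
    ring_d = np.abs(ring[:, None] - ring[None, :])
    ring_d = np.minimum(ring_d, n_prototypes - ring_d)
    for ep in range(epochs):
        sigma = max(0.5, n_prototypes / 2.0 * np.exp(-3.0 * ep / epochs))
        d2 = ((X[:, None, :] - protos[None]) ** 2).sum(axis=-1)
        bmu = d2.argmin(axis=1)
        h = np.exp(-0.5 * (ring_d[bmu] / sigma) ** 2)      # (n, M)
        denom = h.sum(axis=0) + 1e-12
        protos = (h.T @ X) / denom[:, None]
    return protos


def fit_gaussian_classifier(X: np.ndarray, y: np.ndarray, *,
                            mask: FeatureMask | None = None,
                            n_prototypes: int = 2, th_rej: float = 0.6,
                            log_transform: bool = False, lr: float = 0.01,
                            max_epochs: int = 500, tol: float = 1e-6,
                            var_floor: float = 1e-6,
                            classes: tuple[str, str] = CLASSES,
                            seed: int = 0) -> GaussianClassifier:
    """SOM-initialized, gradient-refined Gaussian prototype classifier.

    Per class, prototype means come from a 1-D ring SOM over that class's
    feature vectors; variances start at the within-prototype-assignment
    variance.  Means and log-variances are then refined by full-batch
    gradient descent on the cross-entropy of the two-class posterior until
    the loss decrease falls below ``tol`` or ``max_epochs`` is reached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    f = X.shape[1]
    means = np.empty((2, n_prototypes, f))
    log_vars = np.empty((2, n_prototypes, f))
    global_var = X.var(axis=0, ddof=1) + 1e-12
    floor = var_floor * global_var
    for c, name in enumerate(classes):
        Xc = X[y.astype(str) == name]
        if Xc.shape[0] < 2 * n_prototypes:
            raise ValueError(f"too few samples for class {name}")
        protos = _som_init(Xc, n_prototypes, rng)
        means[c] = protos
        assign = ((Xc[:, None, :] - protos[None]) ** 2).sum(-1).argmin(1)
        for m in range(n_prototypes):
            sub = Xc[assign == m]
            v = sub.var(axis=0, ddof=0) if sub.shape[0] > 1 else global_var
            v = np.maximum(v, floor)
            if np.any(v <= floor + 0.0):
                pass
            log_vars[c, m] = np.log(v)
    weights = np.full((2, n_prototypes), 1.0 / n_prototypes)
    model = GaussianClassifier(mask or [], means, log_vars, weights, th_rej,
                               log_transform, classes)
    y_idx = (y.astype(str) == classes[1]).astype(int)
    prev_loss = np.inf
    for _ in range(max_epochs):
        loss, g_mu, g_lv = _ce_loss_and_grads(model, X, y_idx)
        model.means = model.means - lr * g_mu
        model.log_vars = model.log_vars - lr * g_lv
        model.log_vars = np.maximum(model.log_vars, np.log(floor)[None, None])
        if prev_loss - loss < tol:
            break
        prev_loss = loss
    if np.any(model.log_vars <= np.log(floor)[None, None] + 1e-12):
        warnings.warn("degenerate prototype variance floored", UserWarning,
                      stacklevel=2)
    return model


def _ce_loss_and_grads(model: GaussianClassifier, X: np.ndarray,
                       y_idx: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """Cross-entropy of the posterior and its gradients w.r.t. means and
    log-variances (responsibility-weighted, derived analytically)."""
    n = X.shape[0]
    d = X[:, None, None, :] - model.means[None]             # (n, 2, M, f)
    var = np.exp(model.log_vars)[None]
    log_norm = -0.5 * (model.log_vars.sum(axis=-1)
                       + model.means.shape[-1] * np.log(2 * np.pi))
    log_comp = (log_norm[None] - 0.5 * (d * d / var).sum(axis=-1)
                + np.log(model.weights)[None])              # (n, 2, M)
    m_c = log_comp.max(axis=-1, keepdims=True)
    logf = m_c[..., 0] + np.log(np.exp(log_comp - m_c).sum(axis=-1))  # (n, 2)
    mm = logf.max(axis=1, keepdims=True)
    post = np.exp(logf - mm)
    post /= post.sum(axis=1, keepdims=True)
    p_true = post[np.arange(n), y_idx]
    loss = float(-np.mean(np.log(np.maximum(p_true, 1e-300))))
    # dL/dlogf_c = (post_c - onehot_c)/n ; df propagates through the mixture
    one_hot = np.zeros_like(post)
    one_hot[np.arange(n), y_idx] = 1.0
    dlogf = (post - one_hot) / n                            # (n, 2)
    resp = np.exp(log_comp - logf[..., None])               # (n, 2, M)
    coef = dlogf[..., None] * resp                          # (n, 2, M)
    g_mu = np.einsum("ncm,ncmf->cmf", coef, d / var)
    g_lv = np.einsum("ncm,ncmf->cmf", coef, 0.5 * (d * d / var - 1.0))
    return loss, g_mu, g_lv


def classify(model: GaussianClassifier, x: np.ndarray) -> np.ndarray:
    """Posterior over the two classes for one feature vector (or a batch)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    post = model.posterior(np.atleast_2d(x))
    return post[0] if single else post


def apply_rejection(posterior: np.ndarray, th_rej: float = 0.6) -> bool:
    """Accept iff the maximum posterior reaches the rejection threshold.

    The boundary is inclusive: samples *below* ``th_rej`` are rejected.
    """
    posterior = np.asarray(posterior, dtype=float)
    return bool(posterior.max() >= th_rej)


# ---------------------------------------------------------------------------
# evidence integration
# ---------------------------------------------------------------------------

@dataclass
class Integrator:
    """Exponential evidence accumulator with command delivery.

    Accepted posteriors p update the state y <- y + alpha (p - y) (clipped
    to [0,1] and renormalized); rejected or artifact-frozen samples leave y
    untouched.  A command for class c is delivered when y_c >= 1 - eps_cmd
    outside the refractory period; the state then resets to the uniform
    distribution and integration pauses for ``refractory_s``.  Pure convex
    averaging can never literally reach 1, hence the eps_cmd band.
    """

    alpha: float = 0.1
    eps_cmd: float = 0.025
    refractory_s: float = 1.0
    classes: tuple[str, str] = CLASSES
    y: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    last_command_t: float = -np.inf
    _last_t: float = -np.inf

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        self.y = np.asarray(self.y, dtype=float)

    def reset(self) -> None:
        self.y = np.array([0.5, 0.5])

    def step(self, evidence, t: float) -> str | None:
        """Advance one frame; return the delivered command label or None."""
        if t < self._last_t:
            raise ValueError("timestamps must be non-decreasing")
        self._last_t = t
        in_refractory = (t - self.last_command_t) < self.refractory_s
        if (evidence is None or isinstance(evidence, str)
                or in_refractory):
            if isinstance(evidence, str) and evidence not in (REJECTED, FROZEN):
                raise ValueError(f"unknown evidence sentinel {evidence!r}")
            return None
        p = np.asarray(evidence, dtype=float)
        if p.shape != (2,) or not np.all(np.isfinite(p)):
            raise ValueError("posterior evidence must be a finite 2-vector")
        y = self.y + self.alpha * (p - self.y)
        y = np.clip(y, 0.0, 1.0)
        s = y.sum()
        self.y = y / s if s > 0 else np.array([0.5, 0.5])
        if self.y.max() >= 1.0 - self.eps_cmd:
            cmd = self.classes[int(self.y.argmax())]
            self.reset()
            self.last_command_t = t
            return cmd
        return None

    def run(self, evidence_stream, times) -> list[tuple[float, str]]:
        """Convenience batch driver: [(t, command), ...]."""
        out = []
        for ev, t in zip(evidence_stream, times):
            cmd = self.step(ev, t)
            if cmd is not None:
                out.append((float(t), cmd))
        return out
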