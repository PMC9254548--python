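"""SPD covariance geometry under the affine-invariant Riemannian metric.

The learning analysis represents every 1 s band-passed window by its sample
covariance matrix C = XX'/(T-1), a symmetric positive-definite (SPD) point
on the Riemannian manifold.  Distances between windows and between run-level
class centroids use the affine-invariant geodesic distance

    delta(A, B) = || log(A^{-1/2} B A^{-1/2}) ||_F = sqrt(sum_i log^2 l_i),

with l_i the generalized eigenvalues of the pencil (B, A); run centroids are
geometric (Karcher) means obtained by the classic tangent-space fixed-point
iteration.  All eigen-steps go through Cholesky whitening for stability
rather than explicit inversion.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg as sla

__all__ = ["sample_covariance", "geodesic_distance", "geometric_mean",
           "dispersion", "is_spd"]

#: relative shrinkage added when a covariance is (near-)singular
EPS_SPD_SCALE = 1e-10


class RegularizationEvent(UserWarning):
    """A rank-deficient covariance was shrunk toward the identity."""


def sample_covariance(X: np.ndarray, *, allow_regularization: bool = True
                      ) -> np.ndarray:
    """C = XX'/(T-1) after removing each channel's mean.

    ``X`` is (channels, samples).  If the smallest eigenvalue falls below
    eps = 1e-10 * trace/C, shrinkage ``eps * I`` is added and a
    :class:`RegularizationEvent` warning is issued; with
    ``allow_regularization=False`` a singular matrix raises instead.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (channels, samples)")
    n_ch, T = X.shape
    if T < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / (T - 1)
    C = (C + C.T) / 2.0
    eps = EPS_SPD_SCALE * np.trace(C) / n_ch
    if eps <= 0:
        eps = EPS_SPD_SCALE
    min_eig = float(np.linalg.eigvalsh(C)[0])
    if min_eig < eps:
        if not allow_regularization:
            raise np.linalg.LinAlgError(
                f"singular covariance (min eig {min_eig:.3g}); "
                "T <= C or rank-deficient data")
        warnings.warn("rank-deficient covariance shrunk by eps*I",
                      RegularizationEvent, stacklevel=2)
        C = C + eps * np.eye(n_ch)
    return C


def is_spd(A: np.ndarray, tol: float = 1e-10) -> bool:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        return False
    if not np.allclose(A, A.T, atol=tol * max(1.0, float(np.abs(A).max()))):
        return False
    try:
        np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return False
    return True


def _chol_or_raise(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    try:
        return np.linalg.cholesky((A + A.T) / 2.0)
    except np.linalg.LinAlgError as err:
        raise ValueError("matrix is not symmetric positive definite") from err


def _whiten(mats: np.ndarray, L: np.ndarray) -> np.ndarray:
    """L^{-1} C L^{-T} for a stack of matrices (batched)."""
    inv_L = sla.solve_triangular(L, np.eye(L.shape[0]), lower=True)
    return np.einsum("ij,...jk,lk->...il", inv_L, mats, inv_L)


def geodesic_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant geodesic distance between two SPD matrices."""
    L = _chol_or_raise(A)
    W = _whiten(np.asarray(B, dtype=float)[None], L)[0]
    eigs = np.linalg.eigvalsh((W + W.T) / 2.0)
    if eigs[0] <= 0:
        raise ValueError("second matrix is not positive definite")
    return float(np.sqrt(np.sum(np.log(eigs) ** 2)))


def _logm_spd_stack(W: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((W + np.swapaxes(W, -1, -2)) / 2.0)
    if np.any(vals <= 0):
        raise ValueError("non-SPD matrix in stack")
    lv = np.log(vals)
    return np.einsum("...ij,...j,...kj->...ik", vecs, lv, vecs)


def _expm_spd(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    return (vecs * np.exp(vals)) @ vecs.T


def geometric_mean(mats: np.ndarray | list[np.ndarray], *, tol: float = 1e-8,
                   max_iter: int = 50) -> np.ndarray:
    """Karcher mean of a set of SPD matrices.

    Fixed point of M <- M^{1/2} exp( mean_i log(M^{-1/2} C_i M^{-1/2}) )
    M^{1/2}, initialized at the arithmetic mean; stops when the Frobenius
    norm of the tangent-space mean drops below ``tol``.  On non-convergence
    the best iterate is returned with a warning.
    """
    stack = np.asarray(mats, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] == 0:
        raise ValueError("empty SPD set")
    M = stack.mean(axis=0)
    best, best_norm = M, np.inf
    step = 1.0
    prev_norm = np.inf
    for _ in range(max_iter):
        L = _chol_or_raise(M)
        T = _logm_spd_stack(_whiten(stack, L)).mean(axis=0)
        norm = float(np.linalg.norm(T))
        if norm < best_norm:
            best, best_norm = M, norm
        if norm < tol:
            return M
        # damp the step whenever the tangent residual stops shrinking;
        # the full step can oscillate on badly conditioned sets
        if norm >= prev_norm:
            step = max(step / 2.0, 1.0 / 64.0)
        prev_norm = norm
        M = L @ _expm_spd(step * T) @ L.T
        M = (M + M.T) / 2.0
    # evaluate the final iterate too
    L = _chol_or_raise(M)
    norm = float(np.linalg.norm(_logm_spd_stack(_whiten(stack, L)).mean(axis=0)))
    if norm < best_norm:
        best, best_norm = M, norm
    if best_norm >= tol:
        warnings.warn(f"geometric mean not converged (residual {best_norm:.2e})",
                      RuntimeWarning, stacklevel=2)
    return best


def pairwise_distances_to(mats: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Geodesic distance of each matrix in a stack to ``center`` (batched)."""
    L = _chol_or_raise(center)
    W = _whiten(np.asarray(mats, dtype=float), L)
    vals = np.linalg.eigvalsh((W + np.swapaxes(W, -1, -2)) / 2.0)
    if np.any(vals <= 0):
        raise ValueError("non-SPD matrix in stack")
    return np.sqrt((np.log(vals) ** 2).sum(axis=-1))


def dispersion(mats: np.ndarray | list[np.ndarray], center: np.ndarray
               ) -> float:
    """Mean geodesic distance of the set members to ``center``."""
    stack = np.asarray(mats, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] == 0:
        raise ValueError("empty SPD set")
    return float(pairwise_distances_to(stack, center).mean())
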