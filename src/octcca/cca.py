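"""Canonical correlation analysis via a generalized eigenproblem.

Given two zero-mean multichannel signals A (d_a x Np) and B (d_b x Np), CCA
finds weight vectors w_a, w_b maximizing the Pearson correlation between
w_a' A and w_b' B. With covariance blocks C_aa = A A', C_bb = B B',
C_ab = A B', the squared canonical correlations are the generalized
eigenvalues of

    C_ab C_bb^{-1} C_ba  w = lambda C_aa w,

and the canonical correlations are their square roots. Covariances are left
unnormalized (no 1/Np); correlations are invariant to that scale. Near-
singular covariance blocks (short windows of heavily filtered EEG) are
ridge-regularized with eps * trace/dim on the diagonal, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["CanonicalResult", "cca", "max_canonical_corr", "pearson"]

#: relative ridge added to a covariance block that is numerically singular
RIDGE_EPS = 1e-8
#: min eigenvalue / mean eigenvalue below which a block counts as singular
_SINGULAR_RTOL = 1e-10


@dataclass(frozen=True)
class CanonicalResult:
    """Canonical weights (columns, descending correlation) and correlations."""

    weights_a: np.ndarray  # (dim_a, n_comp)
    weights_b: np.ndarray  # (dim_b, n_comp)
    correlations: np.ndarray  # (n_comp,) in [0, 1], non-increasing


def _as_2d(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "data", x), dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D signal matrix, got ndim={arr.ndim}")
    return arr


def _regularize(cov: np.ndarray, name: str) -> np.ndarray:
    """Ridge a covariance block only if it is numerically rank-deficient."""
    dim = cov.shape[0]
    mean_eig = np.trace(cov) / dim
    if mean_eig <= 0:
        warnings.warn(f"{name} covariance has zero trace; adding absolute ridge")
        return cov + RIDGE_EPS * np.eye(dim)
    min_eig = linalg.eigvalsh(cov)[0]
    if min_eig <= _SINGULAR_RTOL * mean_eig:
        warnings.warn(
            f"{name} covariance is near-singular (min eig {min_eig:.3e}); "
            f"applying ridge {RIDGE_EPS:.0e} * trace/dim"
        )
        return cov + RIDGE_EPS * mean_eig * np.eye(dim)
    return cov


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude element is positive (reproducible output)."""
    idx = np.argmax(np.abs(w))
    return -w if w[idx] < 0 else w


def cca(a, b, n_comp: int | None = None) -> CanonicalResult:
    """Canonical correlation between two signal matrices sharing Np columns.

    Inputs are centered internally, so pre-centering does not change the
    result. Returns the leading ``n_comp`` components (default: all
    min(dim_a, dim_b)).
    """
    A = _as_2d(a)
    B = _as_2d(b)
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"inputs must share the sample axis: {A.shape[1]} vs {B.shape[1]} columns"
        )
    da, db = A.shape[0], B.shape[0]
    max_comp = min(da, db)
    if n_comp is None:
        n_comp = max_comp
    if not (1 <= n_comp <= max_comp):
        raise ValueError(f"n_comp={n_comp} outside [1, {max_comp}]")

    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    Caa = _regularize(A @ A.T, "first-set")
    Cbb = _regularize(B @ B.T, "second-set")
    Cab = A @ B.T

    # M = C_ab C_bb^{-1} C_ba, built symmetrically
    Cbb_inv_Cba = linalg.solve(Cbb, Cab.T, assume_a="pos")
    M = Cab @ Cbb_inv_Cba
    M = (M + M.T) / 2

    eigvals, eigvecs = linalg.eigh(M, Caa)
    order = np.argsort(eigvals)[::-1][:n_comp]  # stable sort; ties by input order
    lams = np.clip(eigvals[order], 0.0, 1.0)
    Wa = eigvecs[:, order]

    Wb = np.empty((db, n_comp))
    for j in range(n_comp):
        wa = _fix_sign(Wa[:, j])
        # scale so wa' C_aa wa = 1 (unit-variance projection)
        na = np.sqrt(wa @ Caa @ wa)
        wa = wa / na if na > 0 else wa
        Wa[:, j] = wa
        wb = Cbb_inv_Cba @ wa  # pairs positively with wa by construction
        nb = np.sqrt(wb @ Cbb @ wb)
        Wb[:, j] = wb / nb if nb > 0 else wb

    return CanonicalResult(
        weights_a=Wa, weights_b=Wb, correlations=np.sqrt(lams)
    )


def max_canonical_corr(a, b) -> float:
    """Largest canonical correlation between the two signal sets."""
    return float(cca(a, b, n_comp=1).correlations[0])


def pearson(u, v) -> float:
    """Pearson correlation of two equal-length vectors (0 on zero variance)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"length mismatch: {u.size} vs {v.size}")
    if u.size < 2:
        raise ValueError("need at least 2 samples")
    du = u - u.mean()
    dv = v - v.mean()
    su = np.sqrt(du @ du)
    sv = np.sqrt(dv @ dv)
    if su == 0 or sv == 0:
        warnings.warn("zero-variance input to pearson; returning 0.0")
        return 0.0
    return float(np.clip((du @ dv) / (su * sv), -1.0, 1.0))
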