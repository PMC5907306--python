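"""Multivariate partial least squares regression via the SIMPLS algorithm.

SIMPLS extracts latent factors by successively deflating the cross-product
matrix S = X^T Y (de Jong's scheme), rather than deflating the data blocks
as NIPALS does.  Both predictors and responses are mean-centered; no
unit-variance scaling is applied.  With k equal to the rank of the centered
predictor block, the fitted values coincide with ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLSRModel", "simpls_fit", "plsr_predict"]


@dataclass
class PLSRModel:
    """Centered-data SIMPLS solution: Y_hat = (X - x_mean) B + y_mean."""

    B: np.ndarray  # p x r coefficients
    intercept: np.ndarray  # r-vector, y_mean - x_mean @ B
    k: int
    feature_means: np.ndarray
    response_means: np.ndarray


def simpls_fit(F: np.ndarray, Y: np.ndarray, k: int) -> PLSRModel:
    """Fit a k-factor SIMPLS regression of Y (n x r) on F (n x p)."""
    F = np.asarray(F, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = F.shape
    if Y.shape[0] != n:
        raise ValueError("F and Y must have the same number of rows")
    if n < 2:
        raise ValueError("at least two training rows are required")
    if not (1 <= k <= min(p, n - 1)):
        raise ValueError(f"k must satisfy 1 <= k <= min(p, n-1) = {min(p, n - 1)}, got {k}")

    x_mean = F.mean(axis=0)
    y_mean = Y.mean(axis=0)
    X0 = F - x_mean
    Y0 = Y - y_mean
    if not np.any(X0):
        raise ValueError("predictor matrix has zero variance after centering")

    r = Y0.shape[1]
    S = X0.T @ Y0  # p x r cross-product, deflated in place
    R = np.zeros((p, k))  # X weights
    Q = np.zeros((r, k))  # Y loadings
    V = np.zeros((p, k))  # orthonormal basis of X loadings

    n_used = k
    for a in range(k):
        # dominant left singular vector of the deflated cross-product
        U, s, _ = np.linalg.svd(S, full_matrices=False)
        if s[0] <= np.finfo(float).eps * max(p, r):
            n_used = a  # cross-product exhausted: no signal left
            break
        w = U[:, 0]
        t = X0 @ w
        t_norm = np.linalg.norm(t)
        if t_norm <= np.finfo(float).eps:
            n_used = a
            break
        t /= t_norm
        w /= t_norm
        p_load = X0.T @ t
        q = Y0.T @ t

        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        v /= np.linalg.norm(v)

        S -= v[:, None] @ (v[None, :] @ S)
        R[:, a] = w
        Q[:, a] = q
        V[:, a] = v

    B = R[:, :n_used] @ Q[:, :n_used].T
    if not np.all(np.isfinite(B)):
        raise ValueError("SIMPLS produced non-finite coefficients")
    intercept = y_mean - x_mean @ B
    return PLSRModel(B=B, intercept=intercept, k=k, feature_means=x_mean, response_means=y_mean)


def plsr_predict(model: PLSRModel, F_new: np.ndarray) -> np.ndarray:
    """Predict responses for new rows: (F_new - x_mean) B + y_mean."""
    F_new = np.asarray(F_new, dtype=np.float64)
    if F_new.ndim == 1:
        F_new = F_new[None, :]
    if F_new.shape[1] != model.B.shape[0]:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.B.shape[0]}, got {F_new.shape[1]}"
        )
    return (F_new - model.feature_means) @ model.B + model.response_means
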