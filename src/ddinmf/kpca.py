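"""Feature-dimension estimation via PCA and Gaussian-kernel kernel PCA.

The reduced dimension is estimated from the ordinary PCA eigen-spectrum
(count the leading components whose eigenvalue is non-negligible relative
to the largest).  Features are then mapped with kernel PCA under the
Gaussian kernel k(x, y) = exp(-||x - y||^2 / (2 * bandwidth)), where
``bandwidth`` plays the role of the kernel variance sigma^2.  New points are
embedded out-of-sample with the training kernel's centering statistics
(Nystrom-style projection), so held-out drugs share the training space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

__all__ = ["KPCAMap", "estimate_dimension", "kpca_fit_transform", "kpca_transform"]


@dataclass
class KPCAMap:
    """Fitted Gaussian kernel PCA: everything needed to embed new points."""

    training_points: np.ndarray  # n x p reference copy
    kernel_bandwidth: float
    n_components: int
    eigenvalues: np.ndarray  # descending, length n_components
    dual_coef: np.ndarray  # n x n_components, columns v_i / sqrt(lambda_i)
    kernel_col_means: np.ndarray  # column means of the training kernel
    kernel_mean: float  # grand mean of the training kernel


def estimate_dimension(F: np.ndarray, epsilon: float = 1e-6) -> int:
    """Count leading PCA eigenvalues >= epsilon * largest eigenvalue."""
    F = np.asarray(F, dtype=np.float64)
    if F.shape[0] < 2:
        raise ValueError("need at least two rows to estimate a dimension")
    X0 = F - F.mean(axis=0)
    sv = np.linalg.svd(X0, compute_uv=False)
    eigvals = sv**2 / (F.shape[0] - 1)
    if eigvals[0] <= 0:
        raise ValueError("feature matrix has zero variance")
    return int(np.sum(eigvals >= epsilon * eigvals[0]))


def _gaussian_kernel(X: np.ndarray, Y: np.ndarray, bandwidth: float) -> np.ndarray:
    return np.exp(-cdist(X, Y, "sqeuclidean") / (2.0 * bandwidth))


def kpca_fit_transform(
    F: np.ndarray, n_components: int, bandwidth: float = 4.0
) -> tuple[KPCAMap, np.ndarray]:
    """Fit Gaussian kernel PCA on F and return the embedded coordinates.

    The kernel matrix is double-centered before eigendecomposition;
    coordinates are eigenvectors scaled by sqrt(eigenvalue), ordered by
    descending eigenvalue.  Components whose eigenvalue is numerically
    nonpositive are truncated.
    """
    F = np.asarray(F, dtype=np.float64)
    n = F.shape[0]
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if not (1 <= n_components <= n):
        raise ValueError(f"n_components must lie in [1, {n}], got {n_components}")

    K = _gaussian_kernel(F, F, bandwidth)
    col_means = K.mean(axis=0)
    grand_mean = float(K.mean())
    Kc = K - col_means[None, :] - col_means[:, None] + grand_mean

    top = eigh(Kc, subset_by_index=(n - n_components, n - 1))
    eigvals = top[0][::-1]
    eigvecs = top[1][:, ::-1]

    tol = max(n * np.finfo(float).eps * max(eigvals[0], 0.0), 0.0)
    keep = int(np.sum(eigvals > tol))
    if keep == 0:
        raise ValueError("kernel matrix has no positive eigenvalues after centering")
    eigvals = eigvals[:keep]
    eigvecs = eigvecs[:, :keep]

    coords = eigvecs * np.sqrt(eigvals)[None, :]
    dual_coef = eigvecs / np.sqrt(eigvals)[None, :]
    kmap = KPCAMap(
        training_points=F.copy(),
        kernel_bandwidth=float(bandwidth),
        n_components=keep,
        eigenvalues=eigvals,
        dual_coef=dual_coef,
        kernel_col_means=col_means,
        kernel_mean=grand_mean,
    )
    return kmap, coords


def kpca_transform(kmap: KPCAMap, F_new: np.ndarray) -> np.ndarray:
    """Embed new points with the training map (no refit)."""
    F_new = np.asarray(F_new, dtype=np.float64)
    if F_new.ndim == 1:
        F_new = F_new[None, :]
    if F_new.shape[1] != kmap.training_points.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: map expects {kmap.training_points.shape[1]}, "
            f"got {F_new.shape[1]}"
        )
    K_new = _gaussian_kernel(F_new, kmap.training_points, kmap.kernel_bandwidth)
    Kc_new = (
        K_new
        - K_new.mean(axis=1, keepdims=True)
        - kmap.kernel_col_means[None, :]
        + kmap.kernel_mean
    )
    return Kc_new @ kmap.dual_coef
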