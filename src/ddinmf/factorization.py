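"""NMF and semi-NMF by multiplicative updates, with objective tracking.

Both factorizations minimize the squared Frobenius residual ||X - W H||_F^2.
NMF constrains W >= 0 and H >= 0 and requires X >= 0.  Semi-NMF admits
mixed-sign X and W while keeping H >= 0: W is refit in closed form through
the Moore-Penrose pseudo-inverse of H, and H takes a multiplicative update
whose numerator/denominator are built from the positive and negative parts
of W^T X and W^T W (see :func:`ddinmf.network.split_signs`), followed by an
elementwise square root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .network import split_signs

__all__ = ["FactorPair", "nmf_decompose", "semi_nmf_decompose", "reconstruction_error"]

_EPS = 1e-9


@dataclass
class FactorPair:
    """Basis matrix W (m x r), nonnegative encoding matrix H (r x n)."""

    W: np.ndarray
    H: np.ndarray
    r: int
    mode: str  # "nmf" | "semi"
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    seed: int | None = None

    @property
    def n_iter(self) -> int:
        return len(self.objective_trace)


def _objective(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    R = X - W @ H
    return float(np.sum(R * R))


def _check_rank(X: np.ndarray, r: int) -> None:
    # r == min(m, n) is admitted: full-rank factorization is well defined and
    # exercised by the exact-recovery checks
    if not (1 <= r <= min(X.shape)):
        raise ValueError(f"r must satisfy 1 <= r <= min{X.shape}, got {r}")


def nmf_decompose(
    X: np.ndarray,
    r: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> FactorPair:
    """Nonnegative factorization X ~ W H by the classical multiplicative rules.

    W and H are initialized i.i.d. Uniform(0, 1) scaled by sqrt(mean(X)/r)
    so the initial product matches X in magnitude.  Iteration stops when the
    relative objective change drops below ``tol`` or after ``max_iter`` steps.
    """
    X = np.asarray(X, dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("NMF requires a nonnegative input matrix")
    _check_rank(X, r)

    rng = np.random.default_rng(seed)
    m, n = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / r)
    W = rng.uniform(size=(m, r)) * scale
    H = rng.uniform(size=(r, n)) * scale

    trace: list[float] = [_objective(X, W, H)]
    converged = False
    for _ in range(max_iter):
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        H *= (W.T @ X) / ((W.T @ W) @ H + _EPS)
        obj = _objective(X, W, H)
        trace.append(obj)
        if abs(trace[-2] - obj) / max(trace[-2], _EPS) < tol:
            converged = True
            break
    return FactorPair(W, H, r, "nmf", trace, converged, seed)


def _semi_init(X: np.ndarray, r: int, init: str, rng: np.random.Generator) -> np.ndarray:
    """Initial H for semi-NMF.

    "kmeans": cluster the columns of X into r groups and use the 0/1
    indicator plus a 0.2 offset (keeps the multiplicative update away from
    absorbing zeros).  "random": |N(0,1)| entries.
    """
    n = X.shape[1]
    if init == "random":
        return np.abs(rng.standard_normal((r, n)))
    if init != "kmeans":
        raise ValueError(f"unknown init {init!r}")
    km = KMeans(n_clusters=r, n_init=5, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(X.T)
    H = np.zeros((r, n))
    H[labels, np.arange(n)] = 1.0
    return H + 0.2


def semi_nmf_decompose(
    X: np.ndarray,
    r: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    init: str = "kmeans",
) -> FactorPair:
    """Semi-NMF X ~ W H with mixed-sign W and nonnegative H.

    Each iteration sets W = X H^+ (H^+ the Moore-Penrose pseudo-inverse)
    and rescales H elementwise by
    sqrt(((W^T X)^pos + (W^T W)^neg H) / ((W^T X)^neg + (W^T W)^pos H)).
    """
    X = np.asarray(X, dtype=np.float64)
    _check_rank(X, r)
    if not np.any(X):
        raise ValueError("semi-NMF is undefined for an all-zero matrix")

    rng = np.random.default_rng(seed)
    H = _semi_init(X, r, init, rng)
    W = X @ np.linalg.pinv(H)

    trace: list[float] = [_objective(X, W, H)]
    converged = False
    for _ in range(max_iter):
        W = X @ np.linalg.pinv(H)
        WtX = W.T @ X
        WtW = W.T @ W
        wtx_pos, wtx_neg = split_signs(WtX)
        wtw_pos, wtw_neg = split_signs(WtW)
        H *= np.sqrt((wtx_pos + wtw_neg @ H + _EPS) / (wtx_neg + wtw_pos @ H + _EPS))
        obj = _objective(X, W, H)
        trace.append(obj)
        if abs(trace[-2] - obj) / max(trace[-2], _EPS) < tol:
            converged = True
            break
    return FactorPair(W, H, r, "semi", trace, converged, seed)


def reconstruction_error(X: np.ndarray, fp: FactorPair) -> float:
    """Frobenius norm ||X - W H||_F (unsquared; the squared objective lives
    in ``fp.objective_trace``)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape != (fp.W.shape[0], fp.H.shape[1]):
        raise ValueError(f"shape mismatch: X {X.shape} vs W H {(fp.W.shape[0], fp.H.shape[1])}")
    return float(np.linalg.norm(X - fp.W @ fp.H, "fro"))
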