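"""Two-phase interaction-prediction pipeline.

Training factorizes the adjacency A ~ W H (NMF on the binarized matrix in
"binary" mode, semi-NMF on the signed matrix in "comprehensive" mode) and
then regresses the transposed encoding matrix H^T on the drug feature
matrix via SIMPLS: H^T = F B.  Prediction maps new-drug features through B
into the latent space (H_x^T = F_x B) and reconstructs interaction scores
against the known drugs as A_x = (W H_x)^T.

Features may optionally be reduced with Gaussian kernel PCA before the
regression; new drugs are embedded with the training-set map so both phases
share one feature space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .factorization import FactorPair, nmf_decompose, semi_nmf_decompose
from .kpca import KPCAMap, kpca_fit_transform, kpca_transform
from .network import FeatureMatrix, SignedAdjacency, binarize
from .plsr import PLSRModel, plsr_predict, simpls_fit

__all__ = [
    "DDINMFModel",
    "ScoreMatrix",
    "train",
    "predict_new",
    "classify_scores",
    "save_model",
    "load_model",
]

MODES = ("binary", "comprehensive")


@dataclass
class DDINMFModel:
    mode: str
    factor_pair: FactorPair
    plsr: PLSRModel
    kpca: KPCAMap | None
    training_drug_ids: list[str]
    r: int
    k: int

    @property
    def W(self) -> np.ndarray:
        return self.factor_pair.W

    @property
    def H(self) -> np.ndarray:
        return self.factor_pair.H


@dataclass
class ScoreMatrix:
    """Predicted interaction scores: rows = new drugs, columns = known drugs."""

    scores: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("score shape does not match id lists")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=pd.Index(self.row_ids, name="drug_id"), columns=self.col_ids
        )


def _numerical_rank(X: np.ndarray) -> int:
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[0] == 0:
        return 0
    return int(np.sum(sv > max(X.shape) * np.finfo(float).eps * sv[0]))


def _resolve_r(A_train: np.ndarray, r) -> int:
    if r == "auto":
        rank = _numerical_rank(A_train)
        r = max(rank // 2, 1)
    r = int(r)
    if not (1 <= r < A_train.shape[0]):
        raise ValueError(f"r must satisfy 1 <= r < m = {A_train.shape[0]}, got {r}")
    return r


def train(
    A: SignedAdjacency,
    F: FeatureMatrix,
    mode: str = "comprehensive",
    r: int | str = "auto",
    k: int = 40,
    factor_opts: dict | None = None,
    kpca_opts: dict | None = None,
    seed: int = 0,
) -> DDINMFModel:
    """Fit the two-phase model on the known drugs.

    Parameters
    ----------
    mode:
        "binary" erases signs and factorizes with NMF; "comprehensive"
        factorizes the signed matrix with semi-NMF.
    r:
        Latent dimension; "auto" uses floor(numerical rank of the training
        matrix / 2).
    k:
        Number of SIMPLS latent factors (capped at its feasible maximum).
    kpca_opts:
        ``None`` disables feature reduction; otherwise a dict with optional
        keys ``n_components`` (int or "auto") and ``bandwidth``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if A.drug_ids != F.drug_ids:
        raise ValueError("adjacency and feature matrix must cover the same drugs in order")
    factor_opts = dict(factor_opts or {})

    if mode == "binary":
        X = binarize(A).matrix.astype(np.float64)
        r = _resolve_r(X, r)
        fp = nmf_decompose(X, r, seed=seed, **factor_opts)
    else:
        X = A.matrix.astype(np.float64)
        r = _resolve_r(X, r)
        fp = semi_nmf_decompose(X, r, seed=seed, **factor_opts)

    feats = F.matrix
    kmap = None
    if kpca_opts is not None:
        opts = dict(kpca_opts)
        n_comp = opts.get("n_components", "auto")
        if n_comp == "auto":
            from .kpca import estimate_dimension

            n_comp = min(estimate_dimension(feats, opts.get("epsilon", 1e-6)), feats.shape[0])
        kmap, feats = kpca_fit_transform(
            feats, n_components=int(n_comp), bandwidth=opts.get("bandwidth", 4.0)
        )

    k_eff = min(int(k), feats.shape[1], feats.shape[0] - 1)
    if k_eff < 1:
        raise ValueError(f"k out of range: {k}")
    plsr = simpls_fit(feats, fp.H.T, k_eff)
    return DDINMFModel(
        mode=mode,
        factor_pair=fp,
        plsr=plsr,
        kpca=kmap,
        training_drug_ids=list(A.drug_ids),
        r=r,
        k=k_eff,
    )


def predict_new(model: DDINMFModel, F_x: FeatureMatrix) -> ScoreMatrix:
    """Score every (new drug, known drug) pair.

    In binary mode larger scores mean more likely to interact; in
    comprehensive mode the sign carries enhancive (+) versus degressive (-).
    """
    overlap = set(F_x.drug_ids) & set(model.training_drug_ids)
    if overlap:
        warnings.warn(f"{len(overlap)} new drug id(s) overlap the training set")
    m = len(model.training_drug_ids)
    if F_x.matrix.shape[0] == 0:
        return ScoreMatrix(np.zeros((0, m)), [], list(model.training_drug_ids))

    feats = F_x.matrix
    if model.kpca is not None:
        feats = kpca_transform(model.kpca, feats)
    H_x_T = plsr_predict(model.plsr, feats)  # n x r
    scores = (model.W @ H_x_T.T).T  # n x m
    return ScoreMatrix(scores, list(F_x.drug_ids), list(model.training_drug_ids))


def classify_scores(scores: ScoreMatrix, mode: str, tau: float = 0.0) -> np.ndarray:
    """Threshold scores into hard labels.

    Comprehensive mode: +1 above tau, -1 below -tau, else 0.  Binary mode:
    1 above tau, else 0.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    s = scores.scores
    if mode == "binary":
        return (s > tau).astype(np.int64)
    return np.where(s > tau, 1, np.where(s < -tau, -1, 0)).astype(np.int64)


def save_model(model: DDINMFModel, out_dir) -> None:
    """Serialize to a directory of CSVs plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = pd.Index(model.training_drug_ids, name="drug_id")
    pd.DataFrame(model.W, index=ids).to_csv(out / "W.csv")
    pd.DataFrame(model.H.T, index=ids).to_csv(out / "H_t.csv")
    pd.DataFrame(model.plsr.B).to_csv(out / "B.csv", index=False)
    meta = {
        "mode": model.mode,
        "r": model.r,
        "k": model.k,
        "seed": model.factor_pair.seed,
        "iterations": model.factor_pair.n_iter,
        "final_objective": model.factor_pair.objective_trace[-1],
        "plsr_intercept": model.plsr.intercept.tolist(),
        "plsr_feature_means": model.plsr.feature_means.tolist(),
        "plsr_response_means": model.plsr.response_means.tolist(),
        "has_kpca": model.kpca is not None,
    }
    if model.kpca is not None:
        kmap = model.kpca
        pd.DataFrame(kmap.training_points).to_csv(out / "kpca_training_points.csv", index=False)
        pd.DataFrame(kmap.dual_coef).to_csv(out / "kpca_dual_coef.csv", index=False)
        meta["kpca"] = {
            "kernel_bandwidth": kmap.kernel_bandwidth,
            "n_components": kmap.n_components,
            "eigenvalues": kmap.eigenvalues.tolist(),
            "kernel_col_means": kmap.kernel_col_means.tolist(),
            "kernel_mean": kmap.kernel_mean,
        }
    (out / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(model_dir) -> DDINMFModel:
    """Load a model saved by :func:`save_model`."""
    src = Path(model_dir)
    meta = json.loads((src / "model.json").read_text())
    W_tab = pd.read_csv(src / "W.csv", index_col=0)
    H_t = pd.read_csv(src / "H_t.csv", index_col=0).to_numpy(dtype=np.float64)
    B = pd.read_csv(src / "B.csv").to_numpy(dtype=np.float64)
    drug_ids = [str(d) for d in W_tab.index]
    fp = FactorPair(
        W=W_tab.to_numpy(dtype=np.float64),
        H=H_t.T,
        r=int(meta["r"]),
        mode="nmf" if meta["mode"] == "binary" else "semi",
        objective_trace=[float(meta["final_objective"])],
        converged=True,
        seed=meta.get("seed"),
    )
    plsr = PLSRModel(
        B=B,
        intercept=np.asarray(meta["plsr_intercept"], dtype=np.float64),
        k=int(meta["k"]),
        feature_means=np.asarray(meta["plsr_feature_means"], dtype=np.float64),
        response_means=np.asarray(meta["plsr_response_means"], dtype=np.float64),
    )
    kmap = None
    if meta.get("has_kpca"):
        kinfo = meta["kpca"]
        kmap = KPCAMap(
            training_points=pd.read_csv(src / "kpca_training_points.csv").to_numpy(np.float64),
            kernel_bandwidth=float(kinfo["kernel_bandwidth"]),
            n_components=int(kinfo["n_components"]),
            eigenvalues=np.asarray(kinfo["eigenvalues"], dtype=np.float64),
            dual_coef=pd.read_csv(src / "kpca_dual_coef.csv").to_numpy(np.float64),
            kernel_col_means=np.asarray(kinfo["kernel_col_means"], dtype=np.float64),
            kernel_mean=float(kinfo["kernel_mean"]),
        )
    return DDINMFModel(
        mode=meta["mode"],
        factor_pair=fp,
        plsr=plsr,
        kpca=kmap,
        training_drug_ids=drug_ids,
        r=int(meta["r"]),
        k=int(meta["k"]),
    )
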