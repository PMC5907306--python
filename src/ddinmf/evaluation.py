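"""Cold-start cross-validation and ranking metrics.

Each CV round holds out 1/K of the drugs as "new" drugs: the training
network is the induced subnetwork on the remaining drugs, and only
(test drug, training drug) pairs are scored — never test x test pairs,
so no held-out topology leaks into training or evaluation.

For signed (comprehensive) prediction the metric inputs are transformed:
enhancive pairs keep their score, degressive pairs contribute the negated
score, both with label 1; non-interacting pairs keep their raw score with
label 0.  AUROC then reduces to the conventional binary computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import predict_new, train
from .network import FeatureMatrix, SignedAdjacency

__all__ = [
    "CVScheme",
    "EvalResult",
    "make_cv_folds",
    "signed_eval_scores",
    "auroc",
    "aupr",
    "run_cv",
    "hitting_ratio",
]


@dataclass
class CVScheme:
    K: int
    folds: list[list[str]]
    seed: int


@dataclass
class EvalResult:
    auroc: float
    aupr: float
    per_fold: list[tuple[float, float]]
    n_repeats: int = 1
    auroc_std: float = 0.0
    aupr_std: float = 0.0
    per_repeat: list[tuple[float, float]] = field(default_factory=list)


def make_cv_folds(drug_ids: list[str], K: int = 10, seed: int = 0) -> CVScheme:
    """Randomly partition drugs into K folds of near-equal size."""
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > len(drug_ids):
        raise ValueError(f"K = {K} exceeds the number of drugs ({len(drug_ids)})")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(drug_ids)))
    folds = [[drug_ids[i] for i in order[f::K]] for f in range(K)]
    return CVScheme(K=K, folds=folds, seed=seed)


def signed_eval_scores(
    scores: np.ndarray, truth: np.ndarray, noninteraction: str = "raw"
) -> tuple[np.ndarray, np.ndarray]:
    """Fold signed truth into a binary ranking problem.

    ``truth`` entries: +1 enhancive, -1 degressive, 0 none.  Enhancive
    pairs keep their score, degressive pairs contribute the negated score
    (a very negative score on a degressive pair is a confident hit), both
    labeled positive.  Non-interactions are labeled negative with their raw
    score by default, or |score| under ``noninteraction="absolute"``.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    if not set(np.unique(truth)).issubset({-1, 0, 1}):
        raise ValueError("truth labels must lie in {-1, 0, +1}")
    if noninteraction not in ("raw", "absolute"):
        raise ValueError("noninteraction must be 'raw' or 'absolute'")

    out = scores.copy()
    out[truth == -1] = -out[truth == -1]
    if noninteraction == "absolute":
        out[truth == 0] = np.abs(out[truth == 0])
    labels = (truth != 0).astype(np.int64)
    return out, labels


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, midrank ties)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step summation, i.e. average
    precision — not trapezoidal)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64)))


def _eval_fold(
    A: SignedAdjacency,
    F: FeatureMatrix,
    test_ids: list[str],
    config: dict,
    seed: int,
) -> tuple[float, float]:
    test_set = set(test_ids)
    train_ids = [d for d in A.drug_ids if d not in test_set]
    A_train = A.subgraph(train_ids)
    if A_train.n_edges == 0:
        raise ValueError("training network has no edges in this fold")

    model = train(
        A_train,
        F.subset(train_ids),
        mode=config.get("mode", "comprehensive"),
        r=config.get("r", "auto"),
        k=config.get("k", 40),
        factor_opts=config.get("factor_opts"),
        kpca_opts=config.get("kpca_opts"),
        seed=seed,
    )
    sm = predict_new(model, F.subset(test_ids))

    idx = {d: i for i, d in enumerate(A.drug_ids)}
    truth = A.matrix[np.ix_([idx[d] for d in test_ids], [idx[d] for d in train_ids])]
    scores = sm.scores

    if config.get("mode", "comprehensive") == "binary":
        labels = (np.abs(truth) > 0).astype(np.int64).ravel()
        s = scores.ravel()
    else:
        s, labels = signed_eval_scores(
            scores.ravel(), truth.ravel(), config.get("noninteraction", "raw")
        )
    return auroc(s, labels), aupr(s, labels)


def run_cv(A: SignedAdjacency, F: FeatureMatrix, config: dict | None = None) -> EvalResult:
    """Repeated K-fold cold-start cross-validation.

    ``config`` keys: mode, r, k, K, repeats, seed, factor_opts, kpca_opts,
    noninteraction.  Aggregates are the mean and standard deviation over
    repeats of the per-repeat fold means.
    """
    config = dict(config or {})
    K = int(config.get("K", 10))
    repeats = int(config.get("repeats", 1))
    seed = int(config.get("seed", 0))

    per_repeat: list[tuple[float, float]] = []
    all_folds: list[tuple[float, float]] = []
    for rep in range(repeats):
        scheme = make_cv_folds(A.drug_ids, K=K, seed=seed + rep)
        fold_metrics = [
            _eval_fold(A, F, fold, config, seed=seed + rep) for fold in scheme.folds
        ]
        all_folds.extend(fold_metrics)
        per_repeat.append(tuple(np.mean(fold_metrics, axis=0)))

    rep_arr = np.asarray(per_repeat)
    return EvalResult(
        auroc=float(rep_arr[:, 0].mean()),
        aupr=float(rep_arr[:, 1].mean()),
        per_fold=all_folds,
        n_repeats=repeats,
        auroc_std=float(rep_arr[:, 0].std()),
        aupr_std=float(rep_arr[:, 1].std()),
        per_repeat=per_repeat,
    )


def hitting_ratio(
    score_list: list[tuple[tuple[str, str], float]],
    truth_set: set[tuple[str, str]],
    k_list: list[int],
) -> dict[int, float]:
    """Fraction of the top-k ranked candidate pairs found in the truth set.

    Pairs are treated as unordered.  ``score_list`` holds
    ((drug_a, drug_b), score) candidates; higher scores rank first.
    """
    if not score_list:
        raise ValueError("candidate list is empty")
    if any(k > len(score_list) or k < 1 for k in k_list):
        raise ValueError("every k must lie in [1, number of candidates]")
    canon = lambda pair: tuple(sorted(pair))
    truth = {canon(p) for p in truth_set}
    ranked = sorted(score_list, key=lambda item: -item[1])
    hits = np.cumsum([1 if canon(pair) in truth else 0 for pair, _ in ranked])
    return {k: float(hits[k - 1] / k) for k in k_list}
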