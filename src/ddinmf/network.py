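"""Signed/binary interaction-network data model and edge-list / feature-table I/O.

A drug-drug interaction (DDI) network is held as a dense symmetric adjacency
matrix.  Signed networks carry entries in {-1, 0, +1}: +1 for an enhancive
interaction, -1 for a degressive one, 0 for no known interaction.  Rows and
columns are aligned to a lexicographically sorted list of drug identifiers so
that file round-trips are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignedAdjacency",
    "BinaryAdjacency",
    "FeatureMatrix",
    "DegreeProfile",
    "read_signed_edge_list",
    "write_signed_edge_list",
    "read_feature_table",
    "write_feature_table",
    "binarize",
    "split_signs",
    "degree_profile",
]

_SIGN_ALIASES = {"1": 1, "+1": 1, "E": 1, "-1": -1, "−1": -1, "D": -1}


def _check_adjacency(matrix: np.ndarray, drug_ids: list[str], domain: set[int]) -> None:
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {matrix.shape}")
    if len(drug_ids) != matrix.shape[0]:
        raise ValueError("drug_ids length does not match matrix size")
    if len(set(drug_ids)) != len(drug_ids):
        raise ValueError("drug_ids must be unique")
    if not np.array_equal(matrix, matrix.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(matrix) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if not set(np.unique(matrix)).issubset(domain):
        raise ValueError(f"adjacency entries must lie in {sorted(domain)}")


@dataclass
class SignedAdjacency:
    """Symmetric m x m adjacency with entries in {-1, 0, +1}."""

    matrix: np.ndarray
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        self.drug_ids = list(self.drug_ids)
        _check_adjacency(self.matrix, self.drug_ids, {-1, 0, 1})

    @property
    def m(self) -> int:
        return len(self.drug_ids)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.matrix)))

    def subgraph(self, drug_ids: list[str]) -> "SignedAdjacency":
        """Induced subnetwork on ``drug_ids`` (kept in the given order)."""
        index = {d: i for i, d in enumerate(self.drug_ids)}
        rows = [index[d] for d in drug_ids]
        return SignedAdjacency(self.matrix[np.ix_(rows, rows)], list(drug_ids))


@dataclass
class BinaryAdjacency:
    """Symmetric m x m adjacency with entries in {0, 1}."""

    matrix: np.ndarray
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        self.drug_ids = list(self.drug_ids)
        _check_adjacency(self.matrix, self.drug_ids, {0, 1})

    @property
    def m(self) -> int:
        return len(self.drug_ids)


@dataclass
class FeatureMatrix:
    """m x p per-drug feature table, rows aligned to ``drug_ids``.

    Features are binary descriptors before any reduction and real-valued
    afterwards (e.g. kernel-PCA coordinates).
    """

    matrix: np.ndarray
    drug_ids: list[str]
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        self.drug_ids = list(self.drug_ids)
        if self.matrix.shape[0] != len(self.drug_ids):
            raise ValueError("row count must equal number of drug ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")
        if self.feature_names is not None and len(self.feature_names) != self.matrix.shape[1]:
            raise ValueError("feature_names length does not match column count")

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def subset(self, drug_ids: list[str]) -> "FeatureMatrix":
        index = {d: i for i, d in enumerate(self.drug_ids)}
        rows = [index[d] for d in drug_ids]
        return FeatureMatrix(self.matrix[rows], list(drug_ids), self.feature_names)


@dataclass
class DegreeProfile:
    """Per-drug degree bookkeeping for a signed network."""

    drug_ids: list[str]
    degree: np.ndarray
    pos_degree: np.ndarray
    neg_degree: np.ndarray
    diff: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.degree = np.asarray(self.degree, dtype=np.int64)
        self.pos_degree = np.asarray(self.pos_degree, dtype=np.int64)
        self.neg_degree = np.asarray(self.neg_degree, dtype=np.int64)
        if not np.array_equal(self.degree, self.pos_degree + self.neg_degree):
            raise ValueError("degree must equal pos_degree + neg_degree")
        self.diff = self.pos_degree - self.neg_degree

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": self.drug_ids,
                "degree": self.degree,
                "pos_degree": self.pos_degree,
                "neg_degree": self.neg_degree,
                "diff": self.diff,
            }
        )


def _parse_sign(token: str) -> int:
    token = str(token).strip()
    if token not in _SIGN_ALIASES:
        raise ValueError(f"malformed sign {token!r}; expected +1/-1 or E/D")
    return _SIGN_ALIASES[token]


def read_signed_edge_list(path, strict: bool = True) -> SignedAdjacency:
    """Read a TSV edge list (columns drug_a, drug_b, sign) into an adjacency.

    Drugs are ordered lexicographically.  Duplicate orientations of the same
    undirected pair collapse silently when signs agree; conflicting signs
    raise in strict mode and keep the first occurrence (with a warning)
    otherwise.  Self-loops always raise.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["drug_a", "drug_b", "sign"]
    if list(table.columns[:3]) != required:
        raise ValueError(f"edge list must have header columns {required}, got {list(table.columns)}")

    edges: dict[tuple[str, str], int] = {}
    for row in table.itertuples(index=False):
        a, b = str(row.drug_a), str(row.drug_b)
        if a == b:
            raise ValueError(f"self-loop on drug {a!r}")
        sign = _parse_sign(row.sign)
        key = (a, b) if a < b else (b, a)
        if key in edges:
            if edges[key] != sign:
                if strict:
                    raise ValueError(f"conflicting signs for pair {key}")
                warnings.warn(f"conflicting signs for pair {key}; keeping first occurrence")
        else:
            edges[key] = sign

    drug_ids = sorted({d for pair in edges for d in pair})
    index = {d: i for i, d in enumerate(drug_ids)}
    matrix = np.zeros((len(drug_ids), len(drug_ids)), dtype=np.int64)
    for (a, b), sign in edges.items():
        matrix[index[a], index[b]] = sign
        matrix[index[b], index[a]] = sign
    return SignedAdjacency(matrix, drug_ids)


def write_signed_edge_list(A: SignedAdjacency, path) -> None:
    """Write one undirected edge per row, signs as +1/-1."""
    i_idx, j_idx = np.nonzero(np.triu(A.matrix))
    table = pd.DataFrame(
        {
            "drug_a": [A.drug_ids[i] for i in i_idx],
            "drug_b": [A.drug_ids[j] for j in j_idx],
            "sign": A.matrix[i_idx, j_idx],
        }
    )
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path, sep: str | None = None) -> FeatureMatrix:
    """Read a CSV/TSV feature table: first column drug id, rest numeric."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep, index_col=0)
    return FeatureMatrix(
        table.to_numpy(dtype=np.float64),
        [str(d) for d in table.index],
        [str(c) for c in table.columns],
    )


def write_feature_table(F: FeatureMatrix, path, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    names = F.feature_names or [f"f{k}" for k in range(F.p)]
    table = pd.DataFrame(F.matrix, index=pd.Index(F.drug_ids, name="drug_id"), columns=names)
    table.to_csv(path, sep=sep)


def binarize(A: SignedAdjacency) -> BinaryAdjacency:
    """Erase signs: entry |a_ij|, turning degressive (-1) edges into 1."""
    return BinaryAdjacency(np.abs(A.matrix), A.drug_ids)


def split_signs(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a real matrix into its nonnegative parts.

    Returns ``(pos, neg)`` with ``pos = (|X| + X) / 2`` and
    ``neg = (|X| - X) / 2``, so ``X == pos - neg``, both parts are
    elementwise nonnegative, and ``pos * neg == 0``.
    """
    X = np.asarray(X, dtype=np.float64)
    absX = np.abs(X)
    return (absX + X) / 2.0, (absX - X) / 2.0


def degree_profile(A: SignedAdjacency) -> DegreeProfile:
    """Count per-drug total, enhancive (+1) and degressive (-1) partners."""
    pos = (A.matrix == 1).sum(axis=1)
    neg = (A.matrix == -1).sum(axis=1)
    return DegreeProfile(A.drug_ids, pos + neg, pos, neg)
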