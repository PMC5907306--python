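"""Signed-network structure: triangle census under balance theory, balance
fractions, latent-space embeddings of the factor matrices, and degree /
embedding rank correlations.

Triangles are unordered node triples whose three pairwise entries are all
nonzero, classified by how many of the three edges are negative: 0 or 2
negatives are balanced, exactly 1 negative is unbalanced, 3 negatives are
weakly balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .factorization import FactorPair
from .kpca import kpca_fit_transform
from .network import DegreeProfile, SignedAdjacency

__all__ = [
    "TriangleCensus",
    "LatentEmbedding",
    "triangle_census",
    "balance_fraction",
    "latent_embedding",
    "degree_embedding_correlation",
]


@dataclass
class TriangleCensus:
    n_ppp: int  # no negative edge
    n_pnn: int  # two negative edges
    n_npp: int  # exactly one negative edge
    n_nnn: int  # three negative edges

    @property
    def n_balanced(self) -> int:
        return self.n_ppp + self.n_pnn

    @property
    def n_unbalanced(self) -> int:
        return self.n_npp

    @property
    def n_weak(self) -> int:
        return self.n_nnn

    @property
    def total(self) -> int:
        return self.n_ppp + self.n_pnn + self.n_npp + self.n_nnn

    def as_dict(self) -> dict[str, int]:
        return {
            "ppp": self.n_ppp,
            "pnn": self.n_pnn,
            "npp": self.n_npp,
            "nnn": self.n_nnn,
            "balanced": self.n_balanced,
            "unbalanced": self.n_unbalanced,
            "weakly_balanced": self.n_weak,
            "total": self.total,
        }


@dataclass
class LatentEmbedding:
    coordinates: np.ndarray  # m x c, columns ordered by descending eigenvalue
    source: str  # "community" (rows of W) | "encoding" (columns of H)
    eigenvalues: np.ndarray
    drug_ids: list[str] | None = None


def triangle_census(A: SignedAdjacency) -> TriangleCensus:
    """Count the four signed triangle patterns.

    Uses closed walks of length 3: with P and N the 0/1 matrices of positive
    and negative edges, triangles with 0/3 negatives are tr(P^3)/6 and
    tr(N^3)/6, and those with exactly 1 or 2 negatives are tr(N P P)/2 and
    tr(P N N)/2 (each unordered triangle yields six ordered walks, of which
    two match a fixed cyclic sign sequence).
    """
    P = (A.matrix == 1).astype(np.float64)
    N = (A.matrix == -1).astype(np.float64)
    n_ppp = round(np.trace(P @ P @ P) / 6.0)
    n_nnn = round(np.trace(N @ N @ N) / 6.0)
    n_npp = round(np.trace(N @ P @ P) / 2.0)
    n_pnn = round(np.trace(P @ N @ N) / 2.0)
    return TriangleCensus(int(n_ppp), int(n_pnn), int(n_npp), int(n_nnn))


def balance_fraction(census: TriangleCensus, include_weak: bool = False) -> float:
    """Fraction of balanced triangles (optionally counting weakly balanced
    ones as balanced)."""
    if census.total == 0:
        raise ValueError("network has no triangles")
    balanced = census.n_balanced + (census.n_weak if include_weak else 0)
    return balanced / census.total


def latent_embedding(
    fp: FactorPair,
    source: str = "community",
    c: int = 3,
    bandwidth: float = 4.0,
    drug_ids: list[str] | None = None,
) -> LatentEmbedding:
    """Kernel-PCA embedding of per-drug latent features.

    "community" embeds the rows of W (how each drug contributes to each
    community); "encoding" embeds the columns of H (how strongly each drug
    belongs to each community).
    """
    if source == "community":
        X = fp.W
    elif source == "encoding":
        if np.min(fp.H) < 0:
            raise ValueError("encoding matrix H must be nonnegative")
        X = fp.H.T
    else:
        raise ValueError(f"source must be 'community' or 'encoding', got {source!r}")
    if c > X.shape[0]:
        raise ValueError(f"c = {c} exceeds the number of drugs ({X.shape[0]})")
    kmap, coords = kpca_fit_transform(X, n_components=c, bandwidth=bandwidth)
    return LatentEmbedding(coords, source, kmap.eigenvalues, drug_ids)


def degree_embedding_correlation(
    emb: LatentEmbedding,
    profile: DegreeProfile,
    which: str = "degree",
    component: int = 0,
) -> float:
    """Spearman rank correlation between a degree quantity and one embedded
    principal component."""
    if which == "degree":
        values = profile.degree
    elif which == "diff":
        values = profile.diff
    else:
        raise ValueError("which must be 'degree' or 'diff'")
    if emb.coordinates.shape[0] != len(values):
        raise ValueError("embedding and degree profile must cover the same drugs")
    coord = emb.coordinates[:, component]
    if np.all(coord == coord[0]) or np.all(values == values[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho = spearmanr(values, coord).statistic
    return float(rho)
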