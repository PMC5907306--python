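"""Synthetic signed networks with planted communities and tunable balance.

Edges follow a planted-partition model (probability ``p_in`` within a
community, ``p_out`` across).  Each drug carries a polarity in {+1, -1} and
the base sign of an edge is the product of its endpoints' polarities — a
construction under which every triangle has an even number (< 3) of
negative edges, i.e. the network is exactly structurally balanced.
``sign_noise`` then flips each edge sign independently, interpolating
toward a random signing.  Feature vectors are block-structured binary
indicators of community membership plus flip noise, so the map from
features to factorization encodings is learnable by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import FeatureMatrix, SignedAdjacency

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_signed_network",
    "generate_features",
    "generate_benchmark",
    "PRESETS",
]


@dataclass
class SyntheticSpec:
    m: int = 200
    c: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    polarity_fraction: float = 0.25
    sign_noise: float = 0.05
    p_features: int = 300
    feature_signal: int = 40
    feature_flip: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_in": self.p_in,
            "p_out": self.p_out,
            "polarity_fraction": self.polarity_fraction,
            "sign_noise": self.sign_noise,
            "feature_flip": self.feature_flip,
        }
        for name, value in probs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not (self.m >= self.c >= 1):
            raise ValueError(f"need m >= c >= 1, got m={self.m}, c={self.c}")
        if self.p_features < self.c * self.feature_signal:
            raise ValueError("p_features must be at least c * feature_signal")


@dataclass
class SyntheticTruth:
    communities: np.ndarray  # community index per drug
    polarity: np.ndarray  # +1/-1 per drug
    adjacency: SignedAdjacency
    features: FeatureMatrix | None = None
    spec: SyntheticSpec | None = None


PRESETS: dict[str, dict] = {
    "small": dict(m=60, c=3, p_features=120, feature_signal=20),
    # Chosen so cold-start recovery is information-theoretically comfortable:
    # edges are i.i.d. given communities, so the Bayes AUROC ceiling is set by
    # p_in/p_out contrast, and sign recovery is capped by the polarity prior.
    "default": dict(
        m=200,
        c=4,
        p_in=0.45,
        p_out=0.005,
        polarity_fraction=0.08,
        sign_noise=0.03,
        p_features=300,
        feature_signal=40,
        feature_flip=0.05,
    ),
}


def generate_signed_network(spec: SyntheticSpec) -> SyntheticTruth:
    """Draw a planted-partition signed network from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    m, c = spec.m, spec.c

    communities = np.sort(rng.integers(c, size=m))
    # guarantee every community is populated
    communities[:c] = np.arange(c)
    communities = np.sort(communities)

    polarity = np.where(rng.random(m) < spec.polarity_fraction, -1, 1)

    same = communities[:, None] == communities[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    upper = np.triu(rng.random((m, m)) < prob, k=1)

    base_sign = polarity[:, None] * polarity[None, :]
    flip = np.where(rng.random((m, m)) < spec.sign_noise, -1, 1)
    signs = np.where(upper, base_sign * flip, 0)
    matrix = signs + signs.T

    drug_ids = [f"d{i:04d}" for i in range(m)]
    adjacency = SignedAdjacency(matrix, drug_ids)
    return SyntheticTruth(communities=communities, polarity=polarity, adjacency=adjacency, spec=spec)


def generate_features(truth: SyntheticTruth, spec: SyntheticSpec) -> FeatureMatrix:
    """Binary features: per-community signal blocks plus flip/background noise."""
    rng = np.random.default_rng(spec.seed + 1)
    m = len(truth.communities)
    F = np.zeros((m, spec.p_features), dtype=np.float64)
    for comm in range(spec.c):
        cols = slice(comm * spec.feature_signal, (comm + 1) * spec.feature_signal)
        F[truth.communities == comm, cols] = 1.0
    n_signal = spec.c * spec.feature_signal
    F[:, n_signal:] = rng.integers(2, size=(m, spec.p_features - n_signal))
    flips = rng.random((m, spec.p_features)) < spec.feature_flip
    F[flips] = 1.0 - F[flips]
    return FeatureMatrix(F, truth.adjacency.drug_ids, [f"f{k}" for k in range(spec.p_features)])


def generate_benchmark(
    preset: str = "default", seed: int = 0
) -> tuple[SignedAdjacency, FeatureMatrix, SyntheticTruth]:
    """Generate a named benchmark (adjacency, features, ground truth)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    spec = SyntheticSpec(**PRESETS[preset], seed=seed)
    truth = generate_signed_network(spec)
    features = generate_features(truth, spec)
    truth.features = features
    return truth.adjacency, features, truth


def save_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "communities": truth.communities.tolist(),
        "polarity": truth.polarity.tolist(),
        "drug_ids": truth.adjacency.drug_ids,
    }
    if truth.spec is not None:
        payload["spec"] = {k: getattr(truth.spec, k) for k in truth.spec.__dataclass_fields__}
    Path(path).write_text(json.dumps(payload, indent=2))
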