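import numpy as np
import pytest
from scipy.stats import spearmanr

from ddinmf import (
    FeatureMatrix,
    ScoreMatrix,
    SignedAdjacency,
    binarize,
    classify_scores,
    load_model,
    predict_new,
    save_model,
    train,
)


def tiny_network():
    """Seven known drugs with a handful of signed interactions."""
    m = 7
    mat = np.zeros((m, m), dtype=int)
    edges = [(0, 1, 1), (0, 2, 1), (1, 2, 1), (2, 3, -1), (3, 4, -1), (4, 5, 1), (5, 6, 1), (3, 6, -1)]
    for i, j, s in edges:
        mat[i, j] = mat[j, i] = s
    ids = [f"d{i}" for i in range(m)]
    return SignedAdjacency(mat, ids)


@pytest.fixture
def tiny():
    A = tiny_network()
    rng = np.random.default_rng(0)
    F = FeatureMatrix(rng.integers(2, size=(7, 12)).astype(float), A.drug_ids)
    return A, F


class TestTrain:
    def test_smoke_contract(self, tiny):
        A, F = tiny
        model = train(A, F, mode="comprehensive", r=2, k=2, seed=0)
        assert model.r == 2
        assert model.factor_pair.H.min() >= 0
        assert np.isfinite(model.factor_pair.objective_trace[-1])

    def test_planted_rank2_recovery(self):
        # A built from a signed rank-2 factorization with F := H0^T: the
        # pipeline should reproduce A's entries up to high rank correlation
        rng = np.random.default_rng(3)
        m = 40
        W0 = rng.standard_normal((m, 2))
        H0 = rng.random((2, m))
        X = W0 @ H0
        # symmetrize and sign to build a valid adjacency
        S = (X + X.T) / 2
        mat = np.where(np.abs(S) > np.median(np.abs(S)), np.sign(S), 0).astype(int)
        np.fill_diagonal(mat, 0)
        ids = [f"d{i:02d}" for i in range(m)]
        A = SignedAdjacency(mat, ids)
        model = train(A, FeatureMatrix(np.abs(rng.standard_normal((m, 8))), ids), "comprehensive", r=4, k=4, seed=0)
        # training-set self-reconstruction correlates with adjacency entries
        recon = model.W @ model.H
        rho = spearmanr(recon.ravel(), A.matrix.ravel()).statistic
        assert rho > 0.5

    def test_self_prediction_spearman(self):
        # exact planted case: A = W0 H0 (signed, rank 2), F = H0^T
        rng = np.random.default_rng(5)
        m = 30
        W0 = np.vstack([rng.standard_normal(m), rng.standard_normal(m)]).T
        H0 = rng.random((2, m))
        X = W0 @ H0
        S = X + X.T
        np.fill_diagonal(S, 0)
        ids = [f"d{i:02d}" for i in range(m)]
        # keep a real-valued target for correlation; adjacency must be ternary
        mat = np.sign(S) * (np.abs(S) > np.quantile(np.abs(S), 0.4))
        np.fill_diagonal(mat, 0)
        A = SignedAdjacency(mat.astype(int), ids)
        F = FeatureMatrix(H0.T, ids)
        model = train(A, F, mode="comprehensive", r=2, k=2, seed=1)
        with pytest.warns(UserWarning, match="overlap"):
            scores = predict_new(model, F).scores  # self-prediction
        rho = spearmanr(scores.ravel(), A.matrix.ravel()).statistic
        assert rho > 0.5

    def test_binary_mode_equals_explicit_binarize(self, tiny):
        A, F = tiny
        m1 = train(A, F, mode="binary", r=2, k=2, seed=4)
        B = binarize(A)
        A_bin = SignedAdjacency(B.matrix, B.drug_ids)
        m2 = train(A_bin, F, mode="binary", r=2, k=2, seed=4)
        assert np.array_equal(m1.W, m2.W)
        assert np.array_equal(m1.plsr.B, m2.plsr.B)

    def test_auto_rank(self, tiny):
        A, F = tiny
        model = train(A, F, mode="binary", r="auto", k=2, seed=0)
        expected = max(np.linalg.matrix_rank(binarize(A).matrix.astype(float)) // 2, 1)
        assert model.r == expected

    def test_mismatched_drugs_rejected(self, tiny):
        A, F = tiny
        F_bad = FeatureMatrix(F.matrix, [f"x{i}" for i in range(7)])
        with pytest.raises(ValueError, match="same drugs"):
            train(A, F_bad, r=2, k=2)

    def test_invalid_mode_rejected(self, tiny):
        A, F = tiny
        with pytest.raises(ValueError, match="mode"):
            train(A, F, mode="nope", r=2, k=2)

    def test_kpca_reduction_path(self, tiny):
        A, F = tiny
        model = train(A, F, r=2, k=2, kpca_opts={"n_components": 4, "bandwidth": 2.0}, seed=0)
        assert model.kpca is not None
        sm = predict_new(model, FeatureMatrix(F.matrix[:2] * 0.0, ["n1", "n2"]))
        assert sm.scores.shape == (2, 7)


class TestPredictNew:
    def test_duplicate_of_training_drug(self):
        A, F, _ = _benchmark_small()
        model = train(A, F, mode="binary", r=6, k=8, seed=0)
        d = 5
        F_new = FeatureMatrix(F.matrix[[d]], ["new0"])
        sm = predict_new(model, F_new)
        recon_row = (model.W @ model.H)[:, d]
        # bounded by the PLSR training residual mapped through W
        resid = model.H.T[d] - (F.matrix[[d]] - model.plsr.feature_means) @ model.plsr.B - model.plsr.response_means
        bound = np.linalg.norm(model.W, 2) * np.linalg.norm(resid) + 1e-8
        assert np.linalg.norm(sm.scores[0] - recon_row) <= bound

    def test_mean_feature_row(self):
        A, F, _ = _benchmark_small()
        model = train(A, F, mode="binary", r=4, k=5, seed=0)
        F_new = FeatureMatrix(model.plsr.feature_means[None, :], ["new0"])
        sm = predict_new(model, F_new)
        expected = model.W @ model.plsr.response_means
        assert np.allclose(sm.scores[0], expected, atol=1e-10)

    def test_empty_input(self):
        A, F, _ = _benchmark_small()
        model = train(A, F, mode="binary", r=4, k=5, seed=0)
        sm = predict_new(model, FeatureMatrix(np.zeros((0, F.p)), []))
        assert sm.scores.shape == (0, A.m)

    def test_overlap_warns(self):
        A, F, _ = _benchmark_small()
        model = train(A, F, mode="binary", r=4, k=5, seed=0)
        with pytest.warns(UserWarning, match="overlap"):
            predict_new(model, F.subset(F.drug_ids[:2]))

    def test_deterministic_end_to_end(self):
        A, F, _ = _benchmark_small()
        new = FeatureMatrix(np.eye(3, F.p), ["n1", "n2", "n3"])
        runs = []
        for _ in range(2):
            model = train(A, F, mode="comprehensive", r=6, k=8, seed=11)
            runs.append(predict_new(model, new).scores)
        assert np.array_equal(runs[0], runs[1])


class TestClassifyScores:
    def test_threshold_rule(self):
        sm = ScoreMatrix(np.array([[0.5, -0.5, 0.0]]), ["n"], ["a", "b", "c"])
        out = classify_scores(sm, "comprehensive", tau=0.1)
        assert out.tolist() == [[1, -1, 0]]

    def test_huge_tau_all_zero(self):
        sm = ScoreMatrix(np.array([[5.0, -9.0]]), ["n"], ["a", "b"])
        assert not classify_scores(sm, "comprehensive", tau=1e12).any()

    def test_binary_mode(self):
        sm = ScoreMatrix(np.array([[0.5, -0.5, 0.0]]), ["n"], ["a", "b", "c"])
        assert classify_scores(sm, "binary", tau=0.0).tolist() == [[1, 0, 0]]

    def test_brute_force_agreement(self, rng):
        s = rng.standard_normal((4, 6))
        sm = ScoreMatrix(s, [f"n{i}" for i in range(4)], [f"k{j}" for j in range(6)])
        tau = 0.3
        out = classify_scores(sm, "comprehensive", tau=tau)
        for i in range(4):
            for j in range(6):
                expected = 1 if s[i, j] > tau else (-1 if s[i, j] < -tau else 0)
                assert out[i, j] == expected

    def test_negative_tau_rejected(self):
        sm = ScoreMatrix(np.zeros((1, 1)), ["n"], ["a"])
        with pytest.raises(ValueError, match="tau"):
            classify_scores(sm, "binary", tau=-1.0)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        A, F, _ = _benchmark_small()
        model = train(A, F, mode="comprehensive", r=6, k=8,
                      kpca_opts={"n_components": 20, "bandwidth": 4.0}, seed=0)
        new = FeatureMatrix(np.eye(2, F.p), ["n1", "n2"])
        expected = predict_new(model, new).scores
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        got = predict_new(loaded, new).scores
        assert np.allclose(got, expected, atol=1e-10)


def _benchmark_small():
    from ddinmf import generate_benchmark

    return generate_benchmark("small", seed=7)
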