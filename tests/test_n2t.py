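import numpy as np
import pytest
from scipy import optimize
from scipy.spatial.transform import Rotation
from scipy.stats import ortho_group

from odieu.embedding import EmbeddingMatrix
from odieu.n2t import (
    AlignmentMap,
    CountInvertibleEmbedder,
    NeuralResponseSet,
    decode_prediction,
    fit_procrustes,
    loocv_eval,
    token_multiset,
)


class TestFitProcrustes:
    def test_exact_similarity_transform_recovered(self):
        rng = np.random.default_rng(0)
        q = rng.standard_normal((20, 5))
        rot = ortho_group.rvs(5, random_state=1)
        e = 2.5 * (q - q.mean(0)) @ rot + np.arange(5)
        amap, residual = fit_procrustes(q, e)
        assert residual < 1e-9
        assert amap.scale == pytest.approx(2.5)

    def test_self_alignment_is_identity(self):
        rng = np.random.default_rng(1)
        q = rng.standard_normal((10, 4))
        amap, residual = fit_procrustes(q, q)
        assert residual < 1e-9
        assert amap.scale == pytest.approx(1.0)
        np.testing.assert_allclose(amap.rotation @ amap.rotation.T, np.eye(4),
                                   atol=1e-10)

    def test_matches_numeric_optimizer_oracle(self):
        """Closed-form objective matches brute-force minimization over
        parametrized 3-D rotations, scale and translation (n=6, d=3)."""
        rng = np.random.default_rng(2)
        q = rng.standard_normal((6, 3))
        e = rng.standard_normal((6, 3))
        _, residual = fit_procrustes(q, e)

        reflect = np.diag([1.0, 1.0, -1.0])

        def objective(params, flip):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            if flip:
                rot = rot @ reflect   # cover orthogonal matrices with det -1
            s = np.exp(params[3])
            t = params[4:]
            return np.linalg.norm(s * q @ rot + t - e)

        best = np.inf
        for flip in (False, True):
            for trial in range(12):
                x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3),
                                     [0.0], np.zeros(3)])
                res = optimize.minimize(objective, x0, args=(flip,),
                                        method="Nelder-Mead",
                                        options={"xatol": 1e-10, "fatol": 1e-12,
                                                 "maxiter": 5000})
                best = min(best, res.fun)
        assert residual == pytest.approx(best, abs=1e-6)

    def test_residual_invariant_under_common_rotation(self):
        rng = np.random.default_rng(3)
        q = rng.standard_normal((15, 4))
        e = q @ rng.standard_normal((4, 4)) + 0.2 * rng.standard_normal((15, 4))
        _, r1 = fit_procrustes(q, e)
        rot = ortho_group.rvs(4, random_state=5)
        _, r2 = fit_procrustes(q @ rot, e @ rot)
        assert r2 == pytest.approx(r1, abs=1e-9)

    def test_orthogonality_enforced(self):
        with pytest.raises(ValueError, match="orthogonal"):
            AlignmentMap(rotation=np.array([[1.0, 0.1], [0.0, 1.0]]), scale=1.0,
                         source_mean=np.zeros(2), target_mean=np.zeros(2))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_procrustes(np.zeros((5, 3)), np.ones((5, 3)))
        with pytest.raises(ValueError):
            fit_procrustes(np.ones((2, 3)), np.ones((2, 3)))


def _latent_linked(n=59, d_q=30, d_e=40, sigma=0.3, seed=0):
    rng = np.random.default_rng(seed)
    lat = rng.standard_normal((n, 8))
    q = lat @ rng.standard_normal((8, d_q)) + sigma * rng.standard_normal((n, d_q))
    e = lat @ rng.standard_normal((8, d_e)) + sigma * rng.standard_normal((n, d_e))
    ids = tuple(f"o{i}" for i in range(n))
    emb = EmbeddingMatrix(index=list(ids),
                          matrix=e / np.linalg.norm(e, axis=1, keepdims=True))
    return NeuralResponseSet(ids, q, animal_id="mouse1"), emb


class TestLoocv:
    def test_noiseless_similarity_link_near_perfect(self):
        rng = np.random.default_rng(4)
        q = rng.standard_normal((20, 6))
        rot = ortho_group.rvs(6, random_state=6)
        e = 1.7 * q @ rot + 0.3
        ids = tuple(f"o{i}" for i in range(20))
        emb = EmbeddingMatrix(index=list(ids), matrix=e)
        res = loocv_eval(NeuralResponseSet(ids, q), emb, seed=0)
        assert res.paired_cs.mean() > 0.99

    def test_latent_link_beats_derangement_null(self):
        neural, emb = _latent_linked(seed=7)
        res = loocv_eval(neural, emb, seed=1)
        s = res.summary()
        assert s["mean_paired_cs"] > s["mean_null_cs"]
        assert s["p_one_sided"] < 1e-3

    def test_shuffled_labels_consistent_with_random_angles(self):
        """With odorant labels destroyed, LOOCV CS matches the distribution
        of angles between random directions (mean ~ 0 within 3 SEs)."""
        rng = np.random.default_rng(8)
        q = rng.standard_normal((40, 10))
        e = rng.standard_normal((40, 10))   # independent of q
        ids = tuple(f"o{i}" for i in range(40))
        emb = EmbeddingMatrix(index=list(ids), matrix=e)
        res = loocv_eval(NeuralResponseSet(ids, q), emb, seed=2)
        se = res.paired_cs.std(ddof=1) / np.sqrt(len(res.paired_cs))
        assert abs(res.paired_cs.mean()) < 3 * se

    def test_dimension_reduction_path(self):
        # embedding dim (40) exceeds neural dim (30): PCA reduction engaged
        neural, emb = _latent_linked(n=30, d_q=10, d_e=25, seed=9)
        res = loocv_eval(neural, emb, seed=3)
        assert res.predicted.shape == (30, 25)

    def test_too_few_odorants_rejected(self):
        neural, emb = _latent_linked(n=3, d_q=3, d_e=3, seed=10)
        with pytest.raises(ValueError):
            loocv_eval(neural, emb)


class TestDecoding:
    def test_round_trip_token_multiset(self):
        inv = CountInvertibleEmbedder.from_texts(
            ["sweet fruity apple", "smoky burnt tar"])
        text = "apple sweet apple"
        decoded = decode_prediction(inv.embed([text])[0], inv)
        assert token_multiset(decoded) == token_multiset(text)

    def test_catalogue_sentence_tokens_recovered(self):
        sentence = "This molecule has a smoky, burnt odor."
        inv = CountInvertibleEmbedder.from_texts([sentence])
        decoded = decode_prediction(inv.embed([sentence])[0], inv)
        assert token_multiset(decoded) == token_multiset(sentence)

    def test_end_to_end_noiseless_procrustes_decoding(self):
        """Exact similarity link between Q-vectors and count embeddings:
        every LOOCV prediction decodes to the target token multiset."""
        rng = np.random.default_rng(11)
        families = ["fruity apple ripe", "smoky burnt ashy", "minty cooling fresh",
                    "floral rose petal"]
        texts = [families[i % 4] + (" juicy" if i % 3 == 0 else "")
                 for i in range(20)]
        inv = CountInvertibleEmbedder.from_texts(texts)
        e = inv.embed(texts)
        rot = ortho_group.rvs(e.shape[1], random_state=12)
        q = (e @ rot.T) / 1.3 + 0.7     # inverse similarity transform
        ids = tuple(f"o{i}" for i in range(20))
        emb = EmbeddingMatrix(index=list(ids), matrix=e)
        res = loocv_eval(NeuralResponseSet(ids, q), emb, seed=4)
        for i, text in enumerate(texts):
            decoded = decode_prediction(res.predicted[i], inv)
            assert token_multiset(decoded) == token_multiset(text)

    def test_dim_mismatch_rejected(self):
        inv = CountInvertibleEmbedder.from_texts(["a b c"])
        with pytest.raises(ValueError):
            inv.invert(np.zeros(99))
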