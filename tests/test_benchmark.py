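import numpy as np
import pytest
from scipy import optimize

from odieu.benchmark import (
    average_embeddings,
    compare_to_consensus,
    emd_1d,
    seeded_derangement,
    similarity_distributions,
    topk_retrieval,
)
from odieu.catalog import DescriptionKind, PairIndex
from odieu.embedding import EmbeddingMatrix


def lp_wasserstein(a, b):
    """Exhaustive optimal-transport LP between two small empirical samples."""
    n, m = len(a), len(b)
    cost = np.abs(np.subtract.outer(a, b)).ravel()
    a_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(m):
        row = np.zeros((n, m))
        row[:, j] = 1
        a_eq.append(row.ravel())
    b_eq = np.concatenate([np.full(n, 1 / n), np.full(m, 1 / m)])
    res = optimize.linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq,
                           bounds=(0, None), method="highs")
    assert res.success
    return res.fun


def _pair_index(n):
    return PairIndex(DescriptionKind.CHD,
                     tuple((f"m{i}", "a", "b") for i in range(n)))


def _emb(keys, mat):
    return EmbeddingMatrix(index=keys, matrix=np.asarray(mat, float))


class TestSimilarityDistributions:
    def test_identity_pairing_all_ones(self):
        mat = np.eye(4)
        keys_a = [(f"m{i}", "a") for i in range(4)]
        keys_b = [(f"m{i}", "b") for i in range(4)]
        d = similarity_distributions(_emb(keys_a, mat), _emb(keys_b, mat),
                                     _pair_index(4), seed=0)
        np.testing.assert_allclose(d.paired, 1.0)
        np.testing.assert_allclose(d.null, 0.0)

    def test_derangement_null_has_no_self_pairs(self):
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            perm = seeded_derangement(50, rng)
            assert not np.any(perm == np.arange(50))

    def test_too_few_pairs_rejected(self):
        mat = np.eye(2)[:1]
        with pytest.raises(ValueError):
            similarity_distributions(_emb([("m0", "a")], mat),
                                     _emb([("m0", "b")], mat), _pair_index(1))


class TestEmd:
    def test_identical_samples_zero(self):
        assert emd_1d([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == 0.0

    def test_shifted_point_masses(self):
        assert emd_1d([0, 0], [1, 1]) == pytest.approx(1.0)

    def test_matches_lp_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, m = rng.integers(1, 9, size=2)
            a, b = rng.random(n), rng.random(m)
            assert emd_1d(a, b) == pytest.approx(lp_wasserstein(a, b), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            emd_1d([], [1.0])

    def test_uninformative_embeddings_give_near_zero_emd(self):
        """A random embedder carries no molecule information: the paired CS
        distribution equals the null up to sampling error."""
        rng = np.random.default_rng(8)
        n = 600
        mat_a = rng.standard_normal((n, 16))
        mat_b = rng.standard_normal((n, 16))
        mat_a /= np.linalg.norm(mat_a, axis=1, keepdims=True)
        mat_b /= np.linalg.norm(mat_b, axis=1, keepdims=True)
        d = similarity_distributions(
            _emb([(f"m{i}", "a") for i in range(n)], mat_a),
            _emb([(f"m{i}", "b") for i in range(n)], mat_b),
            _pair_index(n), seed=0)
        assert d.emd < 0.05


class TestRetrieval:
    def test_orthogonal_embeddings_perfect_at_all_k(self):
        mat = np.eye(6)
        q = _emb([f"m{i}" for i in range(6)], mat)
        g = _emb([(f"m{i}", "b") for i in range(6)], mat)
        truth = {f"m{i}": f"m{i}" for i in range(6)}
        acc = topk_retrieval(q, g, truth, ks=[1, 3, 6])
        assert acc == {1: 1.0, 3: 1.0, 6: 1.0}

    def test_k_equal_gallery_size_is_one(self):
        rng = np.random.default_rng(1)
        mat = rng.standard_normal((5, 8))
        q = _emb([f"m{i}" for i in range(5)], mat)
        g = _emb([(f"m{i}", "b") for i in range(5)], rng.standard_normal((5, 8)))
        truth = {f"m{i}": f"m{i}" for i in range(5)}
        assert topk_retrieval(q, g, truth, ks=[5])[5] == 1.0

    def test_k_beyond_gallery_rejected(self):
        mat = np.eye(3)
        q = _emb(["m0"], mat[:1])
        g = _emb([("m0", "b")], mat[:1])
        with pytest.raises(ValueError):
            topk_retrieval(q, g, {"m0": "m0"}, ks=[2])

    def test_random_embeddings_calibrate_to_k_over_n(self):
        rng = np.random.default_rng(5)
        n_gallery, n_query = 50, 1000
        gallery = rng.standard_normal((n_gallery, 32))
        queries = rng.standard_normal((n_query, 32))
        q = _emb([f"q{i}" for i in range(n_query)],
                 queries / np.linalg.norm(queries, axis=1, keepdims=True))
        g = _emb([f"m{i}" for i in range(n_gallery)],
                 gallery / np.linalg.norm(gallery, axis=1, keepdims=True))
        truth = {f"q{i}": f"m{i % n_gallery}" for i in range(n_query)}
        for k in (1, 5, 20):
            acc = topk_retrieval(q, g, truth, ks=[k])[k]
            expect = k / n_gallery
            sd = np.sqrt(expect * (1 - expect) / n_query)
            assert abs(acc - expect) < 3 * sd

    def test_accuracy_nondecreasing_in_k(self):
        rng = np.random.default_rng(9)
        mat = rng.standard_normal((30, 8))
        q = _emb([f"m{i}" for i in range(30)], mat)
        g = _emb([(f"m{i}", "b") for i in range(30)], rng.standard_normal((30, 8)))
        truth = {f"m{i}": f"m{i}" for i in range(30)}
        acc = topk_retrieval(q, g, truth, ks=list(range(1, 31)))
        vals = [acc[k] for k in range(1, 31)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestConsensusComparison:
    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(2)
        s = rng.random(100)
        v = compare_to_consensus(s, s)
        assert v.gap == 0.0
        assert v.verdict == "at"

    def test_swapped_arguments_negate_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(50), rng.random(60) * 0.5
        v1 = compare_to_consensus(a, b)
        v2 = compare_to_consensus(b, a)
        assert v1.t_statistic == pytest.approx(-v2.t_statistic)

    def test_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_to_consensus([1.0] * 5, [1.0] * 5)


class TestAveragedEmbeddings:
    def test_identical_sources_average_unchanged(self):
        v = np.array([0.6, 0.8])
        embs = {s: _emb([("m1", s)], v[None, :]) for s in ("a", "b", "c")}
        out = average_embeddings(embs, mode="full")
        assert out["m1"] @ v == pytest.approx(1.0)

    def test_two_orthogonal_sources_cs_inv_sqrt2(self):
        embs = {
            "a": _emb([("m1", "a")], np.array([[1.0, 0.0]])),
            "b": _emb([("m1", "b")], np.array([[0.0, 1.0]])),
        }
        out = average_embeddings(embs, mode="full")
        assert out["m1"] @ np.array([1.0, 0.0]) == pytest.approx(1 / np.sqrt(2))

    def test_leave_source_out_manual_three_sources(self):
        vecs = {"a": np.array([1.0, 0, 0]), "b": np.array([0, 1.0, 0]),
                "c": np.array([0, 0, 1.0])}
        embs = {s: _emb([("m1", s)], v[None, :]) for s, v in vecs.items()}
        out = average_embeddings(embs, mode="leave_source_out")
        # excluding a: mean of b,c renormalized -> CS to a = 0
        assert out[("m1", "a")] @ vecs["a"] == pytest.approx(0.0)
        assert out[("m1", "a")] @ vecs["b"] == pytest.approx(1 / np.sqrt(2))

    def test_leave_source_out_single_source_rejected(self):
        embs = {"a": _emb([("m1", "a")], np.array([[1.0, 0.0]]))}
        with pytest.raises(ValueError):
            average_embeddings(embs, mode="leave_source_out")

    def test_full_average_inflates_member_similarity(self):
        """Including a member's own embedding in the crowd average inflates
        its similarity relative to the leave-source-out average."""
        rng = np.random.default_rng(12)
        n = 100
        diffs = []
        embs = {}
        base = rng.standard_normal((n, 16))
        for s in ("a", "b", "c"):
            mat = base + 0.8 * rng.standard_normal((n, 16))
            mat /= np.linalg.norm(mat, axis=1, keepdims=True)
            embs[s] = _emb([(f"m{i}", s) for i in range(n)], mat)
        full = average_embeddings(embs, mode="full")
        loo = average_embeddings(embs, mode="leave_source_out")
        for i in range(n):
            for s in ("a", "b", "c"):
                member = embs[s].row((f"m{i}", s))
                diffs.append(full[f"m{i}"] @ member - loo[(f"m{i}", s)] @ member)
        assert np.mean(diffs) > 0
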