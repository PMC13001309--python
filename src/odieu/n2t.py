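"""Neural-to-text: Procrustes alignment of neural responses into a sentence
embedding space, leave-one-out evaluation, and decoding through an
invertible embedder.

Neural population responses to odorants (Q-vectors, 30-dimensional by
convention) are aligned to sentence embeddings of the corresponding human
descriptions by a similarity transform (translation + isotropic scale +
orthogonal matrix, closed form via SVD).  When the embedding dimension
exceeds the neural dimension, embeddings are reduced to the neural
dimension by PCA fitted on training odorants only; predictions are mapped
back through the transposed loadings before decoding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from odieu.benchmark import seeded_derangement
from odieu.embedding import EmbeddingMatrix, cosine_similarity


@dataclass
class NeuralResponseSet:
    odorant_ids: tuple[str, ...]
    q_vectors: np.ndarray            # (n, d_q)
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.q_vectors = np.asarray(self.q_vectors, float)
        if len(set(self.odorant_ids)) != len(self.odorant_ids):
            raise ValueError("odorant ids must be unique")
        if not np.isfinite(self.q_vectors).all():
            raise ValueError("Q-vectors contain non-finite entries")
        if self.q_vectors.shape[0] != len(self.odorant_ids):
            raise ValueError("rows must match odorant ids")

    @classmethod
    def from_frame(cls, frame, animal_id: str = "") -> "NeuralResponseSet":
        ids = tuple(frame["odorant_id"].astype(str))
        mat = frame.drop(columns=["odorant_id"]).to_numpy(float)
        return cls(ids, mat, animal_id)


@dataclass
class AlignmentMap:
    """x -> scale * (x - source_mean) @ rotation + target_mean."""

    rotation: np.ndarray             # (d, d) orthogonal
    scale: float
    source_mean: np.ndarray
    target_mean: np.ndarray

    def __post_init__(self) -> None:
        gram = self.rotation.T @ self.rotation
        if np.linalg.norm(gram - np.eye(gram.shape[0])) > 1e-8:
            raise ValueError("rotation matrix is not orthogonal to 1e-8")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.scale * (np.atleast_2d(x) - self.source_mean) @ self.rotation \
            + self.target_mean


def fit_procrustes(q: np.ndarray, e: np.ndarray) -> tuple[AlignmentMap, float]:
    """Similarity-transform Procrustes: minimize ||s (Q-c_q) R - (E-c_e)||_F.

    Closed form via SVD of the centered cross-covariance.  Returns the map
    and the residual Frobenius norm.  Requires n >= 3 matched rows, equal
    dimensions and non-degenerate (non-constant) inputs.
    """
    q = np.asarray(q, float)
    e = np.asarray(e, float)
    if q.shape[0] != e.shape[0]:
        raise ValueError("row mismatch between Q and E")
    if q.shape[0] < 3:
        raise ValueError("need n >= 3 matched odorants")
    if q.shape[1] != e.shape[1]:
        raise ValueError(f"dimension mismatch {q.shape[1]} vs {e.shape[1]}; "
                         "reduce the embedding side first (see loocv_eval)")
    mu_q, mu_e = q.mean(axis=0), e.mean(axis=0)
    qc, ec = q - mu_q, e - mu_e
    norm_q = np.linalg.norm(qc)
    if norm_q == 0 or np.linalg.norm(ec) == 0:
        raise ValueError("zero-variance input")
    u, s, vt = np.linalg.svd(qc.T @ ec)
    rot = u @ vt
    scale = float(s.sum() / norm_q**2)
    amap = AlignmentMap(rotation=rot, scale=scale, source_mean=mu_q, target_mean=mu_e)
    residual = float(np.linalg.norm(amap.apply(q) - e))
    return amap, residual


class _PCAReducer:
    """Train-only PCA to d components; inverse maps back via the loadings."""

    def __init__(self, x_train: np.ndarray, dim: int):
        self.mean = x_train.mean(axis=0)
        xc = x_train - self.mean
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        self.components = vt[:dim]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.mean) @ self.components.T

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(z) @ self.components + self.mean


@dataclass
class LoocvResult:
    odorant_ids: tuple[str, ...]
    paired_cs: np.ndarray
    null_cs: np.ndarray
    predicted: np.ndarray            # (n, D) predictions in the embedding space
    seed: int

    def summary(self) -> dict:
        from scipy import stats

        t, p = stats.ttest_ind(self.paired_cs, self.null_cs, equal_var=False)
        return {
            "mean_paired_cs": float(self.paired_cs.mean()),
            "mean_null_cs": float(self.null_cs.mean()),
            "t": float(t),
            "p_one_sided": float(p / 2) if t > 0 else float(1 - p / 2),
            "n": int(len(self.paired_cs)),
            "seed": self.seed,
        }


def _loocv_predict(q: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Leave-one-out Procrustes predictions of embeddings from Q-vectors,
    with train-only PCA reduction when dims differ."""
    n, d_q = q.shape
    preds = np.zeros_like(e)
    for i in range(n):
        train = np.arange(n) != i
        if e.shape[1] > d_q:
            reducer = _PCAReducer(e[train], d_q)
            e_tr = reducer.transform(e[train])
            amap, _ = fit_procrustes(q[train], e_tr)
            preds[i] = reducer.inverse(amap.apply(q[i]))[0]
        else:
            amap, _ = fit_procrustes(q[train], e[train])
            preds[i] = amap.apply(q[i])[0]
    return preds


def loocv_eval(
    neural: NeuralResponseSet,
    embeddings: EmbeddingMatrix,
    seed: int = 0,
) -> LoocvResult:
    """Leave-one-out Procrustes evaluation against a derangement null.

    For each odorant the map is fitted on the remaining n-1, the left-out
    embedding predicted, and CS(predicted, true) recorded.  The null runs
    the same protocol with embedding rows deranged (seeded), destroying the
    odorant correspondence.
    """
    ids = neural.odorant_ids
    if len(ids) < 4:
        raise ValueError("LOOCV needs n >= 4 odorants")
    keys = [k for k in embeddings.index]
    mol_of = {(k[0] if isinstance(k, tuple) else k): k for k in keys}
    try:
        e = np.vstack([embeddings.row(mol_of[i]) for i in ids])
    except KeyError as exc:
        raise KeyError(f"odorant missing from embeddings: {exc}") from exc
    q = neural.q_vectors
    preds = _loocv_predict(q, e)
    paired = np.array([cosine_similarity(preds[i], e[i]) for i in range(len(ids))])
    rng = np.random.default_rng(seed)
    perm = seeded_derangement(len(ids), rng)
    e_null = e[perm]
    preds_null = _loocv_predict(q, e_null)
    null = np.array([cosine_similarity(preds_null[i], e_null[i]) for i in range(len(ids))])
    return LoocvResult(odorant_ids=ids, paired_cs=paired, null_cs=null,
                       predicted=preds, seed=seed)


# ---------------------------------------------------------------------------
# Invertible embedding contract and a toy backend


@runtime_checkable
class InvertibleEmbedder(Protocol):
    def embed(self, texts: Sequence[str]) -> np.ndarray: ...
    def invert(self, vector: np.ndarray) -> str: ...


@dataclass
class CountInvertibleEmbedder:
    """Toy invertible backend: the embedding is the exact (scaled) token
    count vector over a fixed vocabulary; inversion rounds counts back to a
    canonical token multiset."""

    vocab: tuple[str, ...]
    name: str = "toy-invertible"
    deterministic: bool = True

    def __post_init__(self) -> None:
        self._id = {t: i for i, t in enumerate(self.vocab)}

    @classmethod
    def from_texts(cls, texts: Sequence[str]) -> "CountInvertibleEmbedder":
        from odieu.lexical import tokenize

        return cls(vocab=tuple(sorted({t for x in texts for t in tokenize(x)})))

    @property
    def dim(self) -> int:
        return len(self.vocab)

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        from odieu.lexical import tokenize

        out = np.zeros((len(texts), self.dim))
        for i, text in enumerate(texts):
            for tok in tokenize(text):
                if tok in self._id:
                    out[i, self._id[tok]] += 1.0
        return out

    def invert(self, vector: np.ndarray) -> str:
        vector = np.asarray(vector, float).ravel()
        if vector.shape[0] != self.dim:
            raise ValueError(f"vector dim {vector.shape[0]} != embedder dim {self.dim}")
        counts = np.rint(vector).astype(int)
        tokens: list[str] = []
        for i in np.nonzero(counts > 0)[0]:
            tokens.extend([self.vocab[i]] * int(counts[i]))
        return " ".join(tokens)


def decode_prediction(predicted_embedding: np.ndarray, inv: InvertibleEmbedder) -> str:
    """Text reconstruction of a predicted embedding via the invertible backend."""
    return inv.invert(np.asarray(predicted_embedding, float))


def token_multiset(text: str) -> Counter:
    from odieu.lexical import tokenize

    return Counter(tokenize(text))
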