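"""Sentence-embedder contract, cosine similarity and contrastive fine-tuning.

An :class:`Embedder` maps texts to fixed-dimension vectors (unit-normalized
by :func:`embed_texts`).  Fine-tuning pulls together embeddings of
descriptions of the same molecule from different sources (positives) and
pushes apart different-molecule pairs (negatives), with molecule-level
k-fold cross-validation so every molecule is evaluated by the fold model
that never saw it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from odieu import nn
from odieu.catalog import Catalogue, DescriptionKind, DescriptionRecord
from odieu.lexical import STOPWORDS, tokenize


@runtime_checkable
class Embedder(Protocol):
    name: str
    dim: int
    deterministic: bool

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


def _hash_index(token: str, dim: int) -> int:
    return int.from_bytes(hashlib.md5(token.encode()).digest()[:4], "little") % dim


def bow_features(texts: Sequence[str], dim: int, drop_stopwords: bool = True) -> np.ndarray:
    """Hashed bag-of-content-words count features, one row per text."""
    out = np.zeros((len(texts), dim))
    for i, text in enumerate(texts):
        for tok in tokenize(text):
            if drop_stopwords and tok in STOPWORDS:
                continue
            out[i, _hash_index(tok, dim)] += 1.0
    return out


@dataclass
class HashingEmbedder:
    """Deterministic, training-free embedder: hashed bag of content words.

    Identical texts give identical embeddings; texts with disjoint
    vocabularies (under a collision-free hash) give orthogonal ones.
    """

    dim: int = 256
    drop_stopwords: bool = True
    name: str = "toy-hashing"
    deterministic: bool = True

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        feats = bow_features(texts, self.dim, self.drop_stopwords)
        norms = np.linalg.norm(feats, axis=1, keepdims=True)
        return np.divide(feats, norms, out=np.zeros_like(feats), where=norms > 0)


@dataclass
class TrainableBowEmbedder:
    """Linear embedder over hashed bag-of-words features, trainable by
    gradient descent.  At initialization (weight = identity) it embeds
    exactly like :class:`HashingEmbedder` of the same dimension."""

    dim: int = 256
    drop_stopwords: bool = True
    name: str = "trainable-bow"
    deterministic: bool = True
    weight: np.ndarray = None

    def __post_init__(self) -> None:
        if self.weight is None:
            self.weight = np.eye(self.dim)

    @property
    def trainable(self) -> bool:
        return True

    def clone(self) -> "TrainableBowEmbedder":
        return replace(self, weight=self.weight.copy())

    def features(self, texts: Sequence[str]) -> np.ndarray:
        return bow_features(texts, self.dim, self.drop_stopwords)

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        z = self.features(texts) @ self.weight
        norms = np.linalg.norm(z, axis=1, keepdims=True)
        return np.divide(z, norms, out=np.zeros_like(z), where=norms > 0)


@dataclass
class EmbeddingMatrix:
    """Row-aligned embeddings: ``index[i]`` labels ``matrix[i]``."""

    index: list
    matrix: np.ndarray
    embedder_name: str = ""
    normalized: bool = True

    def __post_init__(self) -> None:
        if len(self.index) != self.matrix.shape[0]:
            raise ValueError("index length must match matrix rows")
        self._pos = {key: i for i, key in enumerate(self.index)}

    def row(self, key) -> np.ndarray:
        return self.matrix[self._pos[key]]

    def __contains__(self, key) -> bool:
        return key in self._pos

    def save(self, path: str | Path, seed: Optional[int] = None) -> None:
        import pandas as pd

        path = Path(path)
        frame = pd.DataFrame(self.matrix, columns=[f"e{j}" for j in range(self.matrix.shape[1])])
        frame.insert(0, "id", [str(k) for k in self.index])
        frame.to_csv(path, index=False)
        sidecar = {
            "embedder": self.embedder_name,
            "dim": int(self.matrix.shape[1]),
            "normalized": self.normalized,
            "seed": seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def embed_texts(embedder: Embedder, texts: Sequence[str],
                index: Optional[Sequence] = None) -> EmbeddingMatrix:
    """Embed texts and unit-normalize rows (zero rows stay zero)."""
    if len(texts) == 0:
        raise ValueError("no texts to embed")
    try:
        mat = np.asarray(embedder.embed(list(texts)), float)
    except Exception as exc:  # annotate which batch failed
        raise RuntimeError(f"embedder {embedder.name!r} failed on batch of "
                           f"{len(texts)} texts") from exc
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    mat = np.divide(mat, norms, out=np.zeros_like(mat), where=norms > 0)
    return EmbeddingMatrix(index=list(index) if index is not None else list(range(len(texts))),
                           matrix=mat, embedder_name=embedder.name)


def embed_records(embedder: Embedder, records: Sequence[DescriptionRecord]) -> EmbeddingMatrix:
    """Embed description records, indexed by (molecule_id, source)."""
    return embed_texts(embedder, [r.text for r in records],
                       index=[(r.molecule_id, r.source) for r in records])


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(u @ v / (nu * nv))


# ---------------------------------------------------------------------------
# Contrastive pairs and fine-tuning


@dataclass(frozen=True)
class ContrastivePair:
    text_a: str
    text_b: str
    molecule_a: str
    molecule_b: str
    is_positive: bool


def build_contrastive_pairs(
    catalogue: Catalogue,
    kind: DescriptionKind | str,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> list[ContrastivePair]:
    """Positives = all cross-source same-molecule pairs of ``kind``;
    negatives = seeded uniform sample of different-molecule record pairs."""
    from odieu.catalog import enumerate_cross_source_pairs

    kind = DescriptionKind(kind)
    pair_index = enumerate_cross_source_pairs(catalogue, kind)
    if len(pair_index) == 0:
        raise ValueError("catalogue has no cross-source positives for this kind")
    recs = catalogue.records_of_kind(kind)
    by_key = {(r.molecule_id, r.source): r for r in recs}
    pairs = [
        ContrastivePair(by_key[(m, sa)].text, by_key[(m, sb)].text, m, m, True)
        for m, sa, sb in pair_index.entries
    ]
    rng = np.random.default_rng(seed)
    n_neg = int(round(negative_ratio * len(pairs)))
    keys = sorted(by_key)
    attempts = 0
    negs: list[ContrastivePair] = []
    while len(negs) < n_neg and attempts < 100 * n_neg:
        i, j = rng.integers(0, len(keys), size=2)
        attempts += 1
        if keys[i][0] == keys[j][0]:
            continue
        ra, rb = by_key[keys[i]], by_key[keys[j]]
        negs.append(ContrastivePair(ra.text, rb.text, ra.molecule_id, rb.molecule_id, False))
    return pairs + negs


@dataclass
class FinetuneConfig:
    n_folds: int = 5
    loss: str = "angle"          # "angle" (AnglE-style) or "cosine" (margin fallback)
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-2
    seed: int = 0
    negative_ratio: float = 1.0
    tau: float = 20.0            # ranking-loss scale
    angle_weight: float = 1.0
    margin: float = 0.5          # for the cosine-margin fallback


@dataclass
class FinetuneResult:
    models: list
    fold_of: dict[str, int]      # molecule_id -> index of fold holding it out

    def embedder_for(self, molecule_id: str):
        """The fold model that never saw this molecule during training."""
        return self.models[self.fold_of[molecule_id]]

    def embed_heldout(self, records: Sequence[DescriptionRecord]) -> EmbeddingMatrix:
        """Evaluation-hygiene embedding: each record embedded by the model
        for which its molecule was held out."""
        rows = []
        for r in records:
            model = self.embedder_for(r.molecule_id)
            rows.append(embed_texts(model, [r.text]).matrix[0])
        return EmbeddingMatrix(
            index=[(r.molecule_id, r.source) for r in records],
            matrix=np.vstack(rows),
            embedder_name="finetuned-heldout",
        )


def _ranking_loss(sim_pos: nn.Tensor, sim_neg: nn.Tensor, tau: float) -> nn.Tensor:
    """CoSENT-style ranking: log(1 + sum exp(tau * (s_neg - s_pos)))."""
    diffs = (sim_neg.reshape(1, -1) - sim_pos.reshape(-1, 1)) * tau
    return (diffs.exp().sum() + 1.0).log()


def _angle_similarity(ea: nn.Tensor, eb: nn.Tensor, dim: int) -> nn.Tensor:
    """AnglE complex-angle similarity of row pairs (higher = more aligned)."""
    half = dim // 2
    a, b = ea.slice_cols(0, half), ea.slice_cols(half, 2 * half)
    c, d = eb.slice_cols(0, half), eb.slice_cols(half, 2 * half)
    re = (a * c + b * d).sum(axis=1)
    im = (b * c - a * d).sum(axis=1)
    # rows are unit vectors, so the complex-product normalizer is 1
    return re.abs() + im.abs()


def _pair_loss(model_w: nn.Tensor, feats_a, feats_b, labels, cfg: FinetuneConfig) -> nn.Tensor:
    ea = nn.l2_normalize_rows(nn.Tensor(feats_a) @ model_w)
    eb = nn.l2_normalize_rows(nn.Tensor(feats_b) @ model_w)
    cos = (ea * eb).sum(axis=1)
    pos_mask = np.where(labels)[0]
    neg_mask = np.where(~labels)[0]
    if cfg.loss == "cosine":
        # margin contrastive: positives toward 1, negatives below margin
        pos_term = 1.0 - _take(cos, pos_mask)
        neg_term = (_take(cos, neg_mask) - cfg.margin).relu()
        return (pos_term * pos_term).mean() + (neg_term * neg_term).mean()
    # AnglE-style: cosine ranking + angle ranking
    loss = _ranking_loss(_take(cos, pos_mask), _take(cos, neg_mask), cfg.tau)
    if cfg.angle_weight > 0:
        ang = _angle_similarity(ea, eb, ea.shape[1])
        loss = loss + cfg.angle_weight * _ranking_loss(
            _take(ang, pos_mask), _take(ang, neg_mask), cfg.tau
        )
    return loss


def _take(vec: nn.Tensor, idx: np.ndarray) -> nn.Tensor:
    mat = vec.reshape(-1, 1)
    return mat.gather_rows(idx, np.zeros(len(idx), dtype=int))


def assign_folds(molecules: Sequence[str], n_folds: int, seed: int) -> dict[str, int]:
    """Partition molecules (not descriptions) into folds, seeded."""
    mols = sorted(set(molecules))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mols))
    return {mols[j]: int(i % n_folds) for i, j in enumerate(order)}


def finetune(
    embedder: TrainableBowEmbedder,
    pairs: Sequence[ContrastivePair],
    config: FinetuneConfig = FinetuneConfig(),
) -> FinetuneResult:
    """Molecule-level k-fold contrastive fine-tuning.

    Each fold's model trains only on pairs whose molecules are all outside
    the held-out fold; with ``epochs=0`` the returned models are exact
    copies of the input embedder.
    """
    if not getattr(embedder, "trainable", False):
        raise TypeError(f"embedder {embedder.name!r} does not support gradient training")
    molecules = sorted({p.molecule_a for p in pairs} | {p.molecule_b for p in pairs})
    fold_of = assign_folds(molecules, config.n_folds, config.seed)
    models = []
    for fold in range(config.n_folds):
        model = embedder.clone()
        train_pairs = [p for p in pairs
                       if fold_of[p.molecule_a] != fold and fold_of[p.molecule_b] != fold]
        if config.epochs > 0 and train_pairs:
            _train_one(model, train_pairs, config, fold)
        models.append(model)
    return FinetuneResult(models=models, fold_of=fold_of)


def _train_one(model: TrainableBowEmbedder, pairs, cfg: FinetuneConfig, fold: int) -> None:
    feats_a = model.features([p.text_a for p in pairs])
    feats_b = model.features([p.text_b for p in pairs])
    labels = np.array([p.is_positive for p in pairs])
    w = nn.Tensor(model.weight.copy(), requires_grad=True)
    opt = nn.Adam([w], lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7, fold]))
    n = len(pairs)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if labels[idx].all() or not labels[idx].any():
                continue  # ranking loss needs both classes
            opt.zero_grad()
            loss = _pair_loss(w, feats_a[idx], feats_b[idx], labels[idx], cfg)
            loss.backward()
            opt.step()
    model.weight = w.data
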