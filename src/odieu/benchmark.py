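"""The model-based odor-description benchmark.

Compares the distribution of cosine similarities between embeddings of
same-molecule cross-source description pairs against a shuffled
(derangement) null, summarizes the separation by 1-D earth-mover distance,
measures top-k retrieval accuracy, tests machine outputs against the
human-human consensus, and computes dataset-averaged "crowd" embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from odieu.catalog import PairIndex
from odieu.embedding import EmbeddingMatrix


def seeded_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of range(n) with no fixed points (n >= 2)."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


@dataclass
class SimilarityDistribution:
    paired: np.ndarray
    null: np.ndarray
    seed: int

    @property
    def emd(self) -> float:
        return emd_1d(self.paired, self.null)


def similarity_distributions(
    emb_a: EmbeddingMatrix,
    emb_b: EmbeddingMatrix,
    pairing: PairIndex | Sequence[tuple],
    seed: int = 0,
) -> SimilarityDistribution:
    """Paired (same-molecule) CS sample vs a seeded-derangement null.

    ``pairing`` entries are (molecule_id, source_a, source_b); row keys
    (molecule_id, source) are looked up in each matrix.  The null pairs each
    left row with the right row of a deranged entry (never its own).
    """
    entries = pairing.entries if isinstance(pairing, PairIndex) else list(pairing)
    left, right = [], []
    for mid, sa, sb in entries:
        ka, kb = (mid, sa), (mid, sb)
        if ka not in emb_a or kb not in emb_b:
            raise KeyError(f"pairing entry {(mid, sa, sb)} not resolvable to rows")
        left.append(emb_a.row(ka))
        right.append(emb_b.row(kb))
    if len(left) < 2:
        raise ValueError("need >= 2 pairs")
    left_m, right_m = np.vstack(left), np.vstack(right)
    paired = np.einsum("ij,ij->i", left_m, right_m)
    rng = np.random.default_rng(seed)
    perm = seeded_derangement(len(entries), rng)
    null = np.einsum("ij,ij->i", left_m, right_m[perm])
    return SimilarityDistribution(paired=paired, null=null, seed=seed)


def emd_1d(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """1-Wasserstein distance between two empirical 1-D distributions.

    For equal-size samples this equals the mean absolute difference of the
    sorted samples; unequal sizes use the CDF-integral form.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return float(stats.wasserstein_distance(a, b))


def topk_retrieval(
    query_embs: EmbeddingMatrix,
    gallery_embs: EmbeddingMatrix,
    truth: Mapping,
    ks: Sequence[int],
) -> dict[int, float]:
    """Fraction of queries whose true molecule's gallery item ranks in the
    top k by cosine similarity (stable gallery order breaks ties).

    ``truth`` maps each query index key to the gallery molecule_id that
    counts as correct; gallery index keys are (molecule_id, source) or bare
    molecule ids.
    """
    n_gallery = gallery_embs.matrix.shape[0]
    if max(ks) > n_gallery:
        raise ValueError(f"k={max(ks)} exceeds gallery size {n_gallery}")
    gallery_mols = [key[0] if isinstance(key, tuple) else key for key in gallery_embs.index]
    sims = query_embs.matrix @ gallery_embs.matrix.T
    hits = {k: 0 for k in ks}
    for qi, qkey in enumerate(query_embs.index):
        target = truth[qkey]
        # stable mergesort: ties resolved by gallery order
        order = np.argsort(-sims[qi], kind="stable")
        ranked_mols = [gallery_mols[g] for g in order]
        try:
            rank = ranked_mols.index(target)
        except ValueError:
            raise KeyError(f"query {qkey!r}: molecule {target!r} absent from gallery")
        for k in ks:
            if rank < k:
                hits[k] += 1
    n_q = len(query_embs.index)
    return {k: hits[k] / n_q for k in ks}


@dataclass
class ConsensusVerdict:
    gap: float                  # mean(S_hh) - mean(S_mh), on the CS scale
    t_statistic: float
    p_value: float
    verdict: str                # "below", "at", or "above" consensus

    def __str__(self) -> str:
        return (f"S_mh {self.verdict} consensus "
                f"(gap={self.gap:+.3f}, t={self.t_statistic:.2f}, p={self.p_value:.2g})")


def compare_to_consensus(
    s_hh_sample: Sequence[float],
    s_mh_sample: Sequence[float],
    alpha: float = 0.01,
) -> ConsensusVerdict:
    """Welch two-sample t-test of machine-human CS against human-human CS."""
    hh = np.asarray(s_hh_sample, float)
    mh = np.asarray(s_mh_sample, float)
    if hh.std() == 0 and mh.std() == 0:
        raise ValueError("degenerate (constant) similarity samples")
    t, p = stats.ttest_ind(hh, mh, equal_var=False)
    gap = float(hh.mean() - mh.mean())
    if p < alpha:
        verdict = "below" if gap > 0 else "above"
    else:
        verdict = "at"
    return ConsensusVerdict(gap=gap, t_statistic=float(t), p_value=float(p), verdict=verdict)


def average_embeddings(
    embs_by_source: Mapping[str, EmbeddingMatrix],
    mode: str = "full",
) -> dict:
    """Per-molecule dataset-averaged embeddings.

    ``full``: renormalized mean over every source holding the molecule (the
    crowd embedding CHD-bar).  ``leave_source_out``: for each (molecule,
    source), the renormalized mean over the *other* sources (CHD*-bar),
    keyed (molecule_id, excluded_source); molecules present in a single
    source are an error in this mode.
    """
    per_mol: dict[str, dict[str, np.ndarray]] = {}
    for source, emb in embs_by_source.items():
        for key in emb.index:
            mid = key[0] if isinstance(key, tuple) else key
            per_mol.setdefault(mid, {})[source] = emb.row(key)
    out: dict = {}
    if mode == "full":
        for mid, by_src in per_mol.items():
            mean = np.mean(list(by_src.values()), axis=0)
            out[mid] = mean / np.linalg.norm(mean)
        return out
    if mode != "leave_source_out":
        raise ValueError(f"unknown mode {mode!r}")
    for mid, by_src in per_mol.items():
        if len(by_src) < 2:
            raise ValueError(f"molecule {mid!r} has a single source; "
                             "leave_source_out average undefined")
        for excluded in by_src:
            rest = [v for s, v in by_src.items() if s != excluded]
            mean = np.mean(rest, axis=0)
            out[(mid, excluded)] = mean / np.linalg.norm(mean)
    return out


@dataclass
class BenchmarkReport:
    """Mean CS (+SEM) per description kind against the human consensus."""

    embedder_name: str
    s_hh_mean: float
    s_hh_sem: float
    per_kind: dict[str, dict] = field(default_factory=dict)
    emd: Optional[float] = None
    retrieval: Optional[dict[int, float]] = None
    seed: int = 0

    def add_kind(self, kind: str, sample: Sequence[float],
                 verdict: Optional[ConsensusVerdict] = None) -> None:
        arr = np.asarray(sample, float)
        entry = {
            "mean_cs": float(arr.mean()),
            "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0,
            "n": int(len(arr)),
        }
        if verdict is not None:
            entry.update(t=verdict.t_statistic, p=verdict.p_value, verdict=verdict.verdict)
        self.per_kind[kind] = entry

    def to_frame(self):
        """Table-shaped CSV export: rows = kinds, values x100 with SEM."""
        import pandas as pd

        rows = [{"kind": "S_hh", "mean_x100": 100 * self.s_hh_mean,
                 "sem_x100": 100 * self.s_hh_sem}]
        for kind, entry in self.per_kind.items():
            rows.append({"kind": kind, "mean_x100": 100 * entry["mean_cs"],
                         "sem_x100": 100 * entry["sem"]})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        import json

        payload = {
            "embedder": self.embedder_name,
            "seed": self.seed,
            "s_hh": {"mean": self.s_hh_mean, "sem": self.s_hh_sem},
            "per_kind": self.per_kind,
            "emd": self.emd,
            "retrieval": {str(k): v for k, v in (self.retrieval or {}).items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)
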