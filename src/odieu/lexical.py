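"""Model-free sentence-similarity metrics and the consensus-gap statistic.

All metrics share one deterministic tokenizer (lowercase, Unicode NFC,
split on non-alphanumeric runs) and report on a 0-100 scale, matching the
convention of reporting values multiplied by 100.  The benchmark statistic
is the gap between mean human-human similarity S_hh (same molecule,
different sources) and mean machine-human similarity S_mh.
"""

from __future__ import annotations

import math
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

_TOKEN_RE = re.compile(r"[a-z0-9]+")

STOPWORDS = frozenset(
    "a an and the this that it is are has have of in on with to very or its".split()
)


def tokenize(text: str) -> list[str]:
    """Lowercase, NFC-normalize and split on non-alphanumeric runs."""
    return _TOKEN_RE.findall(unicodedata.normalize("NFC", text).lower())


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


@dataclass(frozen=True)
class MetricScore:
    metric: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 100.0 + 1e-9:
            raise ValueError(f"mean {self.mean} outside [0, 100]")
        if self.sem < 0 or self.n < 1:
            raise ValueError("SEM must be >= 0 and n >= 1")


@dataclass(frozen=True)
class ConsensusGap:
    s_hh: MetricScore
    s_mh: MetricScore

    @property
    def gap(self) -> float:
        return self.s_hh.mean - self.s_mh.mean


# ---------------------------------------------------------------------------
# BLEU


def bleu(
    candidate: str,
    references: Sequence[str],
    max_n: int = 4,
    smooth: bool = False,
) -> float:
    """BLEU on a 0-100 scale: modified n-gram precision with brevity penalty,
    geometric mean over orders 1..max_n.

    No smoothing by default (any zero n-gram precision gives 0), per the
    original definition; ``smooth=True`` applies add-one smoothing to
    higher-order counts for short-text corpora.
    """
    cand = tokenize(candidate)
    if not cand:
        raise ValueError("empty candidate after tokenization")
    refs = [tokenize(r) for r in references]
    if not refs or any(not r for r in refs):
        raise ValueError("empty reference")
    log_precisions = []
    for n in range(1, max_n + 1):
        cand_ngrams = _ngrams(cand, n)
        total = sum(cand_ngrams.values())
        if total == 0:
            # candidate shorter than n: no n-grams of this order
            clipped = 0
        else:
            max_ref = Counter()
            for r in refs:
                for g, c in _ngrams(r, n).items():
                    max_ref[g] = max(max_ref[g], c)
            clipped = sum(min(c, max_ref[g]) for g, c in cand_ngrams.items())
        if smooth and n > 1:
            clipped, total = clipped + 1, total + 1
        if clipped == 0 or total == 0:
            return 0.0
        log_precisions.append(math.log(clipped / total))
    # brevity penalty against the closest reference length
    c = len(cand)
    r = min((abs(len(ref) - c), len(ref)) for ref in refs)[1]
    bp = 1.0 if c > r else math.exp(1.0 - r / c)
    return 100.0 * bp * math.exp(sum(log_precisions) / max_n)


# ---------------------------------------------------------------------------
# ROUGE-L


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b):
            cur.append(prev[j] + 1 if x == y else max(prev[j + 1], cur[j]))
        prev = cur
    return prev[-1]


def rouge_l(candidate: str, reference: str, beta: float = 1.0) -> float:
    """ROUGE-L F-measure (x100): longest-common-subsequence precision/recall."""
    cand, ref = tokenize(candidate), tokenize(reference)
    if not cand or not ref:
        raise ValueError("empty text after tokenization")
    lcs = _lcs_length(cand, ref)
    if lcs == 0:
        return 0.0
    p, r = lcs / len(cand), lcs / len(ref)
    f = (1 + beta**2) * p * r / (r + beta**2 * p)
    return 100.0 * f


# ---------------------------------------------------------------------------
# METEOR


def _stem(token: str) -> str:
    """Tiny rule-based suffix stripper for METEOR's stem-match stage."""
    for suffix in ("ing", "edly", "ed", "es", "s", "ly"):
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            return token[: -len(suffix)]
    return token


def _meteor_alignment(cand: list[str], ref: list[str]) -> list[tuple[int, int]]:
    """Greedy left-to-right unigram alignment: exact matches first, then
    stem matches over the leftovers."""
    matches: list[tuple[int, int]] = []
    used_ref: set[int] = set()
    for stage in (lambda t: t, _stem):
        keyed_ref: dict[str, list[int]] = {}
        for j, t in enumerate(ref):
            if j not in used_ref:
                keyed_ref.setdefault(stage(t), []).append(j)
        for i, t in enumerate(cand):
            if any(m[0] == i for m in matches):
                continue
            js = keyed_ref.get(stage(t))
            if js:
                j = js.pop(0)
                used_ref.add(j)
                matches.append((i, j))
    return sorted(matches)


def _chunk_count(matches: list[tuple[int, int]]) -> int:
    chunks = 0
    prev: Optional[tuple[int, int]] = None
    for i, j in matches:
        if prev is None or i != prev[0] + 1 or j != prev[1] + 1:
            chunks += 1
        prev = (i, j)
    return chunks


def meteor(candidate: str, reference: str) -> float:
    """METEOR (x100): exact+stem unigram alignment, harmonic mean weighted
    towards recall (F = 10PR/(R+9P)), fragmentation penalty
    0.5 * (chunks/matches)^3."""
    cand, ref = tokenize(candidate), tokenize(reference)
    if not cand or not ref:
        raise ValueError("empty text after tokenization")
    matches = _meteor_alignment(cand, ref)
    m = len(matches)
    if m == 0:
        return 0.0
    p, r = m / len(cand), m / len(ref)
    f_mean = 10 * p * r / (r + 9 * p)
    penalty = 0.5 * (_chunk_count(matches) / m) ** 3
    return 100.0 * f_mean * (1.0 - penalty)


# ---------------------------------------------------------------------------
# BERTScore


def hashed_token_embedder(dim: int = 64):
    """Toy per-token embedder for BERTScore tests: stable hash -> unit vector."""
    import hashlib

    def embed(tokens: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(tokens), dim))
        for i, t in enumerate(tokens):
            h = hashlib.md5(t.encode()).digest()
            idx = int.from_bytes(h[:4], "little") % dim
            out[i, idx] = 1.0
        return out

    return embed


def bertscore(
    candidate: str,
    reference: str,
    token_embedder: Callable[[Sequence[str]], np.ndarray],
) -> float:
    """BERTScore F1 (x100) with a pluggable per-token embedder.

    Greedy matching: each token is matched to its maximum-cosine counterpart;
    recall averages over reference tokens, precision over candidate tokens.
    Baseline rescaling is not applied.
    """
    cand, ref = tokenize(candidate), tokenize(reference)
    if not cand or not ref:
        raise ValueError("empty text after tokenization")
    ec, er = np.asarray(token_embedder(cand), float), np.asarray(token_embedder(ref), float)
    ec = ec / np.maximum(np.linalg.norm(ec, axis=1, keepdims=True), 1e-12)
    er = er / np.maximum(np.linalg.norm(er, axis=1, keepdims=True), 1e-12)
    sim = ec @ er.T
    p = float(sim.max(axis=1).mean())
    r = float(sim.max(axis=0).mean())
    if p + r <= 0:
        return 0.0
    return 100.0 * 2 * p * r / (p + r)


# ---------------------------------------------------------------------------
# Aggregation

METRICS: dict[str, Callable[[str, str], float]] = {
    "bleu1": lambda a, b: bleu(a, [b], max_n=1),
    "bleu4": lambda a, b: bleu(a, [b], max_n=4),
    "rougeL": rouge_l,
    "meteor": meteor,
}


def _score_stats(scores: Sequence[float], metric: str) -> MetricScore:
    arr = np.asarray(scores, float)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return MetricScore(metric=metric, mean=float(arr.mean()), sem=sem, n=len(arr))


def consensus_gap(
    pairs_hh: Iterable[tuple[str, str]],
    pairs_mh: Iterable[tuple[str, str]],
    metric: str | Callable[[str, str], float] = "bleu1",
) -> ConsensusGap:
    """S_hh vs S_mh under one lexical metric.

    Human-human pair scores are symmetrized (mean of both directions, each
    partner serving once as sole reference); machine-human pairs are scored
    as (machine candidate, human reference).
    """
    fn = METRICS[metric] if isinstance(metric, str) else metric
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "custom")
    hh = [(0.5 * (fn(a, b) + fn(b, a))) for a, b in pairs_hh]
    mh = [fn(m, h) for m, h in pairs_mh]
    if len(hh) < 2 or len(mh) < 2:
        raise ValueError("need >=2 pairs in each set")
    return ConsensusGap(s_hh=_score_stats(hh, name), s_mh=_score_stats(mh, name))
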