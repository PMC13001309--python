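"""Representational-geometry comparisons between odor spaces.

An odor space is a molecules x coordinates matrix (a perceptual embedding
from any provenance: CNN latents, sentence-embedding manifolds, Isomap of
semantic labels, ...).  The module reduces high-dimensional spaces by
metric MDS, scores shared structure between two spaces by the sum of
squared canonical correlations, and fits cross-space predictive linear
maps evaluated by held-out Pearson correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof


@dataclass
class OdorSpace:
    name: str
    molecule_ids: tuple[str, ...]
    coordinates: np.ndarray          # (n, d)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, float)
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise ValueError("molecule ids must be unique")
        if self.coordinates.ndim != 2 or self.coordinates.shape[0] != len(self.molecule_ids):
            raise ValueError("coordinates must be (n_molecules, d)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates contain non-finite values")
        if self.coordinates.shape[1] < 1:
            raise ValueError("need d >= 1")

    @property
    def dim(self) -> int:
        return self.coordinates.shape[1]

    def restrict(self, ids: Sequence[str]) -> "OdorSpace":
        pos = {m: i for i, m in enumerate(self.molecule_ids)}
        idx = [pos[m] for m in ids]
        return OdorSpace(self.name, tuple(ids), self.coordinates[idx], self.provenance)

    def save(self, path: str | Path) -> None:
        import pandas as pd

        path = Path(path)
        frame = pd.DataFrame(self.coordinates,
                             columns=[f"c{j}" for j in range(self.dim)])
        frame.insert(0, "molecule_id", list(self.molecule_ids))
        frame.to_csv(path, index=False)
        path.with_suffix(".json").write_text(json.dumps(
            {"name": self.name, "provenance": self.provenance, "dim": self.dim},
            indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path, name: Optional[str] = None) -> "OdorSpace":
        import pandas as pd

        path = Path(path)
        frame = pd.read_csv(path)
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            name=name or meta.get("name", path.stem),
            molecule_ids=tuple(frame["molecule_id"].astype(str)),
            coordinates=frame.drop(columns=["molecule_id"]).to_numpy(float),
            provenance=meta.get("provenance", ""),
        )


def overlap(space_a: OdorSpace, space_b: OdorSpace) -> list[str]:
    common = set(space_a.molecule_ids) & set(space_b.molecule_ids)
    return [m for m in space_a.molecule_ids if m in common]


# ---------------------------------------------------------------------------
# MDS


def _classical_scaling(dist: np.ndarray, dim: int) -> np.ndarray:
    """Torgerson double-centering; top-``dim`` coordinates."""
    n = dist.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dim]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def reduce_mds(space: OdorSpace, target_dim: int, seed: int = 0,
               max_iter: int = 300) -> tuple[OdorSpace, float]:
    """Metric MDS on Euclidean distances to ``target_dim`` dimensions.

    Classical (Torgerson) scaling provides the seeded initialization,
    refined by SMACOF.  Returns the reduced space and the normalized
    stress sqrt(sum (d - d_hat)^2 / sum d^2); data whose intrinsic
    dimensionality is at most ``target_dim`` reduce with stress ~ 0.
    """
    if target_dim >= space.dim:
        raise ValueError(f"target_dim {target_dim} must be < d={space.dim}")
    if space.coordinates.shape[0] <= target_dim:
        raise ValueError("need more molecules than target dimensions")
    dist = squareform(pdist(space.coordinates))
    init = _classical_scaling(dist, target_dim)
    coords, raw_stress = smacof(
        dist, n_components=target_dim, init=init, n_init=1,
        max_iter=max_iter, random_state=seed, normalized_stress=False,
    )
    d_hat = squareform(pdist(coords))
    denom = np.sum(dist**2)
    stress = float(np.sqrt(np.sum((dist - d_hat) ** 2) / denom)) if denom > 0 else 0.0
    reduced = OdorSpace(f"{space.name}-mds{target_dim}", space.molecule_ids, coords,
                        provenance=f"metric MDS of {space.name}")
    return reduced, stress


# ---------------------------------------------------------------------------
# CCA


@dataclass
class SharedStructureReport:
    correlations: np.ndarray     # descending canonical correlations
    n_overlap: int
    dims: tuple[int, int]

    @property
    def sum_squared(self) -> float:
        """Effective number of shared dimensions."""
        return float(np.sum(self.correlations**2))


def _pca_whiten(x: np.ndarray, max_rank: int, ridge: float) -> np.ndarray:
    """Center, project to top principal components, and whiten."""
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    keep = min(max_rank, rank)
    s_reg = np.sqrt(s[:keep] ** 2 + ridge)
    return u[:, :keep] * (s[:keep] / s_reg)


def cca_shared_dims(space_a: OdorSpace, space_b: OdorSpace,
                    ridge: float = 1e-8) -> SharedStructureReport:
    """Canonical correlations of two odor spaces over their molecule overlap.

    Each space is centered and projected onto its top min(d, n-1) principal
    components (with a small ridge on the covariance blocks) before the
    SVD-based canonical analysis; the report carries the correlations and
    their squared sum.
    """
    common = overlap(space_a, space_b)
    if len(common) < 3:
        raise ValueError(f"overlap {len(common)} < 3 molecules")
    xa = space_a.restrict(common).coordinates
    xb = space_b.restrict(common).coordinates
    n = len(common)
    qa = _pca_whiten(xa, min(space_a.dim, n - 1), ridge)
    qb = _pca_whiten(xb, min(space_b.dim, n - 1), ridge)
    rho = np.linalg.svd(qa.T @ qb, compute_uv=False)
    rho = np.clip(rho, 0.0, 1.0)
    return SharedStructureReport(correlations=np.sort(rho)[::-1], n_overlap=n,
                                 dims=(space_a.dim, space_b.dim))


# ---------------------------------------------------------------------------
# Predictive linear maps


@dataclass
class MapReport:
    pearson_r: float             # mean per-coordinate held-out Pearson r
    per_coordinate_r: np.ndarray
    train_fraction: float
    seed: int
    n_train: int
    n_test: int


def linear_map_predict(base: OdorSpace, target: OdorSpace,
                       train_frac: float = 0.8, seed: int = 0) -> MapReport:
    """Pseudoinverse linear map base -> target on a seeded molecule split.

    Both spaces are centered using training-set means only; the map is the
    least-squares solution on the training molecules; accuracy is the mean
    per-coordinate Pearson correlation between predicted and true target
    coordinates on the held-out molecules.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    common = overlap(base, target)
    if len(common) < 5:
        raise ValueError(f"overlap {len(common)} < 5 molecules")
    xb = base.restrict(common).coordinates
    xt = target.restrict(common).coordinates
    rng = np.random.default_rng(seed)
    n = len(common)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    train, test = perm[:n_train], perm[n_train:]
    if len(test) < 2:
        raise ValueError("held-out set smaller than 2 molecules")
    mu_b = xb[train].mean(axis=0)
    mu_t = xt[train].mean(axis=0)
    w = np.linalg.pinv(xb[train] - mu_b) @ (xt[train] - mu_t)
    pred = (xb[test] - mu_b) @ w
    true = xt[test] - mu_t
    rs = np.array([
        _safe_pearson(pred[:, j], true[:, j]) for j in range(true.shape[1])
    ])
    return MapReport(pearson_r=float(rs.mean()), per_coordinate_r=rs,
                     train_fraction=train_frac, seed=seed,
                     n_train=len(train), n_test=len(test))


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(stats.pearsonr(a, b).statistic)
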