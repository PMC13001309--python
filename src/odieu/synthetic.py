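"""Seeded synthetic catalogues, descriptors and neural responses.

Every downstream stage (lexical metrics, embedding fine-tuning, benchmark,
odor-space comparison, prefix tuning, Procrustes alignment) is testable
without licensed data: molecules belong to perceptual families with themed
vocabularies, sources describe each molecule with tunable agreement, and
descriptor / neural-response vectors are noisy linear images of a shared
per-molecule Gaussian latent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from odieu.catalog import (
    Catalogue,
    DescriptionKind,
    DescriptionRecord,
    MoleculeRecord,
    normalize_text,
)
from odieu.embedding import HashingEmbedder

# Built-in family vocabularies themed on classical odor-descriptor families.
FAMILY_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "fruity": ("fruity", "apple", "pear", "banana", "berry", "juicy", "ripe", "tropical"),
    "floral": ("floral", "rose", "jasmine", "lilac", "violet", "petal", "honeyed", "powdery"),
    "sulfurous": ("sulfurous", "garlic", "onion", "eggy", "pungent", "rotten", "gassy", "sharp"),
    "woody": ("woody", "cedar", "pine", "resinous", "sawdust", "mossy", "earthy", "dry"),
    "minty": ("minty", "cooling", "menthol", "camphor", "fresh", "herbal", "icy", "clean"),
    "citrus": ("citrus", "lemon", "orange", "zesty", "peel", "tangy", "bright", "sour"),
    "nutty": ("nutty", "almond", "roasted", "toasted", "buttery", "popcorn", "warm", "creamy"),
    "smoky": ("smoky", "burnt", "tarry", "phenolic", "leathery", "ashy", "charred", "dark"),
}

SENTENCE_TEMPLATE = "This molecule has a {tokens} odor."

# Toy SMILES pool: simple alkane/alcohol strings keyed by molecule index.
_SMILES_ATOMS = ("C", "CC", "CCO", "CCC", "CC(C)O", "CCCC", "CCS", "c1ccccc1")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    ``alpha`` is inter-observer agreement: the probability that a source
    draws its descriptive tokens from the molecule's true perceptual family
    rather than from a random other family.
    """

    n_molecules: int = 200
    n_sources: int = 3
    n_families: int = 4
    latent_dim: int = 8
    alpha: float = 1.0
    descriptor_dim: int = 16
    neural_dim: int = 30
    noise_sigma: float = 0.1
    seed: int = 0
    tokens_per_description: int = 3
    #: molecules present in exactly k sources: {multiplicity: count}.
    #: None means every molecule is present in all sources.
    multiplicity_counts: Optional[dict[int, int]] = None
    kinds: tuple[DescriptionKind, ...] = (DescriptionKind.CHD, DescriptionKind.HL)

    def __post_init__(self) -> None:
        if min(self.n_molecules, self.n_sources, self.n_families,
               self.latent_dim, self.descriptor_dim, self.neural_dim) < 1:
            raise ValueError("all sizes/dims must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_families > len(FAMILY_VOCABULARIES):
            raise ValueError(
                f"n_families={self.n_families} exceeds the "
                f"{len(FAMILY_VOCABULARIES)} built-in vocabularies"
            )
        if self.multiplicity_counts is not None:
            if sum(self.multiplicity_counts.values()) != self.n_molecules:
                raise ValueError("multiplicity_counts must sum to n_molecules")
            if any(not 1 <= m <= self.n_sources for m in self.multiplicity_counts):
                raise ValueError("multiplicities must lie in [1, n_sources]")


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests only; never an input to the
    methods under test."""

    latents: np.ndarray               # (n_molecules, latent_dim)
    family_ids: np.ndarray            # (n_molecules,) ints
    family_names: tuple[str, ...]
    molecule_ids: tuple[str, ...]
    descriptor_map: np.ndarray = field(default=None)  # set by generate_descriptors
    neural_map: np.ndarray = field(default=None)      # set by generate_neural_responses


def _rng(config: SyntheticConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _sentence(tokens: Sequence[str]) -> str:
    if len(tokens) == 1:
        joined = tokens[0]
    else:
        joined = ", ".join(tokens[:-1]) + ", " + tokens[-1]
    return normalize_text(SENTENCE_TEMPLATE.format(tokens=joined))


def generate_catalog(config: SyntheticConfig) -> tuple[Catalogue, SyntheticTruth]:
    """Generate a catalogue of family-themed descriptions with agreement alpha.

    Each molecule is assigned a perceptual family and a Gaussian latent whose
    first coordinates encode the family (so descriptors/neural responses
    derived from the latent carry family structure).  Each present source
    contributes one description per requested kind: tokens drawn from the
    true family's vocabulary with probability alpha, else from a random
    other family.  HL records carry the drawn tokens as labels.
    """
    rng = _rng(config, 1)
    families = tuple(sorted(FAMILY_VOCABULARIES))[: config.n_families]
    n = config.n_molecules
    family_ids = rng.integers(0, config.n_families, size=n)
    latents = rng.standard_normal((n, config.latent_dim))
    # family signature in the leading latent coordinates
    k = min(config.n_families, config.latent_dim)
    onehot = np.zeros((n, config.latent_dim))
    onehot[np.arange(n), family_ids % k] = 2.0
    latents = latents + onehot

    molecule_ids = tuple(f"mol{idx:05d}" for idx in range(n))
    sources = tuple(sorted(f"src{j}" for j in range(config.n_sources)))

    # presence pattern
    if config.multiplicity_counts is None:
        multiplicities = np.full(n, config.n_sources, dtype=int)
    else:
        multiplicities = np.concatenate(
            [np.full(c, m, dtype=int) for m, c in sorted(config.multiplicity_counts.items())]
        )
        rng.shuffle(multiplicities)

    cat = Catalogue(sources=list(sources))
    for idx, mid in enumerate(molecule_ids):
        cat.add_molecule(
            MoleculeRecord(mid, smiles=_SMILES_ATOMS[idx % len(_SMILES_ATOMS)])
        )
        present = rng.choice(config.n_sources, size=multiplicities[idx], replace=False)
        fam = int(family_ids[idx])
        for j in sorted(present):
            # tokens drawn once per (molecule, source); shared across kinds so
            # CHD text and HL labels of the same observer are consistent
            tokens = []
            for _ in range(config.tokens_per_description):
                if rng.random() < config.alpha:
                    pick_fam = fam
                else:
                    pick_fam = int(rng.integers(0, config.n_families))
                vocab = FAMILY_VOCABULARIES[families[pick_fam]]
                tokens.append(vocab[int(rng.integers(0, len(vocab)))])
            for kind in config.kinds:
                if kind is DescriptionKind.HL:
                    rec = DescriptionRecord(mid, sources[j], kind,
                                            text=" ".join(tokens), labels=tuple(tokens))
                else:
                    rec = DescriptionRecord(mid, sources[j], kind, text=_sentence(tokens))
                cat.add_record(rec)

    truth = SyntheticTruth(
        latents=latents,
        family_ids=family_ids,
        family_names=families,
        molecule_ids=molecule_ids,
    )
    return cat, truth


def _linear_image(
    truth: SyntheticTruth, config: SyntheticConfig, out_dim: int, salt: int
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    rng = _rng(config, salt)
    # full-rank random map, drawn once per seed
    a = rng.standard_normal((config.latent_dim, out_dim))
    while np.linalg.matrix_rank(a) < min(a.shape):  # pragma: no cover - a.s. full rank
        a = rng.standard_normal((config.latent_dim, out_dim))
    noise = rng.standard_normal((len(truth.molecule_ids), out_dim))
    mat = truth.latents @ a + config.noise_sigma * noise
    return {mid: mat[i] for i, mid in enumerate(truth.molecule_ids)}, a


def generate_descriptors(
    truth: SyntheticTruth, config: SyntheticConfig
) -> dict[str, np.ndarray]:
    """Per-molecule descriptor vectors: A @ latent + sigma * noise."""
    vecs, a = _linear_image(truth, config, config.descriptor_dim, salt=2)
    truth.descriptor_map = a
    return vecs

def generate_neural_responses(
    truth: SyntheticTruth, config: SyntheticConfig
) -> dict[str, np.ndarray]:
    """Per-odorant neural response vectors (Q-vector analogues): B @ latent + noise."""
    vecs, b = _linear_image(truth, config, config.neural_dim, salt=3)
    truth.neural_map = b
    return vecs


def toy_embedder(dim: int = 256, drop_stopwords: bool = True) -> HashingEmbedder:
    """Deterministic training-free sentence embedder for tests and baselines.

    Hashed bag-of-content-words mapped to a unit vector of fixed dimension;
    identical texts map to identical embeddings.
    """
    return HashingEmbedder(dim=dim, drop_stopwords=drop_stopwords)


def vectors_to_frame(vectors: dict[str, np.ndarray]):
    """Emit a molecule_id + coordinate-columns DataFrame (CSV-ready)."""
    import pandas as pd

    ids = sorted(vectors)
    mat = np.vstack([vectors[i] for i in ids])
    cols = [f"x{j}" for j in range(mat.shape[1])]
    frame = pd.DataFrame(mat, columns=cols)
    frame.insert(0, "molecule_id", ids)
    return frame
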