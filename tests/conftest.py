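import numpy as np
import pytest

from odieu.catalog import Catalogue, DescriptionKind, DescriptionRecord, MoleculeRecord
from odieu.synthetic import SyntheticConfig, generate_catalog


@pytest.fixture
def tiny_catalog() -> Catalogue:
    """One molecule described by all three sources, one single-source molecule."""
    cat = Catalogue(sources=["arctander", "goodscents", "leffingwell"])
    cat.add_molecule(MoleculeRecord("m1", "CCS", name="1-pentanethiol"))
    cat.add_molecule(MoleculeRecord("m2", "CCO"))
    for src, text in [
        ("arctander", "This molecule has a sulfurous, garlic odor."),
        ("goodscents", "This molecule has a pungent, rotten odor."),
        ("leffingwell", "This molecule has a garlic, gassy odor."),
    ]:
        cat.add_record(DescriptionRecord("m1", src, DescriptionKind.CHD, text))
    cat.add_record(DescriptionRecord(
        "m2", "arctander", DescriptionKind.CHD, "This molecule has a fruity odor."))
    cat.add_record(DescriptionRecord(
        "m1", "arctander", DescriptionKind.HL, text="sulfurous garlic",
        labels=("sulfurous", "garlic")))
    return cat


@pytest.fixture(scope="session")
def agreement_catalog():
    """Perfect-agreement synthetic corpus (alpha=1) with known family truth."""
    cfg = SyntheticConfig(n_molecules=200, alpha=1.0, seed=11)
    cat, truth = generate_catalog(cfg)
    return cfg, cat, truth


@pytest.fixture(scope="session")
def paper_overlap_catalog():
    """Catalogue reproducing the published source-overlap structure:
    1,762 molecules in exactly two sources, 854 in exactly three."""
    cfg = SyntheticConfig(n_molecules=2616, multiplicity_counts={2: 1762, 3: 854},
                          seed=7)
    cat, _ = generate_catalog(cfg)
    return cat
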