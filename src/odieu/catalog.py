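"""Data model and I/O for multi-source odor-description catalogues.

A catalogue holds molecules (SMILES-keyed records) together with free-text
descriptions and/or semantic label sets contributed by several independent
sources (human datasets or machine predictors).  The central benchmark
quantity — cross-source same-molecule description pairs — is enumerated
here, along with source-overlap summaries.
"""

from __future__ import annotations

import json
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

SCHEMA_VERSION = "1"

#: Human description sources registered by default (the three classical
#: perfumery datasets).  Machine sources can be registered per catalogue.
DEFAULT_SOURCES = ("arctander", "goodscents", "leffingwell")


class DescriptionKind(str, Enum):
    """Provenance taxonomy for a description record.

    HD raw human description; CHD human description completed into a full
    sentence; HL human semantic labels; CHL labels completed into a
    sentence; CDL sentence completed from machine-predicted labels;
    S_ZS / S_HD / S_CHD / S_CHL SMILES-prompted generations (zero-shot or
    few-shot with the respective example kind); MD description generated
    from neural data; GEN reserved for other artifact-generated text.
    """

    HD = "HD"
    CHD = "CHD"
    HL = "HL"
    CHL = "CHL"
    CDL = "CDL"
    S_ZS = "S_ZS"
    S_HD = "S_HD"
    S_CHD = "S_CHD"
    S_CHL = "S_CHL"
    MD = "MD"
    GEN = "GEN"


#: Kinds authored by humans (directly or via sentence completion of human
#: content); eligible for human-human consensus pairing.
HUMAN_KINDS = frozenset(
    {DescriptionKind.HD, DescriptionKind.CHD, DescriptionKind.HL, DescriptionKind.CHL}
)


class CatalogueError(ValueError):
    """Malformed catalogue input (schema or invariant violation)."""


def normalize_text(text: str) -> str:
    """Unicode NFC + whitespace collapse; applied to all stored text."""
    return " ".join(unicodedata.normalize("NFC", text).split())


@dataclass(frozen=True)
class MoleculeRecord:
    molecule_id: str
    smiles: str
    name: Optional[str] = None
    structure_path: Optional[str] = None


@dataclass(frozen=True)
class DescriptionRecord:
    molecule_id: str
    source: str
    kind: DescriptionKind
    text: str
    labels: Optional[tuple[str, ...]] = None
    raw_text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind is DescriptionKind.HL:
            if not self.labels:
                raise CatalogueError(
                    f"HL record for {self.molecule_id!r}/{self.source!r} needs >=1 label"
                )
        elif not self.text:
            raise CatalogueError(
                f"{self.kind.value} record for {self.molecule_id!r}/{self.source!r} "
                "has empty text"
            )


@dataclass(frozen=True)
class PairIndex:
    """Unordered cross-source same-molecule pairs, lexicographically oriented."""

    kind: DescriptionKind
    entries: tuple[tuple[str, str, str], ...]  # (molecule_id, source_a, source_b)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Catalogue:
    """Validated set of molecules, registered sources and description records."""

    molecules: dict[str, MoleculeRecord] = field(default_factory=dict)
    sources: list[str] = field(default_factory=lambda: list(DEFAULT_SOURCES))
    records: list[DescriptionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._keys = {(r.molecule_id, r.source, r.kind) for r in self.records}
        self.validate()

    # -- construction --------------------------------------------------

    def register_source(self, source: str) -> None:
        if source not in self.sources:
            self.sources.append(source)

    def add_molecule(self, mol: MoleculeRecord) -> None:
        if mol.molecule_id in self.molecules:
            raise CatalogueError(f"duplicate molecule_id {mol.molecule_id!r}")
        self.molecules[mol.molecule_id] = mol

    def add_record(self, rec: DescriptionRecord) -> None:
        if rec.source not in self.sources:
            raise CatalogueError(f"unregistered source {rec.source!r}")
        if rec.molecule_id not in self.molecules:
            raise CatalogueError(f"unknown molecule_id {rec.molecule_id!r}")
        key = (rec.molecule_id, rec.source, rec.kind)
        if key in self._keys:
            raise CatalogueError(f"duplicate (molecule, source, kind) {key}")
        self._keys.add(key)
        self.records.append(rec)

    def validate(self) -> None:
        keys = [(r.molecule_id, r.source, r.kind) for r in self.records]
        dupes = [k for k, c in Counter(keys).items() if c > 1]
        if dupes:
            raise CatalogueError(f"duplicate (molecule, source, kind) entries: {dupes[:5]}")
        for r in self.records:
            if r.source not in self.sources:
                raise CatalogueError(f"unregistered source {r.source!r}")
            if r.molecule_id not in self.molecules:
                raise CatalogueError(f"record references unknown molecule {r.molecule_id!r}")

    # -- queries --------------------------------------------------------

    def records_of_kind(self, kind: DescriptionKind | str) -> list[DescriptionRecord]:
        kind = DescriptionKind(kind)
        return [r for r in self.records if r.kind is kind]

    def get_record(
        self, molecule_id: str, source: str, kind: DescriptionKind
    ) -> DescriptionRecord:
        for r in self.records:
            if r.molecule_id == molecule_id and r.source == source and r.kind is kind:
                return r
        raise KeyError((molecule_id, source, kind))

    def sources_per_molecule(self, kind: DescriptionKind) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.records_of_kind(kind):
            out.setdefault(r.molecule_id, []).append(r.source)
        return {m: sorted(set(s)) for m, s in out.items()}

    # -- persistence ----------------------------------------------------

    _COLUMNS = ("schema_version", "molecule_id", "smiles", "name", "source", "kind", "text", "labels")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            mol = self.molecules[r.molecule_id]
            rows.append(
                {
                    "schema_version": SCHEMA_VERSION,
                    "molecule_id": r.molecule_id,
                    "smiles": mol.smiles,
                    "name": mol.name or "",
                    "source": r.source,
                    "kind": r.kind.value,
                    "text": r.text,
                    "labels": ";".join(r.labels) if r.labels else "",
                }
            )
        return pd.DataFrame(rows, columns=list(self._COLUMNS))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            payload = {
                "schema_version": SCHEMA_VERSION,
                "sources": self.sources,
                "molecules": [
                    {"molecule_id": m.molecule_id, "smiles": m.smiles, "name": m.name}
                    for m in self.molecules.values()
                ],
                "records": [
                    {
                        "molecule_id": r.molecule_id,
                        "source": r.source,
                        "kind": r.kind.value,
                        "text": r.text,
                        "labels": list(r.labels) if r.labels else [],
                    }
                    for r in self.records
                ],
            }
            path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        else:
            self.to_frame().to_csv(path, index=False)


def _parse_labels(raw: str) -> Optional[tuple[str, ...]]:
    raw = raw.strip()
    if not raw:
        return None
    return tuple(t.strip() for t in raw.split(";") if t.strip())


def load_catalog(path: str | Path) -> Catalogue:
    """Load a catalogue from CSV or JSON, enforcing all invariants.

    Raises :class:`CatalogueError` naming the offending row/field for
    malformed input and for duplicate ``(molecule, source, kind)`` keys.
    """
    path = Path(path)
    cat = Catalogue()
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for s in payload.get("sources", []):
            cat.register_source(s)
        for m in payload.get("molecules", []):
            cat.add_molecule(
                MoleculeRecord(m["molecule_id"], m.get("smiles", ""), m.get("name") or None)
            )
        for i, r in enumerate(payload.get("records", [])):
            try:
                kind = DescriptionKind(r["kind"])
            except (KeyError, ValueError) as exc:
                raise CatalogueError(f"record {i}: bad kind {r.get('kind')!r}") from exc
            _add_loaded_record(cat, i, r["molecule_id"], r["source"], kind,
                               r.get("text", ""), tuple(r.get("labels") or ()) or None)
        return cat

    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise CatalogueError(f"{path}: empty file (no header)") from exc
    missing = set(Catalogue._COLUMNS) - set(frame.columns)
    if missing:
        raise CatalogueError(f"{path}: missing columns {sorted(missing)}")
    for i, row in frame.iterrows():
        mid = row["molecule_id"]
        if not mid:
            raise CatalogueError(f"row {i}: empty molecule_id")
        if mid not in cat.molecules:
            cat.add_molecule(MoleculeRecord(mid, row["smiles"], row["name"] or None))
        if row["source"] not in cat.sources:
            cat.register_source(row["source"])
        try:
            kind = DescriptionKind(row["kind"])
        except ValueError as exc:
            raise CatalogueError(f"row {i}: unknown kind {row['kind']!r}") from exc
        _add_loaded_record(cat, i, mid, row["source"], kind, row["text"],
                           _parse_labels(row["labels"]))
    return cat


def _add_loaded_record(cat, i, mid, source, kind, text, labels) -> None:
    try:
        rec = DescriptionRecord(
            molecule_id=mid,
            source=source,
            kind=kind,
            text=normalize_text(text),
            labels=labels,
            raw_text=text,
        )
        cat.add_record(rec)
    except CatalogueError as exc:
        raise CatalogueError(f"row {i}: {exc}") from exc


def enumerate_cross_source_pairs(
    catalogue: Catalogue, kind: DescriptionKind | str
) -> PairIndex:
    """All unordered cross-source same-molecule pairs of records of ``kind``.

    The pair count equals sum over molecules of C(m_i, 2), m_i being the
    number of sources holding that kind for molecule i; e.g. 1,762 two-source
    plus 854 three-source molecules yield 1762 + 3*854 = 4,324 pairs.
    """
    kind = DescriptionKind(kind)
    if kind not in HUMAN_KINDS:
        raise CatalogueError(f"{kind.value} is not a human description kind")
    per_mol = catalogue.sources_per_molecule(kind)
    if not per_mol:
        raise CatalogueError(f"no records of kind {kind.value} in catalogue")
    entries = []
    for mid in sorted(per_mol):
        srcs = per_mol[mid]
        for a_i in range(len(srcs)):
            for b_i in range(a_i + 1, len(srcs)):
                entries.append((mid, srcs[a_i], srcs[b_i]))
    return PairIndex(kind=kind, entries=tuple(entries))


def overlap_summary(
    catalogue: Catalogue, kind: DescriptionKind | str
) -> dict[int, int]:
    """Molecule counts by source multiplicity: {1: n1, 2: n2, 3: n3, ...}."""
    kind = DescriptionKind(kind)
    per_mol = catalogue.sources_per_molecule(kind)
    if not per_mol:
        raise CatalogueError(f"no records of kind {kind.value} in catalogue")
    counts = Counter(len(s) for s in per_mol.values())
    return dict(sorted(counts.items()))


def expected_pair_count(summary: Mapping[int, int]) -> int:
    """Pair-count identity: sum over multiplicities of count * C(mult, 2)."""
    return sum(n * comb(mult, 2) for mult, n in summary.items())


def canonical_smiles_merge(catalogue: Catalogue) -> Catalogue:
    """Optional utility merging molecules whose SMILES canonicalize identically.

    Off by default everywhere; molecule identity is otherwise the
    caller-supplied key (canonicalization would silently merge stereoisomer
    entries recorded separately).  Requires rdkit.
    """
    from rdkit import Chem  # local import: optional heavy dependency

    canon: dict[str, str] = {}
    mapping: dict[str, str] = {}
    merged = Catalogue(sources=list(catalogue.sources))
    for mol in catalogue.molecules.values():
        parsed = Chem.MolFromSmiles(mol.smiles) if mol.smiles else None
        key = Chem.MolToSmiles(parsed) if parsed is not None else mol.molecule_id
        if key not in canon:
            canon[key] = mol.molecule_id
            merged.add_molecule(mol)
        mapping[mol.molecule_id] = canon[key]
    for rec in catalogue.records:
        new_id = mapping[rec.molecule_id]
        try:
            merged.add_record(
                DescriptionRecord(new_id, rec.source, rec.kind, rec.text, rec.labels)
            )
        except CatalogueError:
            pass  # same source/kind collapsed onto one canonical molecule
    return merged
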