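"""Core record types shared across the package.

A :class:`PropertyDataset` is the unit every pipeline stage consumes: an
ordered collection of molecule (or protein--ligand complex) records, each
carrying an identifier and an optional numeric target such as logP or pKi.
Order is stable so that index-based train/validation/test splits are
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Atom", "MoleculeRecord", "ComplexRecord", "PropertyDataset"]


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol, residue tag and Cartesian coordinates (Å)."""

    element: str
    res_name: str
    x: float
    y: float
    z: float

    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class MoleculeRecord:
    """One small molecule: identifier, SMILES and an optional target value.

    ``target`` is the supervised property (logP in log-units or pKi on the
    negative-log scale); ``None`` marks a record usable for featurization
    but not for training.
    """

    id: str
    smiles: str
    target: float | None = None

    def has_target(self) -> bool:
        return self.target is not None and math.isfinite(self.target)


@dataclass
class ComplexRecord:
    """A protein--ligand complex as two atom lists with 3D coordinates.

    Ligand atoms are kept verbatim; protein atoms are expected to already
    have waters and monoatomic metal ions removed (done at read time).
    """

    id: str
    ligand_atoms: list[Atom]
    protein_atoms: list[Atom]
    target: float | None = None

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError(f"complex {self.id!r}: ligand has no atoms")
        for atom in [*self.ligand_atoms, *self.protein_atoms]:
            if not all(math.isfinite(v) for v in (atom.x, atom.y, atom.z)):
                raise ValueError(f"complex {self.id!r}: non-finite coordinate")

    def ligand_coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.ligand_atoms], dtype=float)

    def protein_coords(self) -> np.ndarray:
        if not self.protein_atoms:
            return np.empty((0, 3), dtype=float)
        return np.array([[a.x, a.y, a.z] for a in self.protein_atoms], dtype=float)

    def has_target(self) -> bool:
        return self.target is not None and math.isfinite(self.target)


@dataclass
class PropertyDataset:
    """Ordered collection of records with a named property.

    ``n_failed`` counts input entries dropped at parse/featurize time;
    ``n_failed + len(records)`` equals the number of input entries seen.
    """

    records: list[MoleculeRecord | ComplexRecord] = field(default_factory=list)
    property_name: str = "target"
    n_failed: int = 0

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate record id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord | ComplexRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MoleculeRecord | ComplexRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def targets(self) -> np.ndarray:
        """Target vector; raises if any retained record lacks a target."""
        missing = [r.id for r in self.records if not r.has_target()]
        if missing:
            raise ValueError(
                f"{len(missing)} record(s) lack a target value "
                f"(first: {missing[0]!r}); supervised use requires all targets"
            )
        return np.array([r.target for r in self.records], dtype=float)

    def subset(self, indices: Sequence[int]) -> "PropertyDataset":
        """New dataset restricted to ``indices`` (order preserved as given)."""
        return PropertyDataset(
            records=[self.records[i] for i in indices],
            property_name=self.property_name,
            n_failed=0,
        )
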