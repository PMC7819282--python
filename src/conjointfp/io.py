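"""Readers and writers for molecules, property tables and toy 3D complexes.

Parse failures in batch inputs are skipped and counted in
``PropertyDataset.n_failed`` — never fatal — so a partially dirty input
produces a usable dataset plus an honest count, the way large public
compound collections are handled in practice. Missing files or missing
columns are configuration errors and raise immediately.

PDB-style structures are read and written through :mod:`gemmi`; only the
element symbol, residue name and coordinates are consumed.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from rdkit import Chem, RDLogger

from .records import Atom, ComplexRecord, MoleculeRecord, PropertyDataset

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: residue tags treated as water
WATER_RES_NAMES = frozenset({"HOH", "WAT", "H2O"})

#: elements treated as metal ions when they occur as single-atom residues
METAL_ELEMENTS = frozenset(
    {
        "LI", "NA", "K", "RB", "CS", "BE", "MG", "CA", "SR", "BA",
        "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG", "AL", "GA",
        "AG", "AU", "PT", "PD", "CR", "MO", "W", "V", "TI",
    }
)

__all__ = [
    "read_smiles_table",
    "write_smiles_table",
    "read_sdf",
    "write_sdf",
    "read_complex",
    "write_complex_pdb",
    "write_matrix",
    "read_matrix",
    "WATER_RES_NAMES",
    "METAL_ELEMENTS",
]


def _parse_float(text: str | float | None) -> float | None:
    if text is None:
        return None
    try:
        value = float(text)
    except (TypeError, ValueError):
        return None
    return value if math.isfinite(value) else None


def smiles_is_valid(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


# ---------------------------------------------------------------------------
# SMILES/CSV property tables
# ---------------------------------------------------------------------------

def read_smiles_table(
    path: str | Path,
    smiles_column: str = "smiles",
    target_column: str = "target",
    id_column: str | None = None,
    property_name: str | None = None,
) -> PropertyDataset:
    """Read a CSV property table into a :class:`PropertyDataset`.

    One record per row. Rows whose SMILES does not parse or whose target
    is missing/non-numeric are dropped and counted in ``n_failed``. If
    ``id_column`` is None, ids are ``mol_<row>`` by 0-based row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    n_failed = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in filter(None, (smiles_column, target_column, id_column)):
            if col not in header:
                raise KeyError(f"column {col!r} not found in {path} (has {header})")
        for i, row in enumerate(reader):
            smiles = (row[smiles_column] or "").strip()
            target = _parse_float(row[target_column])
            if target is None or not smiles_is_valid(smiles):
                n_failed += 1
                logger.info("row %d dropped (smiles=%r)", i, smiles)
                continue
            rid = row[id_column].strip() if id_column else f"mol_{i}"
            records.append(MoleculeRecord(id=rid, smiles=smiles, target=target))
    name = property_name or target_column
    logger.info("%s: %d records read, %d failed", path.name, len(records), n_failed)
    return PropertyDataset(records=records, property_name=name, n_failed=n_failed)


def write_smiles_table(
    ds: PropertyDataset, path: str | Path, smiles_column: str = "smiles"
) -> Path:
    """Write molecule records as CSV with columns id, smiles, <property>."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", smiles_column, ds.property_name])
        for rec in ds.records:
            writer.writerow([rec.id, rec.smiles, "" if rec.target is None else repr(rec.target)])
    return path


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

def read_sdf(
    path: str | Path,
    target_field: str,
    property_name: str | None = None,
) -> PropertyDataset:
    """Read an SDF file; the target comes from the named SDF data field.

    Molecule blocks that fail to parse are skipped and counted. A block
    missing the target field is retained with ``target=None`` (usable for
    featurization, rejected later by supervised training).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    n_failed = 0
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            n_failed += 1
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
        target = _parse_float(mol.GetProp(target_field)) if mol.HasProp(target_field) else None
        records.append(
            MoleculeRecord(id=rid, smiles=Chem.MolToSmiles(mol), target=target)
        )
    return PropertyDataset(
        records=records,
        property_name=property_name or target_field,
        n_failed=n_failed,
    )


def write_sdf(ds: PropertyDataset, path: str | Path, target_field: str) -> Path:
    """Write molecule records to SDF, storing targets in ``target_field``."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for rec in ds.records:
            mol = Chem.MolFromSmiles(rec.smiles)
            if mol is None:  # records in a dataset already parsed once
                raise ValueError(f"record {rec.id!r}: unwritable SMILES {rec.smiles!r}")
            mol.SetProp("_Name", rec.id)
            if rec.target is not None:
                mol.SetProp(target_field, repr(rec.target))
            writer.write(mol)
    finally:
        writer.close()
    return path


# ---------------------------------------------------------------------------
# 3D complexes (PDB-style)
# ---------------------------------------------------------------------------

def _structure_atoms(path: Path, strip_water_metals: bool = False) -> list[Atom]:
    """Flatten the first model to Atom records.

    With ``strip_water_metals`` on, water residues (HOH/WAT/H2O) and
    single-atom residues of metallic elements (free metal ions) are
    dropped; metals covalently embedded in multi-atom residues are kept.
    """
    structure = gemmi.read_structure(str(path))
    atoms: list[Atom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                res_name = residue.name.strip().upper()
                if strip_water_metals:
                    if res_name in WATER_RES_NAMES:
                        continue
                    if (
                        len(residue) == 1
                        and residue[0].element.name.upper() in METAL_ELEMENTS
                    ):
                        continue
                for atom in residue:
                    atoms.append(
                        Atom(
                            element=atom.element.name.upper(),
                            res_name=res_name,
                            x=atom.pos.x,
                            y=atom.pos.y,
                            z=atom.pos.z,
                        )
                    )
        break  # first model only
    return atoms


def read_complex(
    path_protein: str | Path,
    path_ligand: str | Path,
    complex_id: str | None = None,
    target: float | None = None,
) -> ComplexRecord:
    """Read a protein and a ligand structure file into one complex record.

    Waters (HOH/WAT/H2O) and monoatomic metal ions are deleted from the
    protein side; ligand atoms are kept verbatim. An empty ligand raises.
    """
    path_protein, path_ligand = Path(path_protein), Path(path_ligand)
    for p in (path_protein, path_ligand):
        if not p.exists():
            raise FileNotFoundError(p)
    protein_atoms = _structure_atoms(path_protein, strip_water_metals=True)
    ligand_atoms = _structure_atoms(path_ligand)
    cid = complex_id or path_ligand.stem
    return ComplexRecord(
        id=cid, ligand_atoms=ligand_atoms, protein_atoms=protein_atoms, target=target
    )


def _atoms_to_structure(atoms: Sequence[Atom], name: str) -> gemmi.Structure:
    structure = gemmi.Structure()
    structure.name = name
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, a in enumerate(atoms):
        residue = gemmi.Residue()
        residue.name = a.res_name
        residue.seqid = gemmi.SeqId(i + 1, " ")
        residue.het_flag = "H"
        atom = gemmi.Atom()
        atom.name = a.element
        atom.element = gemmi.Element(a.element.capitalize())
        atom.pos = gemmi.Position(a.x, a.y, a.z)
        residue.add_atom(atom)
        chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    return structure


def write_complex_pdb(record: ComplexRecord, path_protein: str | Path, path_ligand: str | Path) -> None:
    """Write the two halves of a complex as PDB files (one atom per residue)."""
    _atoms_to_structure(record.protein_atoms, record.id + "_protein").write_pdb(
        str(path_protein)
    )
    _atoms_to_structure(record.ligand_atoms, record.id + "_ligand").write_pdb(
        str(path_ligand)
    )


# ---------------------------------------------------------------------------
# Featurized matrices with a JSON sidecar
# ---------------------------------------------------------------------------

def write_matrix(
    X: np.ndarray,
    ids: Sequence[str],
    path: str | Path,
    metadata: dict,
) -> Path:
    """Persist a dense feature matrix as CSV plus a ``.json`` sidecar.

    The sidecar records the fingerprint scheme, block layout and engine
    version so a model never sees a matrix with an unknown layout.
    """
    path = Path(path)
    if X.shape[0] != len(ids):
        raise ValueError("row count does not match number of ids")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + [f"f{j}" for j in range(X.shape[1])])
        for rid, row in zip(ids, X):
            writer.writerow([rid] + [int(v) if float(v).is_integer() else v for v in row])
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], dict]:
    """Inverse of :func:`write_matrix`: returns (X, ids, metadata)."""
    path = Path(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            ids.append(row[0])
            rows.append([float(v) for v in row[1:]])
    sidecar = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(rows, dtype=float), ids, metadata
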