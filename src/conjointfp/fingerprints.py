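"""MACCS keys, ECFP, conjoint concatenations and the SlogP baseline.

The conjoint representation is the package's central object: the 166-bit
MACCS substructure keys and the 2048-bit radius-2 ECFP of the same
molecule, concatenated (MACCS block first) into one 2214-bit input vector.
MACCS keys record the presence of predefined atom/bond/substructure
patterns but carry little connectivity; ECFP hashes each atom's circular
bonded neighborhood and so carries topology but no curated chemistry.
Concatenation keeps both, leaving it to the downstream regressor to weigh
them.

For protein--ligand complexes, the ligand and the binding pocket (protein
atoms within a distance cutoff of any ligand atom, default 4.5 Å) are each
fingerprinted and the blocks concatenated, ligand first.

Fingerprinting is delegated to RDKit; the SlogP baseline is the
Wildman--Crippen atom-contribution method as implemented there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, MACCSkeys, rdDetermineBonds
from rdkit.Chem import rdFingerprintGenerator
from scipy.spatial.distance import cdist

from .records import ComplexRecord, MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintSpec",
    "FingerprintVector",
    "FeaturizationError",
    "maccs_keys",
    "ecfp",
    "ecfp_identifiers",
    "conjoint",
    "extract_pocket",
    "featurize_complex",
    "featurize_dataset",
    "slogp",
    "DEFAULT_POCKET_CUTOFF",
]

DEFAULT_POCKET_CUTOFF = 4.5  # Å, closed boundary (atom at exactly 4.5 Å is kept)


class FeaturizationError(ValueError):
    """A record could not be converted to a fingerprint."""

    def __init__(self, record_id: str, reason: str):
        super().__init__(f"record {record_id!r}: {reason}")
        self.record_id = record_id


@dataclass(frozen=True)
class FingerprintSpec:
    """Parameters of a fingerprint scheme.

    ``scheme`` is one of ``maccs`` | ``ecfp`` | ``conjoint``. Defaults match
    common virtual-screening practice: 166 MACCS keys, ECFP with bond
    radius 2 folded to 2048 bits, conjoint = 166 + 2048 = 2214 bits.
    """

    scheme: str = "conjoint"
    ecfp_radius: int = 2
    ecfp_nbits: int = 2048
    maccs_nbits: int = field(default=166)

    def __post_init__(self) -> None:
        if self.scheme not in ("maccs", "ecfp", "conjoint"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.maccs_nbits != 166:
            raise ValueError("MACCS keys are a fixed 166-key dictionary")
        if self.ecfp_radius < 0 or self.ecfp_nbits < 1:
            raise ValueError("ecfp_radius must be >= 0 and ecfp_nbits >= 1")

    @property
    def n_bits(self) -> int:
        """Vector length for a single molecule under this scheme."""
        if self.scheme == "maccs":
            return self.maccs_nbits
        if self.scheme == "ecfp":
            return self.ecfp_nbits
        return self.maccs_nbits + self.ecfp_nbits


@dataclass(frozen=True)
class FingerprintVector:
    """A fixed-length binary vector tagged with its scheme and provenance."""

    bits: np.ndarray
    scheme: str
    source: str = "molecule"  # molecule | ligand | pocket | complex

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("fingerprint must be a 1-D vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("fingerprint elements must be 0 or 1")
        object.__setattr__(self, "bits", arr)

    def __len__(self) -> int:
        return len(self.bits)


def _as_mol(mol: MoleculeRecord | Chem.Mol | str) -> tuple[Chem.Mol, str]:
    if isinstance(mol, Chem.Mol):
        return mol, mol.GetProp("_Name") if mol.HasProp("_Name") else "<mol>"
    if isinstance(mol, str):
        record = MoleculeRecord(id="<smiles>", smiles=mol)
    else:
        record = mol
    parsed = Chem.MolFromSmiles(record.smiles)
    if parsed is None:
        raise FeaturizationError(record.id, f"unparseable SMILES {record.smiles!r}")
    return parsed, record.id


def maccs_keys(mol: MoleculeRecord | Chem.Mol | str) -> FingerprintVector:
    """166-bit MACCS substructure keys.

    Element ``k-1`` of the output is MACCS key ``k`` (RDKit reserves bit 0
    of its 167-bit vector as a placeholder, dropped here). Key 1 and the
    isotope sub-patterns of keys 2/3 are unmatchable in RDKit's public
    SMARTS definitions and are permanently 0.
    """
    parsed, _ = _as_mol(mol)
    raw = MACCSkeys.GenMACCSKeys(parsed)
    bits = np.zeros(167, dtype=np.uint8)
    bits[list(raw.GetOnBits())] = 1
    return FingerprintVector(bits=bits[1:], scheme="maccs")


def ecfp(mol: MoleculeRecord | Chem.Mol | str, spec: FingerprintSpec | None = None) -> FingerprintVector:
    """Extended-connectivity fingerprint, folded to a binary vector.

    Circular neighborhoods up to ``spec.ecfp_radius`` bonds around every
    atom are hashed to integer identifiers and folded into
    ``spec.ecfp_nbits`` presence bits.
    """
    spec = spec or FingerprintSpec(scheme="ecfp")
    parsed, _ = _as_mol(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=spec.ecfp_radius, fpSize=spec.ecfp_nbits
    )
    raw = gen.GetFingerprint(parsed)
    bits = np.zeros(spec.ecfp_nbits, dtype=np.uint8)
    bits[list(raw.GetOnBits())] = 1
    return FingerprintVector(bits=bits, scheme="ecfp")


def ecfp_identifiers(mol: MoleculeRecord | Chem.Mol | str, radius: int) -> frozenset[int]:
    """Unfolded circular-neighborhood identifiers up to ``radius`` bonds.

    Useful for reasoning about the fingerprint before hash folding: the
    identifier set at radius r is a subset of the set at any r' >= r.
    """
    parsed, _ = _as_mol(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    sparse = gen.GetSparseCountFingerprint(parsed)
    return frozenset(sparse.GetNonzeroElements())


def conjoint(fps: list[FingerprintVector], source: str | None = None) -> FingerprintVector:
    """Concatenate fingerprint vectors, in the given order, into one.

    The default molecular conjoint is (MACCS, ECFP); complex featurization
    passes four blocks. Slicing the output at the cumulative block lengths
    recovers every input exactly.
    """
    if not fps:
        raise ValueError("conjoint() requires at least one fingerprint")
    bits = np.concatenate([fp.bits for fp in fps])
    src = source if source is not None else (
        fps[0].source if len({fp.source for fp in fps}) == 1 else "complex"
    )
    return FingerprintVector(bits=bits, scheme="conjoint", source=src)


def fingerprint_molecule(
    mol: MoleculeRecord | Chem.Mol | str, spec: FingerprintSpec
) -> FingerprintVector:
    """Fingerprint one molecule under ``spec`` (maccs | ecfp | conjoint)."""
    if spec.scheme == "maccs":
        return maccs_keys(mol)
    if spec.scheme == "ecfp":
        return ecfp(mol, spec)
    return conjoint([maccs_keys(mol), ecfp(mol, spec)], source="molecule")


# ---------------------------------------------------------------------------
# Protein--ligand complexes
# ---------------------------------------------------------------------------

def extract_pocket(
    complex_record: ComplexRecord, cutoff_A: float = DEFAULT_POCKET_CUTOFF
) -> ComplexRecord:
    """Restrict protein atoms to the binding pocket around the ligand.

    Keeps exactly the protein atoms whose minimum Euclidean distance to
    any ligand atom is <= ``cutoff_A`` (Å). Waters and metal ions were
    already removed at read time. An empty pocket is legal (warned about);
    its fingerprint blocks are all zeros.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    prot = complex_record.protein_coords()
    if prot.shape[0] == 0:
        return replace(complex_record, protein_atoms=[])
    dmin = cdist(prot, complex_record.ligand_coords()).min(axis=1)
    keep = [a for a, d in zip(complex_record.protein_atoms, dmin) if d <= cutoff_A]
    if not keep:
        warnings.warn(
            f"complex {complex_record.id!r}: no protein atom within "
            f"{cutoff_A} Å of the ligand; pocket fingerprint will be all zeros",
            stacklevel=2,
        )
    return replace(complex_record, protein_atoms=keep)


_CONNECTIVITY_SANITIZE = (
    Chem.SANITIZE_ALL ^ Chem.SANITIZE_KEKULIZE ^ Chem.SANITIZE_PROPERTIES
)


def mol_from_atoms(atoms, record_id: str = "<atoms>") -> Chem.Mol:
    """Build an RDKit molecule from bare (element, x, y, z) atoms.

    Bonds are perceived from interatomic distances. Sanitization is
    permissive: unusual valences in point-cloud pockets must not abort
    featurization.
    """
    rw = Chem.RWMol()
    conf = Chem.Conformer(len(atoms))
    for i, a in enumerate(atoms):
        rw.AddAtom(Chem.Atom(a.element.capitalize()))
        conf.SetAtomPosition(i, (float(a.x), float(a.y), float(a.z)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    try:
        rdDetermineBonds.DetermineConnectivity(mol)
    except (ValueError, RuntimeError) as exc:
        raise FeaturizationError(record_id, f"bond perception failed: {exc}")
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(True)
        atom.SetNumRadicalElectrons(0)
    mol.UpdatePropertyCache(strict=False)
    problems = Chem.SanitizeMol(mol, _CONNECTIVITY_SANITIZE, catchErrors=True)
    if problems != Chem.SanitizeFlags.SANITIZE_NONE:
        raise FeaturizationError(record_id, f"sanitization failed ({problems})")
    return mol


def _empty_fp(spec: FingerprintSpec, scheme: str, source: str) -> list[FingerprintVector]:
    if scheme == "maccs":
        return [FingerprintVector(np.zeros(spec.maccs_nbits, np.uint8), "maccs", source)]
    if scheme == "ecfp":
        return [FingerprintVector(np.zeros(spec.ecfp_nbits, np.uint8), "ecfp", source)]
    return [
        FingerprintVector(np.zeros(spec.maccs_nbits, np.uint8), "maccs", source),
        FingerprintVector(np.zeros(spec.ecfp_nbits, np.uint8), "ecfp", source),
    ]


def _component_fps(
    mol: Chem.Mol | None, spec: FingerprintSpec, source: str, record_id: str
) -> list[FingerprintVector]:
    if mol is None:
        return _empty_fp(spec, spec.scheme, source)
    try:
        if spec.scheme == "maccs":
            return [replace(maccs_keys(mol), source=source)]
        if spec.scheme == "ecfp":
            return [replace(ecfp(mol, spec), source=source)]
        return [
            replace(maccs_keys(mol), source=source),
            replace(ecfp(mol, spec), source=source),
        ]
    except FeaturizationError:
        raise
    except Exception as exc:  # pragma: no cover - engine-level failures
        raise FeaturizationError(record_id, f"{source} featurization failed: {exc}")


def featurize_complex(
    complex_record: ComplexRecord,
    spec: FingerprintSpec,
    cutoff_A: float = DEFAULT_POCKET_CUTOFF,
) -> FingerprintVector:
    """Fingerprint a protein--ligand complex: ligand blocks then pocket blocks.

    Layout (frozen, recorded in dataset metadata):
      * maccs:    ligand-MACCS ++ pocket-MACCS                 (332 bits)
      * ecfp:     ligand-ECFP ++ pocket-ECFP                   (2 x nbits)
      * conjoint: ligand-MACCS ++ ligand-ECFP ++ pocket-MACCS ++ pocket-ECFP
                  (4428 bits at defaults)
    """
    pocket = extract_pocket(complex_record, cutoff_A)
    lig_mol = mol_from_atoms(complex_record.ligand_atoms, complex_record.id)
    pocket_mol = (
        mol_from_atoms(pocket.protein_atoms, complex_record.id)
        if pocket.protein_atoms
        else None
    )
    blocks = _component_fps(lig_mol, spec, "ligand", complex_record.id)
    blocks += _component_fps(pocket_mol, spec, "pocket", complex_record.id)
    return conjoint(blocks, source="complex")


# ---------------------------------------------------------------------------
# Dataset-level featurization
# ---------------------------------------------------------------------------

def featurize_dataset(
    ds,
    spec: FingerprintSpec,
    cutoff_A: float = DEFAULT_POCKET_CUTOFF,
) -> tuple[np.ndarray, list[str], dict]:
    """Featurize every record of a dataset into a dense 0/1 matrix.

    Returns ``(X, ids, metadata)``; metadata records the spec and the
    block layout so downstream models never see a mixed layout. Records
    that fail to featurize are dropped (and reported in metadata).
    """
    rows, ids, failed = [], [], []
    for rec in ds:
        try:
            if isinstance(rec, ComplexRecord):
                fp = featurize_complex(rec, spec, cutoff_A)
            else:
                fp = fingerprint_molecule(rec, spec)
        except FeaturizationError as exc:
            logger.warning("featurization failed: %s", exc)
            failed.append(rec.id)
            continue
        rows.append(fp.bits)
        ids.append(rec.id)
    if not rows:
        raise FeaturizationError("<dataset>", "no record could be featurized")
    X = np.vstack(rows).astype(np.float64)
    is_complex = isinstance(ds[0], ComplexRecord)
    if spec.scheme == "conjoint":
        layout = (
            ["ligand_maccs", "ligand_ecfp", "pocket_maccs", "pocket_ecfp"]
            if is_complex
            else ["maccs", "ecfp"]
        )
    else:
        layout = (
            [f"ligand_{spec.scheme}", f"pocket_{spec.scheme}"]
            if is_complex
            else [spec.scheme]
        )
    metadata = {
        "scheme": spec.scheme,
        "ecfp_radius": spec.ecfp_radius,
        "ecfp_nbits": spec.ecfp_nbits,
        "maccs_nbits": spec.maccs_nbits,
        "block_layout": layout,
        "pocket_cutoff_A": cutoff_A if is_complex else None,
        "n_failed": len(failed),
        "failed_ids": failed,
        "engine": f"rdkit {Chem.rdBase.rdkitVersion}",
    }
    return X, ids, metadata


# ---------------------------------------------------------------------------
# SlogP baseline
# ---------------------------------------------------------------------------

def slogp(mol: MoleculeRecord | Chem.Mol | str) -> float:
    """Wildman--Crippen atom-contribution logP.

    Each atom is assigned one of the published atom types and the estimate
    is the sum of the per-type contributions; atoms matching no specific
    type fall to the method's wildcard type. Purely additive, hence
    invariant to atom order and additive over disconnected fragments.
    """
    parsed, _ = _as_mol(mol)
    return float(Crippen.MolLogP(parsed))
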