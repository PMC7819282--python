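"""Featurize a toy protein--ligand complex: ligand + 4.5 Å binding pocket.

Generates one synthetic complex, writes it out as PDB, re-reads it (which
deletes waters and free metal ions), extracts the pocket — protein atoms
within 4.5 Å of any ligand atom — and builds the 4428-bit complex
conjoint vector: ligand-MACCS ++ ligand-ECFP ++ pocket-MACCS ++ pocket-ECFP.
"""

import tempfile
from pathlib import Path

from conjointfp import (
    FingerprintSpec,
    extract_pocket,
    featurize_complex,
    gen_complexes,
    read_complex,
    write_complex_pdb,
)

raw = gen_complexes(1, seed=4)[0]
print(f"raw complex: {len(raw.ligand_atoms)} ligand atoms, "
      f"{len(raw.protein_atoms)} protein-side atoms (incl. 1 water, 1 Zn)")

tmp = Path(tempfile.mkdtemp())
write_complex_pdb(raw, tmp / "protein.pdb", tmp / "ligand.pdb")
clean = read_complex(tmp / "protein.pdb", tmp / "ligand.pdb", complex_id=raw.id)
print(f"after reading: {len(clean.protein_atoms)} protein atoms "
      "(water and metal ion deleted)")

pocket = extract_pocket(clean, cutoff_A=4.5)
print(f"pocket: {len(pocket.protein_atoms)} atoms within 4.5 Å of the ligand")

fp = featurize_complex(clean, FingerprintSpec(scheme="conjoint"))
print(f"complex conjoint fingerprint: {len(fp)} bits "
      "(166+2048 ligand, 166+2048 pocket)")
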