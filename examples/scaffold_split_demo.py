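"""Random vs scaffold splitting of a molecular dataset.

A random split measures interpolation; a Bemis--Murcko scaffold split
keeps every ring-system chemotype in exactly one partition, so the test
set contains only unseen scaffolds — a harder, more honest estimate of
generalization. The printed leakage count must be zero by construction.
"""

from conjointfp import SyntheticConfig, gen_molecules, random_split, scaffold_split
from conjointfp.splitters import murcko_scaffold

ds = gen_molecules(SyntheticConfig(n_molecules=100, seed=9))
scaffolds = [murcko_scaffold(r.smiles) for r in ds]
print(f"{len(ds)} molecules spanning {len(set(scaffolds))} Bemis-Murcko scaffolds")

rnd = random_split(ds, seed=0)
scf = scaffold_split(ds)
for name, s in (("random", rnd), ("scaffold", scf)):
    print(f"{name:>8s} split: train {len(s.train_idx)}, "
          f"val {len(s.val_idx)}, test {len(s.test_idx)}")

parts = [scf.train_idx, scf.val_idx, scf.test_idx]
part_scaffolds = [{scaffolds[i] for i in p} for p in parts]
leaks = sum(
    len(part_scaffolds[i] & part_scaffolds[j])
    for i in range(3) for j in range(i + 1, 3)
)
print(f"scaffolds shared between scaffold-split partitions: {leaks}")
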