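"""Compute MACCS keys, ECFP and the conjoint fingerprint for one molecule.

The conjoint vector is the exact concatenation (MACCS block first), so
slicing it at position 166 recovers both components — that is the whole
representation trick: keep the curated substructure keys and the hashed
topological neighborhoods side by side and let the regressor weigh them.
"""

import numpy as np

from conjointfp import conjoint, ecfp, maccs_keys, slogp

ASPIRIN = "CC(=O)Oc1ccccc1C(=O)O"

m = maccs_keys(ASPIRIN)
e = ecfp(ASPIRIN)
cj = conjoint([m, e])

print(f"molecule: aspirin ({ASPIRIN})")
print(f"MACCS keys:    {len(m)} bits, {int(m.bits.sum())} set")
print(f"ECFP (r=2):    {len(e)} bits, {int(e.bits.sum())} set")
print(f"conjoint:      {len(cj)} bits = 166 + 2048")
assert np.array_equal(cj.bits[:166], m.bits) and np.array_equal(cj.bits[166:], e.bits)
print("slices recover both blocks exactly")
print(f"Wildman-Crippen SlogP baseline: {slogp(ASPIRIN):.4f} logP units")
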