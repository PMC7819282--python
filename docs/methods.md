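# Methods

## The representation under test

A molecule is featurized three ways:

- **MACCS keys** — a fixed dictionary of 166 predefined substructure
  patterns; bit *k−1* of the output is key *k*. Computed with RDKit's
  public SMARTS definitions; key 1 and the isotope sub-patterns of keys
  2/3 are unmatchable in those definitions and are permanently 0.
- **ECFP** — circular neighborhoods up to radius 2 (bond lengths) around
  every atom, hashed to integer identifiers and folded into 2048
  presence bits (binary, not counts). Radius and width are configurable;
  defaults are the common virtual-screening choice.
- **Conjoint** — the concatenation MACCS ++ ECFP, 2214 bits. The order
  is frozen (MACCS first) so that serialized matrices and fitted models
  are interchangeable; slicing at 166 recovers both blocks exactly.

Fingerprints are computed on the heavy-atom graph with implicit
hydrogens, the standard MACCS/ECFP convention. No standardization (salt
stripping, neutralization, tautomer canonicalization) is applied to
input SMILES; what you read is what gets featurized.

For protein–ligand complexes, the ligand and the binding pocket are
fingerprinted separately and concatenated, ligand blocks first:
ligand-MACCS ++ ligand-ECFP ++ pocket-MACCS ++ pocket-ECFP (4428 bits at
defaults). The pocket is the set of protein atoms whose minimum Euclidean
distance to any ligand atom is ≤ 4.5 Å (closed boundary; the cutoff is a
parameter). Filtering is per atom, not per residue. Waters (residue tags
HOH/WAT/H2O) and free metal ions (single-atom residues of metallic
elements) are deleted at read time; metals embedded in multi-atom
residues are kept. Molecules are rebuilt from bare (element, x, y, z)
atoms by distance-based bond perception with permissive sanitization; an
empty pocket is legal and contributes all-zero blocks.

## Models

All five families implement one `train(spec, X, y)` / `predict(model, X)`
contract, with every stochastic element driven by `spec.seed`.

| family | implementation | key defaults |
|---|---|---|
| rf | scikit-learn RandomForestRegressor | 300 trees, unlimited depth |
| svr | scikit-learn SVR | RBF kernel, C = 5, γ = 0.015, ε = 0.1 |
| xgb | XGBoost | 300 rounds, depth 6, η = 0.1 |
| dnn | in-package NumPy engine | width 100, relu, dropout 0.2, 100 epochs, batch 32 |
| lstm | in-package NumPy engine | 2 LSTM layers + dense(64) + scalar output, 60 epochs |

The SVR constants are the tuned values of the benchmarking protocol this
package implements; the tree-model and neural defaults are this
package's own choices (the searched spaces are exposed in `tune`).

The neural families run on a small NumPy engine written for this
package: dense layers (softsign/relu/linear/tanh), inverted dropout, a
single-timestep LSTM layer, MSE loss and Adam (lr 0.001, β₁ 0.9,
β₂ 0.999). Everything is seeded and single-threaded, so repeated runs
are bit-identical. The LSTM presents the whole fingerprint as one
timestep; the first layer's output dimension equals the input dimension,
and with a zero initial state the recurrent weights receive no gradient
(they are kept for architectural faithfulness). Weights are materialized
lazily at the first fit/predict, so architecture queries on very wide
layers cost nothing. Neural models record a per-epoch (train, validation)
loss history; no early stopping is applied — epochs are a searched
hyperparameter.

**Consensus** — two models of the same family, one trained on MACCS, one
on ECFP, identical training rows; prediction is their unweighted mean.

## Protocol

- **Random split**: |test| = round(0.20·n); the remainder splits
  train:val = 4:1 (val = round(remaining/5), remainder to train;
  round = half-up). Seeded permutation; identical inputs give identical
  splits.
- **Scaffold split**: molecules grouped by Bemis–Murcko scaffold
  (acyclic molecules share the empty scaffold); groups assigned whole,
  largest first (ties by scaffold string), to train until its quota
  fills, then validation, then test. Deterministic, no seed, zero
  scaffold leakage by construction. The validation partition mirrors the
  random protocol's 4:1 rule.
- **Repeated trials**: n independent random splits with seeds
  base_seed + i (default 20); every metric is reported as mean ± sample
  standard deviation across trials.
- **Grid search**: exhaustive, seeded shuffled k-fold CV (default 5),
  score = mean negative MSE. Ties break toward the smaller-capacity
  candidate (a per-family parameter-count proxy), then grid order.
  Failing candidates score −∞ and are logged; the search continues. The
  held-out test partition is never visible to the search. A tuned
  assignment can be frozen (JSON) and reused across datasets.

## Metrics

MSE = Σ(y_true − y_pred)²/n; RMSE = √MSE, in property units. Agreement
is the Pearson correlation coefficient
r = Σ(a−ā)(b−b̄)/√(Σ(a−ā)²·Σ(b−b̄)²). The benchmarking literature this
package follows prints that formula under the label R²; it is the
unsquared r, so this package names it `pearson` and offers
`pearson_squared` separately. Per-molecule deviations |y_true − y_pred|
are binned by the Tetko assessment convention: ≤ 0.5 acceptable,
(0.5, 1.0] disputable, > 1.0 unacceptable (boundary convention frozen:
exactly 0.5 is acceptable, exactly 1.0 disputable), reported as
percentages summing to 100. PCA projection (mean-centred, full SVD) is
provided for visualizing how much chemical-space spread a representation
retains.

## Synthetic data

The generator exists to make every claim testable without external
datasets. Molecules are assembled by seeded single-bond joining of 2–3
fragments from a pool of ~30 drug-like building blocks (aromatic and
aliphatic ring cores, short chains with common heteroatom and halogen
motifs); invalid joins are retried, so every emitted SMILES parses, and
the pool is diverse enough that 200 molecules span ≥ 20 Bemis–Murcko
scaffolds.

Targets are linear in a few fingerprint bits plus Gaussian noise
(default sd 0.5 property units — the scale of the acceptable bin):

y = Σᵢ βᵢ·maccs_bitᵢ + Σⱼ βⱼ·ecfp_bitⱼ + ε.

By default 4 bits per block are auto-selected among columns with
prevalence in [0.15, 0.85] (nearest 0.5 first) whose maximum
single-column cross-block correlation is ≤ 0.6. The cap is what makes
the signal genuinely block-structured: fingerprint blocks of real
molecules are correlated, and without it a planted "ECFP-only" bit can
be a near-copy of a MACCS column, which would let a MACCS-only model
read it off and void the experiment. Effect sizes default to
alternating ±1.0, comparable to the noise scale. Explicit bit indices
and effect sizes can be supplied instead.

Toy complexes embed a fragment-assembled ligand in 3D (ETKDG), centre it
at the origin, and place protein-like atoms at seeded distances spanning
2–8 Å — including, by construction, at least one atom inside and one
outside the 4.5 Å cutoff, plus one water and one Zn ion to exercise the
deletion rules. Their pKi-like targets are random draws.

What the generator does **not** emulate: realistic activity cliffs,
assay noise structure, measurement bias, realistic binding-pose
geometry, or nonlinear structure–property relationships. Passing the
ordering experiment on this generator shows that the pipeline extracts
complementary block information when it exists; it does not by itself
establish the size of the effect on any real dataset.

## The ordering experiment

The package's self-contained analogue of its central claim: on 500
synthetic molecules with block-split signal (noise sd 0.5), over 10
independent random-split trials, the mean held-out Pearson r of a model
trained on the conjoint representation must exceed the better standalone
fingerprint and at least match the consensus ensemble, for SVR and DNN.
Each standalone model suffers omitted-variable bias (it cannot see the
other block's terms); the consensus mean reduces variance but keeps both
biases; the conjoint model nests the true signal. Problem sizes (500
molecules, 10 trials) keep the experiment comfortably reproducible on a
single CPU while leaving the ordering stable across seeds.

## Numerical and degenerate-input choices

- Pearson r of a constant vector raises; it is never silently 0.
- Aggregation of identical trials reports exactly zero spread.
- Empty prediction sets raise; empty matrices predict empty vectors.
- Fingerprint vectors validate binarity and length on construction.
- Parse failures in batch inputs are skipped and counted
  (`n_failed + retained = input entries`), never fatal; missing files or
  columns raise immediately.
- CSV is comma-separated UTF-8 with a header row; coordinates are Å
  throughout, with no unit detection.

## Known limitations

- MACCS cross-engine agreement holds except for chemical-perception
  differences between engines (e.g. aromatic-ring counting on fused
  systems); ECFP bit positions are engine-specific by construction
  because the hashing scheme is not standardized across toolkits.
- The LSTM at conjoint width allocates ~80 M parameters when actually
  trained; it is intended for the smaller representations or for
  architecture experiments, and the benchmark defaults therefore
  exercise DNN and the kernel/tree families at full width.
- No statistical significance testing between representation schemes is
  provided; the harness reports means and spreads only.
- No protonation/tautomer standardization, altloc handling, or full PDB
  semantics; structure files are consumed for element, residue name and
  coordinates only.
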