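# Methods

## Scope and data

The package analyses computed bond dissociation energies (BDEs, kcal/mol) of
cyclic hypervalent halogen(III) reagents: a ring skeleton (labelled 1–5, plus
an external-test skeleton 6) holding an I, Br, or Cl center in the +3
oxidation state, bonded to one of twenty transfer groups (a–t: F, Cl, Br,
CH3, CF3, vinyl, alkynyl, CN, N3, NH2, NHAc, OH, OCH3, OCF3, OAc, OCOCF3,
OBz, OTf, OTs, SCF3). Two packaged tables cover the 5 × 3 × 20 space:

* homolytic BDEs — 300 cells, all numeric, range −11.2 to 84.0 kcal/mol;
* heterolytic BDEs — 300 cells of which 209 are numeric (six transfer groups
  form unstable cations and are tabulated as missing, plus one isolated
  missing cell), range −7.6 to 375.2 kcal/mol.

Both missing-value sentinels of the original tables ("–" and "/") are kept
distinct in the fixtures for provenance; loaders treat both as missing.
The homolytic table is used in full: the reference analysis counts 296
homolytic points against the 300 printed numeric cells without naming an
exclusion rule, so nothing is dropped silently by default and callers can
pass an explicit exclusion list to reproduce a smaller selection.

## Structure registry

Skeleton structures are distributed as template SMILES in
`data/skeletons.tsv`: the halogen position is an atom-mapped iodine
placeholder (`[I:1]`) and the transfer-group site a mapped wildcard
(`[*:2]`); transfer groups (`data/groups.tsv`) carry a single `[*:1]`
attachment. Assembly swaps the placeholder element, bonds the group
attachment atom to the center on the parsed molecule (never by string
splicing), and canonicalises. The registered skeletons are the
field-standard frameworks: benziodoxolone (1), 1,1-dimethylbenziodoxole (2),
1,1-bis(trifluoromethyl)benziodoxole (3), the biphenylene (dibenzohalole)
framework (4), benziodoxathiole 3,3-dioxide (5), and benziodazolone (6).
Where a drawing admits close substitution variants the registry records one
fixed choice; every downstream result depends only on each key mapping to a
consistent structure.

Neutral three-coordinate Br and Cl violate default SMILES valence rules.
All structures — for all three halogens — are therefore parsed with relaxed
valence checking (RDKit sanitization minus the valence-property check).
Canonicalisation under this convention is idempotent (tested across the
enumerated library). No physical bond-order claim is attached to the
hypervalent center; the graph model only requires a consistent topology.

## Cross-halogen linear maps

Within a BDE type, the Br(III) and Cl(III) BDEs of matched
(skeleton, group) pairs vary approximately linearly with the I(III) BDE.
The package fits ordinary least squares with iodine always the predictor
(`y = slope·x + intercept`), via statsmodels; pairs with a missing value on
either side are dropped (100 homolytic pairs; 69 heterolytic). The fitted
coefficients on the packaged tables round to

* homolytic: Br = 0.89·I − 13.85 (R² 0.79), Cl = 0.76·I − 26.02 (R² 0.57)
* heterolytic: Br = 0.96·I − 20.50 (R² 1.00), Cl = 0.92·I − 29.39 (R² 0.99)

The "LE" (linear-equation) prediction route inserts a known iodine BDE into
these maps. `correlation.external_validation_report` reproduces the
external-test comparison (skeleton 6 with F; skeleton 1 with CF2SO2Ph),
scoring each route by RMSE against the DFT reference over the cells the
route predicts (the LE route has no iodine predictions). One published LE
cell (homolytic 6-Cl-F) is not reproducible from the rounded coefficients
(26.1 published vs 25.9 recomputed); the published equations were evidently
applied at full precision before rounding. Both values are reported;
nothing is forced to agree.

## Molecular graphs and node descriptors

Reagent SMILES become attributed graphs: one node per heavy atom (explicit-H
mode available), one symmetric pair of directed edges per bond. Node
features concatenate up to three blocks, in fixed order:

1. **species** — one-hot element identity over {C, N, O, F, S, Cl, Br, I, H}
   (width 9);
2. **charge** — an empirical partial charge plus the formal charge
   (width 2);
3. **neighbor_info** — heavy-atom degree, hydrogen count, neighbour counts
   by element class (C/N/O/S/halogen), sp/sp²/sp³ hybridization flags,
   local unsaturation (bond-order sum minus degree), aromaticity and ring
   flags (width 13).

The neighbor block's composition matters more than any architecture knob:
without the hydrogen/hybridization/unsaturation terms the network cannot
tell many atom environments apart, and held-out R² on the heterolytic task
plateaus near 0.8 regardless of capacity, while a ridge oracle on Morgan
radius-2 environment counts reaches ≈0.95–0.99 — the additive
local-environment function class is adequate, the crude features were not.
With the full block the gap closes.

The partial charge comes from a damped electronegativity-equalization
iteration implemented in the package: charges start at the formal charges
and each bond transfers `0.5^k (χ_j − χ_i) / (2η)` electrons at iteration
k = 1…6, with Pauling electronegativities χ and a fixed hardness η = 4.
The scheme conserves total charge exactly, is deterministic, and is finite
for every atom — including hypervalent halogen(III) centers, for which
RDKit's Gasteiger implementation returns NaN (and propagates it to every
atom of the molecule). The exact descriptor set used upstream is not
published in the main text; the three blocks mirror the named descriptor
families and the block flags in `DescriptorConfig` keep the ablation
structure intact.

## The GAT regressor

Each graph-attention layer updates atom i, per head, as

    h_i' = Σ_{j∈N(i)∪{i}} α_ij · (W h_j)  +  W_s h_i  +  b

with attention logits `e_ij = LeakyReLU(a_src·Wh_j + a_dst·Wh_i)` softmaxed
over the incoming edges of i (self-loops included). Three implementation
choices depart from the textbook layer, all standard practice:

* an explicit self-connection `W_s h_i` outside the softmax — softmax
  weights are convex, so without it the identity map (and any count-linear
  readout) is not representable;
* attention logits initialised to zero, i.e. uniform attention at the start
  of training; random attention init destabilised small-sample fits;
* the last layer is linear (ELU between layers only), so a linear readout
  of pooled embeddings can be exactly linear in atom counts.

Head outputs are concatenated; a mean (default) or sum readout pools atoms;
a one-hidden-layer ELU MLP (default width 64; width 0 gives a linear head)
produces the output in min–max-scaled target space. Metrics are always
computed in kcal/mol after inverse scaling.

Defaults: 2 layers, 4 heads, 16 units per head, mean readout, MLP head 64,
minibatch Adam (batch 32) at 1e-2 with cosine decay to 5e-4, decoupled
weight decay 1e-3 on weight matrices, 400 epochs, no dropout. Input node
features are z-scored on training-set atoms; targets are min–max scaled on
the training split only (homolytic and heterolytic tasks scaled
independently — their ranges differ ~4×). A 10 % validation carve-out from
the training split selects the best epoch (weights restored); the patience
default equals the epoch budget, so the carve-out selects rather than
truncates. Training is deterministic for a fixed config seed. One joint
model is trained per task across all three halogens: the element one-hot is
the only halogen-identity signal in the features.

These defaults were selected on the study tasks themselves: smaller
full-batch configurations underfit the homolytic table badly (held-out
R² ≈ 0.5–0.86), while the chosen configuration reaches a seed-averaged
held-out R² ≈ 0.96 (homolytic) and ≈ 0.98 (heterolytic) at ~20 s per fit
on one CPU. Evaluation protocol: random 9:1 reagent-level split,
R² / MAE / RMSE on the held-out tenth, averaged over ≥5 split/init seeds.
Single-seed results on ~30-molecule test sets scatter by a few hundredths
in R², which is why the package's headline numbers are seed-averaged with
a floor (≥0.90) rather than point estimates.

### Capacity configuration

The architecture's capacity is established on synthetic molecules whose
target is exactly linear in atom counts (`10·#C + 5·#O`): with 1 layer, sum
readout, linear head and weight decay 0.1, held-out R² exceeds 0.99 at
n = 200. The strong decay matters: this function class contains the exact
solution, and shrinkage steers training to it, whereas flexible
configurations interpolate 160 small molecules with spurious nonlinearities
(an MLP fitted to perfect composition counts behaves the same way, reaching
only ≈ 0.90). Count-linear targets are not a function of mean-pooled
features at all, so the capacity configuration necessarily differs from the
mean-pool default used for the BDE tasks.

### Descriptor ablation

`run_ablation` retrains the model under each descriptor configuration
(species-only, charge-only, neighbors-only, all three) on identical
seed-controlled splits and reports seed-averaged train/test metrics sorted
by test R². On the BDE tables the combined configuration matches or beats
every single block; on the synthetic composition-rule control the species
block alone is already sufficient, confirming that the ablation ordering on
real data reflects the data and not the harness.

## Synthetic data

`SyntheticSpec`/`generate_bde_table` emulate the cross-halogen structure of
the real tables: a 5 × 20 grid whose iodine column is drawn from
Normal(54, 13) kcal/mol (the location/spread of the homolytic iodine
column), Br and Cl columns affine in iodine (defaults: the published
homolytic coefficients) plus homoscedastic Gaussian noise (default σ = 3
kcal/mol, consistent with the moderate homolytic scatter), and optional
uniform missingness. Output uses the exact fixture CSV schema.
`generate_toy_library` grows random small organics atom-by-atom on an RWMol
(validity by construction) and computes targets exactly from a named
closed-form composition rule.

What the generators deliberately do not emulate: skeleton- and
group-specific effects (cells are exchangeable within a column),
heteroscedastic residuals, correlated missingness, and any quantum-chemical
realism. Passing the synthetic recovery tests therefore demonstrates the
statistical machinery (fitting, scaling, splitting, training), not chemical
accuracy on real reagents.

## Numerical notes and limitations

* Gradients of the hand-written GAT backward pass are validated against
  central finite differences (tolerance 1e-4 relative) in the test suite.
* Min–max scaling refuses constant input rather than dividing by zero;
  splits use half-up rounding for the test-set size with at least one
  record on each side.
* OLS coefficients are displayed rounded to 2 d.p. and LE predictions to
  1 d.p., matching the reference tables' formatting; computation is at full
  precision.
* The GAT's accuracy claim is interpolation within the studied reagent
  space; extrapolation to new skeleton chemistries rests on two external
  reagents only.
* DFT-level uncertainty in the underlying tables is inherited, not
  modelled.
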