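# Methods

## Scoring model

The pose-rescoring core is the empirical pairwise potential of the
Vina-family scoring function. All five terms are functions of the surface
distance `d = r − R_i − R_j`; terms are summed over intermolecular
heavy-atom pairs with centre distance `r ≤ 8 Å`. The composite score is

    score = (w · terms) / (1 + w_rot · N_rot)

with default weights `w_gauss1 = −0.035579`, `w_gauss2 = −0.005156`,
`w_repulsion = 0.840245`, `w_hydrophobic = −0.035069`,
`w_hbond = −0.587439`, `w_rot = 0.05846` — the published parameters of the
scoring function, kept so that an external engine's score-only output and
this module agree. Van der Waals radii: C/A 1.9, N/NA 1.8, O/OA 1.7,
S/SA 2.0, P 2.1, F 1.5, Cl 1.8, Br 2.0, I 2.2 Å; an atom type without a
configured radius is an error, never silently defaulted. All weights and
radii are overridable (YAML via the CLI, keyword arguments in the library).

Atom typing follows the PDBQT convention: hydrophobic = {C, A, F, Cl, Br,
I}; H-bond acceptors = {NA, OA}; a nitrogen/oxygen is a donor heavy atom
when bonded to a polar hydrogen (type HD) — per an explicit bond table when
available, else by proximity within 1.1 Å (covalent N–H/O–H bonds are
< 1.05 Å). Non-polar hydrogens are excluded from scoring (united-atom
convention); receptor polar hydrogens are retained for donor detection
only. The atom-type vocabulary is closed: unknown codes raise, because a
silently mistyped atom corrupts every downstream feature.

**Approximations.** Intramolecular ligand contributions are not included in
the five feature terms: the features of interest are the part that varies
across receptor structures, and the external engine's per-term breakdown is
accepted through the score-log adapter when exactness to a specific engine
build matters. RMSD is computed without graph-automorphism symmetry
correction. Desolvation and electrostatic terms are out of scope — they are
not part of the six-feature set this pipeline uses.

**Correctness definition.** The vectorised scorer is defined to be correct
when it matches a brute-force pure-python double loop over all atom pairs;
the acceptance script and the test suite check this on 100 random toy
complexes to 1e−9 absolute per term.

## Feature aggregation and labels

Per ligand: component-wise mean over the poses of each structure, then over
the structures of the ensemble. Means are plain (no Boltzmann weighting).
If an engine returns fewer poses than requested the mean runs over what
exists; zero poses, or a missing (ligand, structure) cell, is a hard error
— silent imputation would bias the ensemble average. Feature column order
is fixed everywhere: `gauss1, gauss2, repulsion, hydrophobic, hbond, score`.

Activity: active iff Ki strictly below the threshold; a Ki exactly at the
threshold is inactive (configurable). Standardisation learns mean/std on
training rows only; a zero-variance column maps to 0 with divisor 1 (and a
logged warning), which keeps degenerate synthetic fixtures finite.

Out-of-site poses (centroid farther than 10 Å from the receptor's reference
point) are *reported*, not excluded, by default: whether outlier poses were
dropped before feature averaging is genuinely open, and excluding them
silently would change the features; an opt-in filter covers the other
convention.

## Classifiers

* **LDA/QDA** — Gaussian discriminants with empirical class priors, backed
  by scikit-learn. QDA carries a small covariance regulariser
  (`reg_param = 1e−6`, a convex shrink toward the identity) because 6-D
  per-class covariances can be singular at small n.
* **MLP** — 6 → 16 → 16 → 1, sigmoid activations throughout, batch
  normalisation between the hidden layers and before the output, RMSProp
  (ρ = 0.9, learning rate 1e−3), binary cross-entropy, batch size 64, 2000
  epochs. Implemented directly in numpy; standard batch normalisation is
  used where batch *re*normalisation is unavailable in this stack, and the
  choice is recorded in the model metadata. Training is a pure function of
  the seed; the loss trace is stored (sub-sampled) and a non-finite loss
  aborts with the epoch number.

Splitting is a seeded random partition with `n_train = round(n·fraction)`
(80 % default, unstratified to match plain random assignment; a stratified
option exists). Cross-validation is stratified five-fold with the scaler
re-fitted inside every fold — the no-leakage property is tested by checking
that deleting test ligands leaves fitted parameters byte-identical.

## Evaluation

AUC is the midrank Mann–Whitney statistic (ties count ½), identical to the
trapezoidal area under the ROC curve; the score direction flag is mandatory
because docking scores rank better = lower and a silently inverted AUC is
the classic failure mode (an ensemble member can genuinely discriminate
*inversely*). MCC returns 0 when any confusion-matrix marginal is empty.

Top-k consensus (k = 100 default): per structure, the k best scores with
ties broken by (score, ligand id) for determinism; per pair, the overlap
count and the Spearman correlation of the within-top-k ranks restricted to
the intersection (< 2 common ligands → flagged undefined). A generic
ablation helper returns one structure's top-k set so the effect of removing
a suspect structure's favourites on the others' AUC can be measured.

Liminal robustness removes ligands with Ki in the inclusive window
[5, 15] µM around the 10 µM threshold and re-runs train/test with the same
seed, reporting both metric sets and their deltas; no magnitude assertion
is made — the deltas are the result.

Screening applies a trained model to a library's ensemble features, sorted
by descending probability with `predicted_active = p ≥ 0.5` (configurable);
a library matrix carrying a different fitted scaler than the model's is
rejected by hash comparison.

## Synthetic data

Two generators, both pure functions of seed and spec:

* **Toy complexes** — receptor atoms uniform in a 26 × 28 × 32 Å box,
  ligand poses as jittered copies of a compact base conformation, atom
  types from a weighted palette with polar hydrogens attached (0.96 Å) to a
  fraction of N/O atoms so donors exist. These exercise the scorer's
  geometry; they do not mimic real pocket shapes, packing densities or
  chemistry.
* **Planted activity** — standardized latent features `z ~ N(0, I₆)`,
  latent activity `u = w·z + intercept + ε`, `ε ~ N(0, 0.5²)`, and
  `log₁₀(Ki/µM) = 1 − u`, so the 10 µM threshold sits at `u = 0` and splits
  the classes near 50/50 (matching a near-balanced Ki dataset) while 1 µM
  and 100 µM stay meaningful. Default planted weights
  (0.8, 0.3, −0.6, 0.7, 0.9, −1.2) follow chemical intuition: contact terms
  favour binding, repulsion and a less-negative composite score oppose it.
  Structure heterogeneity is additive feature noise (sd 0.3) plus pose
  jitter (sd 0.15) rather than distinct geometries — this keeps the
  learning-stage tests independent of the scorer, which has its own
  geometric fixtures. The campaign fixture instead derives Ki from features
  actually scored on its toy geometries, so the end-to-end CLI path carries
  real signal.

What passing tests show: the pipeline recovers a planted linear signal and
its weight signs, behaves at chance on null data, and degrades
monotonically with noise. What they do not show: performance on real
docking features, whose term distributions are neither Gaussian nor
independent and whose activity relationship is not linear.

## Problem sizes and numerics

Default study conditions: 294 ligands, 10 structures, 3 poses, 80/20 split,
five-fold CV — the acceptance script runs these in well under a minute on
one CPU, with toy-complex oracles at 40 receptor / 10 ligand atoms × 100
seeds. Numerical conventions worth knowing: the repulsion term underflows
to exactly 0 for |d| < ~1e−154 (harmless); gauss terms are never exactly 0
within the cutoff; PDBQT coordinates round-trip at the format's 3-decimal
precision; batch-norm inference uses running statistics with momentum 0.99.

## Known limitations

No pose search (poses come from an external engine or the generators); no
protonation/charge preparation; no desolvation/electrostatics; no
enrichment-factor or BEDROC metrics; no hyperparameter search or
calibration. The printed per-term breakdown of a specific engine build may
include intramolecular contributions this scorer deliberately omits — the
score-log adapter exists precisely so the features can be sourced from the
engine when that distinction matters.
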