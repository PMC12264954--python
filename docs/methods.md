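# Methods

This note records the modeling choices, numerical conventions, and known
limitations of `cliffdti`. The package implements an activity-cliff-informed
transfer-learning workflow for drug–target interaction (DTI) prediction:
activity-cliff (AC) pairs are mined from an interaction table, a pair
classifier is pretrained on them, and its encoders initialize a DTI affinity
regressor whose error is then examined on a similarity × affinity-difference
threshold grid.

## Activity-cliff definition and mining

Two compounds measured against the same target form an **activity cliff**
when they are structurally highly similar yet differ strongly in activity.
Both conditions are thresholded inclusively:

- **Similarity**: the pair's best score under any of three criteria must be
  ≥ 0.9. The criteria are (a) *substructure*: Tanimoto similarity of
  1024-bit ECFP4 (Morgan radius-2) fingerprints; (b) *scaffold*: Tanimoto
  similarity of the ECFP4 fingerprints of the two Bemis–Murcko scaffolds;
  (c) *string*: 1 − Levenshtein(s₁, s₂)/max(|s₁|, |s₂|) over canonical
  SMILES.
- **Affinity difference**: |Δ affinity| ≥ 1.0 on a log10 scale, i.e. a
  ten-fold change (for integrated scores such as KIBA the threshold applies
  to the score directly and must be chosen by the user).

Pairs that pass the similarity filter but not the affinity threshold are
labeled non-AC; pairs below the similarity filter are discarded entirely.
Replicate measurements are collapsed to their mean before pairing, and two
entries with identical canonical SMILES are never paired.

Scaffold conventions: an acyclic molecule has an empty Bemis–Murcko
scaffold. Two empty scaffolds are treated as identical (scaffold similarity
1); one empty against one ring-bearing scaffold scores 0. Tanimoto of two
all-zero fingerprints is 0 (with a warning).

## Splitting

The **compound-based split** assigns every compound to exactly one of
train/validation/test. Interactions follow their compound; a pair is kept
only if both members share a partition, and cross-partition pairs are
dropped (and counted). Because the AC and DTI tasks consume the same
assignment, no compound can leak from training to test through either task.
A random pair split (`split_pairs_random`) is provided as the deliberately
over-optimistic baseline mode. `assert_no_compound_leakage` re-verifies the
invariant on materialized splits.

## Models

Both tasks share one two-branch architecture family:

- **Compound encoder** — an MLP over the ECFP bit vector, ending in a
  post-activation embedding.
- **Protein encoder** — exactly one dense layer mapping the one-hot target
  vector to a dense embedding. One-hot target identity cannot generalize to
  unseen proteins; this is a deliberate, documented limitation.
- **Head** — an MLP over the concatenated embeddings.

The **AC classifier** passes *both* pair members through the *same*
compound encoder (shared parameters; gradients from both branches
accumulate), concatenates (emb_a, emb_b, emb_target), and trains a sigmoid
head with binary cross-entropy; `pos_weight` can up-weight the minority AC
class. The **DTI regressor** concatenates (emb_drug, emb_target) and trains
a linear-output head with mean squared error.

The network core is a small NumPy implementation (dense layers, He init,
ReLU/tanh, inverted dropout, Adam, manual backprop). Training uses
mini-batch Adam with early stopping on validation loss (training loss when
no validation set is given): training halts after `patience` epochs without
improvement and the parameters of the best epoch are restored. All runs are
deterministic given `random_state`.

The DTI regressor standardizes affinities internally (fit on z-scores,
predictions returned on the original scale). Without this, the initial MSE
gradient on a pK-like scale (values ≈ 4–9) is large enough to destroy
transferred encoder features within the first epochs.

Parameters live in named groups (`compound_encoder`, `protein_encoder`,
optional `adapter`, `head`). Frozen groups are excluded from the optimizer
and verified bit-identical (SHA-256 digest) before and after training.

## Transfer learning

`transfer_encoders(ac_model, plan)` initializes a fresh DTI regressor from
a fitted AC classifier:

- `warm_start` — encoder weights copied; everything trainable.
- `freeze` — encoder weights copied; transferred groups frozen.
- `freeze_plus_layer` — as freeze, plus a new trainable dense adapter in
  the drug branch between the frozen encoder and the concatenation.

Scope `drug_only` transfers the compound encoder only; `drug_and_target`
also transfers the protein encoder. The head is always freshly initialized.
Architecture parameters are inherited from the AC model so shapes match.

## Metrics

Classification: precision, recall, F1, Matthews correlation coefficient
(MCC), and balanced accuracy from the confusion table at threshold 0.5
(p ≥ 0.5 is positive). Zero-denominator conventions: precision/recall with
an empty denominator return 0 with a warning; MCC with a zero denominator
factor returns 0; balanced accuracy with an absent class raises.

Regression: micro-averaged RMSE pools all squared errors; macro-averaged
RMSE averages per-target RMSEs with equal target weight.

## Threshold-grid evaluation

The structure–activity landscape of a test set is summarized on a grid of
(similarity threshold s, affinity-difference threshold a) cells. Under the
default **cumulative** semantics, cell (s, a) holds every test pair with
max-criterion similarity ≥ s and Δ affinity ≥ a, so pair counts are
non-increasing toward the strict corner (asserted at construction). A
disjoint interval-binning semantics is available behind `cumulative=False`.

The cell metric is the RMSE of the DTI predictions over the **unique**
(compound, target) interactions touched by member pairs — an interaction
shared by several pairs counts once. Cells with fewer than `min_pairs`
pairs (default 100) are masked as statistically unreliable. Repeated runs
aggregate cellwise as mean ± sample standard deviation (ddof = 1). The
**differential grid** is baseline − transfer, so positive cells mean the
transfer model achieved the lower RMSE; masks are OR-ed and standard
deviations combined in quadrature.

## Synthetic data generator

The generator emulates a desk-scale chemogenomic matrix with planted
activity cliffs:

- **Library**: a scaffold × R-group combinatorial enumeration. Each of up
  to 8 templates is a small drug-like core with a distinct Bemis–Murcko
  ring system and one attachment point; up to 20 substituent fragments each
  carry at least one interior radius-2 atom environment so their identity
  is decodable from ECFP bits across series. Within a series, compounds
  share a scaffold (scaffold similarity 1, passing the ≥ 0.9 filter);
  across series all three similarities stay below threshold.
- **Affinities** are additive on the log10 scale: a per-(scaffold, target)
  base ~ U(4, 9), a small per-(R-group, target) effect ~ N(0, 0.2), a
  planted cliff term, and observation noise N(0, 0.1). Cliff *presence and
  sign* are drawn per (target, R-group) with probability `cliff_rate` and
  shared across scaffold series; the *magnitude* ~ U(1.5, 3.0) is redrawn
  per (scaffold, target, R-group). Sharing across series mimics a
  pharmacophore-bearing substituent and is what makes the AC task learnable
  under a compound-exclusive split: a model that never saw a test compound
  can still have seen the same R-group trigger cliffs on the same target in
  another series. Were the indicators independent per triple, test-set
  cliffs would be irreducible noise.
- Cliff magnitudes start at 1.5 log units, safely above the 1.0 labeling
  threshold, while R-group effects and noise stay well below it, so mined
  labels recover the planted ones (≥ 95% agreement at default noise; exact
  at zero noise). At `cliff_rate` r, roughly 2·r·(1−r) of same-series pairs
  straddle exactly one cliff member, placing the AC fraction in the
  imbalanced 10–30% regime typical of curated bioactivity extracts.

What the generator does **not** emulate: real chemistry beyond the
enumerated cores (no stereochemistry, tautomers, or synthesis constraints),
assay heterogeneity (a single global noise level instead of
assay-dependent error), non-additive structure–activity relationships
(beyond the cliff terms themselves), correlated targets (targets are drawn
independently; there is no protein-family structure), and matrix sparsity
(every compound is measured against every target).

## Numerical choices

- Fingerprints are dense uint8 0/1 vectors; Tanimoto is computed in NumPy.
- Levenshtein distance via `edlib` (global alignment); similarity is
  1 − d/max length.
- BCE is computed on logits with a numerically stable sigmoid; probability
  clipping at 1e-12 only inside the log.
- Adam uses bias correction; updates are in place over a flat parameter
  list.
- Sample standard deviations use ddof = 1; a single repeat reports std 0
  with a warning.
- All randomness flows through `numpy.random.default_rng(seed)`; no global
  seeding.

## Limitations

- One-hot protein encoding restricts prediction to targets seen during
  training.
- The NumPy training core is CPU-only and sized for desk-scale experiments
  (thousands of pairs), not benchmark-scale sweeps.
- Threshold-grid cells at strict thresholds can hold few pairs; the
  `min_pairs` mask must be respected when reading differential maps.
- Transfer-learning benefits are regime-dependent: on densely observed
  synthetic matrices where the base affinity surface is easy to learn from
  scratch, warm-started encoders can underperform the baseline (see the
  discussion in the repository README).
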