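# cliffdti

Activity-cliff-informed transfer learning for drug–target affinity
prediction.

## The problem

An **activity cliff (AC)** is a pair of structurally very similar compounds
whose measured activities against the same protein target differ strongly —
here, at least ten-fold (1.0 log10 unit). Cliffs are exactly where
quantitative structure–activity models earn or lose their keep: small
structural edits with large affinity consequences are the hardest cases for
**drug–target interaction (DTI)** affinity regression, and the most
valuable to get right during lead optimization.

`cliffdti` implements a complete workflow around this idea:

1. **Mine** AC and non-AC pairs from an interaction table. Two compounds
   are "similar" when any of three criteria reaches 0.9: Tanimoto over
   ECFP4 fingerprints (substructure), Tanimoto over Bemis–Murcko scaffold
   fingerprints (scaffold), or normalized Levenshtein similarity of
   canonical SMILES (string). A similar pair is an AC when
   |Δ affinity| ≥ 1.0 log unit. Both thresholds are inclusive.
2. **Split** at the compound level. Compounds are assigned exclusively to
   train/validation/test; interactions follow their compound, pairs are
   kept only when both members share a partition, and the same assignment
   drives both tasks — so no compound leaks between training and testing
   through either task.
3. **Train** two-branch neural models: an AC pair classifier (one shared
   compound encoder applied to both pair members, one-layer protein
   encoder over the one-hot target, sigmoid head) and a DTI affinity
   regressor (compound encoder + protein encoder + linear-output head).
4. **Transfer** the AC-pretrained encoders into the DTI model: warm start
   (copied, all trainable), frozen, or frozen plus a trainable adapter
   layer; drug branch only or both branches.
5. **Evaluate** on a similarity × affinity-difference threshold grid: each
   cell holds the test pairs above both thresholds, and the cell score is
   the RMSE of the DTI predictions over the unique interactions those
   pairs touch. The **differential grid** (baseline − transfer) shows
   where transfer helps (positive) or hurts (negative).

Since real bioactivity extracts are large and noisy, the package ships a
**synthetic generator** that plants activity cliffs in a scaffold × R-group
combinatorial library with known ground truth, which makes every stage of
the workflow testable end to end. See `docs/methods.md` for the full
modeling and numerical details.

## Worked example

```python
from cliffdti import (ActivityCliffClassifier, MiningConfig, SyntheticConfig,
                      ac_design_matrix, classification_report,
                      generate_dataset, mine_ac_dataset, split_compounds,
                      split_pairs)

# 1. Simulate a desk-scale chemogenomic matrix with planted cliffs
cfg = SyntheticConfig(seed=0)            # 6 scaffolds x 12 R-groups x 8 targets
library, records, truth = generate_dataset(cfg)
print(f"{len(library)} compounds, {len(records)} interactions")

# 2. Mine activity-cliff pairs (>=0.9 similarity, >=10-fold affinity gap)
pairs = mine_ac_dataset(records, library, MiningConfig())
n_ac = sum(p.label for p in pairs)
print(f"{len(pairs)} similar pairs, {n_ac} activity cliffs "
      f"({100 * n_ac / len(pairs):.0f}%)")

# 3. Compound-based split: no compound appears on both sides
assignment = split_compounds(library.keys(), fractions=(0.64, 0.16, 0.2),
                             seed=0)
train, val, test, dropped = split_pairs(pairs, assignment)
print(f"pairs train/val/test: {len(train)}/{len(val)}/{len(test)} "
      f"({dropped} cross-partition pairs dropped)")

# 4. Train the pair classifier and evaluate on unseen compounds
vocab = sorted({r.target_id for r in records})
X_tr, y_tr = ac_design_matrix(train, library, vocab)
X_va, y_va = ac_design_matrix(val, library, vocab)
X_te, y_te = ac_design_matrix(test, library, vocab)
model = ActivityCliffClassifier(
    encoder_hidden_dims=(256, 128), embedding_dim=64,
    protein_embedding_dim=16, head_hidden_dims=(128, 64),
    learning_rate=1e-3, pos_weight=2.0, dropout=0.1,
    max_epochs=60, patience=10, random_state=0)
model.fit(X_tr, y_tr, X_va, y_va)
report = classification_report(y_te, model.predict_proba(X_te)[:, 1])
print({k: round(v, 3) for k, v in report.to_dict().items()})
```

Output (deterministic, ~15 s on one CPU core):

```
72 compounds, 576 interactions
3168 similar pairs, 840 activity cliffs (27%)
pairs train/val/test: 1264/56/96 (1752 cross-partition pairs dropped)
{'precision': 0.964, 'recall': 0.964, 'f1': 0.964, 'mcc': 0.95, 'balanced_accuracy': 0.975}
```

The classifier identifies cliffs among pairs of compounds it has never
seen, far above the majority predictor (MCC 0, balanced accuracy 0.5):
under the compound-exclusive split, cliff-prone R-group/target
combinations observed on training scaffolds generalize to held-out ones.

Estimators follow scikit-learn conventions (`fit`/`predict`/
`predict_proba`, `get_params`/`set_params`, trailing-underscore fitted
attributes) and compose with `sklearn` tooling.

Transfer learning is one call:

```python
from cliffdti import TransferPlan, transfer_encoders

regressor = transfer_encoders(model, TransferPlan("freeze", "drug_and_target"),
                              learning_rate=1e-3, max_epochs=400, patience=60)
regressor.fit(X_dti_train, y_affinity, X_dti_val, y_affinity_val)
```

## Command line

The same workflow is scriptable stage by stage, or end to end:

```bash
cliffdti simulate --seed 0 --out interactions.csv
cliffdti mine-pairs --input interactions.csv --out pairs.csv
cliffdti split --input interactions.csv --fractions 0.64,0.16,0.2 --out split.csv
cliffdti train-ac  --interactions interactions.csv --pairs pairs.csv \
                   --split split.csv --out ac.npz
cliffdti train-dti --interactions interactions.csv --split split.csv \
                   --from-checkpoint ac.npz --mode warm_start --out dti.npz
cliffdti run --out results/      # full pipeline incl. differential grid
```

`cliffdti run` writes the mined pairs, the split table, AC test metrics,
model checkpoints (`ac_model.npz`, `dti_baseline_seed*.npz`,
`dti_transfer_seed*.npz`), baseline/transfer/differential grid CSVs, a
`run.log`, and a `summary.json`, all stamped with the hash of the resolved
configuration. Rerunning with `--skip-train` reuses the checkpoints to
recompute the evaluation; a run directory whose artifacts were produced
under a different configuration hash is refused rather than silently
mixed. Checkpoints reload in Python via `cliffdti.load_model(path)` with
bit-identical predictions.

## Reproduction

The headline verification quantities (mining-oracle agreement, leakage
violations, metric agreement with reference implementations, planted-cliff
recovery, AC-task test performance, baseline vs warm-start transfer RMSE,
training contracts) are recomputed by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(~2 minutes on one CPU core; deterministic given the seed.)

## Known divergence: the transfer-direction result

On the synthetic benchmark, warm-start transfer (AC-pretrained encoders,
all weights trainable) does **not** beat the from-scratch DTI baseline in
the high-similarity/high-Δ grid cell — the opposite of the direction the
workflow is designed to demonstrate, and the test
`test_warm_start_transfer_beats_baseline_in_cliff_cell` fails honestly
rather than being tuned until green. The result is robust in our
experiments: it persists with a near-perfect AC pretraining signal (test
MCC 0.99), across architectures from (128,)-width to (512,)-width
encoders, across fine-tuning learning rates (a 10× lower rate makes it
worse), and with internal target standardization protecting the
transferred features from early gradient shock.

Linear-probe analysis points at the mechanism: AC pair labels are
invariant to the per-(scaffold, target) base affinity (it cancels in the
pair difference), so AC pretraining systematically discards
scaffold-identity information — the dominant term of the affinity surface —
while enriching R-group information. On a densely observed matrix where
the baseline can learn the full surface from scratch, that trade is a net
loss. The differential grids produced by `cliffdti run` make the same
point visually: transfer-favoring cells appear at looser thresholds, not
in the strict-cliff corner. This mirrors the fact that even in the
original experimental setting the benefit shrinks or reverses in the
highest-threshold cells; a sparser, noisier regime (where from-scratch
training is starved) is likely required for the transfer benefit to
materialize, and is left as future work.

## Layout

```
src/cliffdti/
  chemio.py      SMILES, fingerprints, scaffolds, three similarity criteria
  ac_mining.py   AC pair mining and labeling
  splitting.py   compound-based and random splits, leakage checks
  nn.py          NumPy network core (dense layers, Adam, losses)
  models.py      two-branch estimators, transfer, searches
  metrics.py     classification metrics, micro/macro RMSE
  landscape.py   threshold grids, aggregation, differentials, plots
  synthetic.py   scaffold x R-group generator with planted cliffs
  cli.py         click command line
docs/methods.md  modeling choices, conventions, limitations
scripts/acceptance.py  headline verification quantities
tests/           unit, property, and end-to-end acceptance tests
```
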