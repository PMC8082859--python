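# cpdrift

Mondrian conformal prediction for **diagnosing data drift** in binary
toxicity models — and for **repairing calibration** by updating either the
training set or only the calibration set.

## The problem

Toxicity screening data are released in chronological batches: a model is
trained on old data and applied to compounds screened later, often from a
different chemical space. Ordinary classifiers give no warning when this
happens. A conformal predictor does: under exchangeability, the fraction of
prediction sets that miss the true label is guaranteed not to exceed the
chosen significance level ε, so an observed error rate *above* ε is direct
evidence that the new batch has drifted away from the calibration data.
Better still, exchanging just the calibration set for newer data restores
the guarantee without retraining the underlying model.

`cpdrift` implements this workflow end to end for imbalanced binary
endpoints (Tox21-style, ~10% actives):

- **Molecule preparation** — salt stripping, neutralisation, organic/size
  filters, InChI-based conflict-aware deduplication (RDKit).
- **Signature descriptors** — counts of canonical atom-rooted fragments at
  heights 1–3, with the fragment vocabulary fixed by the training set;
  sparse MatrixMarket IO compatible with pre-computed fingerprint files.
- **Conformal layer** — inductive Mondrian CP with margin nonconformity on
  an RBF-SVM score model (C = 50, γ = 0.002 by default), plus two
  aggregation schemes: **ACP** (20 random 70/30 splits, median p-values)
  and **SCP** (fixed 30% calibration set, nonconformity scores averaged
  over 4 partition sub-models — provably valid).
- **Evaluation** — validity, efficiency (fraction of single-label sets),
  calibration-and-efficiency plots, and the RMSD of observed error from
  the diagonal over ε ∈ {0.0, 0.1, …, 1.0}.
- **Six-experiment study design** with persisted fivefold-CV splits:
  internal CV, external prediction, SCP comparison, train-set update,
  calibration-set update, and half-and-half recalibration.
- **Synthetic drifted data** — three-batch class-conditional Gaussian
  scenarios with a covariate-shift dial, so the whole pipeline is testable
  without any downloads.

## The statistics in brief

For a test example with per-class scores (s₀, s₁) summing to 1, the margin
nonconformity under hypothesised label y is

    nc(s, y) = ½ − (s_y − s_{1−y}) / 2  ∈ [0, 1].

The Mondrian (class-conditional) p-value ranks nc against the calibration
nonconformities of class y alone:

    p_y = ( #{i : nc_i ≥ nc_test} + 1 ) / (n_y + 1),

and the prediction set at significance ε is {y : p_y > ε}. With n_y = 8
calibration actives only nine distinct p-values exist — the resolution
limit that small active classes impose on calibration quality.

## Worked example

Simulate a strongly drifted three-batch scenario (2,000 compounds per
batch, 50 features, 10% actives, test/score batches shifted by 3 noise SDs)
and run the six experiments:

```bash
cpdrift simulate --n 2000 --d 50 --drift 3 --seed 1 --out demo/data
cpdrift all --data demo/data --out demo/results --seed 1
```

which prints:

```
experiment 1 (internal_cv): mean error@0.2=0.192 efficiency@0.2=0.833 RMSD=0.022
experiment 2 (pred_score): mean error@0.2=0.874 efficiency@0.2=0.852 RMSD=0.415
experiment 3 (pred_score_scp): mean error@0.2=0.870 efficiency@0.2=0.854 RMSD=0.413
experiment 4 (train_update): mean error@0.2=0.280 efficiency@0.2=0.715 RMSD=0.107
experiment 5 (cal_update): mean error@0.2=0.206 efficiency@0.2=0.836 RMSD=0.014
experiment 6 (cal_update_2): mean error@0.2=0.187 efficiency@0.2=0.859 RMSD=0.015
```

Reading the numbers: the internal CV (1) is well calibrated — 19% observed
error at ε = 0.2, RMSD 0.022. Predicting the drifted score batch with the
same models (2) is wildly invalid (87% error): the drift is detected. The
SCP aggregation (3) does not help, so the p-value aggregation is not the
cause — the data really have drifted. Updating the whole training set with
the intermediate batch and retraining (4) only partially recovers (28%
error), because the update batch is diluted by the stale training data.
Exchanging **only the calibration set** (5, 6) restores validity completely
(error ≈ ε, RMSD ≈ 0.015) at no retraining cost. Each experiment directory
contains per-fold curve tables, RMSD summaries, the ε = 0.2 summary and the
resolved config; `cpdrift plot-cep --results demo/results/exp2_pred_score`
renders the calibration-and-efficiency plot.

The same pipeline runs on real molecules: `cpdrift prep` standardises an
SDF or SMILES CSV, `cpdrift featurise` builds the signature vocabulary and
matrices (or you can feed pre-computed fingerprint MTX files directly).

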