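# Methods

This note records the models, parameter choices and numerical conventions
behind `cpdrift`, and what the synthetic experiments do and do not show.

## Conformal layer

**Score model.** The conformal machinery only requires a score model
mapping a feature vector to two per-class scores in [0, 1] summing to 1.
The default is an RBF support-vector classifier with C = 50 and γ = 0.002
(the hyperparameters established for signature-descriptor toxicity models),
wrapped in Platt-style sigmoid calibration (`CalibratedClassifierCV`,
3-fold, unshuffled, hence deterministic) to obtain comparable per-class
scores. A nearest-centroid softmax scorer (`algorithm="centroid"`) is
provided as a fast drop-in; every conformal guarantee is agnostic to the
score model's quality, which the test suite exercises by running the same
validity checks under both models.

**Nonconformity and p-values.** Margin nonconformity
nc = ½ − (s_y − s_{1−y})/2 and non-smoothed Mondrian p-values
p = (#{nc_cal ≥ nc} + 1)/(n + 1), ties counted in the numerator. The
non-smoothed form is conservative (errs towards validity); a smoothed
variant with uniform tie-breaking is available behind `smoothed=True` for
users who need exactly uniform p-values. Set inclusion uses the strict
inequality p > ε, so ε = 0 always yields {0, 1} and ε = 1 always yields ∅.

**Aggregation.** ACP fits 20 ICPs on independent stratified 70/30
proper/calibration splits and aggregates p-values by median; an even number
of models uses the midpoint mean (the common convention). Median
aggregation stabilises predictions but carries no finite-sample validity
proof. SCP instead keeps a single fixed 30% calibration set, trains one
sub-model on each of 4 equal stratified partitions of the proper training
set, and averages nonconformity scores (calibration and test alike) before
the single rank comparison, preserving exact validity. Partitioning deals
shuffled class members cyclically with a carried pointer so partition
totals differ by at most one while staying stratified.

## Evaluation

Error rate is the fraction of prediction sets excluding the true label;
efficiency is the fraction of single-label sets; per-class versions
restrict to compounds of that true label. The calibration summary is the
RMSD between observed error and ε over the grid {0.0, 0.1, …, 1.0} (11
points, endpoints included). The endpoints contribute (near-)zero deviation
for any conformal predictor, so their inclusion mainly rescales the
summary; the grid in force is written into every result file, and curves on
other grids are accepted. Undefined per-class rates (empty class) propagate
as missing values and are excluded from RMSD means with a logged warning.

**Sampling error of the observed error rate.** Validity checks compare an
observed error rate against ε plus three standard errors. Conditional on a
*fixed* calibration set, the exceedance probability of the calibration
quantile is itself random — Beta-distributed with variance close to
ε(1−ε)/(n_cal+1) — on top of the binomial test-set term, so the package
uses

    SE(ε) = sqrt( ε(1−ε) · (1/n_test + 1/(n_cal+1)) )

(`evaluation.conformal_error_se`), with n_cal the relevant (per-class)
calibration count. Using the test-set term alone systematically rejects
valid predictors whenever the calibration class is small.

## Six-experiment design

A stratified fivefold CV plan is built once per dataset and persisted
(JSON), including every fold's 20 stratified 70/30 ICP splits, so all
experiments that the design requires to share training compounds do so by
construction (verified by comparing persisted indices). Experiment 1 trains
one ACP per fold and evaluates on the held-out fold; experiment 2 predicts
the external (score) batch with those exact models; experiment 3 runs the
SCP variant on the same fold training sets; experiment 4 merges the
intermediate (test) batch into each fold's training data and refits with
fresh splits; experiments 5 and 6 keep the fitted score models and only
exchange calibration data — the whole intermediate batch (5) or a
stratified half of the score batch, predicting the other half (6). In
experiment 5 every ICP receives the same full replacement calibration set
(rather than a resample of it), since the update batch is exchanged
wholesale; this is config-overridable. Fold models persist between
experiments in a versioned joblib archive with a checked loader. The
headline reporting level is ε = 0.2; full-grid curves are always stored.

## Synthetic drifted data

The generator emulates three chronologically released batches with binary
labels drawn at a 10% active rate (Tox21-like imbalance) and
class-conditional isotropic Gaussian features (unit noise SD, class means
3 SDs apart along a random unit axis, d = 50). Drift is a covariate shift:
the test and score batches' class-conditional means are translated by
`drift_delta` noise SDs. The default translation direction is the
inactive→active class axis. This is a deliberate choice: margin
nonconformity depends only on per-class score differences, so a translation
orthogonal to the class-discriminant axis is essentially invisible to the
conformal layer, and a uniformly random direction in 50 dimensions is
almost orthogonal with overwhelming probability. Translating along the
class axis is the minimal covariate shift that actually breaks calibration
— the failure mode the diagnosis targets. A user-supplied drift direction
and a label-flip drift mode (flip probability δ/(1+δ)) are available for
robustness experiments, and a sparse Poisson-count variant feeds
integration tests with the fingerprint-matrix reader.

What passing these tests shows: the conformal layer is valid under
exchangeability, detects a mean-shift drift, and recovers calibration when
the calibration set is exchanged. What they do not show: behaviour under
real descriptor geometry (sparse, high-dimensional, heavy-tailed fragment
counts), label noise between assay runs, or drifts that change the
feature–label relationship rather than the covariate distribution — the
label-flip mode probes the last of these only crudely.

Study-condition sizes used throughout the end-to-end checks and the
acceptance script: 2,000 compounds per batch, d = 50, ACP with 20 ICPs,
SCP with 4 partitions, fivefold CV, drift_delta ∈ {0, 3}.

## Molecule preparation

"Non-organic" is operationalised as "no carbon atom after salt stripping";
the kept fragment is the largest organic fragment by heavy-atom count
(ties broken by canonical SMILES). Neutralisation uses the standard SMARTS
rule `[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]` — protonate
anions and deprotonate cations where valence allows, leaving zwitterions
and non-neutralisable charges (quaternary ammonium, nitro) untouched.
Identity is the standard InChI of the standardised structure. Conflicting
duplicates (same InChI, both labels observed for the endpoint) are removed
entirely, both before and after standardisation, because salt stripping can
merge distinct parents; agreeing duplicates merge keeping the first-seen
record. Tautomer canonicalisation and stereochemistry normalisation are out
of scope, so compound counts on real datasets may differ slightly from
pipelines using other standardisers.

## Signature descriptor

Fragments are induced subgraphs of all atoms within h bonds of a root atom,
h ∈ {1, 2, 3}, hydrogens implicit, counted with multiplicity (a binary mode
exists behind a flag). The canonical form is the lexicographically minimal
depth-first traversal string over all DFS orders, found by exact
branch-and-bound: atom token = element symbol + formal-charge signs, bond
tokens `- = # :`, every branch parenthesised, ring closures emitted at the
later endpoint as `<bond>@<visit index>` (sorted, hence choice-free). The
grammar is decodable, so the encoding is injective up to rooted-graph
isomorphism and invariant under atom relabelling — both properties are
tested, the latter with 100 random renumberings. Exact string compatibility
with other signature implementations is not promised (their dialects are
not published); any injective canonical form preserves the method. The
search is exponential in the worst case but fragments at height ≤ 3 are
small and highly asymmetric in practice; the whole fixture set encodes in
milliseconds.

Test and score molecules are encoded against the training vocabulary
(lexicographic (height, canon) order); novel fragments are dropped
silently, and an all-zero row is kept and logged. Matrices are written as
MatrixMarket with vocabulary and row-id sidecar text files, and the reader
also accepts pre-computed fingerprint matrices with bare fragment strings.

## Known limitations

- ACP validity is empirical, not guaranteed; the suite tests the median
  aggregate only under the study conditions.
- The drifted-scenario conclusions are qualitative orderings (which
  strategies restore calibration), not quantitative predictions for any
  real endpoint; real-data effect sizes depend on the actual drift.
- The preprocessing rule table is intentionally small; it is not a
  replacement for a full structure-standardisation toolchain.
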