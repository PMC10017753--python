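# Methods

This note documents the models, numerical choices and open design decisions
behind `connsae`, and what the synthetic-data experiments do and do not show.

## Network construction

**Structural.** Input is a symmetric (or directed, then averaged both ways)
78x78 matrix of non-negative streamline counts.  Edge weights are
`w_ij = ln(1 + s_ij) / max_kl ln(1 + s_kl)`: the log compresses the heavy
right tail that probabilistic tractography produces for high-anisotropy
bundles, and max-normalisation puts the strongest edge at 1.  The `+1`
offset keeps a single-streamline edge non-zero and makes the transform
defined at 0; after max-normalisation the log base is immaterial.  An
all-zero matrix is an error (nothing to normalise).

**Functional.** Input is a 59x59 correlation matrix.  Binarisation keeps the
`round(cost * n(n-1)/2)` strongest correlations by *signed* value —
negative correlations are effectively never retained at realistic costs;
ranking by absolute value is a documented alternative a caller can apply by
passing `abs(corr)`.  Boundary ties are broken by ascending (row, column)
index so outputs are deterministic.

**Small-world cost range.** For each cost in a grid (default 0.10-0.40 in
steps of 0.02) the small-world index `sigma = (C/C_rand)/(L/L_rand)` is
computed against 20 degree-preserving rewired references (double-edge
swaps, 10 proposals per edge); the longest contiguous run of costs with
sigma > 1.1 is retained.  Characteristic path length on a disconnected
graph is averaged over reachable pairs only.  The threshold, grid and
rewire count are configurable; the defaults mark the regime where the
factor-model correlation matrices are clearly small-world.

The retained range is selected **once per cohort on the cohort-mean
correlation matrix**, not per subject.  Downstream, every subject's nodal
metrics are averaged across the same retained costs; if each subject had a
private range, the cost-averaged feature columns would not be comparable
across rows of the feature table.  Per-subject selection remains available
(`select_smallworld_cost_range` on one matrix) for exploratory use.

## Nodal metrics

Five properties per node, matching Brain Connectivity Toolbox conventions:
strength (weighted) / degree (binary); nodal global efficiency
`E_i = (1/(n-1)) Σ_j 1/d_ij` with `1/inf = 0`; nodal local efficiency (the
mean nodal global efficiency of the subgraph induced by a node's
neighbours; 0 for nodes with fewer than two neighbours); the clustering
coefficient (binary triangle fraction, or Onnela's geometric-mean formula
with weights normalised by the network maximum); and betweenness centrality
normalised by `(n-1)(n-2)/2` (raw values via `normalized=False`; whether
the original analysis normalised is not stated, normalised is the default).
Weighted shortest paths use the connection-length transform `l = 1/w`.

These are dense 59-78-node graphs, so distances come from a vectorised
Floyd-Warshall and betweenness from Brandes accumulation driven by the
distance matrix — batched over all sources with one einsum per BFS level
for binary graphs, per-source for weighted graphs.  Correctness is pinned
by exhaustive path-enumeration oracles (all graphs <= 7 nodes, 1e-10) and a
networkx cross-check; neither oracle is used in the implementation.

Feature vectors concatenate modality -> metric -> node index
(`struct_strength_0` ... `func_betweenness_58`), 390 + 295 = 685 entries.

## Feature reduction

Min-max scaling to [0, 1] is fit on training rows only; validation values
clip to [0, 1]; features constant in training map to 0.  Three filters rank
all features: Welch |t|; mutual information with the label (k-NN estimator,
k = 3, seeded); and |Lasso coefficient| at a 5-fold internally
cross-validated penalty on standardized features (the binary label
regressed as 0/1), with zero coefficients ranked after all non-zero ones in
t-test order.  The published description says only that the three
approaches were "combined"; here the three rank vectors are averaged and
the 60 smallest mean ranks win, ties broken by feature index — symmetric,
scale-free and reproducible.  Scaling and selection are refit inside every
cross-validation fold; a test poisons validation rows to prove no leakage.

## The semi-supervised autoencoder

Architecture: encoder 60-40-20, decoder 20-40-60, classifier head 20-20-1,
sigmoid activations everywhere (including the classifier's hidden layer).
Loss: `0.7 * MSE + 0.3 * BCE`, with MSE the mean-over-subjects of
mean-over-features squared reconstruction error and BCE the mean binary
cross-entropy (probabilities clamped at 1e-7).  Training is full-batch Adam
(lr 1e-3, beta 0.9/0.999) with hand-written backpropagation — at n <= 110
subjects and ~10^4 parameters a deep-learning framework buys nothing, and
the closed-form gradients are verified against central finite differences
in the test suite.  Initialisation is Glorot-uniform from a seeded
generator; a fixed seed makes training bit-reproducible.

Augmentation: every epoch, an independent Bernoulli(0.20) mask selects
input entries to perturb with N(0, 0.02²) noise.  The mask is re-sampled
per epoch (the fixed-subset reading of "20% of the input features" is the
less natural augmentation and is not used); reconstruction targets stay
clean, and the 95% early-stopping accuracy is evaluated on clean inputs.
Training stops when clean training accuracy exceeds 0.95 or at 1000 epochs,
whichever comes first; the stop reason is recorded per fold.

Evaluation: stratified five-fold cross-validation (each fold ~20% of the
sample, class-balanced).  Per fold: validation accuracy at threshold 0.5,
AUC of the predicted probabilities, and validation reconstruction MSE;
means ± SD across folds are reported.  The PCA+SVM baseline (PCA retaining
95% variance, RBF-SVM with sklearn defaults) runs on identical fold
assignments so the comparison is head-to-head.

## Permutation importance

`FI_j = (1/m) Σ_k (H − H'_k)²` with H the cross-entropy of the intact
input (fixed baseline, per the printed formula) and H'_k after the k-th
independent shuffle of column j; m = 1000 by default.  Shuffles are plain
random permutations, not derangements.  Importance is computed on each
fold's validation rows with that fold's model, mapped back to
source-feature indices, and averaged over the folds in which a feature was
selected; the mean + 2 SD rule (population SD; sample SD is a configurable
alternative) is then applied over the ever-selected candidates.  Features
provably ignored by the network (zero first-layer weights) and constant
columns score exactly 0.

## Brain-behaviour analyses

**SVR.** RBF support vector regression predicts a T-score from the
important features under the same five-fold protocol; features and targets
are min-max scaled per training fold, out-of-sample `R² = 1 − SSE/SST`
(SST about the validation fold's mean) and MSE are reported on the scaled
target, predictions are mapped back to the T-score scale.  The epsilon tube
is 0.01 rather than sklearn's 0.1: on a target scaled to [0, 1] an
insensitivity band of 10% of the range caps attainable precision and masks
genuinely predictable targets.  C and gamma stay at sklearn defaults.  The
regression importance statistic mirrors the classification one with MSE in
place of cross-entropy.

**Latent correlations.** Pearson r of each of the 20 latent AE-features
(from one model trained on the full sample, so all subjects share a latent
space) with the T-score; Bonferroni correction multiplies raw p by the
latent dimensionality, capped at 1.  Zero-variance latents are flagged
not-significant.  Latent indices are arbitrary under retraining, so no
index-level claims are made.

**Path model.** Every construct here is a single measured variable (one
brain feature, one latent, one T-score), for which PLS-style structural
equation modelling reduces exactly to least squares on standardized
variables; that reduction is implemented directly.  Layer 1: each selected
latent regressed on the important features; layer 2: the T-score regressed
on the latents plus covariates (age, sex as 0/1, SES, IQ; handedness is
constant in an all-right-handed cohort and is dropped with a warning).
Significance: 5000 bootstrap resamples of subjects, re-standardized within
each resample, two-sided percentile sign test on each coefficient.
Exactly collinear predictors raise an error naming the offending pair.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions.

* **Demographics** are drawn around the published-style group means/SDs
  (age ~13 y, SES ~16 y education, IQ ~112; Conners T-scores: controls
  46.15 (6.02) / 48.38 (5.42), TBI 64.73 (13.49) / 58.44 (14.43)); T-scores
  are truncated to [30, 100] because only means/SDs are given.  Sex and
  ethnicity are drawn at each group's table proportions.  Head-motion
  summaries are lognormal with medians well inside the inclusion cutoffs
  (> 2 mm translation / > 5 deg rotation / > 0.2 mm volume-to-volume
  displacement excludes; boundaries are inclusive).
* **Structural counts**: a cohort-level random topology (density 0.35) with
  lognormal edge means (median ~25 streamlines) is shared by all subjects;
  per subject, each supported edge draws `1 + NegBin(r = 10)` around its
  mean (so density 1 implies a complete positive matrix), times a lognormal
  subject-level scale (sd 0.08).  Planted effects multiply the expected
  counts of a designated node's edges by `exp(-0.145 d)` in the TBI group;
  the constant was calibrated by simulation so the measured Cohen's d on
  the node's downstream strength approximates the requested d at default
  settings.
* **Functional correlations** come from simulated time series (300 samples):
  a global factor (loading 0.3), one of five module factors (loading 0.6)
  and unit noise, so matrices are symmetric positive semidefinite with unit
  diagonal by construction.  Planted effects scale the node's module
  loading by `exp(-0.85 d)` in TBI (calibrated the same way against the
  node's degree at cost 0.25).
* **Symptom couplings** add `slope * z(feature)` to a T-score, where the
  feature is computed from the generated matrices (functional features at
  reference cost 0.25); slopes are in T-score points per SD.

What passing tests on these cohorts show: the pipeline recovers effects of
the planted size at the study's n, stays at chance under label shuffling,
and keeps false-positive rates at their nominal levels.  What they do not
show: robustness to realistic confounds absent from the generator —
site/scanner effects, motion-connectivity coupling, heavy-tailed artefacts,
spatial autocorrelation of neighbouring ROIs, or distance-dependent
tractography bias.  Conclusions about real MRI data require real data.

## Problem sizes and runtime choices

The test suite exercises the full 685-feature pipeline at the study's
sample size (110 subjects) with 20 replicate runs for the null-calibration
and signal-recovery suites; replicate-level permutation importance uses
m = 300 shuffles (Monte-Carlo relative SD of a top score scales as 1/sqrt(m)
and is ~6% there), while single runs and the acceptance script use the
default m = 1000.  Brute-force oracle comparisons enumerate all simple
paths on graphs of <= 7 nodes.  Bootstrap path models use 5000 resamples in
the pipeline and >= 100 in tests.

## Known limitations

* The combination rule for the three feature filters, the cost-range
  aggregation, and the importance fold-averaging are documented choices
  where the published description is silent; alternatives are exposed as
  configuration rather than silently fixed.
* Welch t-statistics recomputed from printed summary statistics of the
  motivating cohort table differ from the printed t-values (e.g. -9.33 vs
  -9.145 for inattention), consistent with the printed tests having been
  run on a slightly smaller post-exclusion sample; this module reports its
  own Welch t and does not force agreement.
* The SSAE is full-batch only; minibatching would matter for cohorts orders
  of magnitude larger than the design targets.
* Path-model p-values are percentile bootstrap sign tests, not BCa
  intervals; at n ~ 100 and 5000 resamples the difference is small.
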