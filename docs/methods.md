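# Methods

This note documents the models, procedures, and numerical choices behind
`megfusion`, and what the synthetic validation does and does not show.

## Design and condition layout

All analyses operate on a 40-condition design: 5 exemplars × 4 object
categories (face, animal, house, man-made) × 2 subjective recognition
outcomes. RDMs use one fixed ordering — recognized block first (rows
0–19), unrecognized block second — so the upper-left quadrant holds R–R
dissimilarities and the bottom-right U–U. Dissimilarity is 1 − Pearson
correlation between condition-averaged patterns; diagonals are undefined
and stored as NaN.

## Synthetic-data generator

The generator defines the study conditions for every downstream test:
300 real-image trials per participant (each of the 20 images 15 times),
272 sensors, epochs −500…2000 ms, recognition outcome Bernoulli(0.5),
categorization correct with probability 0.861 (recognized) / 0.401
(unrecognized), errors uniform over the other three categories. Noise is
i.i.d. standard normal across trials, sensors/voxels, and time — the
simplest null with analyzable chance behavior; no empirical generative
model is implied, and the ground-truth table labels every planted
component as a synthetic stand-in.

Three effects are planted additively, gated by rectangular time windows
(all templates drawn once per dataset from a seeded standard normal):

* **Category effect** (amplitude 1.0, 400–1000 ms, recognized trials
  only): a per-category sensor template. The window brackets the period
  in which category information is typically reported to emerge and
  decay under threshold viewing (significance from roughly 470 ms to
  1060 ms).
* **Two-state offset** (amplitude 1.0, 200–1900 ms): an outcome-specific
  shared template, i.e. a bifurcation of activity into a "recognized"
  and an "unrecognized" state.
* **Recognition shrinkage** (factor 0.3, 130–1900 ms, recognized trials
  only): the exemplar component `e_i` becomes
  `sqrt(1−s)·g + sqrt(s)·e_i` with a shared cluster center `g`. The
  idiosyncratic across-exemplar variance is multiplied by `s` while
  total pattern energy is preserved.

The shrinkage formulation is a deliberate design choice. A pure variance
rescaling — shrinking `e_i` without introducing `g` — is *invisible* to
correlation-distance RDMs, because 1 − r normalizes pattern amplitude:
recognized conditions would remain mutually uncorrelated, no clustering
would appear in the RDM, and MEG–fMRI fusion would carry no
recognition-geometry signal at all (we verified this empirically).
Clustering in correlation space requires a shared direction, so
"reduction of neural variability" is implemented as variability
reduction *around a common center*. The fMRI generator uses the same
formulation: an ROI's 40 condition patterns mix a two-state component
(outcome-specific templates) and a recognition component
(`sqrt(1−s)·g + sqrt(s)·spread` for R conditions, full-variance spread
for U) with per-ROI weights, plus noise.

Default ROI profiles plant the network dissociation of interest: visual
regions (V1–V3, four category-selective VTC regions) two-state-dominant
(weights 1.0 vs 0.3–0.4), frontoparietal regions recognition-dominant
(DAN 0.05, FPCN 0.1, SAL/DMN 0.15 two-state admixture vs 1.0). The
admixture ceiling matters: because Spearman correlations saturate once a
pair class (e.g. all U–U entries) orders consistently below another,
even a modest two-state admixture (≳0.3) in an fMRI RDM flips the
commonality-based dominance call. Profiles were chosen, once, inside the
regime where the planted label is recoverable; regions closer to the
boundary (as the salience network appears to be in real data, where the
model main effect is near zero) are genuinely ambiguous under this
analysis.

Seeding: a `SimulationConfig.seed` fixes all outputs bit-for-bit. Named
substreams (behavior, MEG templates, MEG noise, per-ROI fMRI) are derived
via `SeedSequence` spawn keys, so stages can be regenerated in isolation.

### What the generator does not emulate

* No biophysical forward model: sensors are exchangeable Gaussian
  channels, voxels likewise; no lead fields, no hemodynamic variability
  beyond a single fixed HRF, no autocorrelated or spatially correlated
  noise.
* Condition-stable exemplar templates make *exemplar identity* linearly
  decodable from single trials in both outcomes — and therefore category,
  by memorization — at default SNR. Under i.i.d. noise this is
  unavoidable if condition-level exemplar geometry is to survive trial
  averaging. Tests of category-specific decoding therefore plant a pure
  category signal (exemplar amplitude 0). Passing tests show the
  pipeline recovers what was planted; they do not show that real MEG
  category decoding is free of exemplar-level confounds.
* Behavioral responses are i.i.d. across trials (no staircase dynamics,
  learning, or lapses).

## Decoding

Linear max-margin classification (linear SVM, cost C = 1, liblinear)
per time point on trials × sensors slices. Stratified fivefold
cross-validation assigns each condition's trials to folds by seeded
round-robin with a rotating offset, so every fold holds approximately
the same share of every condition. Class imbalance in a training fold is
handled by a subsampling ensemble: up to 100 classifiers (configurable),
each trained on all minority-class samples plus an equal-sized random
majority-class subsample (subsets drawn with replacement when fewer
distinct subsets exist; a single model when classes are exactly
balanced). Test predictions are unweighted majority votes; ties (even
ensemble sizes) break toward the class with the larger mean decision
value, which keeps results deterministic under a fixed seed. The score
is balanced accuracy — the mean of per-class recalls — pooled over all
folds, in percent. Fold assignment is made once per dataset and shared
across time points. Category decoding runs the binary machinery on all
six category pairs and averages the six scores; a no-resampling variant
covers balanced (localizer-style) designs.

## RSA

`rdm_timecourse` averages trials within condition per time point and
computes the correlation-distance RDM (2.5 ms steps at the full 400 Hz
rate; coarser steps for desk-scale runs). Model RDMs are binary (0 low /
1 high); only their ranks matter downstream, which the tests verify.
The recognized-clustering contrast (mean R–R vs mean U–U off-diagonal
dissimilarity) is tested one-sided per time point with the cluster
sign-permutation machinery. Category information per outcome is the
Spearman correlation between the within-outcome 20×20 quadrant and the
category model. MDS (metric stress minimization, seeded initialization,
4 restarts) is provided for visualization only.

## fMRI GLM

One stick regressor per image × outcome combination (48) plus one
nuisance regressor at the first-question onsets, each convolved with a
single-gamma HRF (shape 6, scale 1 s, unit peak, no undershoot — a
configuration default, not a fitted value) on a 0.1 s grid and sampled
at the TR. Because each image appears once per run with one realized
outcome, 25 of 49 columns are non-zero per run. Betas are unique least
squares on the non-zero columns (rank deficiency is an error; unobserved
conditions return NaN), averaged across runs per condition, scrambled
images dropped, leaving 40 condition patterns per ROI.

## Fusion and commonality

Fusion uses group-average RDMs from each modality (the best estimate of
the true RDM when MEG and fMRI come from different participants).
Vectors are the strictly-lower-triangle entries in row-major order
(length 780); the diagonal is excluded before ranking. All three vectors
(MEG, fMRI, model) are rank-transformed once with average ranks for
ties, then every term of

C = R²(MEG,fMRI) + R²(MEG,model) − R²(MEG,{fMRI,model})

is computed on the same ranks; the joint term is the two-predictor OLS
R², evaluated in closed form from the three pairwise rank correlations.
Whether the three-variable term should rank jointly or per pair is not
determined by the formula's provenance; single joint ranking is the
default and the implementation keeps the alternatives separable. Exactly
rank-identical fMRI and model vectors degenerate to the single-predictor
limit (C = R²(MEG,fMRI)); near-collinearity short of identity raises an
error because the joint R² is numerically ill-defined. C may be
negative (suppression); it never exceeds either simple R² beyond 1e-10,
and the implementation is verified against an explicit
normal-equations oracle to 1e-12 on random instances.

## Cluster permutation inference

Both tests are one-dimensional (temporal contiguity only) and use the
add-one rule p = (1 + #{null ≥ obs}) / (1 + n_perm).

*Sign permutation* (decoding / RSA contrasts): per-timepoint one-sided
Wilcoxon signed-rank tests against chance define suprathreshold points
(p < 0.05); clusters are maximal contiguous runs scored by summed W.
The null flips each subject's (effect − chance) timecourse with
probability 1/2, 5000 times by default, recording the max cluster
statistic. Because |d| is invariant under sign flips, the rank matrix,
tie corrections, and exact null tables are computed once and each
permutation reduces to array arithmetic. The Wilcoxon null is exact for
n ≤ 12 after zero removal (computed by convolution over per-observation
Bernoulli rank contributions — identical to full 2ⁿ enumeration,
including under ties) and a tie-corrected normal approximation without
continuity correction otherwise. Zero differences are dropped
(Wilcoxon's rule). Sign flips are keyed to row order in the input.

*Label permutation* (commonality): each permutation applies one random
simultaneous row/column permutation of the MEG RDM condition labels —
the same permutation at all time points, preserving the temporal
dependence of the null — and recomputes C(t). The cluster-defining
threshold is the per-timepoint 95th percentile of the permuted values;
clusters of suprathreshold observed C are scored by summed C against the
max-cluster null. Ranks permute with the entries, so permuted rank
vectors are reindexed columns of a precomputed matrix and each draw is a
single matrix product.

Both procedures control the family-wise error rate at ≤5% on null
simulations; the test suite and the acceptance script measure this.

## Network statistics

ROIs map to networks by the largest voxel share in a study-layout table
(packaged); an ROI whose winning network is somatosensory/motor is
excluded, and a tie is an error demanding manual resolution. The table's
rows need not sum to 100 (voxels outside the listed networks). Explained
power is max(C,0)/R²_fusion·100, capped at 100, undefined where
R²_fusion ≤ 0. Windows: early = [0, 1000] ms, late = (1000, 2000] ms,
split on the actual time grid (401/400 points at 2.5 ms; sliding 100 ms
and 200 ms variants available). The 2×2 mixed ANOVA treats time points
as independent observational units — replicating the established design
despite temporal autocorrelation, which inflates effective sample size;
a reader should treat its p values as descriptive. A circular
block-bootstrap test of the model main effect
(`block_bootstrap_model_effect`) is provided as an
autocorrelation-robust, non-default alternative. Generalized η² uses
SS_effect / (SS_effect + SS_subjects + SS_residual). Standard mixed
ANOVA degrees of freedom are reported (df2 = N − 2 for all three
effects); published analyses of this kind sometimes print other
denominators, which we do not attempt to reverse-engineer. Post hoc:
paired two-sided Wilcoxon between models within window, two-sided
Mann-Whitney between windows within model, Bonferroni over the four
tests.

## Pipeline

A single global seed fans out to per-stage, per-subject child seeds via
`SeedSequence` spawn keys; rerunning any configuration reproduces
byte-identical numeric artifacts (the manifest records SHA-256 hashes).
ROIs whose fMRI RDMs never positively correlate with the MEG RDMs are
excluded before fusion (permutation criterion on the maximum Spearman
rho over time, or a plain threshold).

## Problem sizes

Desk-scale runs (demo pipeline, test suite, acceptance script) keep the
full 300-trial / 40-condition design — needed so all conditions are
reliably populated at a 50% recognition rate — and scale down sensors
(24–64 where the quantity under test is insensitive to sensor count,
272 where pattern dimensionality matters), sampling rate (4–20 Hz),
subjects per group (4–6), ensemble sizes (6–20 models), and permutation
counts (150–1000). Chance levels, error rates, and oracle equivalences
do not depend on these sizes; statistical power does, which is why the
planted effects use comfortable amplitudes (SNR ≈ 1 per sensor against
unit noise).
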