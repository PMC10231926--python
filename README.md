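# megfusion

Analysis pipeline for studying **object recognition under uncertainty**
with multimodal neuroimaging: time-resolved multivariate decoding of MEG
sensor patterns, representational similarity analysis (RSA), model-driven
MEG–fMRI fusion via commonality analysis, cluster-based permutation
inference, and a network-level decomposition of each model's explanatory
power. Because the original recordings of such studies are rarely
deposited, the package ships a first-class synthetic-data generator that
plants known representational geometries, so every analysis stage can be
validated against a recoverable ground truth.

## Who this is for

Cognitive neuroscientists who want a tested, reusable implementation of
the RSA-fusion workflow — in particular the commonality analysis that
attributes the representational correspondence between whole-head MEG and
ROI-wise fMRI to competing hypothesis geometries — and methodologists who
want calibrated nonparametric inference (sign-flip and condition-label
cluster permutation tests) with known false-positive behavior.

## The model

The experimental design has 40 conditions: 5 exemplar images × 4 object
categories (face, animal, house, man-made) × 2 subjective recognition
outcomes (recognized R / unrecognized U), with stimuli titrated to a ~50%
recognition rate. For each MEG time point *t* and each fMRI region of
interest, 40×40 representational dissimilarity matrices (RDMs, entries
1 − Pearson *r* between condition-averaged patterns) are compared by the
squared Spearman correlation of their lower-triangle vectors,

    R²_fusion(t) = ρ²( MEG_t , fMRI ),

the variance shared by the two modalities. A hypothesis RDM ("model") is
then credited with the portion of that shared variance it can account
for, the commonality coefficient

    C(t) = R²(MEG_t, fMRI) + R²(MEG_t, model) − R²(MEG_t, {fMRI, model}),

where the joint term is the squared multiple correlation from OLS of the
rank-transformed MEG vector on the fMRI and model rank vectors together.
Two models compete: the **recognition model** (recognized-trial patterns
cluster; every cell involving an unrecognized condition is high) and the
**two-state model** (low dissimilarity within each outcome, high between
outcomes). Explanatory power is max(C, 0)/R²_fusion, summarized per
functional network (Visual, SAL, DAN, FPCN, DMN) and per time window
(early 0–1000 ms vs late 1000–2000 ms) with a 2×2 mixed ANOVA
(generalized η²) and nonparametric post hoc tests.

Inference uses cluster-based permutation tests throughout: per-timepoint
one-sided Wilcoxon tests define clusters whose summed statistics are
compared against a max-cluster null from 5000 subject-wise sign flips
(decoding, RSA contrasts), or against a null from random permutations of
the MEG RDM condition labels (commonality timecourses).

## Worked example

```python
import numpy as np
from megfusion import synthgen, rsa, fusion, netstats

cfg = synthgen.SimulationConfig(
    n_trials=300, n_sensors=272, n_voxels_per_roi=200, sfreq_hz=20.0, seed=0)

# one participant's behavior and epochs; group-average RDM timecourse
rdms = []
for s in range(4):
    sub = cfg.with_seed(1000 + s)
    behavior = synthgen.generate_behavior(sub)
    epochs, ground_truth = synthgen.generate_meg_epochs(sub, behavior)
    r, times = rsa.rdm_timecourse(epochs, step_ms=100.0)
    rdms.append(r)
meg_rdms = np.mean(rdms, axis=0)

betas, _ = synthgen.generate_fmri_patterns(cfg, mode="betas")
models = {n: rsa.build_model_rdm(n).values for n in ("recognition", "two_state")}
for roi in ("V1", "L_MFG"):
    ct = fusion.commonality_timecourse(
        meg_rdms, rsa.compute_rdm(betas[roi]), models, times, roi=roi)
    post = times >= 0
    expl = {m: netstats.explained_fraction(ct.c[m], ct.r2_fusion)[post]
            for m in models}
    print(roi, {m: round(float(np.nanmedian(e)), 1) for m, e in expl.items()})
```

Output:

```
V1 {'recognition': 72.1, 'two_state': 97.2}
L_MFG {'recognition': 97.0, 'two_state': 88.7}
```

V1 was planted with a two-state-dominant geometry and the middle frontal
gyrus with a recognition-dominant one; the medians of explained shared
variance (in percent, over post-stimulus time points) recover exactly
that dominance pattern.

The full study — simulation, decoding, RSA, fusion, cluster tests,
network ANOVA, dominance table, figures — runs end to end with

```bash
megfusion run-all --out artifacts/ --seed 0
```

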