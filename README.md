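# oscportraits

Single-trial **oscillatory portraits** and the effective-connectivity
networks they weave.

## The problem

During a visuomotor task, cortical oscillatory power fluctuates from
trial to trial across regions, frequency bands and movement phases.
Trial-averaged measures (ERD/ERS curves) discard exactly this
variability.  A trial's *portrait* keeps it: the 48-vector of mean
log-normalized power over 4 regions (frontal medial, parietal medial,
left/right sensorimotor) × 3 movement phases (Pre / During / Post) × 4
bands (θ 4–8, α 9–12, β 13–35, γ 36–60 Hz).  This package — aimed at
researchers analyzing trial-epoched electrophysiology — provides a
tested pipeline to

* generate synthetic portrait data with known ground truth (`synth`),
* extract portraits from raw signals via Morlet wavelets (`tfr`),
* infer **effective connectivity** (EC) between elements (`ec`),
* characterize EC graphs: weighted homophily with permutation nulls,
  strong links, node strengths (`netstats`),
* discriminate trial categories and predict single-trial behavior
  (`classify`, `behavior`),
* validate everything against IAAFT surrogates (`surrogate`).

## The model

All prediction runs through one Gaussian random-intercept model
(subject j, trial i):

    y_ij = β0 + β1 · x_ij + u_j + e_ij,   e_ij ~ N(0, σ_e²),  u_j ~ N(0, τ²)

EC is the matrix of standardized coefficients from predicting each
element from the other 47 across trials (row = target, column = source;
estimated on 50 subsamples of 75% of trials, averaged, with held-out
Pearson r as cross-validated performance).  Homophily on a label axis
(region / band / phase) is the fraction of total |weight| joining
same-label nodes,

    H_axis = Σ |w| over same-label ordered pairs / Σ |w|,

tested against node-label permutation nulls.  Distribution overlap uses
the Bhattacharyya coefficient BC(P,Q) = Σ √(P·Q).  IAAFT surrogates
preserve each signal's value distribution exactly and its amplitude
spectrum iteratively, destroying the temporal coordination the EC
analysis feeds on.  Details and design rationale: `docs/methods.md`.

## Worked example

```python
import numpy as np
from scipy import stats
from oscportraits import (SynthConfig, generate_portraits, ground_truth_ec,
                          fit_ec, homophily, pairwise_discriminate,
                          predict_behavior)
from oscportraits.netstats import node_strengths

cfg = SynthConfig(n_subjects=4,
                  trials_per_category={"NR-Hit": 200, "NR-Miss": 200}, seed=0)
table, truth = generate_portraits(cfg)

ec = fit_ec(table, include_behavior=True, n_boot=10, seed=0)
truth_ec = ground_truth_ec(cfg, "NR-Hit", standardized=True)
mask = ~np.eye(48, dtype=bool)
r = stats.pearsonr(truth_ec.weights[mask],
                   ec.element_submatrix().weights[mask])[0]
h = homophily(ec)
auc = pairwise_discriminate(table, "NR-Hit", "NR-Miss", n_resamples=25, seed=0)
pred = predict_behavior(table, "error", n_folds=10, seed=0)
```

Output:

```
1600 trials, 4 subjects
mean cross-validated r over targets: 0.606
recovery of ground-truth EC: r = 0.747
homophily (spatial, spectral, temporal): 28.3%, 28.1%, 33.4%
error: in-strength 2.11, out-strength 9.70
duration: in-strength 2.20, out-strength 1.63
NR-Hit vs NR-Miss portrait AUC: 0.695 +- 0.016
movement-error prediction: r = 0.946, MSE = 0.142
```

Reading it: each element is predictable from the rest (mean held-out
r ≈ 0.6), and the estimated network correlates r ≈ 0.75 with the
closed-form ground truth of one category (the estimate pools both
categories, so perfect agreement is not expected at this size; a
single-category run at 5,000 trials reaches r ≈ 0.95).  Homophily
fractions sit well above the ~23–32% chance levels of a uniform graph.
The exogenous error drive shows up as out-strength ≫ in-strength for the
error node, while duration — a readout — shows the reverse.  The
categories separate from full portraits (AUC ≈ 0.70) even though every
single element's distributions overlap almost completely, and movement
error is recovered from the portrait trial by trial.

A command-line interface mirrors the library
(`oscportraits synth|signals|tfr|ec|netstats|classify|behavior|surrogate|all`),
writing CSV/HDF5 artifacts plus a checksum manifest for reproducibility.

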