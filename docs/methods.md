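# Methods

## The object of study

A single trial of a visuomotor task is summarized by its **oscillatory
portrait**: the 48-vector of mean log-normalized spectral power over

* 4 cortical regions (independent components IC1 frontal medial, IC2
  parietal medial, IC3/IC4 left/right sensorimotor),
* 3 movement phases (Pre = [−1.5 s, onset), During = [onset, offset],
  Post = (offset, offset + 1.5 s]),
* 4 frequency bands (theta 4–8 Hz, alpha 9–12 Hz, beta 13–35 Hz,
  gamma 36–60 Hz).

Each entry is an **oscillatory element**.  The package asks how elements
co-fluctuate across trials, how that coordination changes with task
condition and success, and how it relates to behavior (signed movement
direction error; movement duration).

## Time–frequency decomposition (`tfr`)

Signals sampled at 256 Hz are convolved with complex Morlet wavelets with
spectral-width ratio f0/σ_f = 7 (equivalently σ_t = 7/(2πf0)), on a
0.5-Hz grid from 2 to 60 Hz.  The grid's upper edge is set by the gamma
band: a decomposition stopping at 50 Hz could not fill the 36–60 Hz
element.  Kernels are L2-normalized with ±5σ_t support; power is the
squared magnitude of the convolution.  Samples within 3σ_t of a segment
edge are flagged, and a signal shorter than the 3σ_t support of the
lowest frequency is rejected outright.

The task affords no clean baseline interval, so log power is normalized
against the mean log power over all trials and time points of the same
subject and region, separately per frequency.  Normalization is per
region; pooling regions would let a globally strong region shift the
others' baselines.  Elements are means of the normalized map over the
(phase × band) cell, with band edges inclusive on the grid.

## The shared estimation engine (`mixedlm`)

Every predictive step fits the same Gaussian random-intercept model
y_ij = β0 + β1·x_ij + u_j + e_ij with one intercept per subject.  The
implementation profiles the (restricted) likelihood over the variance
ratio ρ = τ²/σ²: for fixed ρ the GLS problem reduces to OLS on
partially-demeaned data, and all candidate-ρ evaluations reuse per-subject
Gram matrices, so one fit costs O(evaluations × p²) after a single pass
over the data.  This matters because the connectivity stage runs
48 targets × 50 bootstrap replicas per network.  Agreement with
statsmodels' `MixedLM` (coefficients ≤ 1e-5, variance components ≤ 1%)
is enforced in the test suite.  REML is the default; at the simulated
sizes ML differs below test tolerances.  Near-singular designs (easy to
produce with 47 correlated predictors on a bootstrap subsample) fall
back to a relative ridge of 1e-6.  Predictions for subjects absent from
training use u = 0.

Predictors — and, in the connectivity stage, targets — are z-scored with
training-set statistics.  The model is scale-equivariant, so this changes
no prediction; it makes coefficients per-SD effects, comparable across
elements and usable directly as network weights.  Without a common scale,
"strong link" thresholds and homophily sums would be unit-dependent.

Binary category labels are fitted with the same Gaussian engine as a
linear probability model; its continuous output is used only as a ROC
score, which is rank-based, so no calibration is needed.  Behavioral
targets are treated as Gaussian with identity link.

## Connectivity (`ec`)

* **FC**: Pearson correlations of the 48 elements, averaged over 50
  subsamples of 75% of trials, drawn without replacement — "bootstrap"
  here follows the subsampling reading of a 75% resample, which keeps the
  held-out 25% disjoint for validation.  Subsampling is stratified by
  subject: a subject absent from a resample would have an unidentifiable
  intercept.
* **EC**: for each node (48 elements, optionally + error and duration),
  a random-intercept regression on all other nodes per resample;
  weights are the mean standardized coefficients (target row, source
  column; diagonal structurally zero), and performance is the Pearson r
  between held-out predictions and truth, averaged over resamples
  (averaging, rather than pooling held-out predictions, was chosen; at
  50 resamples the difference is far below reporting precision).
* Signed weights are stored; |w| is used wherever nonnegative weights
  are required (thresholds, homophily, strengths), since ratio-of-sum
  statistics are ill-behaved under sign cancellation.
* **Cross-training**: models fitted on one category's training subsample
  are evaluated on every category's held-out trials; entries are r
  averaged over the 48 targets.
* **Similarity** between two networks is the Pearson correlation of the
  flattened off-diagonal weights.

## Network statistics (`netstats`)

Homophily on one axis (region / band / phase) is the fraction of total
|weight| on ordered node pairs sharing that label.  Self-loops are
excluded (the diagonal is structurally zero) and each ordered pair counts
once.  The null permutes one label axis across nodes, keeping the wiring
and the other two axes fixed — isolating each homophily type's null —
with p = (1 + #{null ≥ observed}) / (1 + n).  All weights enter the
homophily sums, not only supra-threshold ones: the ratios are defined on
total weight.  Strong links are entries strictly above the 97th
percentile of |weights| pooled over a set of networks (so per-category
graphs share one threshold).  Node in-strength sums the node's row
(sources that predict it), out-strength its column (targets it predicts).

## Classification, behavior, overlap (`classify`, `behavior`)

Pairwise category discrimination uses 100 stratified 75/25 shuffle
splits (the split ratio matches the package's other protocols); controls
permute labels within the training set only, preserving class counts.
Behavior prediction uses 20 random 75/25 folds (random splits, not a
partition), reporting per-fold Pearson r and MSE, with per-category
models fitted separately as well as pooled.  Distribution overlap is the
Bhattacharyya coefficient of two histograms on 20 shared equal-width
bins spanning the pooled range; the bin count is a reported parameter,
not a tuned constant, and the reference selection is an argument because
"a common reference range" admits several readings.

## IAAFT surrogates (`surrogate`)

The surrogate loop alternates imposing the original amplitude spectrum
(keeping current phases) with rank-remapping onto the original's sorted
values, stopping when the rank ordering stabilizes, the relative RMS
spectral mismatch falls below 1e-8, or 100 iterations elapse.  The
returned series is the rank-remapped iterate, so the value multiset is
exactly preserved and the spectrum approximately (≈0.4% relative RMS on
AR(1) noise at n = 1024).  Surrogates are generated per trial and per
region.  Note what survives: the per-trial amplitude spectrum, hence
whole-trial band power.  Couplings carried by trial-total power are
therefore retained by construction; what IAAFT destroys is the
*within-trial temporal arrangement* — epoch-differential coordination.
The surrogate validation accordingly measures the signed coupling in the
injected direction.

## Synthetic data (`synth`)

The generator emulates the study's structure: 24 subjects, ~440 trials
each across the six categories (NR-Hit/Miss, RS-Hit/Miss, Ct-Miss,
AR-Miss; catch and after-rotation trials rarer), with per trial

    x = μ_c + u_s + A_c z + γ_c·err + η,     duration = d0 + c(v·x + ξ)

* **Latent manifold** — A_c = B + δ R_c: a shared 48×5 backbone plus a
  category-specific orthonormal rotation (fixed per category from the
  seed), so manifolds differ in orientation, not scale.  The backbone
  mixes label-structured patterns (same-region / same-band / same-phase
  loadings; the `block_loading` mix defaults to 0.6) with one
  deterministic factor encoding the classic sensorimotor beta ERD/ERS
  signature (Pre +, During −, Post + on IC3/IC4 beta).
* **Category means** — μ_c = δ·m_c with m_c a seeded unit direction.
  The scale ties to δ deliberately: a purely rotational difference
  between equal-mean Gaussians is invisible to a linear classifier, so a
  mean component is what lets the portrait discriminate; spreading it
  over a unit vector keeps every single element's shift at ~δ/√48,
  i.e. per-element distributions overlap almost completely (Bhattacharyya
  ≥ 0.98 at the default δ = 0.6) while the 48-dimensional portrait
  separates.  This is the regime the analyses are designed to expose.
* **Error as driver** — err feeds the 8 medial-frontal During/Post
  elements with total coupling 3.0 (per-element ≈ 1.06 SD of err);
  concentrated loading makes the error node a genuine driver whose
  conditional predictability exceeds its targets', which is what makes
  out-strength dominate in the standardized-coefficient network.
* **Duration as readout** — duration reads the 6 sensorimotor beta
  elements (total coupling 0.9) plus independent noise (SD 2.5 on the
  element scale before the 0.1 duration-scale factor maps it to ~0.25 s
  around a 1.2 s baseline).  The sizeable readout noise keeps R² ≈ 0.33,
  placing held-out prediction r near 0.5 and, more importantly, keeping
  the duration node *less* conditionally predictable than its source
  elements — the condition under which in-strength dominates.  Both
  asymmetry margins were verified in closed form across backbone seeds
  before being frozen.
* **Hit/Miss coupling** — by default |err| < 1 for Hit and ≥ 1 for Miss
  (truncated-normal sampling); the closed-form covariance accounts for
  the truncated error variance.  The coupling can be switched off, which
  is the right condition for checks premised on identically generated
  categories (e.g. cross-training flatness at δ = 0), because Hit and
  Miss error variances otherwise differ by design.
* **Ground-truth EC** — the model is conditionally Gaussian, so the
  population regression weights are −Ω_ts/Ω_tt from the precision matrix
  of the within-subject covariance A_cA_c' + var(err)γγ' + σ²I (τ² is
  excluded: random intercepts absorb it downstream); a standardized
  variant matches the z-scored estimates.
* **Signals** — per region, a sum over bands of band-limited Gaussian
  noise whose epoch amplitudes are exp(element/2), with 50-ms raised-
  cosine ramps at onset/offset, over 1/f broadband noise (level 0.25).
  Band-limited noise rather than sinusoids matches burst-like
  phenomenology without modeling burst statistics.  Durations are
  clipped at 0.45 s so every trial exceeds the lowest-frequency wavelet
  support.

What the generator does **not** emulate: learning dynamics across trials
(trials are exchangeable within category), EEG forward models or ICA
mixing, non-Gaussian element distributions, and any coupling between
epoch length and element content beyond the duration readout.  Passing
tests therefore demonstrate correctness of the machinery and
recoverability under the stated model, not fidelity of any particular
empirical claim about cortical dynamics.

## Problem sizes and numerical choices

Validation runs use deliberately moderate sizes chosen to keep the whole
chain reproducible on one CPU: EC ground-truth recovery on 5,000 trials
across 8 subjects (50 bootstrap replicas); discrimination on 1,800
trials across 6 subjects; cross-training on 3 × 600 trials; 100-replicate
checks for CI calibration and behavior-node asymmetry; 200 signal trials
for extraction fidelity.  Convergence tolerances: ρ optimized on a log
grid to 1e-4; Cholesky pivots below 1e-7 of the largest trigger the
ridge path; IAAFT tolerance 1e-8.  Ties in ROC scoring contribute 1/2 by
the standard convention; the strong-link threshold marks entries
*strictly* above the percentile, so an all-equal network has no strong
links.

## Known limitations

* The homophily percentages, network similarities and behavior
  correlations reported in the motivating literature derive from
  recordings that are not redistributable; this package validates the
  estimators on synthetic ground truth instead of reproducing those
  numbers.
* EC here is cross-trial and static; no lagged or spectral
  (Granger-style) directionality on raw time series is attempted.
* The linear probability classifier is the deliberately simple choice
  matching the rest of the machinery; it cannot exploit purely
  covariance-borne category differences.
* Per-series IAAFT leaves cross-region phase relations undefined; no
  multivariate surrogate is provided.
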