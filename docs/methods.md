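# Methods

This note documents the modelling and numerical choices behind `metabench`:
what the workflow computes, how each model family is configured, what the
synthetic generator does and does not emulate, and where genuinely open
design questions were settled.

## The workflow

For one dataset and one model family the pipeline is:

1. **Split.** Stratified 2:1 train/test split. Per-class training counts are
   `round(2/3 · n_class)` under round-half-even (banker's rounding); the
   remainder forms the test set. The split is made once per dataset and the
   identical sample lists are reused for every family, so family comparisons
   are never confounded by split luck.
2. **Preprocess.** By default log10 transform, per-feature median imputation
   of missing values, then autoscaling (mean 0, unit *population* variance).
   All statistics come from training rows only and are frozen before any
   test or out-of-fold row is touched. Features with zero training variance
   (or no observed values) are dropped with a logged warning rather than an
   error, because bootstrap resamples of small cohorts create them routinely.
3. **Optimise.** For every candidate hyperparameter setting:
   `R²` and `AUC_full` from a fit on the whole training block, and `Q²` and
   `AUC_CV` from 5-fold cross-validation repeated over 10 Monte-Carlo
   repartitions. Out-of-fold predictions are pooled *within* a repartition
   into one length-N vector before the statistic is computed, and the 10
   per-repartition values are averaged; `Q²`'s `SS_tot` uses the full
   training-block outcome mean in every repartition, so all repartitions are
   referenced against the same null model. (Averaging per-fold statistics
   instead would weight folds unequally and behave badly for AUC on small
   folds — this was an open choice and pooling was adopted.) The same fold
   repartitions are reused at every grid point, so settings are compared on
   identical splits.
4. **Select.** In the plane (performance, gap) — `(Q², |R²−Q²|)` for the
   regression-scored families, `(AUC_CV, |AUC_full−AUC_CV|)` for SVMs and
   the random forest, whose margin/vote scores make `R²` uninformative —
   the Pareto front of non-dominated settings is extracted. The knee is the
   front point with maximal perpendicular distance to the chord joining the
   front's extremes; it is accepted if that distance is at least
   `knee_threshold = 0.02` (both axes are in the same units, so the plane is
   used unnormalised; 0.02 makes the visual notion of "a clear inflection"
   deterministic and is configurable). Otherwise the rule falls back to the
   front point whose gap is closest to the 0.2 overtraining rule of thumb.
   All ties break toward the simpler model (fewer components/neurons, lower
   depth, smaller C/γ/learning rate, larger leaf fraction), which also makes
   the selection invariant to grid ordering.
5. **Evaluate.** A fresh model with the selected setting is fit on the
   training block and scored on both partitions; ROC curves and AUCs are
   reported.
6. **Bootstrap.** With hyperparameters fixed, the model is refit on 100
   class-stratified with-replacement resamples of the *complete* dataset.
   Preprocessing is refit on each in-bag (IB) sample; the model is scored on
   the IB multiset and on the untouched out-of-bag (OOB) rows (~36.8% of
   samples). Each ROC curve is linearly interpolated onto a fixed 101-point
   FPR grid and anchored at (0, 0); bands are pointwise 2.5/97.5 percentiles
   across curves, and AUC intervals are percentiles of the per-resample AUC
   distribution. Stratified resampling (rather than plain) keeps small
   cohorts from producing single-class OOB sets; if one still occurs the
   resample is redrawn, with a logged message, up to 10 times.

Everything is seeded through one counter-based scheme
(`SeedSequence([seed, index, …])`), so any single fold, repartition, or
resample is reproducible in isolation and two runs of the same
configuration produce identical reports.

## Model families

All families expose `fit(X, y)` / `decision_scores(X)` with scores oriented
so that higher means more likely the positive class; the conventional
decision threshold for the regression- and probability-scored families is
0.5, with scores exactly at the threshold classified negative.

* **PLS-DA** — SIMPLS, implemented from scratch for a single response. The
  cross-product vector is deflated in feature space (no X deflation); latent
  scores are orthonormal by construction, and the fit reduces exactly to
  `y* = b₀ + x·β`. At `n_latent = rank(X)` the coefficients coincide with
  the least-squares solution, a property the test suite checks against an
  independent NIPALS implementation and a direct solve.
* **PCR / PCLR** — PCA by SVD, then least squares (PCR) or unpenalised
  maximum-likelihood logistic regression on the component scores (PCLR; the
  Newton–Cholesky solver, i.e. iteratively reweighted least squares, with
  gradient tolerance 1e-8 and at most 100 iterations — which also degrades
  gracefully under perfect separation). Both reduce to a single linear form
  in feature space; PCLR outputs probabilities, clipped to
  (1e-12, 1 − 1e-12) to keep the open-interval contract under saturation.
* **SVM-Lin / SVM-RBF** — scikit-learn's SVC (hinge loss). ROC scores are
  the raw signed margins, never thresholded labels. The RBF kernel uses the
  standard convention `K = exp(-γ‖x−y‖²)`; a formulation that squares the
  product `γ‖x−y‖` instead merely reparameterises the grid as γ². SMO
  iterations are capped at 50 000: with a large C on inseparable data the
  solver can otherwise spend minutes chasing a negligible margin change.
* **RF** — 100 CART trees, √M candidate features per split, minimum two
  samples to split (ensemble settings pinned explicitly for
  reproducibility), Gini impurity, via scikit-learn. Tuned: maximum depth
  and the minimum *fraction* of training samples per leaf
  (`ceil(fraction · N)` samples). Scores are the fraction of trees voting
  positive.
* **ANN-LS / ANN-SS** — two-layer feed-forward networks written in numpy:
  a hidden layer of linear (LS) or logistic (SS) neurons and one logistic
  output neuron, trained by full-batch gradient descent on mean binary
  cross-entropy with momentum 0.5, learning-rate decay 0, and a fixed 400
  epochs. Weights initialise from a seeded uniform distribution scaled by
  1/√fan-in; biases start at zero. Full batch (rather than mini-batches)
  keeps the fixed-epoch budget meaningful at these sample sizes and makes
  training bit-for-bit reproducible. Setting `epochs = 0` through the fixed
  settings yields the untrained forward pass, which is used as a no-training
  baseline in tests. A single-linear-neuron LS network is an affine logit
  model, so with enough epochs its loss approaches the logistic-regression
  optimum — an equivalence the suite verifies.

Default search grids (all overridable): components/latent variables
1…min(20, rank); C on 7 log-spaced points 1e-2…1e4; γ on 7 points
1e-5…1e1; depth 1…10 with 8 leaf fractions 0.01…0.20; 1…10 neurons with 7
log-spaced learning rates 1e-3…1.

## The synthetic generator

Metabolomics tables carry strong inter-metabolite covariance: a few latent
biological factors drive many measured intensities. The generator draws
latent scores `T` (n × r), a loading matrix `W` (m × r) with standard-normal
entries, and emits strictly positive intensities
`X = exp(intensity_scale + T·Wᵀ + ε)` with `ε ~ N(0, feature_noise_sd²)` —
multiplicative log-normal noise on the intensity scale, matching the log10
preprocessing default. Class labels are assigned first with exact counts,
then latent scores are drawn conditional on class:

* **linear** — class means at ±`effect_size` on latent axis 1, unit
  within-class variance; population AUC = Φ(√2·effect_size) (≈ 0.998 at the
  default effect 2, a deliberately well-separated regime in which any
  capable family should succeed);
* **nonlinear_radial** — controls form a central Gaussian cloud, cases a
  shell at radius ≥ `effect_size`: radially, not linearly, separable;
* **nonlinear_xor** — the signs of T₁ and T₂ follow quadrant parity (cases
  in the same-sign quadrants), so no linear rule beats chance while kernel
  methods recover the structure.

Missing cells are inserted completely at random. The defaults
(n = 200, m = 100, balance 0.5, rank 2, effect 2.0, noise sd 0.1, no
missingness) emulate a clean, balanced, strongly structured cohort of the
size typical in the benchmarked studies (59–968 samples, 29–747 features).

What the generator does **not** emulate: batch and instrument drift, QC
samples, intensity-dependent missingness (available only as an explicit
extension), heavy-tailed or correlated noise, and — importantly — population
heterogeneity beyond the latent model. Tests passing on this generator show
the machinery behaves as designed on data satisfying its assumptions; they
do not certify performance on messier real tables.

## Canned studies and the sizes used

`metabench.studies` packages four simulation studies, each running the
genuine split → MC-CV → knee → evaluation pipeline with trimmed grids
(neighbourhoods of each family's defaults) so a study completes in minutes
on one CPU:

* *linear sufficiency* — PLS-DA, SVM-Lin, ANN-LS, SVM-RBF, ANN-SS on the
  linear scenario (n = 400, r = 2, effect 2.0): all five reach held-out
  AUC ≥ 0.9 with a spread ≤ 0.05 — projection into latent space makes this
  data linearly separable and the kernel adds nothing;
* *nonlinear detectability* — the same machinery detects constructed XOR
  structure: SVM-RBF and ANN-SS beat every linear family by ≥ 0.15 AUC;
* *interval width vs n* — on matched generators at n = 80 vs n = 800 the
  OOB AUC interval is strictly wider at the small n. This study runs at
  effect 1.0 (AUC ≈ 0.9, the regime of published classifiers) because at
  effect 2.0 every resample of the small cohort classifies perfectly and
  both intervals degenerate to zero width, leaving nothing to compare;
* *band containment* — whether the held-out test ROC lies inside the OOB
  95% band at every grid point.

The pytest suite runs the scenario studies over 5 seeds and the bootstrap
studies over 20 replicates at n_boot = 50; `scripts/acceptance.py` reports
the same quantities over 3 seeds / 10 replicates.

### A caveat on band containment

The OOB band is a *pointwise* 95% percentile band. Containment of the whole
test curve at all 101 grid points is a supremum event, whose probability for
a curve exchangeable with the OOB curves is well below 95%. On this
generator's homogeneous data — where models refit on resamples are nearly
identical and the band therefore reflects little more than evaluation noise
— measured full-path containment is roughly 10–70% depending on regime
(highest when m ≫ n inflates between-model variability), not ≥ 90%. On
heterogeneous real cohorts the between-model (Rashomon) component widens the
band and containment is the norm; reproducing that regime would require a
heterogeneity mechanism the generator intentionally does not have. The
corresponding acceptance test asserts the strict property and is expected to
fail on synthetic data; the containment *fraction* is reported honestly by
the acceptance script.

## Degenerate inputs and numerics

Single-class training labels, non-binary outcomes, broken Data/Peak
linkage, duplicate sample identifiers, and negative intensities are
rejected with specific errors. A class with fewer than two samples cannot
be split; a class smaller than k cannot be k-folded. Zero-variance features
drop with a warning; an all-constant matrix is an error. `R²` is undefined
for a constant outcome, AUC for a single-class vector. AUC ties count ½
(trapezoid over the tie-grouped curve equals the Mann–Whitney form to
1e-12, a property the suite checks exhaustively). Workbook round-trips are
cell-for-cell exact.

## Limitations

Binary outcomes only; no multi-class or survival endpoints. Hyperparameter
search is exhaustive over small grids, not nested: as in the benchmarked
workflow, the same training block selects hyperparameters and feeds the
bootstrap, so a small optimistic bias from that reuse is inherited by
design. Bootstrap intervals are percentile, not bias-corrected. The ANN
training schedule (fixed 400 full-batch epochs) is a faithful fixed setting,
not a convergence guarantee at extreme learning rates.
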