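# Methods

This note records the statistical model, the algorithmic and numerical
choices, the defaults, and the design of the simulation benchmarks.

## Componentwise likelihood-based boosting

### Cox family

Data: right-censored times $t_i = \min(T_i, C_i)$ with event indicators
$\delta_i$; mandatory covariates $z_i$ (clinical), optional covariates $x_i$
(molecular), fixed offset $o_i$. The linear predictor is
$\eta_i = z_i^\top \alpha + x_i^\top \gamma + o_i$ and the Breslow partial
log-likelihood (ties handled by Breslow's method) is the fitting criterion.

The algorithm starts at $\gamma = 0$. At each step it computes, for every
optional covariate $j$ on the standardized scale, the penalized
one-parameter Newton update $\hat\delta_j = U_j / (I_j + \lambda)$ from the
score $U_j$ and Fisher information $I_j$ at the current $\eta$, evaluates
the *unpenalized* partial log-likelihood after each candidate update, and
commits the single update with the largest resulting log-likelihood (ties
broken toward the lowest feature index). The mandatory block $\alpha$ is
refit by full unpenalized Newton (with step halving) after every step; the
offset is never re-estimated. Risk-set sums are computed as reverse
cumulative sums over time-sorted data with tie groups, so one step costs
$O(nq)$.

Internal standardization: optional covariates are centered and scaled by
the population standard deviation (`ddof=0`); mandatory covariates are
centered only. Reported coefficients are mapped back to the original
covariate scale. Constant optional columns are masked and can never be
selected. Partial-likelihood evaluations subtract the running maximum of
$\eta$ before exponentiating, so large offsets cannot overflow.

### Gaussian family

The same componentwise scheme for a continuous response (used by the
linking model): the candidate update is the penalized least-squares step
$\hat\delta_j = z_j^\top r / (z_j^\top z_j + \lambda)$ against the current
residual $r$, the selection criterion is the residual sum of squares, and
intercept plus mandatory block are refit by least squares after every step.
The refit uses a precomputed pseudoinverse; if the mandatory design is rank
deficient (possible on very small overlap samples, e.g. a binary clinical
covariate that is constant there), the fit is the minimum-norm least-squares
solution and a warning is emitted rather than an error, so downstream
pipelines keep running in degenerate resamples.

### Tuning

The number of boosting steps is the main tuning parameter, chosen by k-fold
cross-validation (default 10 folds, stratified by event status for Cox;
fold assignment is a deterministic function of the seed). The Cox CV score
for a fold is the difference `pl(all samples) − pl(training samples)` under
the fold's fit, summed over folds — a held-out partial-likelihood
contribution that needs no per-fold risk-set surgery. The Gaussian score is
mean held-out squared error. Ties are broken toward the smaller step.

The ridge-type penalty matters little as long as it is large enough; the
defaults make each accepted update shrink its one-parameter estimate by a
factor of about 0.1: $\lambda = 9 \cdot (\text{number of events})$ for Cox
and $\lambda = 9n$ for the Gaussian family (optional covariates have unit
variance internally, so $z^\top z = n$). A penalty of zero is allowed and
turns the single-covariate Gaussian case into ordinary least squares in one
step — a convenient analytic check.

## The sequential strategy

* The **signature** passed from the first level to the second is the
  molecular part $x^\top \hat\gamma$ of the first-level linear predictor at
  the cross-validated step, *excluding* the clinical contribution. Clinical
  covariates are present, unpenalized, in every downstream model, so their
  effects are re-estimated there; including them in the offset would fix
  their coefficients at the first-level estimates. The switch
  `offset_includes_clinical=True` restores the full-linear-predictor
  variant.
* The **linking model** regresses the observed signature on clinical
  (mandatory) plus second-layer (optional) covariates over the overlap
  samples; its predictions impute the signature for second-layer samples
  without first-layer measurements. Fewer than 2 overlap samples is an
  error; fewer than 10 a warning.
* The **second-level model** receives the signature as a fixed offset. The
  **reference** model is the identical fit with zero offset; with a zero
  signature the two coincide exactly (an invariant under test).
* Each stage draws an independent sub-seed from the run seed
  (`SeedSequence(seed)`, positions 0–3), so fold assignments in one stage
  do not influence another. All derived seeds are reduced modulo $2^{31}$.
* `order="B_then_A"` swaps the layer roles before fitting.

## Evaluation

* **Brier curves.** $\mathrm{BS}(t) = n^{-1} \sum_i W_i(t)\,
  (\mathbb{1}(t_i > t) - \hat S(t\mid x_i))^2$ with IPCW weights
  $W_i(t) = \delta_i \mathbb{1}(t_i \le t)/\hat G(t_i^-) +
  \mathbb{1}(t_i > t)/\hat G(t)$, where $\hat G$ is the Kaplan–Meier
  estimate of censoring (reverse KM, left limits at event times).
  Predicted survival comes from the Breslow baseline hazard of the fitted
  model, extrapolated as constant beyond the last training event.
* **.632+ estimator.** With apparent error $\bar e$, bootstrap out-of-bag
  error $\hat e$ (Efron's leave-one-out form) and no-information error
  $\hat\gamma$ (every prediction paired with every outcome, computed from
  the moments of the apparent predictions), the relative overfitting rate is
  $R = (\hat e - \bar e)/(\hat\gamma - \bar e)$ clipped to $[0,1]$, the
  weight $w = .632/(1 - .368R)$, and the estimate
  $(1-w)\bar e + w\hat e$. The whole model-building pipeline (CV included)
  is retrained in every bootstrap draw; event-less draws are redrawn. The
  four approaches (sequential, reference, clinical Cox, Kaplan–Meier) share
  bootstrap draws, so comparisons are paired. A per-draw integrated .632+
  value supports variability displays.
* **Integrated error**: trapezoidal integral of the curve over
  $[0, t_{\max}]$ divided by $t_{\max}$, with left-constant extension.
* **Inclusion frequencies**: selection proportions over $B$ subsamples of
  size $\lfloor 0.632\,n\rfloor$ drawn *without* replacement from the
  second-level samples (first-layer-only samples always retained so the
  first-level model keeps its sample base), re-running the entire procedure
  per subsample.

## Preprocessing

* SNP dummy coding: genotype 0 → (0, 1), 1 → (1, 0), 2 → (1, 1) into
  `.d`/`.r` indicator columns — note 0 maps to (0, 1), following the coding
  convention stated with the method.
* Methylation M-values: $\log_2(\beta/(1-\beta))$ with clamping to
  $[10^{-6}, 1-10^{-6}]$.
* Count normalization: median-of-ratios size factors over features positive
  in every sample, then $\log(x+1)$.

## Synthetic cohort generator

Effects are specified on the standardized feature scale (log hazard ratios
per SD). A subset of layer-B features are noisy linear images of the true
layer-A features, $B_j = \rho A^{std}_j + \sqrt{1-\rho^2}\,\varepsilon$, so
layer B carries proxy information that a linking model can exploit. Event
times are proportional-hazards exponential (or Weibull); the censoring
hazard is calibrated by bisection so the *expected* censoring fraction
given the realized event times hits the target. Sample availability masks
are deterministic blocks: overlap first, then layer-A-only, then
layer-B-only. Each component (clinical, layer A, layer B, survival,
censoring) uses an independent sub-stream of the seed.

## Benchmark study designs

All problem sizes are this package's own desk-scale choices: they preserve
the qualitative structure of large two-platform cohorts while keeping each
benchmark within minutes on one CPU.

* **Recovery** (`recovery_benchmark`): n = 300 samples, 200 Gaussian
  layer-A features, 5 true effects of 0.8; B = 50 subsamples of size
  $\lfloor 0.632 n\rfloor$; reported quantity: fraction of true features
  with inclusion frequency ≥ 0.5.
* **Ordering** (`ordering_benchmark`): 20 replicates of an informative
  design (n = 160, 50% overlap, 3 clinical covariates with effect 0.7, 4
  layer-A effects of 0.7 at linkage 0.9, 3 layer-B effects of 0.5, 30%
  censoring), chosen to emulate a setting where established clinical
  predictors are clearly prognostic and both molecular layers add
  complementary information. Reported: median integrated .632+ error per
  approach (10 bootstrap draws per replicate, paired).
* **Overlap** (`overlap_benchmark`): per replicate, one training cohort
  (100 first-layer-only samples + 100 fully overlapping second-level
  samples) whose second-level first-layer availability is thinned to
  {100%, 50%, 15%, 5%}, and one independent 300-sample test cohort
  evaluated as second-layer-only (signature always imputed). The second
  layer is wider here (120 candidate features) so linking-model quality
  depends materially on the overlap size. Reported: median integrated test
  Brier score at full overlap and the median *paired excess* of each
  reduced fraction over full overlap across 40 replicates. The paired
  excess is the right summary because between two already-degraded settings
  (15 vs 5 overlap samples) the error saturates near the no-signature level
  and adjacent comparisons are dominated by noise, while "never better than
  full overlap" is the substantive claim.

  Observed behavior at this scale: thinning the overlap to 15% or 5%
  degrades test error clearly (median paired excess ≈ +0.006 and +0.003 at
  the default seed), but halving it from 100 to 50 samples does not — the
  measured excess is flat to slightly negative (≈ −0.0005, within
  resampling noise). Two effects explain the flat first arm: a 50-sample
  overlap is already enough to learn this linking model, and at full
  overlap the second-level model trains with *observed* signatures but is
  deployed with *imputed* (shrunken) ones, a train/deploy mismatch that
  partially offsets the benefit of more overlap. The corresponding
  acceptance test asserts non-improvement for every reduced fraction and
  currently fails on the 100%→50% arm; it is left failing deliberately
  rather than weakening the check, since the flatness is a property of this
  desk-scale design rather than of the implementation.

## Known limitations

* The generator produces linearly linked layers and proportional-hazards
  outcomes only; no non-linear effects, no competing risks.
* Breslow tie handling only (no Efron option).
* The .632+ no-information error uses the moment form, which assumes the
  squared-error loss used here.
* Full-scale genome-wide feature counts (hundreds of thousands of features)
  are supported by the algorithmic complexity ($O(nq)$ per step) but not
  exercised by the shipped benchmarks.
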