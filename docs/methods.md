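# Methods

## The one-by-one normalization model

RMA treats an observed probe intensity as `O = S + B` with signal
`S ~ Exp(mean β)` and optical background `B ~ N(μ, σ²)`.  Background
correction replaces `O = o` by the posterior mean of `S`, which for this
convolution is the mean of a normal `N(a, σ²)` truncated to `(0, ∞)` with
`a = o − μ − σ²/β`:

    E[S | o] = a + σ · φ(a/σ) / Φ(a/σ).

The implementation evaluates `φ/Φ` through log densities
(`scipy.special.log_ndtr`), so the result is strictly positive and strictly
increasing in `o` for any parameters, without underflow even when
`a/σ < −30`.

**Parameter estimation.**  `(μ, σ, β)` are estimated per array by maximum
likelihood on the convolution density, maximized over `(μ, log σ, log β)`
with Nelder–Mead from a method-of-moments start (the exponential component
carries all the skewness: `skew = 2β³/var^{3/2}`).  A mode-based shortcut
(background mean = intensity density mode) was rejected after analysis: the
mode of the convolution sits at `μ + σ²/β + σ·z*` where `φ(z*)/Φ(z*) = σ/β`
— about `μ + 1.9σ` in the default regime — so mode-based `μ` and `σ` are
inconsistent whatever the bandwidth.  The MLE recovers all three parameters
within ~3% on 100k draws from the exact model.  Fitting one 22k-probe array
takes ~0.15 s.

**Cohort mode.**  Background correction (per-array parameters) → quantile
normalization (each column's sorted values replaced by the across-sample
mean of sorted columns; ties within a column receive the mean of the target
entries their tied ranks span) → log2 → median-polish summarization per
probe-set (expression of sample *j* = overall + column effect *j*).

**Median polish.**  Row sweeps first, then column sweeps, re-centering the
effect medians into the overall term each cycle; convergence when the
largest absolute row/column median of the residuals is ≤ `tol = 1e-6`.  The
default iteration cap is 100: on random 11×30 Gaussian matrices ~80% of
cases converge within 20 sweeps but a few need up to ~100, and a tight
residual-median guarantee is worth the extra sweeps (each is trivially
cheap).  Non-convergence is reported through a flag, never silently.  The
decomposition reconstructs the input exactly by construction, and row and
column effects have median zero.

**Single-array mode.**  The archive freezes: the quantile vector (per-rank
mean of sorted background-corrected reference columns), per-probe effects
(median-polish row effects of the quantile-normalized reference, per
probe-set block), and per-probe-set medians/SDs of the reference's
cohort-RMA expressions.  A new array is background-corrected with its own
MLE parameters, rank-mapped onto the quantile vector (same tie rule as
cohort mode), log2-transformed, summarized as the per-probe-set median of
(probe − probe effect) — the mean-of-middle-two convention for even probe
counts — and centered by the archive medians.  Re-normalizing the reference
arrays against their own archive reproduces their cohort-RMA expressions at
r ≥ 0.99 per sample.

## Classification

Elastic-net logistic (dichotomous / tertile models) or multinomial
(multiclass models) regression in glmnet parameterization: minimize
`(1/n)Σ loss + λ[α‖β‖₁ + (1−α)/2‖β‖₂²]` with an unpenalized intercept.
Fits are delegated to scikit-learn's saga solver with `C = 1/(nλ)` and
`l1_ratio = α`, warm-started along a descending λ path; because saga's
stopping rule can quit with the intercept far from its optimum when every
coefficient is pinned at zero, the intercept is re-solved exactly by Newton
iteration (coefficients fixed) after every fit.  Training data are centered
by their own per-probe-set medians once, before cross-validation; the
per-probe-set SDs of the training cohort are stored in the model.

`(α, λ)` are chosen on a grid by stratified, seeded 10-fold CV minimizing
the per-observation deviance (−2 × mean held-out log-likelihood, pooled
over folds; probabilities clipped at 1e-6).  Deviance ties break toward the
sparser model (larger λ, then larger α).  `TrainingConfig` defaults to the
full published protocol for this classifier family — α from 0.1 to 1 in
steps of 0.025, log λ from −10 to 2 in steps of 0.06 — which is expensive
(~7.5k grid points × folds); the synthetic validation studies pass coarse
grids (3 α × 7 log λ) because their injected signals are strong and the
optimum plateau is wide.

**Prediction.**  A profile must be centered and SD-rescaled before
prediction.  Rescaling multiplies each probe-set by
`training SD / reference SD` so that data normalized against any reference
are on the training scale; when the supplied reference *is* the model's
training cohort the profile is used directly (`reference_is_training`).
A zero reference SD for a model probe-set makes the archive unusable for
that model and is an error.

**Calling.**  Dichotomous: positive class above 0.9, negative below 0.1,
otherwise unclassified (boundaries unclassified — strict inequalities).
Multiclass: argmax class if its probability strictly exceeds 0.5.
Tertile (drug resistance): cohort 33rd/66th percentiles (linear
interpolation) with ≤/≥ comparisons; when the two percentiles coincide
(e.g. all probabilities equal) conflicted samples are called intermediate,
since the cohort carries no evidence to separate them.  The internal
convention is probability of **resistance**: the low tertile is sensitive.
Graham's formula combines per-drug resistance probabilities under
conditional independence and uniform priors; omitting a drug drops its
term, and the 0/0 form (one probability exactly 1, another exactly 0) is
rejected as contradictory certainty.

## Quality control

RLE(probe-set) = expression − reference median; for a centered profile the
values already are the RLE vector, and `compute_rle` refuses a redundant
medians argument to prevent double subtraction.  The report carries the RLE
median and IQR (75th − 25th percentile, linear interpolation over all
probe-sets); a sample fails if IQR strictly exceeds the threshold
(default 0.6, exposed as a parameter).

## Agreement statistics

Unclassified/intermediate is a class of its own: only the diagonal of the
confusion matrix counts as agreement.  Accuracy gets an exact
Clopper–Pearson CI (statsmodels `proportion_confint(method="beta")`).
Weighted κ uses disagreement weights 0 (diagonal), ½ (row or column is the
middle label), 1 (otherwise); `κ_w = 1 − Σw·O / Σw·E` with `E` from the
marginal products, and the large-sample SE of Fleiss, Cohen & Everitt for
the 95% CI (upper bound clipped at 1).  Pearson correlation is computed on
logit probabilities clipped to `[1e-6, 1−1e-6]`, with the Fisher-z interval
`tanh(z ± 1.96/√(n−3))`.  The total least squares line runs along the
principal axis of the centered scatter (orthogonal-distance minimizer),
oriented with positive x-component; a vertical axis is an error.

## The synthetic generator

`SimConfig` emulates one chip lot: per probe-set a linear-scale baseline
`~ Exp(1)` scaled by `signal_mean` (log2 baselines therefore reproduce the
exponential marginal the background model assumes); informative probe-set
*k* adds `class_effect` (log2) to class `k mod K`, so each class owns an
equal share of markers; per-sample biological noise `N(0, noise_sd)`; fixed
per-probe affinities `N(·, probe_affinity_sd²)` on log2; a per-probe batch
shift shared within a laboratory (multiplicative on the linear scale); and
observed intensity = linear signal + `N(background_mu, background_sigma)`,
truncated positive.  Lognormal factors are mean-corrected
(`−s²·ln2/2`) so the linear-scale signal mean stays at `signal_mean`.
Class labels are assigned in exact stated proportions (largest-remainder
rounding, randomly ordered): cohorts in this field are assembled with fixed
group sizes, and exact proportions keep the class mix of a reference subset
comparable to other cohorts — important because the medians of strongly
bimodal marker genes depend on the class mix (see Limitations).

Defaults: 11 probes/probe-set (the U133 Plus 2.0 convention), background
`N(100, 15)` under signal mean 200 (a typical scanned-array regime),
probe-affinity SD 1.0 log2 (real affinities span orders of magnitude),
biological noise 0.2 log2 (clean arrays then sit well below the 0.6 RLE IQR
cutoff, as good-quality real arrays do), class effect 1.5 log2 on 50
informative probe-sets of 500, two balanced classes.  With affinity and
noise spread switched off the marginal intensity distribution is *exactly*
exponential + normal and the background MLE recovers all parameters within
10%; with the default affinity spread the signal is a lognormal mixture of
exponentials, whose extra low-intensity mass the fitted background SD
partly absorbs (σ̂ low by ~25%) while μ and the signal mean stay within
~10% — i.e. the generator is deliberately a little harder than the model.

`simulate_two_lab_study` splits one lot into a reference cohort, same-lab
held-out arrays and batch-shifted held-out arrays.
`simulate_batch_shift_sweep` renders one held-out set under several shift
magnitudes from identical draws (one unit shift vector, scaled), giving
paired QC comparisons free of between-level simulation noise.

What the generator does **not** emulate: FFPE degradation, spatial
artifacts, mismatch probes, cross-hybridization, multimodal continuous
class gradients.  Passing tests therefore show the pipeline's internal
consistency and its qualitative batch-shift behaviour, not clinical-grade
performance on real cohorts.

## Validation studies and problem sizes

`refrma.studies` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`):

* **one_by_one_agreement_study** — 2,000 probe-sets × 11 probes, 30
  reference + 30 held-out + 30 shifted arrays.  Matched reference: per-
  sample r vs cohort RMA ≥ 0.995 for every sample; batch-shifted reference
  (SD 0.8 log2): median r drops to ~0.98.
* **classifier_recovery_study** — 300 probe-sets, 120 training / 40 test
  samples, effect 1.5 on 50 probe-sets → held-out accuracy ~1.0; the null
  (effect 0, 100 test samples) stays at chance.
* **call_agreement_study** — 30 reference + 120 validation arrays; weighted
  κ between cohort-route and one-by-one-route calls.
* **qc_shift_study** — paired sweep over shift SD {0, 0.2, 0.4, 0.8}; the
  median RLE IQR rises monotonically and ≥ 95% of clean samples pass
  at 0.6.

These sizes are an order of magnitude below a real chip (54k probe-sets)
— the pipeline is linear in probes, and the studies' statistical properties
are already stable at this scale.

## Known limitations

* Centering by reference medians assumes the reference's class composition
  matches the classifier's training cohort.  For sharply bimodal marker
  genes the median jumps between class modes with small composition
  changes; combined with a near-unpenalized (separable-data) fit this can
  shift logits substantially.  In practice: build references with a known,
  balanced composition, prefer stronger shrinkage, and watch the RLE IQR.
* The background MLE assumes a single exponential signal scale; arrays with
  extreme bimodal signal may fit β between the modes.
* The tertile caller is cohort-relative by definition and cannot be applied
  to a single sample in isolation.
* κ and accuracy CIs are large-sample / exact-binomial respectively; the
  original publications of such protocols do not name their CI procedures,
  and numerical identity with them is not claimed.
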