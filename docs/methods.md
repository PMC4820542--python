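# Methods

`uncstress` simulates and analyses an aversive probabilistic learning
experiment in which acute stress is driven by the learner's own uncertainty.
This note documents the models, the synthetic-data generator, the numerical
choices, and what the package's tests do and do not establish.

## The task

A session is 320 trials split into 10 contiguous blocks of 26–38 trials.
Within a block, one of two stimuli (A/B) appears per trial (i.i.d. uniform)
and the aversive outcome ("snake", coupled to shock) follows the shown
stimulus with a fixed block contingency; contingencies are reciprocal,
p(snake|B) = 1 − p(snake|A). The block levels are 90/10 (×4, two per
direction), 70/30 (×4) and 50/50 (×2). Block order is a seeded permutation
constrained so that no two consecutive blocks share a contingency — without
the constraint identical neighbours would merge into one long block and the
session would not contain ten distinguishable regimes. Subjective stress is probed 65
times per session at gaps of 4–6 trials; gaps are drawn uniformly from
{4, 5, 6} and then shrunk minimally (seeded) until the last prompt fits the
session. Per-trial event timings (stimulus 300±50 ms, decision window
1000±200 ms, prediction display 1200±200 ms, outcome 1000±200 ms, ITI
2000±500 ms) are jittered uniformly; self-paced breaks are placed every
~10 min of task time.

## Learning models

All filters expose the same first-level quantities per trial k: the
pre-outcome prediction μ̂₁(k) = p(snake | shown stimulus), its Bernoulli
variance σ̂₁ = μ̂₁(1−μ̂₁) ("irreducible uncertainty", maximal 0.25 at
μ̂₁ = 0.5), and the outcome prediction error δ₁ = u − μ̂₁.

**3-level binary HGF.** Beliefs about the stimulus–outcome tendency live on
the log-odds scale (level 2, mean μ₂, variance σ₂ = "estimation
uncertainty") and about its volatility at level 3 (μ₃, σ₃ = "volatility
uncertainty"). Updates are precision-weighted prediction errors:

    μ̂₁ = s(μ₂);  δ₁ = u − μ̂₁
    σ̂₂ = σ₂ + exp(κμ₃ + ω)
    π₂ = 1/σ̂₂ + μ̂₁(1−μ̂₁);  σ₂ ← 1/π₂;  μ₂ ← μ₂ + σ₂ δ₁
    w₂ = exp(κμ₃ + ω)/σ̂₂;  δ₂ = (σ₂ + Δμ₂²)/σ̂₂ − 1
    π₃ = 1/(σ₃ + ϑ) + (κ²/2) w₂ (w₂ + (2w₂ − 1) δ₂)
    σ₃ ← 1/π₃;  μ₃ ← μ₃ + (κ/2) σ₃ w₂ δ₂

κ is fixed at 1 so exactly two perceptual parameters are free: ω (constant
log-volatility at level 2; baseline update speed) and ϑ ∈ (0, 1)
(metavolatility; step size of the volatility level). Initial moments default
to μ₂⁽⁰⁾ = 0, σ₂⁽⁰⁾ = 1, μ₃⁽⁰⁾ = 1, σ₃⁽⁰⁾ = 1. The recursion is declared
invalid (and the parameter set given evidence −∞ during fitting) if π₃ ≤ 0,
any moment becomes non-finite, or log-scale quantities exceed float range.
The filter runs on the stimulus-A belief axis (reciprocity makes one belief
sufficient) and is then projected onto the shown stimulus, so μ̂₁/σ̂₁/δ₁ are
comparable across models; σ̂₁ and the higher-level moments are invariant
under this flip.

**Rescorla–Wagner.** v ← v + α(u − v) on the probability scale of the shown
cue, with reciprocal coupling. Two variants probe the task's symmetry
assumptions: `independent_cues` keeps separate beliefs per stimulus;
`dual_alpha` selects α_shock or α_noshock by the trial's outcome.

**Sutton K1.** A fixed-structure meta-learning rule: δ = u − v;
β ← β + μ_gain δ h; α = min(1, e^β); v ← v + αδ; h ← (h + αδ) max(0, 1 − α).
Only μ_gain is fitted; β₀ = log 0.2, h₀ = 0.

**Observation model.** Unit-square sigmoid,
P(predict snake) = μ̂₁^ζ / (μ̂₁^ζ + (1−μ̂₁)^ζ), with ζ fixed at 1
(probability matching) by default and optionally estimable. Missed choices
contribute no likelihood, but outcomes still update beliefs.

**Fitting.** MAP estimation in an unconstrained space (ω native; ϑ via
logit with upper bound 1; α via logit; μ_gain via log) with Gaussian priors
ω ~ N(−3, 4²), logit ϑ ~ N(−2, 2²), logit α ~ N(0, 2²),
log μ_gain ~ N(−4, 2²). Optimisation is seeded multi-start BFGS (default 3–5
starts sampled from the priors) with a Nelder–Mead fallback. Log model
evidence is the Laplace approximation, log p(y) ≈ log p(y, θ̂) +
(d/2) log 2π − ½ log |H|, with H the central finite-difference Hessian
(step 10⁻³) of the negative log joint at the MAP; a non-positive-definite
Hessian flags the fit as non-converged and falls back to the
prior-curvature penalty. MAP+Laplace is this package's approximation of
choice for variational model evidence: on a conjugate-Gaussian toy problem
it is exact (tested to 10⁻⁶), and model recovery on synthetic cohorts is
clean in both directions (HGF data select HGF; RW data select RW).

## Random-effects model selection

Group-level BMS treats each subject's best model as a latent draw from a
population distribution with Dirichlet(α₀ = 1) prior. The variational
iteration updates responsibilities g_nk ∝ exp(log-evidence_nk + ψ(α_k) −
ψ(Σα)) and counts α_k = α₀ + Σ_n g_nk to convergence (tol 10⁻⁸ on α).
Exceedance probabilities use 10⁶ seeded Dirichlet draws (exact Beta-CDF
integral for two models). Against an exact Gibbs sampler of the same
hierarchical model the variational posterior is mildly overconfident
(exceedance within ~0.05–0.1 on small cohorts); this matches the behaviour
of the standard implementations of this algorithm.

## Stress-rating models

Ratings are z-scored per subject before analysis (between-subject scale use
is arbitrary). Four regressions predict rating k = 2..65 from an intercept,
the previous rating, the number of shocks since the previous rating, and one
model-specific term: summed |δ₁| since the last rating (surprise), or
σ̂₁ / σ₂ / σ₃ at the rating trial i(k). This package's conventions for the
genuinely open design points: the shock/surprise window is the half-open interval
(i(k−1), i(k)] — the rating trial itself counts; σ̂₁ is the pre-outcome value
at i(k) while σ₂ and σ₃ are post-update values; the first rating is dropped
rather than imputing a lag. An optional `combined` design carries all three
uncertainties. Fits are OLS; BIC = (p+1)·ln n − 2·log L̂ with the Gaussian
MLE likelihood (the residual variance counts as a parameter; the constant
cancels in comparisons). BMS over rating models uses evidence = −BIC/2. An
`objective` design variant replaces σ̂₁ with p(1−p) from the true block
contingency of the shown stimulus.

## Physiology

**Response functions.** Pupil: h(t) = tⁿ exp(−n t / t_max), which peaks
exactly at t_max; canonical constants n = 10.1, t_max = 930 ms. Luminance
constrictions use the same family with faster dynamics (population average
n = 3.6, t_max = 839 ms), fitted per subject from passive-viewing traces by
bounded least squares (amplitude profiled out analytically; seeded
multistart). SCR: a gamma density smoothed with a Gaussian; the
defaults (shape 3.0745, scale 1.5 s, smoothing sd 0.3 s) were chosen once to
place the kernel peak in the physiological 2–6 s window, and all are
configurable — no specific published constant set is claimed. All kernels are peak-normalized.

**Preprocessing.** Pupil: downsample to 100 Hz → zero-phase 3rd-order
Butterworth low-pass at 4 Hz → linear interpolation across blink gaps
extended 140 ms either side → linear detrend → z-score. SCR: 1st-order 5 Hz
low-pass applied at the raw rate (filtering after downsampling to 10 Hz
would put the cutoff at Nyquist) → downsample to 10 Hz → mask samples whose
absolute second difference exceeds 10 MADs (non-physiological rate of
change; the threshold constant is this package's choice)
→ mask the first five trials after each break → detrend → z-score on
unmasked samples. Detrending precedes z-scoring so the output has unit
variance exactly. A recording with >50% masked samples raises a quality
error, mirroring subject rejection.

**Convolution GLM.** Delta regressors at stimulus, outcome, shock and
rating-prompt onsets; a parametric delta at outcome scaled by |δ₁|; a boxcar
across each trial scaled by σ̂₁ — all convolved with the canonical kernel.
Event regressors get first/second-derivative columns (central differences,
peak-normalized) orthogonalized to their primary after z-scoring and
rescaled to unit variance, so shared variance is apportioned to the primary.
Pupil designs add a luminance-kernel column at image onsets (negative:
constriction). Degenerate columns (zero prediction errors, constant σ̂₁) are
dropped with a warning. Fitting is iteratively reweighted least squares with
a Tukey bisquare weight (tuning 4.685, MAD scale), excluding masked samples.

**Epochs and tuning.** Outcome-locked epochs span −2 to +6 s (2 s of
pre-outcome context; the endpoint is this package's choice). Median splits
on σ̂₁ and |δ₁| (ties to the low bin) give a 2×2 per-subject cell table for
the repeated-measures ANOVA, which for a 2×2 within design is computed
exactly from per-subject contrasts (F(1, n−1) = t²; partial η² reported).
Baseline arousal is the mean signal in the 500 ms before stimulus onset
(the window length is this package's choice of "trial start"). Tuning curves bin trials by μ̂₁
into 9 equal-width bins (empty bins merge into their neighbour) and fit
a·E[p(1−p)]+c to the bin means, where the predictor is the within-bin mean
of p(1−p) — aggregating predictor and response identically makes the
noiseless case exact. The same machinery serves response times.

## Cortisol

Panels are subjects × 8 samples (nmol/l): two separate-day baselines,
arrival, pre-task, 10/20/30 min into task, post-task. Analysis is on natural
logs; subjects whose mean separate-day baseline exceeds the population
baseline mean by 3 s.d. (computed on raw concentrations) are excluded. The
omnibus test is Skillings–Mack: within-subject ranks of observed cells,
centred and weighted by √(12/(k_i+1)), with the pairwise co-occurrence
covariance (Σ_jj = Σ(k_i − 1) over subjects observing j; Σ_jj' = −#subjects
observing both) and a Moore–Penrose inverse; T is referred to χ² with t−1
df. On complete panels T equals the Friedman statistic exactly (tested
against an independent ranking oracle). Follow-up contrasts use the paired
Wilcoxon signed-rank test with normal approximation, tie correction and
discarded zero differences — the appropriate form for within-subject
contrasts on the same panel.

## The synthetic cohort

The generator's defaults describe a realistic 45-subject cohort for this
paradigm: ω ~ N(−3, 1²) and logit ϑ ~ N(−2, 0.7²) across subjects
(parameter sets whose filter diverges on a subject's outcome sequence are
redrawn); ζ = 1. Rating coefficients centre on group means typical of this
kind of cohort (previous rating 0.25,
shocks 0.074, irreducible uncertainty 0.099) with between-subject spread and
rating noise sd 0.25; physiological uncertainty sensitivities centre on 0.11
(pupil) and 0.044 (SCR). A shared latent factor contributes to the
subjective and physiological uncertainty sensitivities so the two are
positively coupled across subjects (coupling 0 makes them independent).
Response times are affine in σ̂₁ (400 ms + 800 ms·σ̂₁ + N(0, 100 ms)),
truncated at the decision window; ~2% of trials are additionally missed at
random. Physiological traces are the convolution GLM run forward plus linear
drift and Gaussian noise, with seeded blink dropouts (annotated) for pupil
and movement artifacts around breaks for SCR. Cortisol is log-normal
(baseline 6.9 nmol/l, between-subject sd 0.4 and within-subject sd 0.25 on
the log scale) with a +0.5 log-unit elevation at the 20-min-into-task sample
and 17.5% of cells missing (28 of a 20×8 panel). PSS questionnaire scores
are generated by a Gaussian copula whose latent correlation 2·sin(πρ/6)
yields a population Spearman correlation of ρ = 0.39 with ϑ, then
discretized to 0–40.

What the generator does **not** emulate: pharmacokinetic cortisol dynamics
(a single elevated sample stands in for the response curve), gaze position
and other pupil nuisance sources beyond luminance and blinks, non-Gaussian
physiological noise spectra, learning or fatigue drifts in the rating scale,
and any systematic relationship between learning parameters and stress
sensitivity beyond those stated. Passing recovery tests therefore shows the
estimators are correct and calibrated under the stated generative
assumptions — not that real recordings meet those assumptions.

## Recovery and calibration designs

Model- and parameter-recovery tests use effect sizes chosen for
identifiability (e.g. an uncertainty coefficient of 1.5 with noise sd 0.15
for the stress-model recovery): they test the machinery, not the population
effect size, which at the default magnitudes is deliberately weak relative
to rating noise. Calibration tests run 1000–2000 null replicates per
statistic. Cohort-scale tests run 20–45 subjects and the pipeline smoke
tests 3–4 subjects with short sessions for physiology; these sizes are the
package's test-design choices.

## Known limitations

- MAP+Laplace evidence is an approximation to full variational inference;
  its mild overconfidence is inherited by BMS exceedance probabilities.
- The SCR canonical kernel constants are plausible defaults constrained
  only by the peak-latency property, not an empirically fitted set.
- The Skillings–Mack implementation uses average ranks for ties without a
  tie-corrected covariance; with continuous data (and log-cortisol) ties
  have measure zero.
- `sensitivity_coupling` reports uncorrected correlations; users needing
  family-wise control should apply their own correction.
- The 2×2 ANOVA is exact only for the 2×2 within-subject design; it does not
  generalize to more levels.
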