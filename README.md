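# uncstress

Simulation and analysis of **uncertainty-driven acute stress** in aversive
probabilistic learning.

In the underlying experimental paradigm, participants predict which of two
outcomes follows a visual cue across 320 trials while the cue→outcome
contingency drifts between blocks (90/10, 70/30, 50/50, reciprocal across
cues); the aversive outcome is coupled to an electric shock. Acute stress is
measured concurrently through subjective ratings (65 per session), pupil
diameter, skin conductance and salivary cortisol. The scientific question is
*which computational quantity of learning drives stress* — and the answer
this pipeline operationalises is the learner's **irreducible uncertainty**:
the Bernoulli variance σ̂₁ = μ̂₁(1−μ̂₁) of their own trial-by-trial outcome
prediction μ̂₁.

The package is for computational-psychiatry and affective-science
researchers who want a tested, fully synthetic re-implementation of this
analysis chain — no participant data are required; a seeded generator
produces cohorts with the statistical structure the analysis assumes.

## What's inside

| Module (`uncstress.`) | Contents |
| --- | --- |
| `task`, `cohort` | Task-session generator; synthetic subjects (HGF agents, ratings, physiology, cortisol, PSS) |
| `learning` | 3-level binary Hierarchical Gaussian Filter, Rescorla–Wagner (+independent-cue and dual-learning-rate variants), Sutton K1; unit-square-sigmoid choice likelihood; MAP fitting with Laplace model evidence |
| `bms` | Random-effects Bayesian model selection (Dirichlet variational scheme, exceedance probabilities) |
| `stress` | The four competing regressions of z-scored stress ratings (surprise / irreducible / estimation / volatility) with BIC + BMS |
| `physio` | Canonical pupil & SCR response functions, preprocessing, convolution GLM with robust (bisquare IRLS) fitting, outcome-locked median-split epochs, inverted-U tuning curves |
| `endocrine` | Cortisol panel preparation, Skillings–Mack test for repeated measures with missing cells, paired Wilcoxon |
| `groupstats` | Correlations with a KS normality gate, 2×2 repeated-measures ANOVA, RT tuning, sensitivity-coupling report |
| `pipeline`, `cli` | Stage orchestration (`uncstress run-all`, `simulate`, `fit-learning`, `bms`, `stress`, `physio`, `cortisol`, `group`, `validate`) |

The numbered scripts under `analysis/` are thin narrative drivers over the
library, writing their tables under `results/`. The model maths and design
choices are documented in [`docs/methods.md`](docs/methods.md).

## The core model

The 3-level binary HGF tracks beliefs at three levels — the outcome
tendency on the log-odds scale (μ₂, σ₂), and its volatility (μ₃, σ₃) — with
precision-weighted prediction-error updates; two free parameters per
subject: ω (baseline update speed) and ϑ (metavolatility). The three
variances map onto three species of uncertainty: **irreducible** σ̂₁ =
μ̂₁(1−μ̂₁), **estimation** σ₂, **volatility** σ₃. Stress ratings at prompt
k are then modelled as

    Stress(k) = β₀ + β₁·Stress(k−1) + β₂·#shocks(i(k−1), i(k)] + β₃·σ̂₁(i(k)) + ε

against alternatives that replace the σ̂₁ term with summed |δ₁| (surprise),
σ₂ or σ₃; physiological signals are modelled with the same regressors
convolved with canonical response functions (pupil kernel
h(t) = tⁿ e^(−nt/t_max), n = 10.1, t_max = 930 ms).

## Worked example

Fit the three learning models to a default 45-subject synthetic cohort and
select among them:

```bash
python analysis/03_select_learning_model.py --seed 1 --subjects 45 --out results/analysis
```

```
        rw: frequency 0.04, exceedance 0.000
 sutton_k1: frequency 0.29, exceedance 0.003
       hgf: frequency 0.67, exceedance 0.997

selected model: hgf
```

The cohort was generated by HGF agents, and random-effects BMS recovers
that: the HGF is the most frequent model in the population (expected
frequency 0.67) and is almost certainly the most frequent (exceedance
0.997). Next, the stress-rating model comparison:

```bash
python analysis/04_model_subjective_stress.py --seed 1 --subjects 45 --out results/analysis
```

```
    surprise: frequency 0.17, exceedance 0.001
 irreducible: frequency 0.52, exceedance 0.997
  estimation: frequency 0.15, exceedance 0.000
  volatility: frequency 0.17, exceedance 0.001

selected stress model: irreducible
```

Ratings were generated from the lag + shocks + irreducible-uncertainty
model, and BIC + BMS identify it against the three alternatives. The
cortisol driver prints the omnibus and follow-up tests
(`Skillings-Mack T7 = 33.15, p = 0.0000`, 1 baseline outlier excluded;
`baseline vs 20 min into task: Wilcoxon Z = 3.30, p = 0.0010` for the same
seed) — the generator places its stressor-evoked elevation at the sample
taken 20 min into the task, and the rank tests localize it there.

Run everything (including the slower physiology stage) with:

```bash
uncstress run-all --seed 1 --out results/pipeline
```

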