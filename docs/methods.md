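# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## The generative model

Each simulated trial belongs to a (lab, subject, item, word-type) cell of
a crossed design: subjects are nested in labs, items are crossed with
subjects, and every subject sees every item once (one article epoch and
one noun epoch per sentence).  The latent single-trial N400 window-mean
amplitude is

    a = α + (β_w + u_s^slope + w_iw^slope + l^slope) · c/100
        + u_s^int + w_iw^int + l^int + ε,

where `c` is the item's cloze in percent, `β_w` the word-type-specific
cloze effect (µV per 0→100% cloze), `u_s` subject effects (shared across
word types: same head, same session), `w_iw` item effects (drawn per
item × word type: the article and the noun are different words),
`l` optional lab effects, and `ε ~ N(0, sd_trial)` the trial residual of
the *window mean*.  The voltage of a trial is

    v(channel, t) = a · T_N400(channel, t) [+ a_P600 · T_P600(channel, t)]
                    + 1/f^a noise,

with smooth unimodal templates (Gaussian in time, peaking at 400 ms /
650 ms; centro-parietal / parietal scalp weighting).  **Calibration
contract**: each template is scaled so that its mean over the six ROI
channels (Cz/C3/C4/Pz/P3/P4) and its analysis window (200–500 ms for the
N400, 500–800 ms for the P600) equals exactly 1.  The clean ROI window
mean of a trial therefore *equals* `a`, and β carries the interpretable
unit "µV per 0→100% cloze".  With all variance parameters and the noise
amplitude at zero, the ROI mean is exactly α — this is asserted in the
tests.

Cloze values are drawn per item: a decile is sampled from
`cloze_decile_weights` (defaults put 37.5% of mass in the 0–10 bin and 4%
in the 91–100 bin, with the middle deciles sparsest — the skew that makes
bin averages unequally reliable), then an integer percent is drawn
uniformly within the decile (cloze norms are counts of respondents, hence
integers).

Background noise is synthesised in the frequency domain with power
∝ 1/f^a (a = 1 by default) and scaled to an exact per-trace RMS
(`noise_sd`, default 5 µV).  The spec's parameter set names no noise
amplitude; `noise_sd` is exposed as an explicit field.  Artifact
injection adds either a frontal blink-like pulse (150 µV peak, 35 ms
width) or a single-sample step (60 µV/ms), both strictly beyond the
rejection thresholds, and flags the trial in the generator's ground
truth.

Defaults for the variance parameters are choices of this package, not
values asserted by any study: `sd_trial = 10 µV` (a realistic single-trial
window-mean residual for EEG), subject/item intercept and slope SDs of
1–2 µV, lab effects 0.  They are configuration, exposed in
`GeneratorParams`.

### Seeding

Every stage draws from `numpy.random.default_rng([seed, stage_key])` with
a distinct key per stage (design / voltages / artifacts), so that nearby
integer seeds never share a stream between stages — important for
replicate simulations with consecutive seeds.

### Fast table-level path

`simulate_trial_table` draws ROI window means directly from the latent
amplitude model, skipping waveform synthesis.  Differences from the epoch
path: the residual is `sd_trial` only (the background-noise window mean
is absent), the pre-article window is pure `N(0, sd_trial)` noise, and
the N400 template tail does not leak into the P600 window.  It exists for
simulation studies with hundreds to thousands of replicates (coverage,
type-I error, power), where waveform synthesis would dominate the cost;
the pipeline itself always uses the epoch path.

## Preprocessing

* **Baseline**: subtract the per-trial, per-channel mean over −100..0 ms
  (`pre100`), −500..0 ms (`pre500`), or nothing (`none`, the default of
  the bin-averaged route).  Windows are closed on both ends; boundary
  samples are included (fixed for bit-reproducibility).
* **Band-pass (bin route only)**: Butterworth with `order=4` passed to
  the designer, band 0.2–15 Hz, applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase with the squared magnitude response.
  Padding extends to ~3 time constants of the low cutoff, but a 1.5 s
  epoch cannot fully escape the 0.2 Hz high-pass transient — that is a
  property of band-passing segmented data, not of this implementation,
  and the magnitude-response tests check the filter itself.
* **Artifact rejection**: a trial is rejected if on any channel the
  max−min range within any sliding 150 ms window strictly exceeds 120 µV,
  or |Δv|/Δt strictly exceeds 50 µV/ms.  The window length in samples is
  `round(0.150 × rate)`; the step rule normalises by the actual
  inter-sample interval, so any sampling rate works.  All channels in the
  container are examined (configurable).  The per-trial log records the
  rule fired and the channel/time of the earliest violation
  (peak-to-peak wins ties).
* **Participant exclusion**: a participant is dropped entirely when they
  retain fewer than `min_per_type` (default 60-of-80) article trials or
  noun trials in the main experiment; "fewer than" is strict.
* **Window means**: arithmetic mean over samples with
  `start ≤ t ≤ end`, then the unweighted mean over the named channels.

## Bin-averaged route

Bins are `[0,10], (10,20], …, (90,100]` on integer-percent cloze
(`assign_bin`); averaging is within participants first, then unweighted
across participants per lab (a participant with 3 trials in a bin counts
as much as one with 30); empty cells are absent rows.  Pooling
concatenates the per-lab bin rows ("labs as multiple observations of each
bin average") rather than averaging them.  Pearson r is computed per
channel with the two-tailed p from `t = r√((n−2)/(1−r²))`; per-lab
p-values on ≤10 points are reported uncorrected.  The Fisher-z interval
reproduces the reference anchor: `fisher_ci(0.68, 10) → (0.09, 0.92)`
after 2-decimal rounding.

## Single-trial mixed models

### Solver

`clozerep.mixedlm` implements the profiled ML deviance of the
penalized-least-squares formulation of the LMM (the lme4 formulation):
β and σ² are profiled out, and only the relative covariance factors θ
(one lower-triangular block per random term, diagonal for the
uncorrelated "||" form) are optimised — L-BFGS-B with bound-constrained
diagonals followed by a Nelder–Mead polish, starting at a relative SD of
0.3 with a warm-start hook for nested-model chains.  All linear algebra
is dense (q, the random-effect dimension, stays in the hundreds for these
designs), which keeps a fit in the 0.1–0.5 s range and makes
thousand-replicate simulations feasible.  The solver is validated against
R's lme4 on the same data (log-likelihood to 1e−3, coefficients to 1e−3)
in `tests/test_mixedlm.py`; on one singular-boundary test case it finds a
*better* optimum than lme4's default optimiser (verified through lme4's
own deviance function).

A full model can come out marginally below its nested reduction when the
covariance optimiser stalls near a boundary; every comparison site then
refits the full model warm-started from the reduced model's θ and keeps
the better fit (`ensure_nested`), so LRT χ² values are never negative by
construction rather than by clamping.

### Coding and transformation

Cloze is z-scored with the sample SD over the modelled rows (per word
type for the separate models, combined for the interaction model; the
scope and scale factor are recorded, and β_raw is invariant to the choice
— tested).  Laboratory uses sum-to-zero contrasts with the last lab as
the implicit reference (the choice is immaterial to LRTs).  Word type and
grammaticality are coded ±0.5 so their coefficients are directly
condition differences in µV.  Coefficients and Wald 95% CIs
(± z₀.₉₇₅ · SE) are back-transformed as `β_raw = β_z · 100 / sd(cloze%)`.

### The ladders

Per word type, Models 1–4 (above) with correlated `(cloze | subject) +
(cloze | item)`; LRT df are (#labs−1, #labs−1, 1).  The word-type
interaction uses uncorrelated random intercepts and slopes for cloze,
word type and their product (the richer structure converges only in the
"||" form).  Accuracy moderation z-scores each subject's accuracy over
subjects and tests `accuracy × cloze` then `cloze | accuracy`, df 1
each.  The pre-article analysis reruns Models 3 vs 4 on the −500..−100 ms
window of the 100 ms-baselined data (a negative control: the context is
identical before the article).  The P600 control compares
`~ grammaticality + (grammaticality | subject) + (grammaticality | item)`
to its null on the 500–800 ms window of the control-session trials.
Non-convergent fits fall back along: drop random correlations → drop the
item slope → drop the subject slope, with each step recorded in the
result.

## Bayesian layer

* **Replication Bayes factor for correlations**: the prior on ρ under
  "the effect is what the original study says" is the original study's
  posterior under a uniform(−1, 1) prior — proportional to the exact
  sampling density of Pearson's r (hypergeometric form, evaluated on the
  log scale).  BF_r0 integrates the replication likelihood over that
  prior (trapezoid on a 4097-point grid over (−0.9999, 0.9999)) and
  divides by the likelihood at ρ = 0.  Every call recomputes on a doubled
  grid and raises if log BF moves by more than 1e−3.  The prior is kept
  untruncated: its mass already encodes the original effect's direction.
* **Posterior summaries**: the mixed-model estimate and SE are treated as
  a normal likelihood on the z-cloze scale and combined with a normal
  prior (precision-weighted conjugate update).  This replaces a full
  MCMC mixed-model fit with a deterministic, testable approximation built
  on the ML fit; it ignores uncertainty in the variance components, which
  is the main source of discrepancy with a full Bayesian fit.
* **Savage–Dickey**: BF₀₁ = posterior(0)/prior(0) with closed-form
  normal densities.  Evidence grades: 1 none, (1,3) anecdotal, [3,10)
  moderate, [10,30) strong, [30,100] very strong, >100 extreme, applied
  to max(BF, 1/BF).

## Problem sizes used by the checks

The acceptance script simulates 3 labs × 16 subjects × 50 items (plus a
40-item control session) — large enough for the 2.2 µV noun effect to be
reliably detected while the 0.3 µV article effect is not, reproducing the
qualitative asymmetry the pipeline exists to measure.  The calibration
tests use 2 labs × 12 subjects × 40 items × 200 replicates (CI coverage,
mean bias) and 2 labs × 8 subjects × 24 items × 1,000 replicates (type-I
error), both on the fast table path.  These sizes are the package's
desk-scale study conditions; full-scale designs (9 labs × ~40 subjects ×
80 items) run through exactly the same code.

## What passing tests do and do not show

The generator emulates the statistical structure of multi-lab single-trial
EEG — crossed random effects, skewed cloze, 1/f noise, canonical component
topographies, blink/step artifacts — but not: ocular components needing
ICA, bad channels, amplifier drift or between-lab filter differences,
overlapping components, or any systematic confound between cloze and item
properties.  Passing calibration tests therefore shows the *routes* are
correct and calibrated under the stated model, not that real EEG satisfies
that model.  Known limitations: Wald CIs mildly undercover with few
clusters (coverage ≈ 0.93 at 24 subjects in the acceptance test — the
known few-cluster behaviour of ML mixed models, not a defect of the
implementation); the conjugate posterior understates posterior spread
relative to full MCMC; and the bin route's transient response to the
0.2 Hz high-pass on 1.5 s epochs is inherited from the procedure it
reimplements.
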