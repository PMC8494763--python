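# Methods

## Data model

A consultation is a sequence of fixed-length video frames (default
0.04 s), each carrying a binary face-AOI hit and a validity flag. All
rates use the *analysed* time base: invalid frames (physical-examination
gaps, tracker dropout) are removed from both numerator and denominator,
never recoded as "no gaze". Timestamps, if present in input files, are
advisory; frame index × frame interval defines time. Frame indexing is
0-based and all intervals are half-open `[start, end)`.

## Gaze instances and the three measures

A gaze instance (run) is a maximal block of consecutive ON frames that
are all valid. A valid OFF frame *or* an invalid frame interrupts a run;
the optional `bridge_invalid_frames` parameter merges runs across short
all-invalid gaps for users whose upstream pipeline drops isolated frames
(default 0: a strict reading of "uninterrupted"). An optional
`min_instance_frames` filter discards runs shorter than a threshold —
useful when the upstream AOI software applied smoothing — and removes the
filtered runs from both the instance count and the gaze-duration total so
that the measure identity survives filtering. The default (1 frame) keeps
raw runs, since no particular smoothing can be assumed.

For a segment with ON-seconds `T_on`, instance count `k > 0` and analysed
minutes `M`: duration/min `= T_on / M`, frequency/min `= k / M`, mean
dwell `= T_on / k`. With `k = 0` mean dwell is *undefined* and propagates
as NaN — never 0, which would break `duration = frequency × dwell`.

**Segment boundaries (truncate-onset policy).** A run crossing a segment
boundary contributes its in-segment seconds to each side's duration but
counts as an instance only in the segment containing its onset. Under any
partition of a stream this conserves total gaze seconds exactly and
counts every instance exactly once. A consequence worth knowing: a
segment can have positive duration with zero instances (a run that
entered from the previous segment), in which case its dwell is undefined.

**Deciles.** The valid-frame sequence of a consultation is partitioned
into 10 contiguous bins with boundaries at `floor(d · N/10)` over
valid-frame ordinal positions (N = number of valid frames, at least 10).
Defining bins over valid frames rather than wall-clock frames keeps
gap-masked stretches from distorting the time base; profiles are
identical whether or not a masked gap is embedded in the stream.

**A note on frequency bounds.** On a fully valid stream, runs need
separating OFF frames, so frequency/min ≤ 60/(2·dt) + 1/M. When runs are
separated only by *invalid* frames this bound does not apply (the
separators leave the denominator); the universal bound is 60/dt.

## Decile trend model

Per-consultation per-decile values are modelled as
`y_cd = β₀ + β·(d − 5.5) + b_c + ε_cd` with a random intercept `b_c` per
consultation, fitted by REML (statsmodels MixedLM). The decile index is
centred at 5.5 for numerical stability; β is reported per decile on the
original scale. The wording of the source analyses ("mixed-effects
analysis on aggregated decile averages") is ambiguous, so an
`method="aggregate"` option fits OLS on the 10 cross-consultation decile
means instead; in a balanced design both give the same slope. Only a
random intercept is modelled (no random slopes, no physician level) —
the minimal structure the description supports.

Degenerate inputs are handled explicitly rather than passed to the
optimizer: if the within-consultation residual variance is numerically
zero (noise-free profiles), the pooled within-consultation least-squares
slope is exact and is returned with zero standard error (p = 0 for a
non-zero slope, p = 1 for flat profiles); if additionally all profiles
are constant and identical, the fit is singular and raises
`SingularFitError`.

## Correlations

Pearson r and two-sided p come from `scipy.stats.pearsonr`; rows with an
undefined dwell are dropped listwise per pair with a log record. The
three pairwise tests among duration/frequency/dwell form one family and
are each tested at α = 0.05/3 ≈ 0.017 (Bonferroni). Correlations of the
measures with satisfaction and consultation length are reported at the
uncorrected α = 0.05 — the family correction in the source design applies
to the three-way family — with family-corrected p-values
(`p_value_family`) alongside for conservative readers. Zero-variance
inputs raise rather than returning NaN silently.

## Thin-slice models

The slice is the first `round(slice_seconds / dt)` *valid* frames; the
remainder is everything after it ("remainder", not "whole consultation" —
using the full consultation would leak the slice into its own outcome).
Consultations with no valid frame beyond the slice are excluded with a
log record. For each measure and slice length:

    remainder ~ intercept + slice + total_minutes        (OLS)

with total analysed minutes as confounder. With
`with_physician_effect=True` the same rows are refit with a per-physician
random intercept (maximum likelihood), and the two fits are compared by a
likelihood-ratio test. Because the variance parameter sits on the
boundary of its space under the null, the χ²₁ tail probability is halved;
AICs of both fits are also reported. The mixed fit reports the *marginal*
R² (fixed-effects variance over fixed + random + residual variance,
following Nakagawa & Schielzeth) so the fixed-only and mixed variants are
comparable; the summary prints R² both as a proportion and as a
percentage. Reported significance stars follow the usual legend
(*p < 0.05, **p < 0.01, ***p < 0.001).

## Synthetic cohort generator

**Process.** Each consultation is an alternating renewal process: ON
(face gaze) episode lengths are lognormal, OFF episodes gamma, drawn
sequentially and rounded to whole frames (minimum 1 frame). The
stationary limits are duration/min = 60·E[ON]/(E[ON]+E[OFF]),
frequency/min = 60/(E[ON]+E[OFF]), dwell = E[ON]; these closed forms
(`analytic_expectations`) are the package's independent oracle for the
whole measure pipeline. The initial state is ON with the stationary
probability.

**Traits.** Each consultation (dyad) draws two *independent* lognormal
traits: a duration propensity D (s of gaze per minute, median 26.9,
log-sd 0.45, clipped to [4, 56]) and a frequency propensity F
(instances/min, median 25.3, log-sd 0.40, clipped to [6, 78]); episode
means follow as E[ON] = D/F and E[OFF] = (60−D)/F, so E[OFF] > 0 is
automatic. The implied mean dwell D/F is kept inside the observed
plausible range [0.15, 6.8] s by adjusting F in the extreme tails.
Independence of D and F is what makes measured duration and frequency
uncorrelated while dwell = duration/frequency correlates positively with
duration and negatively with frequency — the qualitative pattern the
analyses are designed to detect. A physician-level log-normal shift on
both traits exists (`physician_effect_sd`) but defaults to 0: with it,
gaze style belongs to the dyad, and the thin-slice random-effect
comparison correctly prefers the fixed model.

**Within-consultation decline.** Episode means drift smoothly with the
consultation fraction τ ∈ [0, 1]: E[ON] is multiplied by
`on_decay^(τ−½)` (default 0.75) and E[OFF] by `off_growth^(τ−½)`
(default 2.08), so the person's trait values hold at mid-consultation. A
smooth multiplicative trend was chosen over phase changes because the
observed decile profiles decline gradually. With these defaults the
duration decile profile falls roughly linearly by ≈1.26 s/min per decile.

**Satisfaction.** The 0–100 satisfaction score loads on the latent
frequency trait z: `s = 75 + 12·(ρ·z/σ_z + √(1−ρ²)·η)`, clipped to
[0, 100]. The loading is inflated by the analytic attenuation between z
and exp(z) so that the raw-scale correlation with measured frequency
lands near the 0.309 target.

**Cohort layout.** 16 physicians; per-physician patient counts lognormal
(median 6, clipped to 2–14, ≈100 consultations in total); consultation
lengths lognormal (median 14.1 min, clipped to [3, 45.2]).

**Calibration.** Episode shapes (`on_sigma = 0.6`, gamma `off_shape =
0.7`), the trait medians and the decay ratios were calibrated once, by
simulation across seeds, to land jointly on: cohort medians ≈ 27 s/min
duration, ≈ 26 /min frequency, ≈ 1.05 s dwell; a duration decile slope
≈ −1.26 s/min; a satisfaction–frequency r ≈ 0.31; duration–frequency
independence; and monotone growth of thin-slice R² in slice length.
They were frozen afterwards; the defaults *are* the study conditions and
are not per-analysis tuning knobs.

**What the generator does not emulate.** Real gaze streams are not
renewal processes: episode lengths are serially correlated, conversation
phases (greeting, history taking, physical examination, closing) create
structured non-stationarity rather than a smooth trend, triadic
consultations (caregiver present) inflate face gaze, and AOI-detection
errors produce correlated frame noise rather than clean episodes. The
generator also draws satisfaction from a single latent link, while real
satisfaction has many determinants. Passing tests therefore demonstrate
that the *pipeline* recovers known structure from data of this shape —
not that real consultations have that structure.

## Problem sizes and runtime choices

Test and reproduction runs use the generator's default scale (≈100
consultations of median 14 min at 25 fps, ≈2 million frames per cohort).
Monte-Carlo assertions use 20 seeds (calibration recovery), 100 seeds
(thin-slice monotonicity), 200 seeds (correlation structure) and 60
seeds (random-effect null); the renewal oracle uses a single 10-hour
stream with moderate-variance episode shapes (lognormal σ = 0.5, gamma
shape 3) so that Monte-Carlo error stays well inside the 1% tolerance.
Oracle-equivalence checks cover 10,000 random streams of 1–5,000 frames
with random validity masks and random segment boundaries against a pure
per-frame scanner.

## Known limitations

* The trend model fits a straight line over deciles; genuinely
  non-monotone time courses (e.g., a mid-consultation dip during
  examination-heavy visits) are summarised, not modelled.
* The mixed-model p-values are Wald-type; for very small cohorts a
  likelihood-profile or bootstrap interval would be preferable.
* No rejection cutoff is imposed for streams with heavy data loss; the
  validity mask records per-frame exclusions, and deciding how much loss
  disqualifies a consultation is left to the analyst.
* Marginal R² makes mixed and fixed fits comparable but, like any R² for
  mixed models, is a convention rather than a uniquely defined quantity.
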