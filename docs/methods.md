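# Methods

`audiocog` simulates an auditory cognitive test battery for older adults at
the stimulus-parameter level and reproduces the statistical pipeline used to
compare in-person with web-based administrations of that battery.  This note
documents the models, their assumptions, the calibration procedure, the
numerical choices, and what the simulations can and cannot show about real
data.

## The battery

**Speech-in-noise thresholds (DIN, SIB).**  Both instruments are adaptive
1-up/1-down tracks over SNR: a correct response lowers the SNR by the current
step, an error raises it.  The track starts at 0 dB SNR with a 5 dB step,
drops to 2 dB after the 3rd reversal and to 0.5 dB after the 6th, stops at
the 10th reversal, and scores the threshold as the mean SNR of the last five
reversals (lower = better).  Two practice trials at +10 dB precede the track
and are excluded.  Conventions that the published description leaves open are
fixed so that deterministic runs are enumerable: the first response defines
the initial direction without logging a reversal; a reversal is logged at the
SNR of the trial whose response flips the direction; a reduced step takes
effect for the first movement after the triggering reversal is logged.  A
`max_trials` cap (default 150) converts degenerate runs (perfect or chance
performers, which never produce 10 reversals) into a flagged non-converged
track with an undefined threshold rather than an exception.

**Virtual listeners.**  Humans are replaced by a four-parameter logistic
psychometric function `p = γ + (1−γ−λ)·logistic((snr−t50)/s)` with guess rate
γ ∈ [0, 0.5], lapse rate λ ∈ [0, 0.1], 50% point `t50` (dB) and spread `s`
(dB).  A 1-up/1-down rule converges to the 50%-correct point, so for γ=λ=0
the track estimates `t50` — a testable property (the mean estimated threshold
over 1000 runs sits within 0.7 dB of `t50`).  Cohort simulations use `s` =
1.0 dB for both speech tasks; the two tasks differ only in how the listener's
`t50` is derived from the latent trait layer.

**Auditory working-memory matching (AuM).**  A block interleaves 16
frequency trials (targets uniform on 440–880 Hz) and 16 AM-rate trials
(uniform on 5–20 Hz), after 2 excluded practice trials per feature.  The
response scale adds 10% padding at either end of the stimulus range and is
mapped affinely onto [0, 1]; errors are response − target in normalized scale
units, which makes the frequency and AM-rate precisions directly comparable.
The response model is target + constant bias + Gaussian noise, clipped to the
screen.  Precision is the inverse of the maximum-likelihood Gaussian SD of
the per-feature errors, with the mean left free so that a constant response
bias inflates the location, not the scale.  A zero-spread sample raises a
degenerate-sample error (precision is undefined, not infinite, keeping the
downstream log transform well-defined).  `1/SD_hat` is biased upward at 16
trials (median ≈ +5–7% for Gaussian errors); the cohort calibration absorbs
this (below).  Open design points — whether the on-screen scales were linear
or logarithmic, whether the fitted mean was free, and the units of the
published precision values — were resolved as: linear scales, free mean, and
published values read as log-precision analysis units.

**Questionnaire (GMSI).**  38 items on a 1–7 scale partitioned into five
domains (9, 9, 7, 7, 6 items); the total is the sum of domains = sum of
items, spanning 38–266.  Scoring is independent of the particular partition,
which is a configuration artifact; the default map is a synthetic stand-in
with the canonical domain sizes, not the published questionnaire key.

## The synthetic cohort

**Demographics.**  153 main-cohort participants with ages from a truncated
Gaussian on [50, 86] whose post-truncation mean and SD equal 67 and 10 (the
parent parameters are solved numerically).  An 89-person add-on cohort
(mean 65, SD 8) participates on the web only and has no audiogram, matching
the combined web sample of 147.

**Audiograms.**  Each main participant gets a two-ear audiogram on the 5 dB
audiometer grid (250 Hz–8 kHz, ceiling 100 dB HL) built around a target
best-ear high-frequency average (mean of 4 and 8 kHz, better ear).  The
marginal distribution of that average is piecewise-uniform over the category
bands so the configured hearing mix (11.1% normal, 18.9% mild, 54.3%
moderate, 15.7% severe) is approximately met; the published band definitions
leave 60–80 dB HL unassigned, and that gap is closed into "moderate".
Hearing-aid use is a probabilistic function of hearing loss tuned to ≈15% of
the cohort.

**Latent traits.**  One multivariate-Gaussian layer with six dimensions —
musical sophistication, speech-in-noise ability (threshold direction),
frequency memory, AM-rate memory, age and hearing loss — where age and
hearing loss enter through Gaussian copulas so their marginals are exactly
the ones above.  Default off-diagonals are chosen so that the *observed*
cross-measure correlations, after measurement attenuation, land near the
published associations (speech-in-babble ~ AM memory ≈ 0.46 in person and
≈ 0.18 on the web; musicality ~ frequency memory ≈ 0.5 in both settings).
The positive sign of the babble-threshold/AM-memory association is
reproduced as published even though it is counterintuitive (worse
speech-in-noise thresholds pairing with higher memory precision).

**Measure calibration and engine noise.**  For each measure with targets
(μ_in, s_in, μ_web, s_web, retest r) the trait z maps affinely to the task
parameter per setting:

    X_in  = μ_in_eff  + a·z + engine noise         a² = s_in² − v_in
    X_web = μ_web_eff + b·z + N(0, τ²) + engine noise
    b = g · r·s_in·s_web / a,   τ² = s_web² − v_web − b²

The web setting therefore carries extra zero-mean parameter noise sized so
the realized cross-setting correlation equals the target; an infeasible
request (SD below engine noise, or r too high once engine noise is counted)
raises a calibration error.  The constants (v, bias, gain g) are *factory
calibration*: fixed-point Monte-Carlo estimates at the default engine
settings, frozen in `_calibration.py`.  They absorb (i) staircase threshold
estimation noise and the transient bias of approaching a positive threshold
from the fixed 0 dB start (≈ −0.3 to −0.5 dB); (ii) precision-estimation
noise and small-sample bias at 16 trials; and (iii) the variance compression
caused by response clipping — compression strong enough for the frequency
feature that some effective `v` values are negative (the latent spread must
be inflated before the engine squashes it).  The questionnaire chain is
exact: session totals are drawn on the calibrated scale, clipped to
[38, 266], and item vectors with Likert-like scatter are constructed to sum
to the rounded total exactly, so the questionnaire carries no hidden engine
noise — which is precisely why it attains the highest retest correlation, as
in the study.  At n = 10,000 the simulated in-person means and SDs sit
within ~2% of all five targets, and the five retest correlations average
0.82/0.53/0.52/0.75/0.44 against targets 0.82/0.55/0.55/0.75/0.44 at n≈58
over 100 replicates.  The frozen constants are valid at the default engine
configurations; changing staircase schedule, listener spread, or block
length degrades the calibration gracefully.

**Web-return selection.**  Return probability = base rate (0.656) ×
penalties for age > 70 (×0.45), severe hearing loss (×0.35) and hearing-aid
use (×0.35), forced to zero above age 75.  Defaults yield 58 ± 6 returners
out of 153 (37.9%), a severe-hearing-loss fraction among returners well
below the cohort's, and a significant over-70 participation difference.

**Randomness.**  Every stream derives from one top-level seed through keyed
`SeedSequence`s (seed, participant, setting, task), so runs are byte-for-byte
reproducible and adding a task or participant never perturbs other streams.

## The analysis pipeline

Memory precisions are log-transformed; other variables can be z-scored
(Pearson statistics are invariant to this; ICC is computed on the
untransformed pairing so absolute agreement retains meaning).  Missing
values (e.g. a non-converged staircase) propagate — every statistic is
complete-case and reports the n it actually used; nothing is imputed.

* **Pearson r** with a two-sided t-based p and a Fisher-z CI
  (`atanh r ± z_crit/√(n−3)`); a bootstrap percentile CI is available by
  configuration.  The published CIs for these data match no standard method,
  so no attempt is made to reproduce them.
* **ICC**: two-way random-effects, absolute-agreement, single-measurement
  ICC(2,1) from the mean-squares decomposition by default (consistency
  ICC(3,1) by flag); negative estimates are returned as computed and
  flagged.
* **Williams–Steiger t** for two dependent correlations sharing a variable,
  with df = n − 3 and a positive-definiteness check on the implied 3×3
  correlation matrix.
* **Bootstrap correlation differences**: row resampling with replacement
  (default B = 1000), percentile CI; significance = CI excluding zero.
  Degenerate resamples (a constant column) are redrawn and counted.
* **Chi-square** 2×2 tests without continuity correction (Yates by flag).
* **Residualization**: OLS on intercept + covariates; correlating
  residualized variables equals the textbook partial correlation.
* No multiple-testing correction anywhere, matching the exploratory design.

Problem sizes used by the test suite and the acceptance script — 2000
replicates at n = 58 for correlation recovery, 1000 staircase runs for
convergence, 200 replicate studies for the reliability ordering, one
10,000-participant study for moment calibration — were chosen as the
smallest sizes at which Monte-Carlo error is well inside each check's
tolerance.

## What the simulations do and do not show

Passing tests demonstrate that the instruments' scoring rules, the
attenuation model and the statistics are implemented correctly and that the
generator reproduces the published summary statistics it was calibrated to.
They do not validate the psychological model: real listeners drift between
sessions (3–6 month retest interval), differ in lapse/guess behaviour, hear
through heterogeneous devices, and may respond on non-Gaussian error
distributions; none of that is modelled.  The joint distribution of age,
hearing loss and ability beyond the published marginals is an artifact
choice.  One sampling property worth noting: at n ≈ 58 the sampling SD of a
correlation near 0.8 is ≈ 0.04–0.07, so the questionnaire's *sample* retest
correlation exceeds all four behavioral measures in only ~80–85% of
replicate studies even though its population value is strictly highest —
single-study reliability rankings at this sample size are unstable.

## Known limitations

* Factory-calibration constants are point estimates; residual calibration
  error is ~1–2% of an SD on means and ~2% relative on SDs.
* The frequency-memory chain operates in a strongly nonlinear (clipped)
  regime; its realized retest correlation plateaus ≈ 0.01 below the 0.75
  target.
* Audiogram shapes are stylized (high-frequency sloping loss only).
* The hearing-aid count and web hearing-mix figures in the source material
  are internally inconsistent; defaults use the in-person percentages and
  qualitative directions.
* No audio is synthesized or played; the simulation begins and ends at
  stimulus parameters.
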