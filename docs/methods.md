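# Methods

This note documents the models, conventions and numerical choices behind
`stridecycle`, and what the synthetic-data tests do and do not establish
about real data.

## Gait extraction

Vertical head position during walking oscillates with one trough per
footfall (double support) and one peak per swing.  Traces are linearly
detrended per trial (drift in head height otherwise biases trough
prominence), low-pass filtered with a zero-phase 2nd-order Butterworth at
4 Hz (the step rate is ~1.7 Hz; the filter prevents sensor noise from
displacing minima), and troughs are found with a prominence threshold of
0.25 x the 5-95 percentile height range and a minimum separation of
0.35 s (just below the fastest plausible step).  When the raw signal is
effectively noiseless (high-frequency residual under 2% of the height
range) each trough is snapped to the raw local minimum, removing the
filter's one-to-two-sample displacement; under real noise the filtered
location is the better estimate and is kept.  Trials are excluded for
sampling gaps over 3 frame intervals (wireless drop-out), a flat height
signal, a median step duration outside 0.35-1.0 s, or fewer than three
troughs.

Strides (two sequential steps) are resampled by linear interpolation onto
a 200-point phase grid (0.5-100% in 0.5% steps); at 90 Hz every step
contributes over 30 raw samples, so higher-order interpolation changes
nothing material.  Stride *curves* are epoched from overlapping trough
triples by default (more strides, smoother averages); a non-overlapping
(tiling) mode exists for sensitivity analysis.

## Event phase assignment

Behavioural events are assigned the percentile of the stride within which
they occurred.  For events, strides tile the trial from the first detected
trough (troughs 0-2, 2-4, ...), each event belongs to exactly one stride,
and phase is `100*(t - start)/(end - start)` on the half-open interval
(0, 100] - an event at a footfall belongs to the stride that footfall
closes.  Tiling (rather than assigning events to overlapping strides) is
what makes the phase variable span the full cycle: assigning each event to
the stride starting at the most recent trough would fold all phases into
(0, 50%].  Left/right foot identity is not distinguished, so stride parity
is arbitrary; any measure at an even number of cycles per stride is
unaffected, and odd frequencies are inherently parity-ambiguous in this
design.  Events before the first trough or after the last complete stride
are dropped and counted; conservation (kept + dropped = total) is asserted
end to end.

Measures: accuracy is the per-bin mean of hit indicators; reaction time is
the per-bin mean over hits only; response likelihood is the phase density
of response *onsets* normalized to mean 1 (a target-locked fraction-answered
variant is available behind a flag); target density is the same
normalization applied to target onsets.  Binning defaults to 40 bins
(20, 100 and 200 are supported); empty bins propagate as missing and are
dropped from fits, never imputed.  A clock-time control folds the same
events modulo 1 s epochs instead of strides.

## Fixed-frequency Fourier model and permutation inference

For a binned series y(x), x in (0, 1], the model at frequency w (cycles
per stride) is `a0 + a1 cos(2πwx) + b1 sin(2πwx)`.  With w fixed this is
ordinary least squares, solved exactly - an iterative optimizer would
converge to the same optimum, so none is used.  Amplitude is
`sqrt(a1² + b1²)` and phase `φ = atan2(-b1, a1)`, making the model
`a0 + A cos(2πwx + φ)`; R² is 1 - SSres/SStot, defined 0 for a constant
series.  The sweep covers 0.2-10 cps in 0.2 steps (50 frequencies); argmax
ties break toward the lower frequency.

The null is built by shuffling outcome values across events within each
participant (phases fixed - exactly equivalent to shuffling the events'
bin allocation), rebinning, averaging across participants with equal
weight (a pooled-events mode exists behind a flag), re-running the sweep,
and retaining the maximum R² over all 50 frequencies per permutation.
The 95% critical value uses the conservative next-higher order statistic,
so strict exceedance keeps family-wise error at or below 5% at finite
permutation counts.  For density measures, where permuting event outcomes
is a no-op, the per-bin counts are permuted across bin positions instead.
Participant-level tests use the same max-statistic rule against the
participant's own null by default; a per-frequency rule is available
behind a flag.  Significant participants are banded by best frequency:
2 cps band = [1.5, 2.5], 4 cps band = [3.5, 4.5], high > 5.

Under white noise the argmax of the sweep is *not* uniform across the
grid: frequencies below ~0.8 cps complete less than a cycle over the
stride and are nearly collinear with the intercept, and the top grid
frequency absorbs the high tail.  This is a property of R² screening in
general and is precisely why inference is based on the max-statistic null
rather than on argmax symmetry.

## Population prevalence

With k of n participants significant at per-test false-positive rate α,
the probability a random participant tests significant is
`θ(γ) = (1-γ)α + γ·s` with prevalence γ and within-participant sensitivity
s (default 1; exposed as a parameter).  Under a uniform prior the
posterior over γ is the binomial likelihood in θ(γ); the MAP is
`clamp((k/n - α)/(s - α), 0, 1)` and the posterior is evaluated on a
2001-point grid in log space.  The 95% HPDI is found by discrete
water-filling (lower the density threshold until 95% of mass is included;
report the covering interval), which is robust to the truncated-Beta shape.
Exact enumeration over k ~ Binomial(36, θ(0.5)) gives a frequentist
coverage of 93.5% for the 95% HPDI at γ = 0.5 - slightly conservative
intervals are expected from the discreteness of k at n = 36.

## Circular statistics

Participant phases are taken from the fit at 2 cps (even for participants
whose best frequency is elsewhere in the 1.5-2.5 band, so phases are
commensurable).  The Rayleigh statistic is Z = n·r̄² with r̄ the mean
resultant length; the p-value uses the standard second-order series
approximation (exact-style permutation p behind a flag), and "circular
variance" is reported as 1 − r̄, the convention that reproduces the
package's reference checks.  The approximation is monotone in r̄
throughout the meaningful range and only wobbles at p below ~1e-5.

## QUEST staircase

The staircase tracks a posterior over the detection threshold on a
151-point contrast grid (0.4 to 1.0, step 0.004).  Contrast is expressed
internally in decibels of the raw grayscale value, dB(c) = 20·log10(c):
converged staircase means near 0.44 then sit at ≈ −7.1 dB, consistent with
the scale on which such staircases are conventionally summarized.  The
prior is Gaussian in dB (sd 2) centred on the 0.45 starting contrast; the
likelihood is the classic Weibull in dB with slope β = 3.5, guess 0.5 and
lapse 0.01, *shifted so the tracked parameter is the 75%-correct
intensity* (the criterion offset is −0.84 dB for these parameters).  That
shift is what makes "place trials at posterior quantiles of the threshold"
hold accuracy at the target rate; without it the staircase would converge
to the Weibull's natural ~81% point.  Each target draws its contrast
uniformly from seven posterior quantiles (percentiles 25-75), enabling the
offline psychometric fit; three optional familiarization targets at fixed
0.45 are logged and excluded from fits.  One dynamical caveat: because the
guess floor makes a miss roughly three times as informative as a hit near
threshold, artificial forced-alternation input drives the posterior
upward - equilibrium claims are therefore tested against stochastic
observers, where the posterior mean converges to within ±0.01 of the
observer's 75% point and accuracy to 0.75 ± 0.03.

The offline psychometric model is a cumulative normal with fixed guess 0.5
and lapse free on [0, 0.05], fitted by maximum likelihood (L-BFGS-B on
(μ, log σ, lapse)); threshold50 = μ, width = σ·(z₀.₉₅ − z₀.₀₅) ≈ 3.29σ,
slope = (1 − guess − lapse)/(σ√(2π)).  Degenerate data (e.g. all hits)
are fitted but flagged.

## Gaze quality control

Blinks are detected as per-axis frame-to-frame jumps above 0.8 m in the
recorded gaze-direction coordinate stream; the entry and exit jumps of one
blink are separated by the blink's duration, so seeds within 350 ms are
merged into one interval.  Repair replaces samples from 200 ms before to
200 ms after each interval with a modified-Akima (makima) interpolation
through the remaining samples, per axis; edge blinks fall back to
nearest-valid filling and are flagged, and samples outside padded windows
are returned bit-identical.  Targets whose gaze-to-target angle exceeded
12.1° (the annulus radius) at onset are excluded, with missing gaze as a
distinct drop reason.  The mechanical-artefact control bins the standard
deviation of detrended gaze-origin coordinates by stride phase: a flat
profile argues against tracking artefacts masquerading as perceptual
modulation.

## Synthetic generator: what it emulates

Defaults emulate the study conditions end to end: 36 participants, 140
walking (plus 40 stationary) 9 s trials at 1.1 m/s sampled at 90 Hz;
stride duration 1.18 s ± 0.069 across participants (step 0.59 s), per-step
jitter sd 0.04 s and a 3% per-trial tempo factor; vertical head motion as
per-step raised-cosine arcs of ±2.5 cm with 3 mm sensor noise (so
step-duration jitter accumulates, unlike a global sinusoid); eight target
anchors 0.95 s apart with ±0.5 s jitter drawn sequentially under the 0.8 s
minimum inter-target interval, 10% withholding (7.2 presented
targets/trial in expectation, ~1000 scheduled per participant of which a
few percent fall outside complete strides and are dropped); 20 ms targets.
Detection follows `P(hit|x) = 0.75 + A·cos(2πfx + φ)` with
participant-specific frequency (default mixture: one third at 2 cps, one
third at 4 cps, one third unmodulated), amplitude 0.12, and phases
von-Mises clustered (κ = 2) around a swing-phase optimum; reaction times
are anti-modulated with shared phase (amplitude 30 ms, noise sd 80 ms,
floor 0.15 s) and every hit emits a response at onset + RT.  False alarms
default to zero with a configurable Poisson rate.  A QUEST staircase can
run alongside to give each target a realistic contrast level.

Two generator features deserve emphasis because they are what make target
phases uniform over the stride, as in real data: a gait-initiation latency
drawn from U(0, 1.2 s) before the first step (without it the first
footfall always lands within one step of trial onset and the fixed anchor
grid leaves a strong stride-frequency ripple in phase density), and the
trial-to-trial tempo variation.  Even so, pooled target-phase density
retains a ~3-5% slow ripple - as the real design does, where
target-presentation likelihood also shows above-chance fluctuations that
do not co-occur with the ~2 cps performance peaks.  Uniformity is
therefore asserted on pooled cohorts (chi-square GOF at n = 10⁴), and
performance inference never assumes exact density flatness.

What the synthetic tests establish: the pipeline recovers injected
frequencies to ±0.2 cps and phases to ±45° in ≥90% of runs at the study's
event counts; the permutation machinery is type-I calibrated; prevalence
and circular statistics reproduce their closed forms.  What they do not
establish: robustness to non-sinusoidal head trajectories, asymmetric
gait, treadmill data, response omissions/false alarms at high rates, or
eye-movement artefacts beyond the modelled blink/exclusion mechanics.

## Problem sizes and reproducibility

The test suite runs its heavier calibrations at deliberately reduced but
statistically adequate sizes, chosen once: type-I calibration uses 200
cohorts of 8 participants x 300 targets with 200 permutations (the
false-positive rate of a max-statistic test does not depend on cohort
size); recovery uses 100 seeded runs of 900 targets; the staircase check
uses 20 seeded runs of 800 targets.  The full pipeline at study scale (36
participants x 180 trials, 1000 permutations) runs in a few minutes on one
CPU.  All randomness flows from explicit seeds through spawned
sub-streams (one per participant, stage and measure), so cohorts are
byte-identical across regenerations and the analysis report is
byte-identical across reruns with the same seed.
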