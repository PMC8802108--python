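# Methods

This note documents the models behind `cardiobeat`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do and
do not establish about real recordings.

## Beat schedule model

Spontaneous beating is modelled as a renewal process on inter-beat intervals
(IBIs).  The base IBI is 60/`base_rate`; multiplicative Gaussian jitter with
coefficient of variation `rate_jitter_cv` (default 0.05, the low end of
beat-rate variability seen in spontaneously beating preparations) is clipped
at 0.1× the base interval to keep intervals positive.  Two arrhythmia
phenotypes can be superimposed:

* **Extreme pauses** (the concentration-independent, "stochastic" phenotype).
  The number of pauses is Poisson with mean `pause_rate`·n_beats/1000.  A
  pause is injected by replacing a randomly chosen IBI with a draw from
  `pause_duration_range` (default 4–6 s for the slow cluster model whose
  scoring cutoff is 3 s; 1.5–2.5 s for the fast monolayer model with its 1-s
  cutoff).  Because pauses lengthen intervals rather than delete beats, each
  injected pause maps one-to-one to an extreme R-R interval, which makes
  recovery scoring exact.  Parameter validation requires the minimum pause to
  exceed the longest ordinary interval, so an injected pause is never
  confusable with jitter.
* **Tachy–brady alternation**: square-wave rate modulation with period
  `tachy_brady_period`, alternating between `base_rate·ratio` and
  `base_rate/ratio`.  A square wave is the simplest model producing
  alternating fast and slow runs, and its noiseless limit (two exact interval
  values) is directly assertable.

The schedule generator is sequential when tachy–brady modulation is on (the
rate depends on elapsed time) and vectorised otherwise; both paths are
bit-reproducible for a fixed seed.

## MCG waveform

The contraction event is an asymmetric biphasic template: half-sine upstroke
(20 % of the event width) to the R peak, cosine decline (35 %) to an S trough
at −`relaxation_depth_fraction`·amplitude, cosine recovery to baseline.  The
R peak sits exactly at the scheduled beat time, so detector timing can be
checked to one sample.  The R-S span of a noiseless event is
amplitude·(1 + depth).  Defaults: 100 nN amplitude, depth 0.2, width 0.5 s,
1 kHz sampling (a typical force-sensor rate; the event width and depth are
free choices — only their consequences, not their values, are asserted).
Gaussian noise (default 2 % of amplitude in the recovery tests) and a
sinusoidal baseline drift emulate measurement noise and slow cantilever/stage
relaxation.

## Beat detection

R peaks are local maxima with prominence above an adaptive threshold:
max(absolute floor, `noise_multiple`·robust noise SD, `prominence_fraction`·
robust amplitude range), where the noise SD is 1.4826·MAD and the range is a
high percentile minus the median.  Peaks must clear a refractory separation
(0.25 s for the MCG profile, 0.1 s for MEA — both below the fastest
physiological rate of the respective model).  The S trough is the signal
minimum between an R peak and the next (or the segment end).  Plateau ties
resolve to the earliest sample.  Two numerical details matter:

* the trace is padded below its minimum before peak search so an event
  truncated at a segment edge is still found, with a height criterion
  (median + prominence) preventing the padding from promoting edge noise;
* R and S deflections are read from a local parabola fit (±12 ms) rather than
  the raw extreme sample.  Reading the extreme of noisy samples biases the
  mean R-S span upward by ≈2 noise SDs per landmark (≈6 % at 2 % noise); the
  fit is unbiased and leaves noiseless values and timings untouched.

The MEA detector profile raises the noise multiple to 12 and uses the full
maximum for the amplitude range: field-potential spikes are a few
milliseconds wide, occupy <1 % of samples at 10 kHz (so percentile-based
ranges miss them), and the extreme prominence of pure noise over a 0.1-s
refractory window at 10 kHz reaches ≈9 noise SDs.

BR is defined as 60/mean(R-R) rather than count/duration: it is insensitive
to partial beats at segment edges.  Both are available.  Optional detrending
(moving-median subtraction, window = 3 beat periods estimated in a first
pass) handles baseline wander larger than the drift default; it is off by
default so the noiseless closed forms stay exact.

## MEA channel QC

A channel is rejected if it has fewer than 3 detected spikes, a spike SNR
(median peak height over MAD noise SD) below 5, or a beat count deviating
from the across-channel median by more than 20 %.  The minimum-spike rule is
needed because a noise-only channel yields a handful of detections whose SNR
sits just above the detection threshold; requiring a plausible count
separates them cleanly.  At least 3 accepted channels are required, the
recording BR is the mean of per-channel BRs, and the R-R sequence used for
arrhythmia scoring comes from the single highest-SNR channel to avoid
cross-channel interval-merging artifacts.  Amplitudes never propagate past
the per-channel layer.

## Arrhythmia scoring

Extreme intervals are counted with a strict inequality (R-R > cutoff);
the cutoff is 3 s for the human-cluster profile and 1 s for the murine
monolayer profile.  Interval counts are pooled across recordings within an
arm before the 2×2 test (rates are reported per 1000 contractions per arm);
per-recording counts are also available for sensitivity checks.  The Yates
statistic uses the closed form with the continuity correction clamped at
zero, so near-homogeneous tables give exactly 0 rather than a spurious
positive value; its equivalence with the cell-wise Σ(|O−E|−½)²/E computation
is asserted over random tables.

## Calcium model and kinetics

A transient rises linearly to its peak and decays exponentially.  The
configured `rise_time` is the 10 %→100 % rise (the ramp's full length is
rise_time/0.9), so the measured time-to-peak — onset defined as the last
10 %-of-peak crossing before the peak — recovers `rise_time` directly.
Decay time is peak → 10 % of peak, interpolated between samples; on a pure
exponential it equals τ·ln 10 (a 50 % variant is available).  ΔF/F0 uses
F0 = 10th percentile of the raw trace.

Sparks are Gaussian bumps (default FWHM 80 ms, amplitude 0.3× the transient)
placed uniformly at random in diastolic windows at `spark_rate` per second of
diastole, then thinned to a minimum separation of 2× the spark width: release
sites are refractory, and two bumps closer than their own width are one
physical event — without thinning, ground truth would list events that are
unresolvable in the signal by construction.  Detection smooths the diastolic
signal with a 3-point moving average, estimates noise by MAD on diastolic
samples, and accepts local maxima above 3.8 noise SDs that stay below the
transient threshold (50 % of the robust maximum).  Both thresholds are
signal-relative, so spark detection is invariant to rescaling the trace.
Sparks and transient spans are disjoint by construction of the search mask.

## Drug-response model

The chronotropic effect is linear in log₁₀(concentration), anchored at 1.0
at the lowest concentration of the ladder with slope 0.1 per decade (a ≈30 %
rate increase over a 3-decade ladder, matching the magnitude of a clear but
sub-doubling chronotropic response).  Inotropy is a per-concentration
multiplier, by default non-monotone (1.25, 1.10, 1.20, 1.05) — force rises at
low dose without a log-linear trend.  The extreme-pause rate under drug is
one shared value across concentrations (default 20/1000 vs 2/1000
spontaneous), the defining property of the concentration-independent
phenotype.  Dose-trend regression fits per-concentration mean responses, so a
non-monotone profile inflates the 2-df residual and correctly deflates the
trend test while the log-linear BR trend stays significant.

With pauses active, mean R-R inflation grows with beat rate (a faster
schedule accumulates more pauses per unit time), biasing the recovered BR
slope downward by roughly 13 %; the slope-recovery check therefore runs the
chronotropy-only configuration, and the pause phenotype is assessed by the
contingency layer where it belongs.

## Group statistics

Welch ANOVA, the Brown–Forsythe F* mean-comparison test and Games–Howell are
computed from their closed forms (scipy provides the F and studentized-range
distributions); one-way ANOVA and Kruskal–Wallis delegate to scipy.  Note the
Welch statistic equals the classical F under homogeneity only for k = 2
groups; for k > 2 its denominator correction exceeds 1 at any finite n.
ROUT-style screening applied to a single column of scalars degenerates to a
robust location/scale residual screen (median, 1.4826·MAD) with
Benjamini–Hochberg control at Q (default 1 %) — a faithful simplification of
the robust-regression original for grouped scalar metrics; with n < 3
screening is skipped with a warning.  Parametric and rank-based results are
always emitted side by side; nothing is gated on a normality test.

## Virtual experiment and problem sizes

`run_virtual_experiment` simulates control plus a concentration ladder
(default 10 µM–10 mM, 4 steps), with one baseline and one treatment segment
per recording, detects beats, normalizes treatment metrics to each
recording's own baseline (and second-stage to the control-arm mean), pools
R-R intervals per arm for contingency testing, and optionally adds per-arm
calcium line scans.  Defaults are 8 recordings per arm and 120-s measurement
segments — a desk-scale run of the same design as a full-day protocol with
600-s segments; both are configurable and all conclusions asserted in the
test suite are sample-size-aware (Poisson/binomial tolerances).  Seeds are
spawned per recording from one master seed; reruns are byte-identical, and a
run manifest (config + seeds + version) reproduces the run exactly.

## What the simulator does not capture

The generator is phenomenological: no ionic currents, no excitation–
contraction coupling, no cAMP/ryanodine-receptor kinetics.  Waveforms are
stylized templates; real MCG morphology varies between clusters and over
time, real MEA spikes have richer shapes and field-potential-duration
structure (not analyzed here), and real calcium sparks have 2-D spatial
extent (the kymograph option replicates a 1-D profile with spatial noise).
Noise is Gaussian and stationary; real recordings show movement artifacts and
amplitude rundown.  Passing recovery tests therefore demonstrates that the
analysis chain is correct and calibrated under its stated model, not that
detection thresholds transfer unchanged to any particular instrument — the
thresholds exist as configuration for exactly that reason.
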