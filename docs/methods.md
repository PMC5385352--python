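# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `ccmotion`. Notation: *f* stimulus frequency (Hz), *v*
peak velocity (cm/s), *d* = 1/(2*f*) half-cycle duration (s),
*D* = *v*/(π*f*) movement extent (cm).

## Stimulus model

A section is a sinusoidal oscillation: each movement (turning point to
turning point) has a half-sine speed profile of duration *d* peaking at
*v*; the extent *D* = *v*/(π*f*) is the unique amplitude consistent with
those two constraints. The built-in program has 11 one-minute trials and 31
sections (nine trials of three sections, two of two), drawing six
frequencies and five peak velocities so each level appears at least five
times.

Conventions the program itself leaves open, fixed here:

* **Section durations.** Nominal splits (thirds, or halves for two-section
  trials) are minimally adjusted so every section holds a whole number of
  half-cycles while the trial stays 60 s. All three-section trials keep
  20 s sections (40·*f* is an integer for every design frequency); the
  two-section trials resolve to 30/30 s and 28/32 s. Ties prefer the
  lexicographically smaller duration vector. If no whole-cycle partition
  exists within ±2 s of nominal, nominal durations are kept (the truncated
  half-cycle is smoothed by the join blend) with a warning.
* **Concatenation is position-continuous.** Each section starts at the
  turning point the previous section ended on; the oscillation center
  shifts by half the extent change. This is the integral of concatenated
  half-sine speed pulses, keeps C0/C1 continuity trivially, and leaves
  exactly one acceleration zero crossing (AZC) per half-cycle — which the
  CC definition requires of the stimulus itself. Centering every section on
  a fixed workspace midpoint instead would force position jumps of up to
  ~19 cm into the join blend and inject spurious stimulus AZCs.
* **Joins** are blended over ±250 ms with the cubic (Hermite) polynomial
  matching position and velocity at the window edges. Acceleration inside
  the window is the cubic's (linear) second derivative.
* **Initial phase**: trials start at rest at center − *D*/2, moving
  rightward. Recorded in the section annotations.
* The (0.25 Hz, 46.6 cm/s) cell implies *D* ≈ 59.3 cm, wider than the
  45.5 cm tablet the design assumes; the builder warns and proceeds
  (`strict_workspace=True` turns this into an error). Analyses are
  translation-invariant, so the overflow only matters for rendering on
  physical hardware.

## Preprocessing and registration

Raw (time, position) records are linearly resampled to a uniform grid
(canonical rate 100 Hz — ≥10× the highest design frequency and fine enough
to resolve the 0.15 s timing threshold), zero-phase low-passed with a
2nd-order Butterworth at 5 Hz, then differentiated with a Savitzky–Golay
filter (order 2, 150 ms window); half a filter window is cropped at each
edge. The pre-filter matters: the derivative filter alone amplifies
0.05 cm position noise into ~15 cm/s² acceleration noise, which would
swamp AZC detection, while corrective jitter lives below ~3 Hz and passes
the 5 Hz cutoff untouched. NaN gaps ≤ 100 ms are interpolated; longer gaps
or >5% missing samples are rejected.

Registration estimates a single constant lag (response late = positive) by
maximizing the Pearson correlation of the velocity channels over ±0.5 s at
sample resolution. Continuous time-warping is deliberately out of scope:
per-segment timing differences are measured separately as dT. Samples that
edge-shifting invalidates are flagged, and segments not fully covered by
valid data are excluded from classification rather than classified on
padded data.

## AZC detection and jitter

AZCs are sign changes of acceleration, linearly interpolated to sub-sample
precision; exact zeros inherit the preceding sign so a zero plateau only
counts when the sign actually flips. A hysteresis guard iteratively removes
the *pair* of adjacent crossings bounding any acceleration lobe whose peak
magnitude is below 2% of the trace maximum; this suppresses noise wiggles
while preserving sign alternation, and has no effect on noise-free traces.

Response AZCs are matched one-to-one to stimulus AZCs within ±0.2 s
(slightly above the dT threshold plus a typical sensorimotor delay) by
optimal assignment: maximum matched count, then minimum total time
difference. Unmatched response AZCs are **jitter points**. The jitter
frequency of an interval between consecutive jitter points is half its
reciprocal; the reported peak is the mean of interval frequencies inside
the modal 0.05 Hz histogram bin (ties toward the lower bin), which is exact
for frequencies sitting on bin edges.

## Segments, metrics, CC

Segments are stimulus half-cycles between turning points; at section joins
the boundary moves to join − 0.25 s, so the whole blend window belongs to
the following half-cycle's segment and segments still tile the trial.

Per segment, a local lag ℓ* maximizes the velocity cross-correlation
within ±0.5 s; then

* dT = |ℓ*| (s),
* dV = RMS(v_resp(t+ℓ*) − v_stim(t)) / RMS(v_stim)  (unitless),
* dX = RMS(x_resp(t+ℓ*) − x_stim(t)) / extent(x_stim)  (unitless).

A segment is **CC** iff it contains exactly one response AZC, that AZC is
matched to a stimulus AZC, dV < 0.95 and dT < 0.15 s. %CC is time-weighted
(CC-covered time over classified time), consistent with rendering CC as
periods rather than counts. CC probability per frequency/velocity bin is
segment-weighted: each half-cycle is one Bernoulli trial.

## Similarity and the shuffled null

Per section, participants' binary CC vectors (1 inside CC segments) are
compared pairwise with Hamming distance; the section's distance score is
the mean over all unordered pairs (153 for N = 18). The null redraws each
participant's vector from the same section *position* (first/second/final
third) of a uniformly random trial — trial identity is destroyed, section
position preserved — 10,000 times, averaging scores per section. Vectors
compared across trials of different section lengths are cropped to their
common prefix. The implementation precomputes Hamming fractions for every
(participant, trial) × (participant, trial) pair per section position, so
each shuffle is a table lookup and the full 10,000-shuffle null costs a
few seconds.

Because sections within a trial share a stimulus program, the 31 section
scores are averaged within trial before inference: a two-sided
matched-pair t-test on 11 trial pairs (df = 10), with a 95% CI on the mean
difference. A zero-variance difference is flagged degenerate (t of 0 or
±∞) instead of propagating numerical noise.

## Frequency dependence and cross-experiment comparison

Per-participant OLS slopes of CC probability on bin center feed a
one-sample t-test against zero, one-sided (greater); participants with
fewer than three non-empty bins are excluded with a warning. Free-motion
half-cycles are binned at the design frequencies via measured frequency
0.5/duration, with edges midway between centers and open outer bins; empty
bins are reported as empty (NaN), never as zero probability.

Cross-experiment comparison uses a mixed (split-plot) ANOVA — between
factor experiment, within factor frequency — via `pingouin.mixed_anova`,
with listwise exclusion of subjects missing within-cells and Tukey HSD on
subject means for the between factor. Two conventions: an effect with
exactly zero sum of squares reports F = 0 (the fully degenerate design
would otherwise yield 0/0), and a single within-level design collapses to
a one-way between-subjects ANOVA (whose F equals the squared two-sample t
for two groups).

## The synthetic follower

No public dataset accompanies this tracking design, so the generator *is*
the study population for all end-to-end results; it encodes the
intermittent-control account the analysis is built to detect:

* **Submovements** are minimum-jerk pulses,
  x(τ) = d(10τ³ − 15τ⁴ + 6τ⁵): single velocity peak 1.875·d/T, exactly one
  AZC. Overlapping submovement velocities superpose linearly; position is
  the integral of the summed velocity.
* **Smooth-duration limit**: per half-cycle the follower draws
  T_lim ~ Normal(μ_T = 1.3 s, σ_T = 0.15 s, truncated at 0). If d ≤ T_lim
  it emits one submovement spanning the half-cycle; otherwise it chains
  k = ⌈d/T_lim⌉ submovements through intermediate stimulus positions
  perturbed by Normal(0, 0.05·D) endpoint noise — the velocity dips between
  chained pulses are extra AZCs, i.e. jitter. The stochastic limit
  generalizes the ~1 s ceiling on smooth movements reported in the
  motor-control literature and is placed so 2 s half-cycles (0.25 Hz) are
  essentially never smooth (P ≈ 1.5×10⁻⁶) while 1.33 s half-cycles
  (0.375 Hz) often are (P ≈ 0.4).
* **Planning** is predictive, aligned to stimulus turning points viewed
  through a sensorimotor delay (0.15 s); each half-cycle is planned from
  the follower's current position to the stimulus's next turning point, so
  position offsets cannot accumulate. Onsets carry Normal(0, 0.03 s)
  jitter.
* **Corrections**: every 0.25 s the follower compares its delayed plan
  with the stimulus; a corrective submovement fires with hazard
  0.1 per cm of momentary error per second of observation (and only while
  its onset still lands inside the ongoing half-cycle). Long slow
  movements therefore accumulate corrections — the same mechanism that
  makes low-frequency tracking jittery also grades the non-CC rate across
  the high-frequency bins.
* **Cohorts** draw participant-level parameters from bounded uniform
  ranges around the defaults (μ_T ± 0.1 s, delay ± 0.03 s, endpoint noise
  ± 0.01), keeping the zero-CC-at-0.25 Hz property of the defaults intact.
  **Free dyads** draw frequency and peak velocity per half-cycle from
  configurable ranges (defaults 0.1–1.2 Hz, 15–45 cm/s, velocity capped so
  the extent stays on a 1.5×-half-width track), with the follower tracking
  the improvised leader.

Everything is reproducible from a single integer seed (cohorts spawn
per-participant seeds from the master seed).

### What the generator does and does not emulate

It reproduces the *structural* signatures the pipeline measures: zero CC
at 0.25 Hz, a steep monotone CC–frequency relation with positive slopes
for every simulated participant, stimulus-locked CC placement (real
distance scores far below the shuffled null), jitter frequencies in the
sub-Hz range, and a free-motion CC curve that rises with frequency and
drops off at the top (open) bin. It is *cleaner* than human data: CC
probability saturates near 0.98 at high frequencies (humans plateau lower),
the top two frequency bins differ by only ~0.005 so their ordering is
sampling-sensitive at cohort size 18, overall %CC (~68%) is higher than
human cohorts report, and the peak-velocity effect comes out slightly
negative (larger extents draw more corrections) where humans show a mildly
positive one. Passing tests therefore validate the pipeline's mechanics
and the direction of its effects, not human effect sizes.

## Problem sizes and numerical notes

The test suite and acceptance script simulate the full 18-participant,
11-trial cohort at 100 Hz (~20 s end to end on one CPU) and use 10,000
shuffles in the acceptance script (1,000 in the faster test variants; the
shuffle estimator is determinism- and enumeration-tested separately).
Segment metrics need ≥4 samples and a non-degenerate stimulus segment;
degenerate inputs raise typed errors rather than returning NaNs. All
cross-correlation lag searches run at sample resolution; reported lags are
therefore quantized to 10 ms at the canonical rate.
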