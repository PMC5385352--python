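# ccmotion

Analysis pipeline for **co-confident (CC) motion** in one-dimensional
visuomotor tracking and mirror-game kinematics.

In the mirror-game paradigm two players (or a player and a computer-driven
"virtual leader") improvise synchronized left–right movements. Tracking is
sometimes reactive — riddled with small corrective *jitter* movements — and
sometimes *co-confident*: smooth, synchronized, co-predictive. `ccmotion`
implements the full quantitative chain used to study when CC happens:

1. **Stimulus synthesis** (`ccmotion.stimulus`) — an 11-trial, 31-section
   program of half-sine oscillations. Each section fixes a frequency
   *f* ∈ {0.25 … 0.875} Hz and peak velocity *v* ∈ {20.0 … 46.6} cm/s; each
   movement's speed profile is a half sine of duration 1/(2*f*) peaking at
   *v*, giving a movement extent *D* = *v*/(π*f*). Section joins are blended
   with a cubic matched in position and velocity (C0/C1 continuity).
2. **Kinematics** (`ccmotion.kinematics`) — resampling, low-pass +
   Savitzky–Golay differentiation, constant-lag registration of response to
   stimulus by velocity cross-correlation, and acceleration-zero-crossing
   (AZC) enumeration. A smooth movement has exactly one AZC (its speed
   peak); extra AZCs are the signature of corrective submovements.
3. **CC detection** (`ccmotion.cc_detection`) — per stimulus half-cycle:
   response AZCs are matched one-to-one to stimulus AZCs (unmatched ones
   are *jitter points*; jitter frequency = 0.5/interval), relative errors
   dX, dV and timing error dT are computed, and a segment is CC iff it has
   exactly one matched AZC, dV < 0.95 and dT < 0.15 s.
4. **Similarity** (`ccmotion.similarity`) — are CC placements
   stimulus-locked across participants? Per section, the mean pairwise
   Hamming distance between participants' binary CC vectors (153 pairs for
   N = 18) is compared with a null in which each participant's vector is
   redrawn from the same section position of a random trial (10,000
   shuffles), via a matched-pair t-test over the 11 trials.
5. **Frequency dependence** (`ccmotion.frequency_analysis`) — CC
   probability per frequency/velocity bin, per-participant regression
   slopes with a one-sided t-test, binning of free (two-player style)
   motion at the design frequencies, and a mixed-design ANOVA with Tukey
   HSD for cross-experiment comparison.
6. **Synthetic data** (`ccmotion.synthetic_data`) — an intermittent-control
   follower: minimum-jerk submovements, a stochastic ~1.3 s ceiling on
   smooth-movement duration, sensorimotor delay, endpoint/timing noise and
   error-triggered corrections. It generates whole cohorts and free-motion
   dyads so every pipeline stage is testable without human data.

## Worked example

```python
import ccmotion as cm

cohort = cm.simulate_cohort(n_participants=18, master_seed=1)
analysis = cm.analyze_cohort(cohort)

print(cm.cc_probability(analysis.segments, axis="frequency"))
#      bin  probability  n_segments
# 0  0.250     0.000000        1134
# 1  0.375     0.372714        1422
# 2  0.500     0.916667        1944
# 3  0.625     0.964720        2466
# 4  0.750     0.982103        2682
# 5  0.875     0.984355        3132

slopes = cm.participant_slopes(analysis.segments, axis="frequency")
print(f"t({slopes.df}) = {slopes.t_statistic:.1f}, p = {slopes.p_value:.2g}")
# t(17) = 61.0, p = 1.2e-21

sim = cm.similarity_analysis(analysis.cc_vectors, n_shuffles=10_000, seed=1)
print(f"real {sim.real_scores.mean():.2f} vs null {sim.null_scores.mean():.2f}, "
      f"t({sim.df}) = {sim.t_statistic:.2f}")
# real 0.12 vs null 0.42, t(10) = -9.23
```

Reading: at 0.25 Hz (2 s movements) no simulated participant ever produces
a CC segment — the smooth-duration limit forces every slow half-cycle to be
split into several submovements, i.e. jitter. CC probability then rises
steeply with stimulus frequency; all 18 per-participant regression slopes
are positive. CC placement is strongly stimulus-locked: real
cross-participant distance scores sit far below the trial-shuffled null.

A command-line surface wraps the same functions:

```bash
ccmotion generate-stimuli --out stimuli/
ccmotion simulate-cohort --n 18 --seed 1 --out data/
ccmotion detect-cc --stimulus data/ --responses data/ --out cc/
ccmotion similarity --cc-vectors cc/cc_vectors.json --seed 1 --out sim.json
ccmotion analyze --segments cc/cc_segments.csv --out report/
```

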