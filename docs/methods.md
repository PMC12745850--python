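# Methods

`nyctinast` analyses nyctinastic (day/night) movement of plants — the model
organism is *Mimosa pudica* — filmed under repeating **Light1–Light2–Dark**
lighting cycles: two illuminated "days" followed by one day of continuous
darkness. The scientific question is whether pre-light movement anticipates
the upcoming lighting condition, i.e. whether the plants move more in the
hours before a light onset that will actually happen than before one that
will not.

## Schedule model

A cycle consists of three days of equal length *N* hours. A Light day is
dark for *N*/4, lit for *N*/2, dark for *N*/4; the Dark day is unlit for all
*N* hours. The same clock partition into *pre-light* [0, *N*/4), *light-on*
[*N*/4, 3*N*/4) and *post-light* [3*N*/4, *N*) is applied to every day, Dark
days included — the intervals are defined by the clock, not by the lamp.
Three presets cover the experimental phases:

| phase | day length | cycle span | light on |
|---|---|---|---|
| 1 | 24 h | 72 h | 12 h/Light day (local hours 6–18) |
| 2 | 20 h | 60 h | 10 h/Light day |
| 3 | drawn per cycle | 3·*N* | *N*/2 per Light day |

Phase 3 draws *N* uniformly from a configurable set, by default the even
hours {10, 12, …, 32}. (Published descriptions of the design give the
support both as "10–32 h" and as eleven levels "10–30 h"; the generator
keeps the wider, even-hour reading and the set is a parameter.) All
bookkeeping is in seconds from the phase origin; every interval is half-open
[start, end), so a timestamp on a boundary belongs to the later segment, and
cycle indices are 1-based because the learning curve takes log(cycle).

Useful closed forms used as test oracles: a 24-h span at the 20-s capture
cadence holds exactly 4320 frames; a constant-*N* schedule with a successor
cycle has a maximal continuous dark run of 1.5·*N* h (post-light *N*/4 +
Dark day *N* + next pre-light *N*/4), which is 36 h for phase 1.

## Motion metric and artifact exclusion

Motion between consecutive frames is the mean absolute difference of the
8-bit green channel, the channel in which the plants have contrast. The
series convention is one value per frame (the change *from the previous
frame*), with the first frame flagged invalid. A missing or corrupt frame
invalidates the two differences it touches instead of aborting the run —
long recordings lose the odd frame and the analysis must survive that.

Three artifact classes are excluded before any statistic is computed:

* **lighting transitions** — the camera switches to/from infrared mode and
  produces one enormous spurious difference; the frame at the switch and
  one frame either side are dropped (3 frames per transition);
* **key frames** — periodically fully-encoded video frames create illusory
  change values; every frame at an index multiple of the configured period
  is dropped (no default period: it is a property of the encoder, not of
  the biology, so directory input assumes none);
* **watering** — spraying closes and reopens the leaves for reasons
  unrelated to the light cycle; everything in [start, end + 70 min) of each
  watering event is dropped. The window is closed/open to match the global
  half-open convention, so a zero-duration event at a grid time removes
  exactly 210 frames at 20-s cadence.

Gaussian smoothing (window *w* frames, σ = *w*/6 so the window spans about
±3σ, reflect-padded) is provided for display only; statistics always use
raw valid frames.

## Statistics

**Cell means.** Valid frames are averaged per (cycle × day condition ×
time-of-day) cell; a cell with no valid frames is missing, not zero. The
frame-count-weighted mean of the cells reconstructs the global valid-frame
mean exactly, which is tested.

**Anticipation statistic.** Per cycle,
`difference = (pre-light L1 + pre-light L2)/2 − pre-light Dark`. During
pre-light the plants are always in darkness and have been for at least
*N*/4 h, so any systematic difference between Light-day and Dark-day
pre-light movement reflects anticipation of what follows, not the stimulus
itself.

**Learning curve.** `difference(c) = a·log(c) + b` fitted by ordinary least
squares on log(cycle). The log base defaults to natural log and is
configurable; the reported bases of comparable fits are not standard, and
base only rescales `a`, never r². r² of a zero-variance response is
reported missing rather than 0 or 1.

**Repeated-measures ANOVA.** Within factors: day condition (3 levels) and
time-of-day (3 levels); the observational unit is the cycle; cycle number
(and day length in phase 3) enter as centered continuous covariates. The
implementation uses the balanced within-subject partition: per stratum, the
orthonormal contrast scores of each cycle are regressed on the covariates;
the factor SS is the contrast-mean term, each factor×covariate SS is the
Type-III extra sum of squares, and the residual is the full-model RSS with
`df = df_factor · (n − 1 − p)` for *p* covariates. With 23 cycles and the
cycle covariate this yields residual dfs of 42/42/84 for the three strata,
with 6 cycles 8/8/16, and with 30 cycles and two covariates 54/54/108 —
precisely the error terms of the study design. The frequently quoted
`df_error = (n−1)·df_factor` rule is the same arithmetic with an effective
`n` one less per covariate; the helper `error_df()` exposes that
bookkeeping (42 at n = 22, df = 2). Because the two conventions coincide
numerically there is a single implementation, not two modes. Reduced to the
no-covariate two-way case the partition reproduces `pingouin.rm_anova`
sum-for-sum, which is the independent oracle in the test suite. Partial
eta-squared is SS_effect/(SS_effect + SS_residual) per stratum. Cycles with
any missing cell are dropped listwise. No multiple-testing correction is
applied across simple-effects analyses.

**Day-length stratification.** Per-cycle differences are split by whether
the cycle's day length lies in the anticipation band, default [12, 24] h
inclusive at both ends (12-h and 24-h days behave like the fixed-length
phases); the in-band group also gets a learning-curve fit on the original
cycle numbers.

## Synthetic data generator

The generator is the package's ground-truth instrument; it emulates the
statistical structure of the recordings, not their optics. Per frame the
expected motion is

```
mu(t) = baseline_dark
      + light_boost · 1[lights on]
      + spike_height · exp(−Δframes/spike_decay_frames) after each switch
      + s · δ(c)/2 during pre-light   (s = +1 Light days, −1 Dark day)
```

with `δ(c) = a_true·log(c) + b_true` applied only when the cycle's day
length is inside `anticipation_band`. The symmetric ±δ/2 coding is a
modelling choice — observed data only constrain the Light−Dark difference,
not its decomposition — and makes the expectation of the anticipation
statistic exactly δ(c), so estimator bias is directly measurable. Negative
early-cycle differences arise naturally from `b_true < 0`; there is no
separate mechanism.

Defaults are chosen to sit at the scale of the real group-level series:
dark baseline 0.85 motion units, light boost 0.15, switch spikes of height
2 decaying over ~5 frames, `a_true = 0.10`, `b_true = −0.18`, band
[12, 24] h. Noise has two components: per-frame Gaussian noise
(`noise_sd = 0.05`) and a per-cell Gaussian random effect
(`cell_sd = 0.02`). The split matters: cell means average hundreds to
thousands of frames, so per-frame noise alone cannot produce the observed
cycle-to-cycle scatter of cell means (~0.02 motion units) without a frame-level
σ so large that truncation at zero would distort everything. With the
default split the truncation probability per frame is < 10⁻⁶ and cell means
scatter at the intended scale. Realized motion is expectation + cell effect
+ frame noise, clipped at zero; clipping is a (negligible) bias source by
construction.

What the generator does **not** emulate: thigmonastic touch responses,
free-running circadian drift in constant darkness, slow coloration shifts,
camera auto-exposure, or any pulvinus biophysics. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes; they do
not validate the biological model against real recordings.

`render_frames` draws green leaflet segments whose per-frame angular jitter
is proportional to the commanded motion value on a background that follows
the light state (default 320×180, a 36×-reduced 16:9 frame). The
render-then-extract round trip is monotone: extracted motion increases
strictly across commanded amplitude blocks and rank-correlates framewise at
ρ ≥ 0.9. `inject_artifacts` adds the three artifact classes; injected
watering decays are truncated at the 70-min boundary, the recovery period
the exclusion window is designed to cover, so exclusion restores clean cell
means to machine precision (the paired-run oracle in the tests).

## Numerical and design choices

* Half-open intervals everywhere; boundary frames belong to the later
  segment. Interval boundaries are compared as `4u < N` and `4u < 3N` in
  seconds to avoid floating-point division at boundaries.
* The transition frame is the first frame at/after the switch time
  (half-open convention); it carries the spurious difference.
* Type-III covariate SS are computed by explicit model comparison (drop one
  covariate, refit), so correlated covariates (cycle and day length) are
  each adjusted for the other.
* Learning-curve fits require ≥ 2 distinct cycles; ANOVA requires at least
  `2 + p` complete cycles.
* Pipeline randomness flows from one root seed through named
  `numpy.random.SeedSequence` substreams (schedule draw, simulation), so a
  fixed config reproduces every numeric output bit-for-bit.

## Problem sizes

Simulation-heavy tests and the Monte-Carlo calibrations run the full study
designs (23 × 72-h cycles etc.) at a 60–120-s capture cadence rather than
the camera's 20 s. Cell means are plain frame averages, so the cadence
changes only the per-cell frame count, not the estimand; the package's
Monte-Carlo checks (100-seed parameter recovery, 200-replicate type-I
calibration) are run at these sizes. The rendering round trip uses 300
frames at 320×180.

## Known limitations

* The ANOVA treats the cycle as the observational unit of a single plant
  group, exactly as the group-level design requires; it cannot speak to
  individual-plant variability.
* Covariate effects are modelled as linear in cycle number and day length
  within each stratum; a saturating learning process is only captured
  through the separate log-curve fit.
* Real video input must be pre-extracted to frames (PNG/JPEG); containers
  are not decoded.
* The day-length band analysis assumes one day length per cycle, as the
  randomized design provides.
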