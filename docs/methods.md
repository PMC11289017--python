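# Methods

This note documents the models, parameter choices, and numerical
decisions behind gazebench, and what the simulation-based tests do and
do not establish about real recordings.

## Geometry

Visual angles are computed per axis about the screen centre:
`deg = atan((p − c) · pitch / D) · 180/π`, with the pixel pitch derived
from the display diagonal under a square-pixel assumption (enforced to
0.1 %). The exact 3-D gaze-vector angle differs from the per-axis atan
by well under 0.1° at the default desktop geometry (15″, 1440 × 900,
600 mm), and per-axis angles keep x and y separable for the per-axis
precision metrics, so the simpler convention is used throughout.
Pixel and degree coordinates share the same sign convention (y grows
downward) to avoid silent axis flips. Angular distance is the Euclidean
norm in degree space and is a metric on the screen plane.

## Synthetic recordings

The simulator separates three layers.

**Stimuli.** The grid task places `rows × cols` equidistant targets
(default 7 × 8 inside a 60 px margin) in a seeded random order, one per
trial (1500 ms on, 500 ms gap). The pursuit target moves at constant
per-trial speed (drawn uniformly from 100–400 px/s; each trial's speed
is constant because no speed law is imposed) while its direction angle
diffuses with variance 887 deg²/s, reflecting specularly at the screen
edges; reflection steps are flagged so diffusion can be re-estimated
from unreflected increments. Free viewing presents 18 images for 6 s.
The head tasks use seven roll angles (−15°…15° in 5° steps) and a 3 × 5
yaw target lattice.

**Observer.** Gaze sits on the current target plus white fixational
"tremor" (default SD 0.1°; real fixational noise is temporally
correlated drift + microsaccades, which the white model deliberately
ignores — only centroids and spreads matter downstream). Target changes
trigger 40 ms linear saccade ramps (the battery never analyses saccade
dynamics, so velocity profiles are not modelled). Pursuit gaze follows
the target path delayed by 100 ms and scaled by gain 0.95 about the
screen centre, and holds the final path position after the trial rather
than snapping away — an instantaneous position step at a recording
boundary is both behaviourally wrong and a biased landmark for the lag
estimator. Blinks arrive as a Poisson process (0.1 Hz, 100–250 ms) and
mask both trackers. Confirmation presses follow each grid/head target
offset by N(300, 60²) ms with lognormal durations (median 250 ms,
σ = 0.45, so roughly 6 % exceed the 500 ms rejection bound and exercise
that rule). The ground-truth timeline runs at 500 Hz.

**Trackers.** A tracker samples the truth at its nominal rate with
Gaussian timestamp jitter (clipped at 0.45 sample periods to keep
timestamps monotone), reads the truth at `t − latency`, applies a
constant bias and per-sample Gaussian noise in degree space, and loses
samples to truth blinks, Bernoulli dropouts, and tracker-level blink
episodes. Loss is surfaced either as retained confidence-0 rows with
missing positions (webcam style) or as absent samples (lab style). Two
presets bracket realistic magnitudes and are defaults, not claims:
"lab" (500 Hz, bias (0.3, 0.4)° → norm 0.5°, noise 0.3°, 0.5 %
dropouts, missing-sample loss) and "webcam" (30 Hz, 10 ms latency,
bias (0.6, 0.8)° → norm 1.0°, noise 0.7°, 1 % dropouts, confidence
column, 230 ms clock offset).

Everything is driven by `numpy` seeded generators; a fixed scenario and
seed reproduce results bit-identically.

## Synchronization

The clock lag between streams is the integer shift, on a uniform
auxiliary grid at the higher nominal rate (2 ms at 500 Hz), maximizing
the mean of the x- and y-axis Pearson correlations over jointly valid
grid points; ties break toward smaller |lag|, and fewer than 100
jointly valid samples at every shift is an error. Both axes are
averaged for robustness; window length is simply the stream overlap.
Lag search uses FFT cross-correlations of masked sums, so the cost is
near-linear in stream length. A `whiten` option correlates first
differences instead — useful for two high-rate streams with sharp
saccade landmarks, but off by default because differencing a 30-Hz
stream's linear interpolation degenerates into a staircase and loses
the fine-scale alignment information.

On 600-s pursuit recordings with per-sample noise up to ~0.5° the
estimator localizes an injected offset to within one 2-ms grid step;
the residual error is noise-limited (the correlation peak's curvature
is set by the signal's velocity variance), so shorter recordings or a
piecewise-constant fixation signal widen it to several steps.

Resampling is linear interpolation between valid samples only, marked
invalid outside the stream or when the bracketing valid samples are
more than `max_gap_ms` apart (default 100 ms — shorter than a typical
blink, so blinks are never bridged and cannot leak into the loss or
correlation metrics). The merged series lives on the low-rate stream's
native timestamps; a merged row is valid only where both sources are.
Clock-rate mismatch (linear drift) is out of scope: the lag is one
constant per recording.

## Fixation detection

Dispersion is the maximum pairwise Euclidean distance in degree space —
rotation-invariant, unlike the classic I-DT box measure (x-range +
y-range), which is available as `metric="bbox"` for cross-checks. The
detector is a strict single left-to-right pass (no lookahead, as a
real-time system requires): open at `min_points` (≥ 3) consecutive
valid samples under the threshold; extend while the dispersion stays
under the threshold and its relative increase stays under
`max_relative_change` (0.5 by default; the relative test is waived when
the current dispersion is exactly zero, where a ratio is undefined);
on a relative-change failure alone, slide by adding the new sample and
evicting the oldest if that does not increase dispersion; otherwise
close. Evicted samples remain members of the fixation being built, so
every valid sample belongs to at most one fixation, and an invalid
sample always terminates the candidate. Centroids are member means; an
optional minimum duration (default 100 ms) filters afterwards.

The default threshold of 1.0° suits low-noise signals. In the battery,
thresholds are per-tracker (lab 2.0°, webcam 3.0°) because the expected
max-pairwise spread of a stationary fixation grows with both the
per-sample noise SD and the number of samples in the window; roughly
5× the 2-D per-sample noise SD holds fixations together without
merging adjacent grid targets (whose spacing is ~2.8–4.0°).

Offset-related fixations: a trial's fixation qualifies if the
confirmation press falls inside the fixation interval and lasted under
500 ms, judged per tracker; among several qualifying fixations the one
overlapping the trial interval longest wins — overlap only ranks
candidates and never disqualifies a fixation that starts after the
target offset, since the press itself typically lands there.

## Quality metrics and statistics

Accuracy records carry eccentricity (outer = boundary ring of the grid,
26 of 56 positions; the class map is overridable) and task half (by
presentation order). Across-subject precision uses n−1 SDs per axis
per location and excludes single-contributor locations instead of
imputing (exclusions are reported). Loss in confidence mode is the
share of confidence-0 samples; in missing mode, 1 − observed/expected
with expected = ⌊interval × nominal rate⌋, clipped to [0, 100] %.
Cohort correlations are plain means of per-subject r (Fisher-z
averaging behind a flag); subjects with fewer than 30 jointly valid
rows are excluded. Drift correction estimates the constant offset as
the per-axis median (mean by flag) of centroid − target over ≥ 3
recalibration points, leave-one-out cross-validated; the held-out mean
error is the reported reliability residual.

ANOVAs are full-factorial OLS fits with Type-II sums of squares —
invariant to factor order and appropriate for the mild imbalance left
by excluded trials (Type-II SS only add up to the total on balanced
designs, which is what the additivity test checks). η² is effect SS
over total SS, p values are uncorrected, and an empty design cell
raises an error naming the cell rather than producing an inestimable
decomposition. The paired t test returns (0, n−1, 1) for identical
inputs and raises on zero-variance nonzero differences, which in this
bench always indicate a degenerate simulation. KDE heatmaps use
`scipy.stats.gaussian_kde` with Scott's rule by default, fall back to
an explicit isotropic Gaussian for degenerate point sets, and are
normalized to a peak of 1. The calibration summary is the plain column
mean of the packaged per-participant table rounded to two decimals.

The battery runner wires the stages per subject and task, estimates
each session's lag from the data (the webcam stream is brought onto the
lab clock, which is also the clock the press events live on), and
assembles a summary table (loss mean/SD, correlations, fixation and
offset-fixation counts, accuracy and precision mean/SD per tracker and
task), the accuracy and precision ANOVAs, and the head-task loss
t tests. RMS-S2S is computed within detected fixations so saccade
displacement does not inflate it. Seeds are spawned from a single root
`SeedSequence`, so reports regenerate bit-identically.

## Problem sizes

The study-scale scenario uses 19 subjects and the full five-task
battery. Tests and the end-to-end determinism check run a scaled-down
scenario (3 subjects, 4 × 4 grid, shortened trials) chosen to exercise
every stage, including both ANOVA factor crossings; the lag-recovery
and diffusion-recovery checks use single 600-s pursuit recordings,
where the Monte-Carlo error of the diffusion estimate is about 1 %.

## Limitations

- White tremor and ramp saccades are simplifications; conclusions about
  detector behaviour on real oculomotor noise (drift, 1/f structure,
  microsaccades) require real data.
- The synchronizer models a constant clock offset only; true clock-rate
  drift would need a linear term.
- Passing the simulation-based checks shows the pipeline recovers known
  injected parameters under its own observation model — it does not
  certify the accuracy of any particular physical tracker.
- The battery's per-tracker dispersion thresholds are tuned to the
  preset noise magnitudes; markedly noisier streams need larger
  thresholds (and will pay for them in spatial selectivity).
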