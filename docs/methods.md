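# Methods

This note documents the models, numerical choices and known limitations of
`gazekit`. All positions are degrees of visual angle with the origin at the
screen center, +x right, +y up; pixels appear only at the I/O edges via the
exact arctangent conversion `deg = atan(offset_cm / viewing_distance_cm)`.
Tracking loss is represented in-band as `valid=False` samples carrying NaN
positions; no stage ever interpolates across a gap.

## Imaging

The pupil and Purkinje detectors use double thresholding, 8-connected
components and intensity-weighted sub-pixel centroids; no ellipse fitting.
Pixels strictly below `dark_threshold` form pupil candidates, gated by a
pixel-count range to exclude eyelash shadows and specks; the largest
surviving component wins and its centroid is weighted by darkness
(`threshold − intensity`), which exploits the anti-aliased pupil edge for
sub-pixel accuracy. Because the corneal glint usually sits *on* the pupil,
it punches a bright hole in the dark component; the hole is filled at full
interior weight before the centroid, otherwise the missing area biases the
pupil center by ~0.2 px toward the far side. The glint search runs inside a
circular region of interest centered on the detected pupil (default radius
60 px), keeps components strictly above `bright_threshold`, and picks the
one with the highest peak intensity (ties by integrated brightness).
Either failure yields `ok=False`, which downstream becomes an invalid
sample.

Centers are (x, y) = (column, row) with the origin at the top-left pixel
center and y increasing downward, so that `(U, V) = purkinje − pupil` keeps
U horizontal and V vertical.

The synthetic renderer draws a mid-gray iris (128), a dark pupil disk (20,
radius 30 px) with analytic edge coverage, a Gaussian glint (σ = 2 px,
amplitude 235 so its peak saturates even over the dark pupil), optional
i.i.d. Gaussian pixel noise, and quantises to 8 bits. On this fixture the
detectors recover (U, V) to < 0.3 px with noise SD 8 intensity levels and
are translation-equivariant to < 0.1 px. Real images differ in ways the
renderer does not model — eyelid occlusion, non-circular pupils, uneven
illumination, motion blur — so these numbers bound sensor noise effects
only, not anatomical ones.

## Calibration

The sum-of-squared-distance objective separates into two independent linear
regressions on the design `[U V 1]`, solved in closed form with
`numpy.linalg.lstsq`; a rank check rejects collinear feature sets. Two
sample-selection windows are provided, both with strict (open-interval)
boundary comparisons: `exclusion_window` drops samples within 200 ms of any
target motion (the end of the final dwell counts as a motion, since the
target disappears there), and `arrival_window` keeps samples 200–800 ms
after each arrival. For jump schedules with a 1000 ms dwell the two
selections coincide. The fit report carries SSE and the per-target mean
Euclidean error whose nine-location average is the conventional ≤ 0.8°
acceptance check. No outlier trimming or sample weighting is applied.

## Filtering and velocity

The low-pass is a third-order Butterworth applied forward and backward
(`scipy.signal.filtfilt`), giving zero net phase and an effective magnitude
equal to the single-pass magnitude squared. Edge transients are controlled
by odd-reflection padding of length 3·(order+1) (capped at segment length −
1). Valid segments are filtered independently; segments shorter than
3·(order+1) samples pass through unfiltered and are reported to the caller.
Requesting a cutoff at or above Nyquist raises — at 120 Hz sampling a 60 Hz
cutoff removes nothing, so filtering is simply skipped at that rate.

The discrete filter is designed by the standard prewarped bilinear
transform, so its squared magnitude is exactly `1/(1 + (ν/ν_c)⁶)` with
`ν = tan(πf/f_s)`; tests verify measured attenuation against that closed
form (to ~1e-15 on interior samples) and verify the unwarped analog curve
only approximately near the cutoff, where frequency warping contributes up
to ~0.02 at 50 Hz under 500 Hz sampling.

Speed is the central difference of position over *actual* timestamps
(one-sided at segment ends), in deg/s; recorded intersample intervals
jitter, and using the nominal rate would bias velocities on slow hosts.
Speed is undefined (NaN) on invalid samples and never bridges a gap.

## Event detection

Maximal runs of samples with speed strictly above the threshold become
candidates; a run's onset/offset are the timestamps of its first/last
supra-threshold sample and its duration their difference. Candidates
shorter than the minimum saccade duration are discarded; a single
left-to-right pass then merges consecutive candidates whose gap is strictly
below the minimum fixation duration (the merge is idempotent and its output
gaps are all ≥ the threshold). Merged saccades take their amplitude from
the positions at the merged onset and offset, not the sum of sub-saccade
amplitudes. Complementary intervals become fixations with
valid-sample-centroid positions; the minimum fixation duration acts only as
the merge criterion and never deletes short terminal fixations.

An event is flagged `unreliable` when it contains an invalid sample *or
directly abuts one*: a gap can truncate a run and hide its true boundary,
so an event whose edge touches a gap cannot be trusted either. Trial
classification treats an unreliable first saccade as a detection failure.

Whether detection runs on the filtered or raw trace is the caller's choice;
the recommended (and CLI) behaviour is to filter at 60 Hz when the sampling
rate exceeds 120 Hz. A threshold detector systematically reports onsets
~2–4 ms late relative to true motion onset (the velocity must climb to
threshold, and the first supra-threshold *sample* lags the crossing by up
to one interval) and clips a few hundredths of a degree from each end of a
saccade; both effects are visible in the recovery numbers below and are
properties of the method, not bugs.

## Trial analysis

The first saccade with onset ≥ the target-onset message time (closed
boundary) is scored. A trial is valid iff that saccade exists, is not
gap-flagged, has latency inside the closed 100–600 ms window, and lands
within 2.0° (inclusive) of the expected position — the target for
prosaccades, its point reflection about fixation for antisaccades. Checks
run in that order, so each trial gets exactly one rejection reason.
Fixation accuracy is the mean distance between valid gaze samples and the
target in a half-open [+250, +750) ms window after each target jump; empty
windows are skipped and reported. Task summaries use valid trials only;
the removal fraction is exactly 1 − n_valid/n_trials.

## Simulator

The simulator emulates the recording side of the three tasks the analysis
targets, with every random draw flowing from one mandatory seed (identical
config + seed ⇒ bit-identical CSV).

* **Kinematics.** Saccades follow a raised-cosine velocity profile
  `v(t) = (A/D)(1 − cos 2πt/D)` with peak `2A/D` and a linear main-sequence
  duration rule `D = d0 + d1·A`, defaults 20 ms + 2 ms/°: a 4.2° saccade
  lasts ≈ 28 ms and peaks ≈ 295 °/s, typical of human main-sequence data.
  Fixations are the current goal plus isotropic Gaussian noise (default
  SD 0.1°, the precision of a good video tracker).
* **Tasks.** Antisaccade: blocks alternate anti/pro instruction, four
  4.2° target directions balanced within each 20-trial block, fixation
  durations drawn from {1000…1500} ms, trials 3 s long. Gap/overlap: five
  fixation-offset offsets {−200…+200} ms and two directions balanced per
  block; default generative latency means 160/175/195/220/240 ms (SD
  30 ms) increase monotonically from gap to overlap, the canonical effect.
  Grid: each trial visits 11 distinct nodes of a 6×6 grid with 2.7°
  spacing, dwelling 1 s per node. Latencies are truncated-normal on
  [80, 700] ms (ex-Gaussian available); draws whose saccade would overrun
  the trial are resampled and logged.
* **Sampling imperfections.** Timestamp jitter is i.i.d. Gaussian noise on
  each intersample interval, so the configured jitter SD is directly the
  interval SD a recording diagnostic should recover. Frame drops are
  i.i.d. Bernoulli deletions. Tracking loss is a two-state Markov chain
  (per-sample entry probability, mean gap duration), producing the
  contiguous `valid=False` runs real Purkinje dropouts show.
* **Feature and image streams.** Inverting a calibration model maps the
  degree-space trace to camera features; rendering those features as glint
  displacements around a fixed pupil produces ocular image sequences, so
  the imaging → calibration → filtering → detection → analysis chain can be
  exercised end to end against generative truth.

What passing tests on this simulator show — and what they do not: they
verify the pipeline's algebra, conventions and noise behaviour under a
smooth, single-saccade-per-event model. Real data add corrective saccades,
smooth pursuit, blinks with recovery artifacts, pupil-size changes and
head-motion residuals, none of which the generator emulates.

## Problem sizes and numerical conventions

The shipped verification suite uses: 50 random models (noiseless
calibration recovery, tolerance 1e-9 relative); exhaustive detector
equivalence on all supra-threshold patterns up to 12 samples plus 10,000
random patterns up to 20 samples against a literal reference
implementation; 200 injected saccades (2–10°) per sampling rate at
120/250/400/500 Hz for detection recovery (recall ≥ 95%, onset error ≤ one
interval + 12 ms, median amplitude error ≤ 0.3°); ten sines at 5–50 Hz for
the zero-phase checks; a 40-trial fixture with six planted violations for
classification; twenty 400-trial gap/overlap sessions for latency recovery
(per-condition means within 2·SEM of generative means in ≥ 90% of
condition×session cells — the detector's few-ms onset lag consumes much of
that margin, so this check sits near its own Monte-Carlo noise floor); 1e5
window samples for the Rayleigh closed form σ√(π/2) (3%); and a 50-pose
rendered sweep for feature recovery (0.5 px). Percentiles interpolate
linearly between order statistics; sample SDs use n−1; window and
threshold boundary conventions are as stated above.
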