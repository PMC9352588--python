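# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and the
known limitations.

## Stimulus kinematics

Virtual conspecifics are black dots whose position is updated either on
every display frame ("continuous") or once per bout period 1/*f*
("bout-like", instant jumps).  Displacement bookkeeping is done in arc
length, so the time-averaged speed over any whole number of bout periods
equals the configured average speed exactly, and the revolution time of
a circular path is 2πr/v̄ independent of bout frequency (22.6 s at
5 mm/s, r = 18 mm).

**Angular conversions.**  Angular *size* uses the exact subtended-angle
formula 2·atan(d/2r); angular *speed* and *acceleration* use the
arc-length (small-angle) conversion v/r and a/r.  This mixed convention
is the only one consistent with every printed conversion pair of the
rig's stimulus set (e.g. 4 mm → 12.7°, 5 mm/s → 15.9°/s,
12 m/s² → 38.2 × 10³ °/s²).  The update interval is floored to integer
milliseconds (666 ms at 1.5 Hz), matching projector frame arithmetic.
An instant jump occupies exactly one display frame, so its acceleration
is d/Δt² with d = v̄/f and Δt the frame period; this reproduces all five
printed (speed; acceleration) pairs at 1.5 Hz and 60 fps.

**Gaussian bout profiles.**  A bout with controlled peak acceleration is
a Gaussian speed pulse per period, amplitude normalized so the mean
speed over the period is exactly v̄ (discrete normalization on the
sampled grid).  The pulse is truncated at ±3σ with the pedestal value
subtracted, keeping the series continuous at the truncation edge —
otherwise the edge step would dominate finite-difference acceleration.
With the pulse mass k = ∫±3 (e^{−u²/2} − e^{−9/2}) du ≈ 2.4332, the
width follows in closed form from the requested peak acceleration a:
σ = √(v̄ T e^{−1/2} / (k·a)).  A zero-floor pulse cannot have a peak
acceleration below ≈ 6v̄/T; shallower targets (the 0.02 m/s² condition)
are realized as a Gaussian speed *ripple* around the mean with σ = T/6
and amplitude set by the target slope.  The two regimes coincide at the
threshold, and all five study accelerations {0, 0.02, 0.5, 2, 12} m/s²
are reproduced within 0.01% on a dense grid.  Requests narrower than one
frame interval are clipped to it with a warning.

**Trefoil path.**  The three-lobed closed curve
(x, y) = s·(sin t + 2 sin 2t, cos t − 2 cos 2t)/3 (maximum radius = s)
is reparameterized to uniform arc length on a 20 001-point grid and
sampled per motion profile.  Chord speed equals arc speed to < 0.5% for
continuous sampling; instant jumps keep exact arc bookkeeping but chords
shorten slightly on high-curvature lobes.

**Trajectory smoothing** convolves each coordinate with a unit-sum
Hamming window (length 20, valid mode; output length n − 19), the
standard de-jittering step before heading computation on naturalistic
replay trajectories.

## Shoaling metrics

Tracks are uniformly sampled (nominally 30 fps) dish-centred positions
in mm.  **Attraction** compares the real mean inter-animal distance per
non-overlapping 5-min chunk (IADr, trailing partial chunk dropped)
against a time-shift null: the neighbour trajectory is cyclically
shifted within the chunk by k·chunk/11 for k = 1..10 (minimum shift
≈ 27 s, symmetric coverage, no near-zero shifts) and IADs is the mean
over shifts.  attraction = (IADs − IADr)/IADs per chunk; the per-animal
value is the mean over chunks (chosen over frame pooling; chunks weight
time equally).  The statistic is invariant under rigid motion of both
tracks and ≤ 1 by construction.

**Neighbour maps** histogram neighbour positions in the focal animal's
heading-up egocentric frame (60 × 60 mm, 1 mm bins — fine enough to
resolve the 3 mm smoothing kernel).  Heading comes from the track when
present, otherwise from frame-to-frame displacement; samples moving
< 0.1 mm/frame have no defined heading and are skipped (tallied).
Out-of-extent samples are discarded but counted.

**Repulsion** smooths the map with a Gaussian (σ = 3 mm), takes 24
equally spaced radial scans from the centre to 29 mm — each scan
averaging 5 parallel rays spanning a 5 mm width, bilinear
interpolation — and averages them.  With r_peak the radius of maximum
density, the score is the area between the peak level and the scan at
r < r_peak, divided by the 29 mm scan length ("area above the average
line scan" read as the deficit left of the peak; stated explicitly
because the phrase admits other readings).  A centre-peaked map scores
exactly 0.

**Bouts** are contiguous spans of frame-to-frame speed above an adaptive
threshold (median + 3·raw MAD + 10⁻⁶ mm/s; the tiny floor keeps a
perfectly steady glide at zero bouts).  One span = one bout; duration is
the span length, time the speed peak within it.  **Escape**: a looming
trial counts as an escape when the path length in the 1 s after the loom
exceeds twice the path length in the 1.3 s before; trials with truncated
windows are excluded.

## Neural tuning

Traces are raw fluorescence, ROI × time at 1 volume/s (after fivefold
mean-downsampling from 5 volumes/s acquisition).  ΔF/F uses the mean
fluorescence over the 5 s before onset as F₀; ROI-presentations with F₀
below 1% of the ROI's median fluorescence are flagged invalid rather
than producing unbounded values.  Mean responses average across
presentations of a stimulus first (per time point, over valid
presentations), then over the full 22.6 s stimulus window.

The **responsiveness filter** computes, per stimulus, the given
percentile of that stimulus's responses across ROIs and keeps ROIs
strictly exceeding the cutoff for at least one stimulus (95 for
volumetric juvenile data, 90 for the ablation dataset, 50 for
single-plane larvae; the reference distribution is per-stimulus across
ROIs — a documented, configurable choice).

**BPI** contrasts category means (bout-like 0.75–3 Hz vs continuous
6–60 Hz, irrespective of size or direction).  Negative mean responses
are allowed; BPI may then leave [−1, 1] and is reported with an
`out_of_range` quality flag, but BPN status remains simply BPI > 0.5.
A zero denominator yields an undefined BPI with reason code.  The
classification wrapper `classify_bpns` additionally requires the total
category response (bout + continuous mean ΔF/F) to exceed a floor
(default 0.1): an ROI below it has no measurable response, and a BPI
computed from its noise is a coin flip — this floor plays the same role
as responsiveness thresholding while keeping sensitivity accounting
against ground truth meaningful.  A percentile filter that keeps only
the top 5% per stimulus cannot, by construction, pass a selective
population comprising 15% of ROIs.

**Tuning peaks** interpolate the support points with a degree-2
interpolating spline and take the argmax over the support interval
(boundaries allowed).  Frequency axes are interpolated in log₂(f):
supports span 0.75–60 Hz and a linear axis degenerates the spline's
peak.  Duplicate support points are rejected.

A known small bias: with a 7 s calcium kernel and 20 s inter-stimulus
gaps, residual calcium decays into the next baseline window.  The offset
is deterministic given a schedule and shifts the population-mean BPI of
untuned responders by ~+0.01 — the same order as the near-zero
population means seen in real recordings.  It is a property of the
measurement, not of the index.

## Anatomical density

Cell coordinates (µm, reference-brain space) are split at the midline
(x ≤ midline → left; the tie goes left deterministically) and a separate
Gaussian KDE (bandwidth 10 µm; 14 µm for 7 dpf larvae) is fitted per
hemisphere with the points it contains; each kernel is evaluated over
its hemisphere's in-mask voxels, scaled by its point count, and the
merged field is rescaled so that Σ density · voxel volume equals the
total point count (mask first, then normalize).  Densities are per µm³
internally and reported per 1000 µm³.  The default evaluation grid is
2 µm isotropic, configurable; mass conservation holds to < 10⁻⁶
relative on any grid.  Contours binarize the field at thresholds (0.1,
0.15, 0.3 cells per 1000 µm³ by default), take a maximum-intensity
projection per anatomical axis, and trace marching-squares contours;
higher-threshold contours nest inside lower ones.  Region fractions
assign each point to the region mask covering its nearest voxel, with an
explicit `unassigned` catch-all so fractions always sum to 1.

## Activity (c-fos) quantification

The activity channel is divided voxelwise by the pan-neuronal reference
channel; the depth attenuation common to both channels cancels in the
ratio.  Voxels whose reference falls below 1% of the in-brain median are
masked (NaN) instead of producing unbounded ratios.  No smoothing on the
quantification path.  Bulk cluster signal is the mean ratio over a
cluster's valid voxels.  Cohen's d uses the pooled-SD convention
(negative = below the no-stimulus baseline); tests are two-tailed
two-sample t-tests (Student by default, Welch available), with
significance tiers at p < 0.05/m, 0.01/m, 0.001/m where m is the number
of stimulus-vs-baseline comparisons within each cluster (m = 3 for the
full condition set).  Effect profiles are clustered with average-linkage
Euclidean hierarchical clustering; rows with any undefined d are dropped
(reported), not imputed; leaf order is SciPy's deterministic ordering.

## Synthetic data

The generators define the package's test conditions; all are
bit-reproducible under a fixed seed.

**Dyads** are minimal bout-based kinematic swimmers in a 100 mm dish:
bouts at 1.25 Hz (jittered intervals), displacement per bout v̄/f so the
mean speed is the configured 5 mm/s, heading a noisy random walk
(SD 0.7 rad/bout), reflective dish boundary.  The follower corrects a
fraction (the attraction gain, default 0.8) of its bearing error toward
the partner when beyond the preferred distance (12 mm) and steers away
inside the exclusion radius (6 mm; 8 mm in the repulsion tests).  Bouts
are simulated event-wise and rendered to 30 fps with each bout executed
over 0.2 s.  This is a test harness for the metrics — it makes no claim
about fish locomotor control, has no speed modulation, glide dynamics or
social-memory state, and its wall behaviour is a simple turn-to-centre
rule.

**Calcium populations** contain selective neurons (log-Gaussian
frequency tuning, centre 1.2 Hz, width 1 octave), flat responders and
silent neurons (selective fraction 0.15; half the remainder flat).
Stimulus drive is filtered by a single-exponential kernel (τ = 7 s,
instantaneous rise — rise kinetics are irrelevant to 22.6 s window
means), Gaussian noise is added at 5 volumes/s in ΔF/F units (default SD
25% of the response amplitude), and traces are mean-downsampled
fivefold.  Not emulated: motion artefacts, neuropil contamination,
bleaching, Suite2p segmentation errors — passing tests show the
*analysis* recovers planted tuning under realistic noise, not that
segmentation-stage artefacts are handled.

**Volumes** build the reference channel from a smooth base field times
exp(−z/λ) depth attenuation (λ = 150 µm) and a per-animal global gain;
the activity channel multiplies it, inside each cluster mask, by
1 + s·(d + ε) with s the between-animal SD (0.15) and the per-animal
deviates ε standardized within each group — so the planted Cohen's d is
realized in-sample at the configured group size, separating the
pipeline-recovery question from t-test sampling power.  Voxel noise
(2%) is negligible after cluster averaging.

## Problem sizes and runtimes

Defaults used by the test suite and the acceptance script: 6000 s
independent dyads (20 attraction chunks) and 1200 s follower dyads at
30 fps; 1000-neuron populations with 4 presentations per frequency
(~15 min of recording at 5 volumes/s); 40 × 40 × 20 voxel volumes at
8 animals per condition; 4 µm KDE grids over ~200 µm volumes.  The full
suite runs in well under a minute on one CPU; the acceptance script in a
few seconds.

## File formats

Tracks and schedules are CSV (`t_s,x_mm,y_mm[,heading_rad]`;
`onset_s,duration_s,label[,freq_hz]`), trace matrices CSV with a JSON
sidecar carrying the sampling rate, volumes multi-page float32 TIFF with
a JSON sidecar carrying the voxel spacing in µm.  Units are fixed per
format (mm, s, µm) and validated at load; image volumes are
voxel-indexed with spacing metadata; egocentric outputs use +y =
heading-up.  CSV reads use round-trip float parsing so a
convert-identity is byte-exact.

## Limitations

* The follower model and all generator defaults are package choices, not
  fitted to behavioural data; recovery tests validate the metrics, not a
  behavioural theory.
* Image registration, ROI segmentation and mask drawing are upstream of
  this package: coordinates, masks and traces arrive registered.
* The repulsion score depends on the smoothing kernel and scan geometry;
  values are comparable within a fixed parameter set only.
* On flat density plateaus the scan's argmax (r_peak) is arbitrary
  within the plateau; the score is unaffected because the deficit
  integrand vanishes there.
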