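# Methods

This note documents the models, conventions and numerical choices behind
each pipeline, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Conventions

Frame `i` occurs at `t = i / frame_rate`, frame 0 at `t = 0`. Light/dark
phase intervals are half-open `[start, end)`, so a frame on a boundary
belongs to the later phase; this makes per-phase aggregation unambiguous.
Input positions may arrive in pixels (with a per-file flag) or physical
units; conversion happens once, at load, with `mm_per_pixel` for trajectory
data and `um_per_pixel` for cardiac/flow imaging. Readers reject NaN and
physically impossible values (negative O₂, short axis exceeding long axis)
rather than imputing, and malformed TrackMate sub-header rows are dropped
and counted, never silently.

## Locomotion

Step speed is `‖p_{i+1} − p_i‖ · frame_rate / gap`, with the frame gap in
the denominator so tracker dropouts do not inflate speeds. Each step accrues
its length to exactly one velocity band — inactivity below 0.5 mm/s,
cruising from 0.5 to 20 mm/s inclusive of both boundaries, burst strictly
above 20 mm/s — so band distances sum to the path length by construction.
The boundary assignment follows the banding's inclusive wording ("0.5 to
20 mm/s"); only strict exceedance is burst.

Burst *events* are a separate endpoint with a pixel-based threshold
(default 20 px/s, converted via `mm_per_pixel`): an event is a maximal
contiguous run of steps at or above threshold, assigned to the phase where
it starts, reported as events/min of that phase.

Rotation scoring works on headings of consecutive displacements after a
jitter gate (steps shorter than 0.05 mm are merged forward, because
sub-pixel displacements carry no directional information). Signed turn
angles are accumulated; a rotation is complete when the accumulated turn
reaches 360° with consistent sign *and* the maximum pairwise distance among
the arc's vertices exceeds the 2 mm diameter gate. The 60° "back angle" is
interpreted as a reversal tolerance: an opposing turn larger than it aborts
the rotation in progress and starts a new arc — the only self-consistent
reading that uses an angle, and it is exposed as a parameter. The diameter
uses the maximum pairwise vertex distance rather than an enclosing-circle
fit: it is simple, monotone in arc size, and has no degenerate
configurations. A tolerance of 1e-6 degrees on the 360° completion test
absorbs the rounding of turn angles assembled from floating-point headings.
Counter-clockwise is the mathematically positive direction in the (x, y)
plane; if the source coordinate system is image-like (y down), cw/ccw swap,
which matters only for labelling, not counts.

Per-phase-type endpoints are arithmetic means over that phase type's
occurrences (the photomotor protocol repeats each phase four times).

## Cardiac

Beats are local minima of the short-axis signal — peak contraction, the
sharpest and most detectable landmark — after a 5-frame moving average
(25 ms at 200 fps; minimal smoothing that preserves timing, exposed as a
parameter). Peak picking enforces a minimum separation of `60/max_rate`
seconds and a prominence of 20% of the signal's peak-to-trough amplitude;
beat times are refined by parabolic interpolation around each extremum,
giving sub-frame (< 5 ms) timing. The A–V and V–A intervals therefore use
contraction landmarks; if relaxation landmarks are preferred the same
machinery applies to the signal's maxima, but contraction extrema are
sharper and were chosen as the default.

Chamber volume uses the prolate-spheroid convention `V = (π/6)·L·W²` with
both minor axes equal to the short-axis diameter; 1 pL = 1000 µm³. The
constant is the conventional choice for zebrafish chamber measurements made
on a single optical plane; an oblate variant can be configured by swapping
axis roles upstream.

End-diastole is the frame of maximal short axis between successive beats,
end-systole the minimal short axis between successive diastoles; EDV and
ESV average the per-cycle volumes (robust to slow drift, unlike a global
max/min). ESV exceeding EDV after averaging raises a data-quality error,
since it can only arise from mis-detected beats. CO = SV × HR holds exactly
by construction, with HR taken from the ventricular series.

Poincaré SD1/SD2 use *population* variance over the lag-1 pair set, which
makes the identity `SD1² + SD2² = Var(xᵢ) + Var(xᵢ₊₁)` exact and therefore
testable to machine precision; with n ≥ 25 intervals the difference from
the sample-variance convention is under 2%.

## Respirometry

The corrected series is `o2_fish(t) − (o2_blank(t) − o2_blank(t₀))` on the
union of both wells' sample times inside the analysis window (linear
interpolation, never extrapolation). Any drift common to all wells — sensor
temperature response, surface exchange — cancels exactly when linear and to
interpolation accuracy otherwise. Both standard closed-respirometry
readouts are reported, the windowed ΔO₂ and the negated least-squares slope
in ppm/min, because "relative oxygen consumption" is not a uniquely defined
statistic; consumers pick one downstream. No body-mass normalisation is
applied (larvae are not weighed in this assay class).

## Hemodynamics

Per-step cell speeds are pooled within a recording; tracks shorter than two
rows are warned about and skipped. The mean velocity is the mean over all
step speeds. The *maximal* velocity is the peak of the per-frame mean
time-course smoothed by a centred 5-frame moving average — a raw per-spot
maximum would be dominated by localization jitter (a single 0.5 µm error at
200 fps is a 100 µm/s speed spike). The window is exposed; larger windows
can only lower the reported peak on pulsatile data. Speeds are unsigned
magnitudes; no vessel-axis projection is attempted since no vessel geometry
is available in the track table.

## Group statistics

Dunn's z uses pooled mid-ranks with the tie-corrected variance
`N(N+1)/12 − Σ(t³−t)/(12(N−1))` and Bonferroni adjustment over all pairs
(conservative and reproducible; Šidák is switchable). Fisher's LSD is the
protected form: pairwise t on the pooled MSE with N−k df, reported
unadjusted, with letters separating groups only when the omnibus F is
significant. The two-way ANOVA uses Type II sums of squares (well defined
for unbalanced layouts without an ordering assumption) via statsmodels.
Compact letter displays use insert-and-absorb; an explicit checker verifies
on every output that letter sharing coincides with pairwise
non-significance. All-identical data short-circuit to H = 0 with all pairs
non-significant, and zero within-group variance with unequal means is
reported as F → ∞, p → 0.

## Synthetic data

The generators emulate the raw inputs of a typical larval study —
photomotor trajectories over an 80-min alternating light/dark schedule,
two-chamber 200-fps/10-s heart recordings, 80-min O₂ plates sampled once a
minute, and 10-s blood-cell track tables — with defaults chosen to be
physiologically plausible for 3–5 dpf larvae: light/dark cruising speeds
1.5/3.0 mm/s (dark hyperactivity ×2), heart rate 150 bpm with 10 ms
beat-interval variability, AV delay 80 ms, ventricular geometry
100×50 → 90×40 µm, O₂ starting at 8 ppm declining ~0.03 ppm/min per larva
over a 0.01 ppm/min plate drift, and dorsal-aorta flow 500 + 400·max(0,
sin 2π·2.5t) µm/s. All generators are bit-for-bit deterministic given a
seed, with per-subject substreams spawned from it.

Design choices that make ground truth exact rather than approximate:

* Beat intervals follow a stationary AR(1) process with configurable lag-1
  autocorrelation ρ, so the SD2 > SD1 asymmetry is reachable and the
  Poincaré estimator is testable beyond the i.i.d. case. Chamber axes sit
  at the diastolic geometry and dip to the systolic geometry in a
  raised-cosine bump centred on each beat, placing the short-axis minimum
  exactly at the programmed beat time.
* Rotation bouts are polygonal loops entered and exited *tangentially*: k
  full loops contribute exactly k·360° of turning and leave the heading
  unchanged, so programmed counts are exact for noise-free input. Loops
  replace walk steps in place, keeping phase boundaries frame-aligned.
* When burst bouts are requested, baseline step speeds are clipped just
  below the burst threshold and loop polygons are refined until loop steps
  are sub-threshold, so programmed burst-run counts are exact ground truth.

What the simulators do **not** emulate: well-wall interactions and
thigmotaxis, tracker identity switches and dropouts (gaps are supported by
the pipeline but not generated), heart-rate drift within a recording,
sensor-spot calibration error, out-of-plane cell motion, and any
pharmacokinetics — treatment groups are plain multipliers on generator
parameters. Passing recovery tests therefore demonstrates correctness of
the endpoint computations under clean acquisition, not robustness to every
artefact of real video tracking.

One subtlety found while designing the end-to-end study check: with a fixed
10-s recording, changing mean heart rate changes the *number* of beats and
hence the sampling distribution of interval statistics such as SD1, so SD1
is not a valid "untouched" endpoint in a study whose treatment multiplies
HR — a rank test at n = 20/group reliably notices the change in estimator
spread. The end-to-end study therefore uses endpoints whose generating
process is genuinely identical across groups (programmed burst rate,
blank-corrected O₂ slope) as its negative controls.

## Problem sizes

The shipped tests and the acceptance script run scaled-down but
structurally faithful versions of the assays: four 60-s photomotor phases
instead of eight 10-min ones (the per-phase endpoint definitions are
length-invariant), 10-s heart and flow recordings at 200 fps as in the
protocol, 100-replicate study simulations at n = 20/group, and 5000-dataset
null calibrations at n = 10/group. These sizes keep the full suite in the
tens of seconds while leaving every estimator operating in the same regime
(tens of beats, thousands of steps, ~80 O₂ samples) as the full-length
assays.

## Known limitations

* The rotation definition (accumulated-turn with diameter gate and back
  angle) is one self-consistent reading of the tracker vendor's
  undocumented counter; absolute counts on real exports may differ from the
  vendor's, though within-study contrasts should be preserved.
* Burst events are computed on centroid speed; activity metrics based on
  pixel-change counts are out of scope.
* The ellipsoid volume model assumes two equal minor axes measured on one
  optical plane; true chamber eccentricity biases EDV/ESV jointly, largely
  cancelling in EF and SF.
* A–V/V–A intervals use contraction landmarks (see Cardiac above).
* O₂ traces are used as-is in ppm; Stern–Volmer sensor calibration and
  temperature compensation belong upstream.
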