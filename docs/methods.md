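# Methods

This note records the models, conventions and numerical choices behind
kinassess, and what the synthetic validation does and does not demonstrate.

## Coordinate conventions and the kinematic chain

All analysis happens in an anatomical body frame: x sagittal (forward),
y vertical (up), z transverse (to the participant's right). Raw camera
coordinates must be converted with a rigid calibration (rotation + origin,
accepted in the trial manifest) before analysis, because every angle
definition assumes these axes. Twelve joints are tracked: head, three spine
joints, and shoulder/elbow/wrist/hand on both sides — the subset that the
angle definitions actually use.

Per frame, the unit vectors are `SE` (shoulder→elbow), `EW` (elbow→wrist),
`WH` (wrist→hand) on the assessed side, `SH` (right→left shoulder line,
always right→left regardless of side), and `TR` along the trunk. The trunk
vector runs spine_base→spine_shoulder by default — the longest spine segment,
hence the least sensitive to per-joint noise — with spine_mid→spine_shoulder
available (`kin.trunk_joints`), since either choice is defensible.

## Angles

With dot products clamped to [−1, 1] (so every angle is in [0°, 180°] for any
finite input):

* SF = acos(−u_y · SE), SA = acos(u_z · SE), EF = acos(SE · EW)
* WF = acos(EW · SH) in the `printed` dialect, acos(EW · WH) in the
  `hand_segment` dialect
* TT = acos(u_z · TR)
* TF / TL = acos(u_y · TR_proj) with TR projected onto the sagittal (x–y) /
  frontal (z–y) plane and renormalized

For a left-side assessment u_z is mirrored so SA and TT are side-symmetric;
mirrored motion yields identical values on either side.

Two definitions are deliberately shipped in parallel and echoed in output
provenance, never substituted silently:

* **WF dialect.** The conventional shoulder-line form (`printed`, the
  default) does not involve the hand segment at all, so it measures
  forearm-vs-shoulder-line orientation rather than an anatomical wrist angle;
  the `hand_segment` form is the literal wrist flexion. The synthetic
  generator drives the hand-segment angle, so recovery of a wrist target is
  asserted only under that dialect.
* **Torsion.** TT as defined above measures trunk obliquity relative to the
  lateral axis: it responds to lateral lean (it is ~90° − TL for small tilts)
  and not at all to axial rotation of the shoulder girdle. A true
  transverse-plane girdle rotation measure is provided separately as
  `shoulder_line_torsion`.

## Preprocessing and differentiation

Joint coordinates are filtered with a 3rd-order low-pass Butterworth at 6 Hz.
The filter is applied forward and backward by default (`filter.zero_phase`),
so segmentation timing carries no phase lag; the squared magnitude response
means the single-pass −3 dB point becomes −6 dB. Signals are extended by
reflection at the ends; trials start and end at rest, so edge transients are
benign. Filtering happens on coordinates before any vector/angle computation;
derivatives are then taken on the derived series.

Tracking dropouts are linearly interpolated per joint up to
`gaps.max_gap_s` (default 0.2 s); longer gaps, or gaps touching the trial
boundary, abort the trial with a diagnostic.

Derivatives use compact second-order finite differences (central stencils in
the interior, one-sided of the same order at the ends). This matters for the
jerk: repeated two-point differencing biases the normalized-jerk integral by
several percent at 100 Hz through boundary contamination, whereas the compact
stencils reproduce the closed form to <0.1% at 100 Hz and ~0.6% at 30 Hz.

## Phase segmentation

The reference angle is sagittal-plane shoulder flexion for reaching (the
shoulder→elbow vector projected onto the x–y plane before the angle is taken
— the projection makes "in the sagittal plane" explicit) and elbow flexion
for hand-to-mouth. The speed is the absolute first derivative of the
reference angle, low-pass filtered again with the same filter, because
differentiation re-amplifies band-edge noise.

Onset is the last sample below 5% of the peak speed before the peak; offset
is the first sample below it after the peak. On a noiseless minimum-jerk
profile this window captures ≥99% of the angular displacement. Phases
shorter than `segment.min_duration_s` (0.2 s; actual reaching phases last
several times that) are discarded as threshold jitter.

One phase per trial — around the global speed peak — is the default,
matching a protocol of single start-to-target movements. An iterative
multi-burst mode (extract the largest remaining burst, suppress it, repeat
while the remaining peak is ≥20% of the global maximum) is available for
recordings that genuinely contain repetitions. It is opt-in rather than the
default because, at realistic markerless noise (≈2 mm at 30 Hz), rest-period
noise in the differentiated angle reaches 20–25% of a movement's peak speed
and would otherwise be harvested as spurious near-zero-displacement
"repetitions" that corrupt subject averages.

A movement whose peak speed is comparable to the noise floor (e.g. a
severely impaired subject with a ~2° excursion) may legitimately yield no
detected phase; downstream tooling treats that trial as contributing no
results and reduces group sizes accordingly, with a warning.

## Parameters

Each parameter is the range of motion (max − min) of its series over the
phase. Displacement series are taken along a body axis, relative to the
phase onset, and normalized by limb length (mean |shoulder−elbow| + mean
|elbow−wrist| over the trial) so participants of different stature are
comparable; signs are kept in the series (forward and up positive) and
removed by the ROM. A `start_end` alternative (absolute onset-to-offset
change) is available via `kin.displacement_mode` for users who prefer the
net displacement reading.

Normalized jerk is computed on the assessed-side wrist trajectory by default
(`kin.nj_endpoint`): the wrist is the most distal joint that markerless
trackers still reconstruct reliably, whereas hand tracking is the noisiest.
The squared jerk magnitude is integrated over the phase by the trapezoid
rule; the third derivative is evaluated on the full trajectory so phase
interiors are unaffected by recording edges. A phase whose path length is
below 1 µm raises a degenerate-movement error rather than returning a
meaningless ratio.

Two practical properties of NJ are worth stating explicitly:

* **Threshold clipping lowers NJ below the closed form.** sqrt(360) ≈ 18.97
  is the value over the exact movement; the 5% velocity threshold clips the
  movement tails, which carry little displacement but a large share of the
  squared-jerk integral (~40% for a minimum-jerk profile). NJ measured over
  a detected phase of an ideally smooth movement therefore sits around
  11–15 rather than 19. Reported healthy-cohort NJ values below sqrt(360)
  are consistent with this, not anomalous.
* **NJ is noise-dominated on noisy data.** White 2 mm position noise at
  30 Hz survives the 6 Hz filter enough to swamp the third derivative,
  inflating NJ by roughly an order of magnitude. NJ comparisons are only
  meaningful between recordings of comparable noise characteristics; real
  tracker streams are temporally smoothed and behave more gently than the
  white-noise model used in simulation.

## Severity classes and statistics

Fugl-Meyer classes: severe FM ≤ 15, severe-moderate 15 < FM < 35,
moderate-mild 35 ≤ FM < 54, mild FM ≥ 54 — mutually exclusive and exhaustive
as printed inequalities, so no tie-breaking is needed. Controls are labelled
`healthy` and never classified through FM.

Per-subject parameter means (across a subject's phases) feed the group
statistics. The battery: KS normality screen (naive KS against a
moment-fitted normal by default, which is conservative; the Lilliefors
variant, with proper size and far better power, is selectable and is what a
formal normality decision should use); all-pairs two-sample t-tests
(classical equal-variance Student by default, Welch by config); Bonferroni
correction within each parameter's family of pairwise tests (10 for five
groups), not across parameters. Cohen's d uses the balanced pooled SD
`sqrt((sd1² + sd2²)/2)`.

A-priori sample sizes come from the noncentral t distribution: the smallest
per-group n whose two-sample t-test with noncentrality `d·sqrt(n/2)` and
`2n − 2` degrees of freedom reaches the requested power (default α = 0.05
two-tailed, power 0.95). At these defaults the expected severe-vs-healthy
shoulder-flexion contrast (85±10 vs 40±20, d = 2.85) requires 5 subjects per
group; the moderate contrast (85±10 vs 60±18, d = 1.72) requires 10
(at power 0.80: 4 and 7). The power default is a documented assumption —
published a-priori analyses rarely state all settings, and no single
standard setting reproduces every printed group size.

## The synthetic generator

The generator exists because patient recordings for this protocol are not
public; it is the test bed that defines what "correct" means for the
pipeline.

A seated skeleton (default geometry: upper arm 0.30 m, forearm 0.25 m, hand
0.08 m, trunk 0.50 m, shoulder width 0.36 m, neck 0.15 m; all overridable)
is driven through one movement of duration 2 s (default) padded by 0.5 s of
rest on both sides, at 30 Hz — a typical markerless frame rate. Design
choices that matter:

* **Angles are exact by construction.** Shoulder flexion/adduction set the
  shoulder→elbow orientation directly (requiring the adduction excursion not
  to exceed the flexion excursion — other profiles raise "unreachable");
  elbow and wrist angles rotate each segment about the flexion axis by the
  scripted angle. The assessment therefore recovers every driven angle ROM
  limited only by filtering/segmentation effects (worst case ≈0.2° over all
  presets, noiseless).
* **Compensations are independent dials.** Trunk forward/lateral tilt rotate
  the trunk vector; girdle torsion rotates the shoulder line about the trunk
  axis; head forward/vertical offsets are applied to the head directly
  rather than through the neck chain, so the head-displacement targets are
  not contaminated by trunk tilt. This sacrifices anatomical coupling for
  controllability — a deliberate trade in a validation instrument.
* **What is and is not a target.** SF, SA, EF, WF (hand-segment), TF, TL,
  HF, HV are independently recoverable. SV/EV/WV follow from the arm
  kinematics and are not separately scripted. The printed TT angle tracks
  lateral tilt (see above), so a torsion amplitude is not recoverable
  through it.
* **Smoothness.** k ≥ 1 overlapping minimum-jerk sub-movements (each of
  duration 2T/(k+1), onsets spaced so velocity bells overlap at half-width,
  keeping the composite monotone with no rest between bursts). Measured NJ
  rises monotonically with k; a frozen calibration table maps a target NJ to
  the nearest k. Targets below the single-movement floor map to k = 1.
* **Noise and cohorts.** Isotropic white Gaussian position noise (default
  2 mm for cohort simulation). Cohorts draw each subject's targets
  independently from normal distributions with the published group means and
  SDs, clipped to the reachable range; real inter-parameter couplings within
  patients (e.g. flexion deficit vs head compensation) are not recoverable
  from group summaries and are not modelled. Everything is reproducible from
  a single seed.

What passing tests show: the pipeline recovers known kinematic ground truth
through the full preprocess→segment→assess chain, the statistics are
calibrated, and group-level impairment gradients of the published size and
variability survive realistic sensor noise at n = 10 per group. What they do
not show: validity on real tracker output (correlated noise, occlusions,
soft-tissue artifacts), anatomical plausibility of the compensation
coupling, or clinical sensitivity beyond the simulated effect sizes.

## Numerical and reporting details

* Frame timestamps must be uniform within 1 ms of 1/fs; assessment requires
  ≥ 2 s of data.
* Dot products clamped to [−1, 1]; vector normalizations below 1e-9 m raise
  degenerate-geometry errors naming the segment.
* Report tables print mean(SD) to three significant digits; comparison CSVs
  carry full-precision statistics.
* All outputs embed the effective configuration and package version;
  identical inputs, configuration and seed give byte-identical outputs.
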