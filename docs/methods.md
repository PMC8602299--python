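# Methods

This note documents the models and numerical choices behind `wristkin`: what
each pipeline assumes, which parameters matter, what the synthetic data do and
do not emulate, and where the design was genuinely open.

## Conventions

Quaternions are scalar-first `(w, x, y, z)`, Hamilton product, representing
world←sensor rotations.  The world frame is right-handed and Z-up: gravity is
`(0, 0, −9.81)` m/s², world X is the horizontal projection of the magnetic
field, Y = Z×X.  Accelerometers measure specific force, so a static sensor
reads +9.81 m/s² along world up.  The magnetic dip angle is arbitrary
throughout — only the horizontal field component ever defines heading, so
results cannot depend on latitude.

## IMU orientation pipeline

**Magnetometer calibration.**  Hard-iron offset and soft-iron distortion are
fitted by linear least squares on the general quadric `xᵀMx + bᵀx = 1`
through samples collected while waving the sensor.  The centre gives the
hard-iron vector; the symmetric square root of `M`, normalised to unit
determinant, gives the soft-iron matrix, so calibration restores sphericity
without rescaling the field.  The fit refuses rank-deficient (coplanar)
clouds: the design-matrix condition is checked and the quadric must be a
genuine ellipsoid (all eigenvalues positive).  Parameters are static; a
calibration is only valid near where it was collected.

**Rest seeding.**  Each recording starts with ~5 s of rest with the limb
hanging.  The gyro bias is the mean gyro over that window.  The initial
orientation comes from a closed-form two-vector (TRIAD-style) construction on
the mean accelerometer and magnetometer readings; it is exact on noiseless
input and refuses windows whose accelerometer norm is >20% from gravity or
whose field is within 5° of gravity.  The rest window is then tiled onto the
front of the recording until 30 s of synthetic static data precede the real
start (`prepend_total`), and the filter consumes it at a high gain.  This lets
the run itself use a low gain — the estimate is already converged when the
movement begins — which minimises how hard transient accelerations and
magnetic disturbances can pull on the estimate.

**Complementary filter.**  Per sample the orientation is propagated by the
trapezoidally averaged gyro rate through the exact quaternion exponential, then
corrected by gain-scaled vector errors:

* *tilt*: cross product of measured and predicted gravity directions in the
  sensor frame; skipped when the accelerometer norm leaves [2, 20] m/s²;
* *heading*: the horizontal component of the world-frame magnetometer reading
  is rotated onto world X by a correction about the world vertical axis.
  Because a rotation about world Z leaves `Rᵀẑ` invariant, magnetometer input
  cannot change the estimated gravity direction — this is exact, not
  first-order, and is the pipeline's main defence against magnetic distortion.

Defaults: `run_gain` 0.1 /s, `init_gain` 2.5 /s (time constant 0.4 s, so the
30 s prepend converges from any seeding error), `rest_duration` 5 s,
`prepend_total` 30 s, `mag_yaw_only` on.  Gains trade distortion rejection
against gyro-drift correction; 0.1 /s corrects the default bias residual
(~2 mrad steady state) while keeping reach-acceleration artefacts below ~0.3°
on noiseless data.

## Tracker (pose) pipeline

Lighthouse-tracked poses arrive in a Y-up native frame and are mapped to the
Z-up world by the fixed right-handed change of basis X←x, Y←−z, Z←y (an
isometry; orientations are conjugated by the same rotation).  Dropout runs no
longer than `max_gap` = 0.2 s are filled by spherical interpolation between
the flanking valid samples; longer gaps stay explicitly masked and propagate
as invalid samples through the chain.  Both trackers are resampled by slerp
onto a shared uniform 100 Hz timeline before the chain.  Tracker positions are
ingested and re-emitted but never used: the chain needs orientations only,
which keeps the two sensor routes interchangeable downstream.

## Kinematic chain and its calibrations

`p = L_arm·R(q_arm)u_arm + L_fa·R(q_hc)R(q_fa)u_fa` with the shoulder fixed at
the origin.  ‖p‖ ≤ L_arm + L_fa always, with equality exactly for collinear
segments (the full-extension reach radius).

**Baseline removal.**  The limb axis in each sensor frame is derived from the
hanging rest pose, `u = R(q0)ᵀ(0,0,−1)`, with `q0` the eigenvector-mean
orientation over the rest window.  Consequently only the sensor's placement
*along* the limb matters; any mounting rotation about the limb axis cancels
identically (verified to 1e-9 cm).  The configured nominal axis is used only
to warn when the derived axis deviates by more than 20° (likely misplacement).
Windows moving more than 1°/sample RMS are rejected.

**Flexion–extension (FE) calibration.**  During passive elbow FE the hinge
axis is estimated per sensor as the principal (SVD) direction of that sensor's
world-frame angular velocity; signs are matched by correlating the projected
rates.  The heading correction is the world-Z rotation aligning the two
axes — a one-time correction applied to the forearm's world frame.  When the
upper arm barely moves (<2° excursion) its axis is unobservable and the
correction falls back to identity, which is also the correct default whenever
both sensors already share a world reference (common magnetic north for IMUs,
common lighthouse frame for trackers).  The calibration movement must span at
least 20° of relative rotation, and near-vertical hinge axes (within ~10° of
world Z) are rejected as heading-unobservable.  The synthetic FE scenario
includes a gentle ±6° whole-limb rock alongside the 70° elbow flexion: passive
manipulation never isolates the forearm perfectly, and the rock is precisely
what makes the hinge axis visible to the arm sensor.

## Metrics

* **EPD/AROM.**  EPD is the pointwise norm of `p`; per-target EPD is the mean
  over a held reach; AROM = EPD at target − EPD over the rest interval
  immediately preceding that reach.  Whether the rest reference is per-reach
  or session-initial is genuinely ambiguous in practice; per-reach is the
  default with `rest_reference="session"` available.
* **Hold segmentation.**  Stationary runs are maximal intervals with
  |d(EPD)/dt| below 2 cm/s lasting ≥ 1 s.  The first run (or a configured
  initial duration) is the session rest; because the reaching task returns to
  rest between reaches, later runs are taken to alternate hold/rest, labelled
  T1, T2, … in temporal order.  Recordings that violate the alternation
  assumption should use the annotation override (`label,t_start,t_end` CSV),
  which the CLI accepts everywhere.
* **Sweep area.**  `p` is projected on the world X–Y plane and the absolute
  shoelace sum is taken with implicit closure, matching the behaviour of
  common polygon-area routines on self-intersecting paths; a self-intersection
  warning is logged (via a geometric simplicity check) since the number is
  then a signed-sum magnitude rather than an enclosed area.
* **Endpoint speed.**  Each axis is differentiated with fixed-coefficient
  smooth noise-robust central differences (default window 7; exact on
  quadratics, noise response tangent to zero at Nyquist) with reflection
  padding, then the 3-D norm is taken.  Window 7 at 100–200 Hz suppresses
  sensor noise with ~30 ms of effective lag; larger windows trade lag for
  smoothing.
* **Peak envelope and smoothness.**  A cubic spline through the strict local
  maxima (plus endpoints) of the speed series, floored at zero; with fewer
  than two interior maxima the series is its own envelope (a spline through
  <3 points is degenerate, and a single-peaked stroke needs none).
  Smoothness = max/mean of the envelope over the movement, clamped at 1
  against floating-point rounding of the mean.  A constant profile gives
  exactly 1; a minimum-jerk stroke gives 15/8.
* **Agreement.**  Bland–Altman bias and 95% limits of agreement use the
  sample (n−1) standard deviation, pooled across all errors; Pearson p-values
  come from the t transform with n−2 degrees of freedom.

## Synthetic data: what it emulates, and what it does not

Ground-truth motion uses minimum-jerk timing throughout.  Reaches interpolate
the segment directions from the hanging rest to the target's
inverse-kinematics configuration (elbow offset below the shoulder–wrist line)
in joint space: a straight-line wrist path out of the fully extended rest
would require unbounded elbow angular acceleration (the two-segment chain has
a square-root singularity at full extension), so joint-space interpolation is
both smoother and more physiological; hold EPDs and the bell-shaped speed
profile are unaffected.  Sweeps abduct the straight(ened) arm to horizontal,
then sweep 180° of azimuth at constant elbow angle 180° − deficit; with zero
deficit the wrist traces a semicircle of radius L_arm + L_fa.
`sub_movements > 1` splits the sweep into separate strokes with 0.5 s stops,
emulating the segmented movement of impaired reaching.

The forward models derive gyro rates from quaternion differencing,
accelerometer readings from double-differentiated sensor positions plus
gravity (sensors sit at 75% of the arm and 60% of the forearm), and
magnetometer readings through the configured hard/soft-iron distortion of a
dipped 50-unit field.  Default noise reflects commodity hardware: gyro
0.005 rad/s RMS with 0.002 rad/s bias, accelerometer 0.05 m/s², magnetometer
1% of field RMS, tracker orientation 0.3° RMS; one integer seed drives every
draw, and identical configurations are bit-identical.

Not emulated: soft-tissue artefact (sensors are rigidly segment-fixed),
spatially varying magnetic fields (distortion is uniform; a field *step* is
used only to demonstrate the heading constraint), sensor scale-factor and
temperature effects, and tracker position error.  Passing the synthetic
recovery study therefore shows the *algorithms* are correct and noise-robust
at realistic sensor magnitudes — not that skin-mounted sensors on a moving
human achieve the same accuracy; on real data the residual error is expected
to be dominated by exactly the unmodelled terms, and the synthetic error
statistics (biases of hundredths of a centimetre) are correspondingly tighter
than what hardware studies report.

## Validation study sizes

The bundled study (`scripts/acceptance.py`, mirrored by the acceptance tests)
uses 54 reaches (9 per each of 6 targets, ~6.3 min of 100 Hz data through two
sensors) and eight sweep sessions with deficits 0–70° and 1–4 sub-movements —
sizes chosen to exercise every target and both pipelines while keeping a full
run in tens of seconds on one CPU.  Reported quantities: EPD/AROM error bias
and SD per method (cm), cross-method Pearson r and Bland–Altman summaries for
sweep area and smoothness, the analytic semicircle area (π·55²/2 ≈
4751.66 cm²), the minimum-jerk smoothness (1.875), and the full-extension
radius (55 cm).

## Known limitations

* The hold segmentation's hold/rest alternation assumes the task's
  return-to-rest structure; free-form recordings need annotations.
* The heading (FE) correction is one-time; slow relative drift between the two
  sensors' world frames within a recording is not re-estimated.
* `mag_yaw_only = False` (full 3-D field correction) references the field
  direction captured at the seed and is provided for comparison only.
* Elbow angle and elbow position are exposed but not validated beyond their
  geometric identities.
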