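# Methods

This note documents the models, parameter choices, and numerical decisions
behind `soundnav`, and what the synthetic data can and cannot show.

## Coordinate conventions

Right-handed frame: X forward along the course, Y left, Z up; floor at
z = 0; the registered world origin is the course start line. Quaternions are
scalar-first (w, x, y, z). The device forward axis at identity orientation
is +X, its up axis +Z, its left axis +Y. Session logs live in an arbitrary
per-session frame (random planar rotation plus XY offset, gravity-aligned),
exactly because live tracking systems have no absolute reference; the
fiducial record in each log carries enough information to undo it.

## Environment geometry

The hallway is a watertight rectangular box with inward-facing triangles;
floor faces are labeled `floor`, side and end walls `wall`, the ceiling
`other`. These labels mirror the semantic surface classes a scene-
understanding system assigns during reconstruction (`wall`, `floor`,
`door`, `other`); the package carries them as data and never infers them.

Obstacle courses follow the feasibility-study protocol: a 3 m × 20 m
hallway, a 12 m start-to-finish course, five person-sized inflatable
columns of height 1.6 m. Column **radius defaults to 0.25 m** — the
protocol fixes only the height, so the radius is this package's choice of a
plausible "punching-bag" column and is configurable. Placement is rejection
sampling under the generator's own completability guarantees: longitudinal
centers in [1.5, 11.0] m, pairwise surface clearance ≥ 0.7 m, and at least
one wall gap ≥ 0.8 m per column; up to 10 000 attempts before a
`GenerationError`. Layouts are pure functions of (config, seed).

Raycasting is vectorized Möller–Trumbore over all faces with a minimum
parametric distance of 1e-6 m (self-intersection guard) and ties broken
toward the smallest face index. The mesh sizes involved (hundreds of faces)
make an all-triangle sweep both exact and fast; no spatial index is needed.

## Sonification

The probe-source layout and tone frequencies are fixed by the application
being modeled: center/left/right at 0°/±30° yaw playing G4 (392 Hz), upper
at +20° pitch playing B4 (493.88 Hz), and 30°/60° downward sources playing
E4 (329.63 Hz) and C4 (261.63 Hz). Offsets are applied yaw-first about the
device up axis, then pitch about the device left axis.

The original system delegates attenuation and panning to a game engine and
does not publish the curves, so both are explicit, documented choices here:

* **Rolloff**: inverse-distance, clamped below a reference distance of
  1.0 m (`a = d₀/max(d, d₀)`), silent beyond a 10 m max range. Monotone and
  bounded, matching standard engine "logarithmic" rolloff behavior.
* **Pan**: constant-power on the sine of head-relative azimuth. Elevation
  affects only distance, never pan, and front/back is not disambiguated —
  plain stereo, no HRTF.
* A ray that misses within range mutes its source (`hit = false`, zero
  gains) — the open-doorway case.

Rendering is offline: gain control points at the 60 Hz frame rate,
linearly interpolated to audio rate; each source is a constant-frequency
sinusoid (phase continuous by construction), summed over sources and
peak-normalized to 0.9 full scale only if the mix would clip. WAV output is
32-bit float at 44.1 kHz. Real-time playback, material-dependent acoustics,
and binaural filtering are out of scope.

## Trial simulator

The simulator is the package's synthetic stand-in for human obstacle-course
trials; its defaults encode the study conditions rather than being free
dials. A walker (vertical cylinder, radius 0.3 m, device at 1.4 m height)
follows a piecewise-linear waypoint path from x = −0.5 m (so the
origin-crossing timing rule is exercised) to beyond the finish, deflecting
laterally by `avoidance_radius` around each column toward the roomier side.
Device yaw tracks the travel direction smoothed over 0.25 s, plus a
sinusoidal seeking sweep `A·sin(2πft)` and yaw noise.

Tracking noise is **temporally correlated**, not white: Gaussian noise
filtered with a 1 s correlation time and rescaled to the requested standard
deviation (filtered on a padded series so the edges are stationary).
Per-frame white noise at 60 Hz would dwarf the ~3 mm inter-frame steps and
destroy any travel-direction estimate — real handheld tracking error is
slow sway and drift, which this emulates.

Two presets bracket the study's behavioral orderings:

| preset     | speed (m/s) | seek A (rad) | seek f (Hz) | avoidance (m) | pos. noise (m) |
|------------|------------|--------------|-------------|----------------|----------------|
| unassisted | 0.24       | 0.15         | 0.20        | 0.35           | 0.12           |
| assisted   | 0.18       | 0.45         | 0.25        | 0.65           | 0.04           |

Speeds are set so a nominal 12 m traversal matches the studied mean elapsed
times (≈50 s unassisted, ≈67 s assisted); avoidance radii straddle the
contact threshold (user radius 0.3 + column radius 0.25 = 0.55 m) so the
collision ordering emerges geometrically. The presets are calibrated to
reproduce *orderings* of the study conditions, never magnitudes: per-trial
collision counts, for instance, are higher than human ones because the
simulated walker never reacts to contact. Passing the preset-contrast tests
shows the analytics framework discriminates the two behavior classes; it
says nothing about human performance.

Collision events are contiguous intervals where the horizontal distance to
a column axis drops below the contact threshold, closed only after
separation exceeds threshold + 0.05 m (hysteresis), so jittery grazing
counts once.

Session logs are JSON lines: one header object (schema version, trial id,
`active`/`passive` mode, fiducial pose), then one record per frame with
timestamp, position, and quaternion at full float precision. The
`active`/`passive` mode flag is metadata (soundscape on vs recording-only)
and never affects metrics.

## Analytics

**Registration.** The recorded fiducial position defines the translation;
the rotation is sequential two-axis alignment: rotate the recorded fiducial
X axis onto the target X axis (minimal rotation about their common
perpendicular), then rotate the resulting Y axis onto the target Y about
the now-common X. X and Y jointly constrain Z, so the transform is fully
determined; a zero-norm fiducial axis raises `RegistrationError`. The same
rigid transform applies to all positions and orientations, making every
metric invariant to the session frame (tested to 1e-9).

**Travel direction.** Per-step `atan2(Δy, Δx)`; steps below a stationarity
epsilon (1e-4 m) inherit the last valid angle (the head of the series
backfills from the first valid step — the walker hasn't moved yet, so the
first real direction is the best estimate); the series is unwrapped before
any differencing so deviations near ±π do not alias, then smoothed by a
centered moving average over 0.5 s. The window removes gait-scale jitter;
the exact smoother was an open choice and is configurable.

**Seeking.** The deviation series (yaw − travel direction) is detrended by
subtracting its least-squares line; left (>0) and right (<0) turns are
examined separately; local maxima (endpoints excluded) are kept when their
topographic prominence exceeds `prominence_fraction` (default 0.075) of the
maximum absolute *detrended* deviation — whether the 7.5% threshold refers
to the pre- or post-detrend maximum was ambiguous; post-detrend is used and
the fraction is a parameter. One caveat discovered in testing: OLS
detrending of a finite sweep with integer cycles and sine phase removes a
genuinely nonzero best-fit slope, shifting peak values by a few percent —
so a K-cycle amplitude-A sweep scores close to, but not exactly, 2KA. The
recovery tests assert the 2KA relation within 10%.

**Elapsed time.** Timestamp of the first sample with x > 12 m minus the
first with x > 0. A trajectory that never finishes raises
`IncompleteTrialError` carrying the protocol's 3-minute cap; `trial_report`
converts this to a capped, flagged row rather than dropping the trial.

**Scores.** `SPI = 1/(ΔT·(C+1))` exactly; group normalization divides by
the group maximum (all-zero groups are an error). `ADREV` is the raw
quotient C/ΔT min–max scaled to [1, 8] within the comparison group (a
degenerate group scores 1). The raw quotient rewards fast, collision-heavy
runs; because the intended orientation of the traditional 1–8 scale is
ambiguous, a `reverse` flag flips it and neither direction is presented as
canonical. Survey ratings r ∈ {1..6} map to (r−1)/5, averaged.

## Problem sizes

The test suite and reference checks run at desk scale by choice: raycast
oracle equivalence on 1000 random rays against an exhaustive per-triangle
oracle; yaw extraction against a rotation-matrix oracle on 10⁴ random
quaternions; registration of three random-frame copies of one path;
seeking recovery over amplitudes 0.1–0.5 rad; and 20 seeded trials per
behavior preset for the ordering contrast.

## Known limitations

* The simulator is open-loop: the walker never *hears* the soundscape, so
  closed-loop audio-driven navigation cannot be studied with it.
* Obstacles are static vertical cylinders; no dynamic obstacles, overhangs,
  or non-planar floors (stairwell-like meshes can be loaded from OBJ/PLY
  for qualitative runs only).
* Stereo gains are a pan/rolloff model, not a measured HRTF; front/back
  confusion is inherent.
* ADREV's published 1–8 rubric is not reproduced; only the quotient and a
  linear group scaling are implemented.
* Human cohort statistics (per-participant learning curves and their
  magnitudes) are out of scope; synthetic aggregates mirror structure, not
  effect sizes.
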