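"""Trajectory analytics for navigation trials.

Implements the full scoring pipeline for a recorded session:

1. **Registration** — every session has an arbitrary, gravity-aligned
   origin; the recorded fiducial (calibration-panel) pose is used to
   translate the data to a common origin and rotate it by sequential
   two-axis alignment (X axes first, then Y about the now-common X).
2. **Travel direction** — per-step planar angle of consecutive
   displacements relative to +X, with stationary samples inheriting the
   last valid angle, unwrapping, and centered moving-average smoothing.
3. **Deviation / seeking** — device yaw minus travel direction, linearly
   detrended; the seeking ("total head turn angle") score is the sum of
   absolute prominent peaks of the detrended deviation, split into left
   (> 0) and right (< 0) turns, keeping only peaks whose topographic
   prominence exceeds a configurable fraction (default 7.5%) of the
   maximum absolute detrended deviation.
4. **Elapsed time** — timestamp of the first sample past the finish
   threshold minus timestamp of the first sample past the origin.
5. **Scores** — SPI = 1 / (elapsed * (collisions + 1)), normalized per
   group by its maximum; ADREV = collisions / elapsed, min--max scaled to
   [1, 8] within a comparison group; survey ratings on 1..6 map to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, peak_prominences

from .environment import CourseLayout
from .errors import (
    ConfigError,
    DirectionError,
    GimbalError,
    IncompleteTrialError,
    RegistrationError,
)
from .transforms import Pose, as_rotation, check_unit_quaternion, to_wxyz
from .trial_sim import CollisionEvent, PoseSample, SessionLog, detect_collisions

__all__ = [
    "RegisteredTrajectory",
    "DeviationSeries",
    "TrialMetrics",
    "AnalysisParams",
    "register_session",
    "travel_direction",
    "yaw_angle",
    "deviation_series",
    "seeking_score",
    "elapsed_time",
    "spi",
    "normalize_scores",
    "adrev",
    "normalize_survey",
    "trial_report",
    "aggregate_report",
]


@dataclass
class RegisteredTrajectory:
    """Session samples expressed in the common course frame."""

    samples: list[PoseSample]
    rotation: np.ndarray  # (3, 3) applied to session-frame data
    translation: np.ndarray  # (3,) so that p_course = R @ p_session + t

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.samples])

    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.samples])

    def orientations(self) -> np.ndarray:
        return np.array([s.orientation for s in self.samples])


@dataclass
class DeviationSeries:
    """Per-step deviation of device yaw from the travel direction."""

    path_fraction: np.ndarray  # in [0, 1], one value per step
    deviation: np.ndarray  # radians, yaw - travel direction
    detrended: np.ndarray  # radians, deviation minus its linear trend

    @classmethod
    def from_deviation(cls, deviation, path_fraction=None) -> "DeviationSeries":
        """Build a series from a raw deviation signal, detrending it."""
        dev = np.asarray(deviation, dtype=float)
        if path_fraction is None:
            path_fraction = (
                np.linspace(0.0, 1.0, len(dev)) if len(dev) > 1 else np.zeros(len(dev))
            )
        return cls(np.asarray(path_fraction, float), dev, _detrend(dev))


@dataclass
class TrialMetrics:
    """All per-trial scores.  Group-relative fields (``spi_normalized``,
    ``adrev_raw``/``adrev_scaled``) are NaN unless a comparison group was
    supplied."""

    trial_id: str
    mode: str
    elapsed_time: float  # seconds
    collisions: int
    seeking: float  # radians, total head turn angle
    spi_raw: float  # 1/seconds
    spi_normalized: float = float("nan")
    adrev_raw: float = float("nan")
    adrev_scaled: float = float("nan")
    incomplete: bool = False


@dataclass
class AnalysisParams:
    """Tunable analysis parameters with their defaults.

    ``prominence_fraction`` is the peak filter threshold as a fraction of
    the maximum absolute detrended deviation; ``smoothing_window`` the
    centered moving-average window for the travel-direction series;
    ``time_cap`` the per-trial limit applied to incomplete trials.
    """

    prominence_fraction: float = 0.075
    smoothing_window: float = 0.5  # seconds
    stationary_epsilon: float = 1e-4  # meters
    start_x: float = 0.0
    user_radius: float = 0.3
    hysteresis: float = 0.05
    time_cap: float = 180.0  # seconds (3-minute trial limit)
    adrev_reverse: bool = False


# ---------------------------------------------------------------------------
# Registration


def _axis_alignment_rotation(r_fid: np.ndarray, r_target: np.ndarray) -> np.ndarray:
    """Sequential two-axis alignment.

    First the recorded fiducial X axis is rotated onto the target X axis
    (minimal rotation about their common perpendicular); then the rotated
    fiducial Y axis is brought onto the target Y axis by a rotation about
    the now-common X axis.  Together these fully constrain the rotation
    (X and Y jointly fix Z).
    """
    from scipy.spatial.transform import Rotation

    x_rel, y_rel = r_fid[:, 0], r_fid[:, 1]
    x_abs, y_abs = r_target[:, 0], r_target[:, 1]
    for v in (x_rel, y_rel, x_abs, y_abs):
        if np.linalg.norm(v) < 1e-9:
            raise RegistrationError("degenerate fiducial orientation (zero-norm axis)")

    def rot_between(a, b):
        a = a / np.linalg.norm(a)
        b = b / np.linalg.norm(b)
        axis = np.cross(a, b)
        s, c = np.linalg.norm(axis), float(np.dot(a, b))
        if s < 1e-12:
            if c > 0:
                return np.eye(3)
            # antiparallel: rotate pi about any perpendicular axis
            perp = np.cross(a, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(a, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            return Rotation.from_rotvec(math.pi * perp).as_matrix()
        angle = math.atan2(s, c)
        return Rotation.from_rotvec(angle * axis / s).as_matrix()

    r1 = rot_between(x_rel, x_abs)
    y_mid = r1 @ y_rel
    # signed angle about the common X axis
    angle = math.atan2(float(np.dot(np.cross(y_mid, y_abs), x_abs)), float(np.dot(y_mid, y_abs)))
    r2 = Rotation.from_rotvec(angle * x_abs).as_matrix()
    return r2 @ r1


def register_session(
    log: SessionLog, target_fiducial_pose: Pose | None = None
) -> RegisteredTrajectory:
    """Rigidly map a session into the common course frame via its fiducial.

    The recorded fiducial position moves to the target fiducial position
    and the fiducial axes align to the target axes; the same rotation and
    translation are applied to every sample's position and orientation.
    """
    if target_fiducial_pose is None:
        target_fiducial_pose = Pose()
    fid = log.fiducial
    R = _axis_alignment_rotation(
        fid.rotation().as_matrix(), target_fiducial_pose.rotation().as_matrix()
    )
    t = target_fiducial_pose.position - R @ fid.position
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_matrix(R)
    pos = np.array([s.position for s in log.samples]) @ R.T + t
    quats = to_wxyz(rot * as_rotation(np.array([s.orientation for s in log.samples])))
    samples = [
        PoseSample(s.timestamp, p, q)
        for s, p, q in zip(log.samples, pos, quats)
    ]
    return RegisteredTrajectory(samples=samples, rotation=R, translation=t)


# ---------------------------------------------------------------------------
# Direction series


def travel_direction(
    positions,
    timestamps,
    smoothing_window: float = 0.5,
    stationary_epsilon: float = 1e-4,
) -> np.ndarray:
    """Per-step planar travel direction relative to +X, in radians.

    Steps whose displacement is below ``stationary_epsilon`` inherit the
    last valid angle (leading stationary steps take the first valid one);
    the series is unwrapped and then smoothed by a centered moving average
    of ``smoothing_window`` seconds.  Returns ``len(positions) - 1`` values.
    """
    pos = np.asarray(positions, dtype=float)
    ts = np.asarray(timestamps, dtype=float)
    if len(pos) < 2:
        raise ConfigError("need at least 2 positions")
    d = np.diff(pos[:, :2], axis=0)
    step = np.linalg.norm(d, axis=1)
    valid = step >= stationary_epsilon
    if not np.any(valid):
        raise DirectionError("all displacements below stationary epsilon")
    ang = np.arctan2(d[:, 1], d[:, 0])
    # forward-fill invalid steps with the last valid angle, backfill the head
    idx = np.where(valid, np.arange(len(ang)), -1)
    idx = np.maximum.accumulate(idx)
    first_valid = int(np.argmax(valid))
    idx[idx < 0] = first_valid
    ang = ang[idx]
    ang = np.unwrap(ang)
    dt = float(np.median(np.diff(ts)))
    window = max(1, int(round(smoothing_window / dt)))
    return uniform_filter1d(ang, size=window, mode="nearest")


def yaw_angle(orientation) -> float | np.ndarray:
    """Planar heading of the device forward axis, radians relative to +X.

    Accepts a single quaternion (returns a scalar) or an (N, 4) array
    (returns an unwrapped series).  Raises :class:`GimbalError` when the
    forward axis is within 1e-6 of vertical.
    """
    q = check_unit_quaternion(orientation)
    single = q.ndim == 1
    q2 = q.reshape(-1, 4)
    fwd = as_rotation(q2).apply(np.array([1.0, 0.0, 0.0]))
    fwd = fwd.reshape(-1, 3)
    horiz = np.hypot(fwd[:, 0], fwd[:, 1])
    if np.any(horiz < 1e-6):
        raise GimbalError("device forward axis is (numerically) vertical")
    ang = np.arctan2(fwd[:, 1], fwd[:, 0])
    if single:
        return float(ang[0])
    return np.unwrap(ang)


def _detrend(y: np.ndarray) -> np.ndarray:
    x = np.arange(len(y), dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept)


def deviation_series(
    trajectory: RegisteredTrajectory,
    smoothing_window: float = 0.5,
    stationary_epsilon: float = 1e-4,
) -> DeviationSeries:
    """Deviation of device yaw from travel direction, per step, detrended.

    Both series are unwrapped before differencing so deviations near +-pi
    do not alias.  ``path_fraction`` is cumulative planar distance
    normalized to [0, 1].
    """
    pos = trajectory.positions()
    ts = trajectory.timestamps()
    travel = travel_direction(pos, ts, smoothing_window, stationary_epsilon)
    yaw = yaw_angle(trajectory.orientations())
    dev = np.asarray(yaw)[:-1] - travel
    step = np.linalg.norm(np.diff(pos[:, :2], axis=0), axis=1)
    cum = np.cumsum(step)
    total = cum[-1] if cum[-1] > 0 else 1.0
    return DeviationSeries(
        path_fraction=cum / total,
        deviation=dev,
        detrended=_detrend(dev),
    )


def seeking_score(
    deviation: DeviationSeries, prominence_fraction: float = 0.075
) -> float:
    """Total head turn angle: sum of absolute prominent deviation peaks.

    The detrended deviation is split into left (> 0) and right (< 0)
    turns; local maxima of each (the right series negated) are kept only
    when their topographic prominence exceeds ``prominence_fraction``
    times the maximum absolute detrended deviation.  Series endpoints are
    not peaks.  A constant series scores 0.
    """
    if not 0.0 < prominence_fraction < 1.0:
        raise ConfigError("prominence_fraction must be in (0, 1)")
    d = np.asarray(deviation.detrended, dtype=float)
    if len(d) < 3:
        raise ConfigError("need at least 3 samples for peak analysis")
    peak_scale = float(np.max(np.abs(d)))
    if peak_scale < 1e-15:
        return 0.0
    threshold = prominence_fraction * peak_scale
    total = 0.0
    for series, sign in ((d, 1.0), (-d, -1.0)):
        peaks, _ = find_peaks(series)
        if peaks.size == 0:
            continue
        prom = peak_prominences(series, peaks)[0]
        keep = peaks[(prom > threshold) & (series[peaks] > 0)]
        total += float(np.sum(np.abs(d[keep])))
    return total


# ---------------------------------------------------------------------------
# Scalar metrics


def elapsed_time(
    samples: list[PoseSample], start_x: float = 0.0, finish_x: float = 12.0
) -> float:
    """Trial time: first sample past the finish plane minus first sample
    past the start plane (both crossings in the +X direction).

    Raises :class:`IncompleteTrialError` (carrying the 3-minute cap) when
    the finish threshold is never crossed.
    """
    x = np.array([s.position[0] for s in samples])
    t = np.array([s.timestamp for s in samples])
    started = np.nonzero(x > start_x)[0]
    if started.size == 0:
        raise IncompleteTrialError("trajectory never crossed the start plane")
    finished = np.nonzero(x > finish_x)[0]
    if finished.size == 0:
        raise IncompleteTrialError("trajectory never crossed the finish threshold")
    i0, i1 = int(started[0]), int(finished[0])
    if i1 < i0:
        raise ConfigError("finish crossed before start")
    return float(t[i1] - t[i0])


def spi(elapsed: float, collisions: int) -> float:
    """Safety Performance Index: ``1 / (elapsed * (collisions + 1))``.

    Higher is better; the +1 guards the zero-collision case.
    """
    if elapsed <= 0:
        raise ConfigError("elapsed time must be positive")
    if collisions < 0:
        raise ConfigError("collision count must be >= 0")
    return 1.0 / (elapsed * (collisions + 1))


def normalize_scores(values) -> np.ndarray:
    """Divide a group of nonnegative scores by the group maximum."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ConfigError("empty score group")
    if np.any(v < 0):
        raise ConfigError("scores must be nonnegative")
    m = float(v.max())
    if m <= 0:
        raise ConfigError("all-zero score group cannot be normalized")
    return v / m


def adrev(
    elapsed: float,
    collisions: int,
    group: list[tuple[float, int]],
    reverse: bool = False,
) -> tuple[float, float]:
    """Collisions-per-time quotient, min--max scaled to [1, 8] in a group.

    Returns ``(raw, scaled)``.  Raw = collisions / elapsed, so a fast and
    collision-heavy trial scores a *higher* raw quotient than a slow,
    careful one; ``reverse=True`` flips the 1..8 scale for callers who
    want larger to mean better performance.  A degenerate group (all raws
    equal) scores 1 for every trial.
    """
    if not group:
        raise ConfigError("ADREV group must be nonempty")
    for te, _ in group:
        if te <= 0:
            raise ConfigError("non-positive elapsed time in ADREV group")
    if elapsed <= 0:
        raise ConfigError("elapsed time must be positive")
    if not any(
        math.isclose(te, elapsed, rel_tol=1e-12) and ce == collisions
        for te, ce in group
    ):
        raise ConfigError("queried trial must be a member of its ADREV group")
    raws = np.array([c / te for te, c in group], dtype=float)
    raw = collisions / elapsed
    lo, hi = float(raws.min()), float(raws.max())
    if hi == lo:
        return raw, 1.0
    frac = (raw - lo) / (hi - lo)
    if reverse:
        frac = 1.0 - frac
    return raw, 1.0 + 7.0 * frac


def normalize_survey(responses) -> float:
    """Mean survey score on [0, 1] from ratings on the 1..6 agreement scale
    (1 maps to 0, 6 maps to 1)."""
    r = np.asarray(responses)
    if r.size == 0:
        raise ConfigError("empty survey response list")
    if np.any((r < 1) | (r > 6)) or not np.all(np.equal(np.mod(r, 1), 0)):
        raise ConfigError("survey responses must be integers in [1, 6]")
    return float(np.mean((r.astype(float) - 1.0) / 5.0))


# ---------------------------------------------------------------------------
# Composition


def trial_report(
    log: SessionLog,
    layout: CourseLayout,
    events: list[CollisionEvent] | None = None,
    params: AnalysisParams | None = None,
    group: list[tuple[float, int]] | None = None,
    return_traces: bool = False,
):
    """Register a session and compute every per-trial metric.

    ``events`` may carry externally recorded collisions; when omitted they
    are detected geometrically from the registered trajectory.  Incomplete
    trials (finish never crossed) are reported with ``elapsed_time`` set
    to the time cap and flagged, not dropped.  With ``return_traces`` the
    normalized-speed-vs-path-fraction trace is returned alongside.
    """
    if params is None:
        params = AnalysisParams()
    traj = register_session(log, layout.fiducial_pose)
    if events is None:
        events = detect_collisions(
            traj.samples, layout, params.user_radius, params.hysteresis
        )
    collisions = len(events)
    dev = deviation_series(traj, params.smoothing_window, params.stationary_epsilon)
    seeking = seeking_score(dev, params.prominence_fraction)
    incomplete = False
    try:
        elapsed = elapsed_time(traj.samples, params.start_x, layout.course_length)
    except IncompleteTrialError:
        elapsed = params.time_cap
        incomplete = True
    spi_raw = spi(elapsed, collisions)
    adrev_raw = adrev_scaled = float("nan")
    spi_norm = float("nan")
    if group is not None:
        adrev_raw, adrev_scaled = adrev(
            elapsed, collisions, group, reverse=params.adrev_reverse
        )
        spi_norm = float(
            spi_raw / max(spi(te, ce) for te, ce in group)
        )
    metrics = TrialMetrics(
        trial_id=log.trial_id,
        mode=log.mode,
        elapsed_time=elapsed,
        collisions=collisions,
        seeking=seeking,
        spi_raw=spi_raw,
        spi_normalized=spi_norm,
        adrev_raw=adrev_raw,
        adrev_scaled=adrev_scaled,
        incomplete=incomplete,
    )
    if not return_traces:
        return metrics
    pos = traj.positions()
    ts = traj.timestamps()
    step = np.linalg.norm(np.diff(pos[:, :2], axis=0), axis=1)
    speed = step / np.diff(ts)
    peak = speed.max() if speed.size and speed.max() > 0 else 1.0
    traces = {
        "path_fraction": dev.path_fraction,
        "normalized_speed": speed / peak,
        "deviation": dev.deviation,
        "detrended": dev.detrended,
        "positions": pos,
    }
    return metrics, traces


def aggregate_report(metrics: list[TrialMetrics]):
    """Per-trial table plus per-mode OLS trend slopes.

    SPI is normalized by the maximum within the supplied set; the trend
    slope for each mode is the ordinary-least-squares slope of each metric
    over trial index (the learning-effect summary).  Returns
    ``(per_trial_df, aggregate_df)``.
    """
    import pandas as pd

    if not metrics:
        raise ConfigError("no trials to aggregate")
    df = pd.DataFrame(
        {
            "trial_id": [m.trial_id for m in metrics],
            "mode": [m.mode for m in metrics],
            "elapsed_time_s": [m.elapsed_time for m in metrics],
            "collisions": [m.collisions for m in metrics],
            "seeking_rad": [m.seeking for m in metrics],
            "spi_raw": [m.spi_raw for m in metrics],
            "adrev_raw": [m.adrev_raw for m in metrics],
            "adrev_scaled": [m.adrev_scaled for m in metrics],
            "incomplete": [m.incomplete for m in metrics],
        }
    )
    df["spi_normalized"] = normalize_scores(df["spi_raw"].to_numpy())
    rows = []
    for mode, sub in df.groupby("mode", sort=True):
        row = {"mode": mode, "n_trials": len(sub)}
        for col in ("elapsed_time_s", "collisions", "seeking_rad", "spi_normalized"):
            y = sub[col].to_numpy(dtype=float)
            row[f"mean_{col}"] = float(np.mean(y))
            if len(y) >= 2:
                row[f"slope_{col}"] = float(np.polyfit(np.arange(len(y)), y, 1)[0])
            else:
                row[f"slope_{col}"] = float("nan")
        rows.append(row)
    return df, pd.DataFrame(rows)
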