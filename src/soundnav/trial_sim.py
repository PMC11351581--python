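"""Synthetic navigation trials.

Generates blindfolded-style obstacle-course traversals as 60 Hz pose logs
in the recording schema of the navigation aid (timestamp, position x/y/z,
quaternion w/x/y/z per rendered frame), together with ground-truth collision
events.  The walker follows a waypoint path that deflects laterally around
each column, its device yaw tracks a smoothed travel direction plus a
sinusoidal "seeking" sweep and Gaussian noise, and the whole log is expressed
in a random, gravity-aligned session frame (planar rotation + XY offset) so
that fiducial registration is a non-trivial step of the analysis, just as it
is for real recordings whose origin is arbitrary per session.

Two documented presets bracket the study's conditions qualitatively:
``assisted`` (slower, wide avoidance, strong seeking) and ``unassisted``
(faster, tight avoidance, little seeking).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .environment import CourseLayout
from .errors import ConfigError, FormatError, SimulationError
from .transforms import Pose, check_unit_quaternion, quat_multiply, yaw_quaternion

__all__ = [
    "PoseSample",
    "SessionLog",
    "BehaviorParams",
    "CollisionEvent",
    "BEHAVIOR_PRESETS",
    "simulate_trial",
    "detect_collisions",
    "write_session_log",
    "read_session_log",
]

SESSION_SCHEMA = "soundnav-session-v1"

#: Device height above the floor while held in front of the walker, meters.
DEVICE_HEIGHT = 1.4


@dataclass
class PoseSample:
    """One timestamped 6-DOF record."""

    timestamp: float  # seconds
    position: np.ndarray  # (3,) meters
    orientation: np.ndarray  # (4,) quaternion (w, x, y, z)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = check_unit_quaternion(
            np.asarray(self.orientation, dtype=float).reshape(4)
        )


@dataclass
class SessionLog:
    """An ordered pose sequence plus the session-frame fiducial record."""

    samples: list[PoseSample]
    fiducial: Pose
    mode: str = "active"  # active: soundscape on; passive: recording only
    trial_id: str = "trial"

    def __post_init__(self):
        if len(self.samples) < 2:
            raise ConfigError("session log needs at least 2 samples")
        if self.mode not in ("active", "passive"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        ts = np.array([s.timestamp for s in self.samples])
        if np.any(np.diff(ts) <= 0):
            k = int(np.argmax(np.diff(ts) <= 0)) + 1
            raise FormatError(f"non-increasing timestamp at record {k}")
        rate = (len(ts) - 1) / (ts[-1] - ts[0])
        if not (30.0 <= rate <= 120.0):
            raise ConfigError(f"nominal sample rate {rate:.1f} Hz outside [30, 120]")

    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.samples])

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.samples])

    def orientations(self) -> np.ndarray:
        return np.array([s.orientation for s in self.samples])


@dataclass
class BehaviorParams:
    """Walker behavior knobs.

    ``forward_speed`` is speed along the waypoint path; ``seek_amplitude``
    and ``seek_frequency`` parameterize the sinusoidal device sweep about
    the travel direction; ``avoidance_radius`` is the lateral deflection
    around each obstacle center.
    """

    forward_speed: float = 0.24  # m/s
    seek_amplitude: float = 0.15  # radians
    seek_frequency: float = 0.2  # Hz
    avoidance_radius: float = 0.5  # meters
    position_noise_sd: float = 0.0  # meters, per-axis
    yaw_noise_sd: float = 0.0  # radians
    user_radius: float = 0.3  # meters; walker modeled as vertical cylinder
    seed: int = 0

    def __post_init__(self):
        if self.forward_speed <= 0:
            raise ConfigError("forward_speed must be positive")
        for name in (
            "seek_amplitude",
            "seek_frequency",
            "avoidance_radius",
            "position_noise_sd",
            "yaw_noise_sd",
            "user_radius",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


#: Preset behaviors bracketing the study conditions.  Forward speeds are set
#: so a nominal 12 m traversal takes ~50 s (unassisted) vs ~67 s (assisted);
#: the assisted walker sweeps the device widely and keeps a wide berth, the
#: unassisted walker hurries with a tight, noisy berth.
BEHAVIOR_PRESETS: dict[str, BehaviorParams] = {
    "unassisted": BehaviorParams(
        forward_speed=0.24,
        seek_amplitude=0.15,
        seek_frequency=0.20,
        avoidance_radius=0.35,
        position_noise_sd=0.12,
        yaw_noise_sd=0.05,
    ),
    "assisted": BehaviorParams(
        forward_speed=0.18,
        seek_amplitude=0.45,
        seek_frequency=0.25,
        avoidance_radius=0.65,
        position_noise_sd=0.04,
        yaw_noise_sd=0.05,
    ),
}


@dataclass
class CollisionEvent:
    """One contiguous interval of contact with an obstacle."""

    obstacle_index: int
    onset_time: float
    offset_time: float

    def __post_init__(self):
        if self.offset_time < self.onset_time:
            raise ConfigError("collision offset before onset")


# ---------------------------------------------------------------------------


def _waypoints(layout: CourseLayout, behavior: BehaviorParams) -> np.ndarray:
    """Start, one lateral deflection per obstacle, end beyond the finish."""
    half = layout.hallway_width / 2.0
    margin = behavior.user_radius + 0.05
    pts = [np.array([-0.5, 0.0])]
    for ob in sorted(layout.obstacles, key=lambda o: o.center_xy[0]):
        x, y = ob.center_xy
        gap = 2.0 * (ob.radius + behavior.user_radius)
        if layout.hallway_width - 2.0 * ob.radius < 2.0 * behavior.user_radius:
            raise SimulationError(
                f"obstacle at x={x:.2f} leaves no traversable gap "
                f"(need {gap:.2f} m of free width)"
            )
        # deflect toward the roomier side; fall back to the other side if the
        # preferred one would push the walker into a wall
        side = -1.0 if y > 0 else 1.0
        wp_y = y + side * behavior.avoidance_radius
        if abs(wp_y) > half - margin:
            wp_y = y - side * behavior.avoidance_radius
            if abs(wp_y) > half - margin:
                raise SimulationError(
                    f"avoidance radius {behavior.avoidance_radius} m infeasible "
                    f"for obstacle at ({x:.2f}, {y:.2f})"
                )
        pts.append(np.array([x, wp_y]))
    pts.append(np.array([layout.course_length + 0.7, 0.0]))
    return np.array(pts)


def _path_at(waypoints: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Positions at arc lengths ``s`` along the piecewise-linear path."""
    seg = np.diff(waypoints, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.clip(s, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    return waypoints[idx] + frac[:, None] * seg[idx]


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(x, size=max(1, window), mode="nearest")


def _smooth_noise(
    rng: np.random.Generator, n: int, sd: float, frame_rate: float,
    tau: float = 1.0,
) -> np.ndarray:
    """Temporally correlated Gaussian noise with standard deviation ``sd``.

    Device tracking error is dominated by slow sway/drift, not per-frame
    white jitter, so white noise is Gaussian-filtered with correlation
    time ``tau`` seconds and rescaled to the requested amplitude; the
    result is smooth at the frame scale, like real handheld sway.
    """
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    from scipy.ndimage import gaussian_filter1d

    sigma = max(1.0, tau * frame_rate)
    pad = int(4 * sigma)  # filter a padded series so edges are stationary
    w = rng.normal(0.0, 1.0, size=n + 2 * pad)
    x = gaussian_filter1d(w, sigma=sigma, mode="nearest")[pad : pad + n]
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_trial(
    layout: CourseLayout,
    behavior: BehaviorParams,
    frame_rate: float = 60.0,
    arbitrary_frame_seed: int = 0,
    mode: str = "active",
    trial_id: str = "synthetic",
) -> tuple[SessionLog, list[CollisionEvent]]:
    """Simulate one traversal; returns the session log (in a random session
    frame) and the ground-truth collision events (in the course frame).

    Deterministic for fixed ``(layout, behavior, frame_rate,
    arbitrary_frame_seed)``; behavior noise draws from ``behavior.seed``, the
    session frame from ``arbitrary_frame_seed``.
    """
    if frame_rate <= 0:
        raise ConfigError("frame_rate must be positive")
    rng = np.random.default_rng(behavior.seed)
    frame_rng = np.random.default_rng(arbitrary_frame_seed)

    wps = _waypoints(layout, behavior)
    total_len = float(np.sum(np.linalg.norm(np.diff(wps, axis=0), axis=1)))
    n = int(math.floor(total_len / behavior.forward_speed * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    xy = _path_at(wps, behavior.forward_speed * t)

    # truncate once the walker is past the finish margin (keep one sample beyond)
    beyond = np.nonzero(xy[:, 0] > layout.course_length + 0.5)[0]
    if beyond.size:
        n = int(beyond[0]) + 1
        t, xy = t[: n], xy[: n]
    if n < 2:
        raise SimulationError("trial too short; lower frame_rate or speed")

    noise = np.column_stack(
        [
            _smooth_noise(rng, n, behavior.position_noise_sd, frame_rate),
            _smooth_noise(rng, n, behavior.position_noise_sd, frame_rate),
        ]
    )
    xy = xy + noise
    z = np.full(n, DEVICE_HEIGHT)

    # device yaw: smoothed travel direction + seeking sweep + noise
    d = np.diff(xy, axis=0)
    step_yaw = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    yaw = np.concatenate([step_yaw, step_yaw[-1:]])
    yaw = _moving_average(yaw, int(round(0.25 * frame_rate)))
    yaw = yaw + behavior.seek_amplitude * np.sin(
        2.0 * np.pi * behavior.seek_frequency * t
    )
    yaw = yaw + _smooth_noise(rng, n, behavior.yaw_noise_sd, frame_rate)

    course_positions = np.column_stack([xy, z])
    events = detect_collisions(
        [
            PoseSample(ti, p, yaw_quaternion(yi))
            for ti, p, yi in zip(t, course_positions, yaw)
        ],
        layout,
        user_radius=behavior.user_radius,
    )

    # express everything in a random gravity-aligned session frame
    theta = float(frame_rng.uniform(-math.pi, math.pi))
    offset = np.concatenate([frame_rng.uniform(-5.0, 5.0, size=2), [0.0]])
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    q_frame = yaw_quaternion(theta)

    samples = [
        PoseSample(
            ti,
            R @ p + offset,
            quat_multiply(q_frame, yaw_quaternion(yi)),
        )
        for ti, p, yi in zip(t, course_positions, yaw)
    ]
    fid = layout.fiducial_pose
    fiducial = Pose(
        R @ fid.position + offset, quat_multiply(q_frame, fid.orientation)
    )
    log = SessionLog(samples=samples, fiducial=fiducial, mode=mode, trial_id=trial_id)
    return log, events


def detect_collisions(
    samples: list[PoseSample],
    layout: CourseLayout,
    user_radius: float = 0.3,
    hysteresis: float = 0.05,
) -> list[CollisionEvent]:
    """Contact intervals between the walker cylinder and each obstacle.

    A contact opens when the horizontal distance to an obstacle axis drops
    below ``user_radius + obstacle.radius`` and closes only once separation
    exceeds that threshold plus ``hysteresis``, so jittery grazing contact
    is counted once.  Samples must be in the course frame.
    """
    if not layout.obstacles:
        return []
    t = np.array([s.timestamp for s in samples])
    xy = np.array([s.position[:2] for s in samples])
    events: list[CollisionEvent] = []
    for k, ob in enumerate(layout.obstacles):
        dist = np.linalg.norm(xy - ob.center_xy, axis=1)
        thresh = user_radius + ob.radius
        in_contact = False
        onset = 0.0
        last_inside = 0.0
        for ti, di in zip(t, dist):
            if not in_contact and di < thresh:
                in_contact = True
                onset = ti
                last_inside = ti
            elif in_contact:
                if di < thresh:
                    last_inside = ti
                elif di > thresh + hysteresis:
                    events.append(CollisionEvent(k, onset, last_inside))
                    in_contact = False
        if in_contact:
            events.append(CollisionEvent(k, onset, last_inside))
    events.sort(key=lambda e: e.onset_time)
    return events


# ---------------------------------------------------------------------------
# Session-log I/O: JSON lines, one header object then one record per frame.


def write_session_log(log: SessionLog, path) -> None:
    with open(path, "w") as fh:
        header = {
            "schema": SESSION_SCHEMA,
            "trial_id": log.trial_id,
            "mode": log.mode,
            "fiducial": log.fiducial.to_dict(),
        }
        fh.write(json.dumps(header) + "\n")
        for s in log.samples:
            rec = {
                "t": s.timestamp,
                "p": s.position.tolist(),
                "q": s.orientation.tolist(),
            }
            fh.write(json.dumps(rec) + "\n")


def read_session_log(path) -> SessionLog:
    """Parse a session log, validating schema and timestamp monotonicity.

    Raises :class:`FormatError` naming the offending record on malformed
    JSON, missing fields, or non-monotone timestamps.
    """
    samples: list[PoseSample] = []
    header = None
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: invalid JSON at record {k}: {exc}") from exc
            if k == 0:
                if "schema" not in obj:
                    raise FormatError(f"{path}: record 0 is not a session header")
                header = obj
                continue
            try:
                sample = PoseSample(float(obj["t"]), obj["p"], obj["q"])
            except KeyError as exc:
                raise FormatError(
                    f"{path}: record {k} missing field {exc}"
                ) from exc
            if samples and sample.timestamp <= samples[-1].timestamp:
                raise FormatError(
                    f"{path}: non-increasing timestamp at record {k}"
                )
            samples.append(sample)
    if header is None:
        raise FormatError(f"{path}: empty session log")
    try:
        fiducial = Pose.from_dict(header["fiducial"])
        mode = header["mode"]
        trial_id = header["trial_id"]
    except KeyError as exc:
        raise FormatError(f"{path}: header missing field {exc}") from exc
    return SessionLog(samples=samples, fiducial=fiducial, mode=mode, trial_id=trial_id)
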