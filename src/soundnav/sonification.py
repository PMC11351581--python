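"""Soundscape generation.

Six probe rays are cast from the device pose in a "t" configuration:
center, 30 degrees left and right (all G4, 392 Hz), 20 degrees up (B4,
493.88 Hz), and 30/60 degrees down (E4 329.63 Hz, C4 261.63 Hz).  Each
ray's nearest mesh hit becomes a virtual tone source whose stereo gains
encode distance (inverse-distance rolloff, clamped below a reference
distance) and head-relative azimuth (constant-power pan on sin(azimuth)).
Elevation affects only distance, not pan; a ray that misses within range
mutes its source.  An offline renderer turns a sequence of per-frame
placements into a stereo waveform with per-frame gain control points
linearly interpolated to audio rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .environment import LabeledMesh, ray_mesh_intersect
from .errors import ConfigError
from .transforms import as_rotation, check_unit_quaternion

__all__ = [
    "SourceSpec",
    "SoundscapeConfig",
    "SourcePlacement",
    "default_source_config",
    "body_ray_direction",
    "cast_soundscape_frame",
    "stereo_gains",
    "render_soundscape",
    "write_wav",
]


@dataclass(frozen=True)
class SourceSpec:
    """One probe ray: angular offsets from the device forward axis plus the
    tone it plays.  Yaw is positive to the left, pitch positive up."""

    name: str
    yaw_offset: float = 0.0  # radians
    pitch_offset: float = 0.0  # radians
    tone_frequency: float = 392.0  # Hz

    def __post_init__(self):
        if self.tone_frequency <= 0:
            raise ConfigError("tone_frequency must be positive")
        if abs(self.yaw_offset) > math.pi or abs(self.pitch_offset) > math.pi / 2:
            raise ConfigError("source angular offset out of range")


@dataclass
class SoundscapeConfig:
    sources: list[SourceSpec]
    max_range: float = 10.0  # meters; rays miss (source mutes) beyond this
    reference_distance: float = 1.0  # meters; attenuation clamps below this
    enabled: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if not self.max_range > self.reference_distance > 0:
            raise ConfigError("require max_range > reference_distance > 0")
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ConfigError("source names must be unique")
        for name in names:
            self.enabled.setdefault(name, True)

    def enabled_sources(self) -> list[SourceSpec]:
        return [s for s in self.sources if self.enabled.get(s.name, True)]

    def source(self, name: str) -> SourceSpec:
        for s in self.sources:
            if s.name == name:
                return s
        raise KeyError(name)

    # angles are stored in radians but serialized in degrees for readability
    def to_dict(self) -> dict:
        return {
            "max_range": self.max_range,
            "reference_distance": self.reference_distance,
            "sources": [
                {
                    "name": s.name,
                    "yaw_offset_deg": math.degrees(s.yaw_offset),
                    "pitch_offset_deg": math.degrees(s.pitch_offset),
                    "tone_frequency_hz": s.tone_frequency,
                    "enabled": self.enabled.get(s.name, True),
                }
                for s in self.sources
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SoundscapeConfig":
        sources = [
            SourceSpec(
                s["name"],
                math.radians(s.get("yaw_offset_deg", 0.0)),
                math.radians(s.get("pitch_offset_deg", 0.0)),
                s["tone_frequency_hz"],
            )
            for s in d["sources"]
        ]
        enabled = {s["name"]: bool(s.get("enabled", True)) for s in d["sources"]}
        return cls(
            sources=sources,
            max_range=float(d.get("max_range", 10.0)),
            reference_distance=float(d.get("reference_distance", 1.0)),
            enabled=enabled,
        )

    @classmethod
    def load_json(cls, path) -> "SoundscapeConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SourcePlacement:
    """A frame-resolved source: where its ray hit and the stereo gains."""

    source: str
    frame_index: int
    hit: bool
    point: np.ndarray | None
    distance: float
    gain_left: float
    gain_right: float


def default_source_config() -> SoundscapeConfig:
    """The six-source "t" configuration with its standard tones."""
    deg = math.radians
    return SoundscapeConfig(
        sources=[
            SourceSpec("center", 0.0, 0.0, 392.0),
            SourceSpec("left", deg(30.0), 0.0, 392.0),
            SourceSpec("right", -deg(30.0), 0.0, 392.0),
            SourceSpec("upper", 0.0, deg(20.0), 493.88),
            SourceSpec("lower30", 0.0, -deg(30.0), 329.63),
            SourceSpec("lower60", 0.0, -deg(60.0), 261.63),
        ]
    )


def body_ray_direction(pose_orientation, spec: SourceSpec) -> np.ndarray:
    """World-frame unit direction of a source's probe ray.

    The device forward axis (+X at identity) is rotated by the yaw offset
    about the device up axis (+Z), then by the pitch offset about the
    device left axis (+Y), then taken to the world frame by the pose
    orientation.
    """
    q = check_unit_quaternion(pose_orientation)
    cy, sy = math.cos(spec.yaw_offset), math.sin(spec.yaw_offset)
    d_yaw = np.array([cy, sy, 0.0])
    cp, sp = math.cos(spec.pitch_offset), math.sin(spec.pitch_offset)
    # rotation by -pitch about +Y tilts the forward axis upward for pitch > 0
    d_local = np.array(
        [cp * d_yaw[0], d_yaw[1], sp * d_yaw[0]]
    )
    d_local /= np.linalg.norm(d_local)
    return as_rotation(q).apply(d_local)


def stereo_gains(pose, hit_point, reference_distance: float = 1.0):
    """Per-ear gains for a source at ``hit_point`` heard from ``pose``.

    Distance attenuation ``a = d_ref / max(d, d_ref)`` (inverse-distance
    rolloff, clamped); constant-power pan ``p = sin(azimuth)`` with azimuth
    the signed head-relative horizontal angle, positive to the right::

        gain_left = a * sqrt((1 - p) / 2),  gain_right = a * sqrt((1 + p) / 2)

    so that ``gain_left**2 + gain_right**2 == a**2`` for every placement.
    """
    rel = np.asarray(hit_point, float) - pose.position
    dist = float(np.linalg.norm(rel))
    if dist < 1e-12:
        raise ConfigError("hit point coincides with the listener position")
    a = reference_distance / max(dist, reference_distance)
    r = as_rotation(pose.orientation).inv().apply(rel)
    # device frame: +X forward, +Y left -> positive azimuth to the right
    azimuth = math.atan2(-r[1], r[0]) if (abs(r[0]) > 0 or abs(r[1]) > 0) else 0.0
    p = math.sin(azimuth)
    return a * math.sqrt((1.0 - p) / 2.0), a * math.sqrt((1.0 + p) / 2.0)


def cast_soundscape_frame(
    mesh: LabeledMesh,
    pose,
    config: SoundscapeConfig,
    frame_index: int = 0,
) -> list[SourcePlacement]:
    """Raycast every enabled source for one frame and compute its gains."""
    if len(mesh) == 0:
        raise ConfigError("mesh is empty")
    placements = []
    for spec in config.enabled_sources():
        direction = body_ray_direction(pose.orientation, spec)
        hit = ray_mesh_intersect(mesh, pose.position, direction, config.max_range)
        if hit.hit:
            gl, gr = stereo_gains(pose, hit.point, config.reference_distance)
            placements.append(
                SourcePlacement(
                    spec.name, frame_index, True, hit.point, hit.distance, gl, gr
                )
            )
        else:
            placements.append(
                SourcePlacement(spec.name, frame_index, False, None, math.inf, 0.0, 0.0)
            )
    return placements


def render_soundscape(
    placements_per_frame,
    frame_rate: float,
    sample_rate: float = 44100.0,
    duration: float | None = None,
    config: SoundscapeConfig | None = None,
) -> np.ndarray:
    """Offline-render a sequence of per-frame placements to stereo audio.

    Each source is a continuous-phase sinusoid at its tone frequency whose
    per-ear amplitude is piecewise-linearly interpolated between the frame
    gain control points.  Channels are summed over sources and peak-
    normalized to 0.9 full scale only if the mix would clip.  Returns an
    ``(n_samples, 2)`` float array, ``n_samples = round(duration * fs)``.
    """
    placements_per_frame = list(placements_per_frame)
    if not placements_per_frame:
        raise ConfigError("empty placement sequence")
    if frame_rate <= 0:
        raise ConfigError("frame_rate must be positive")
    if sample_rate < 8000:
        raise ConfigError("sample_rate must be >= 8000 Hz")
    if config is None:
        config = default_source_config()
    n_frames = len(placements_per_frame)
    if duration is None:
        duration = n_frames / frame_rate
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    frame_t = np.arange(n_frames) / frame_rate

    names: list[str] = []
    for frame in placements_per_frame:
        for p in frame:
            if p.source not in names:
                names.append(p.source)

    left = np.zeros(n)
    right = np.zeros(n)
    for name in names:
        freq = config.source(name).tone_frequency
        gl = np.zeros(n_frames)
        gr = np.zeros(n_frames)
        for i, frame in enumerate(placements_per_frame):
            for p in frame:
                if p.source == name:
                    gl[i], gr[i] = p.gain_left, p.gain_right
        env_l = np.interp(t, frame_t, gl)
        env_r = np.interp(t, frame_t, gr)
        wave = np.sin(2.0 * np.pi * freq * t)
        left += env_l * wave
        right += env_r * wave
    peak = max(np.abs(left).max(initial=0.0), np.abs(right).max(initial=0.0))
    if peak > 1.0:
        scale = 0.9 / peak
        left *= scale
        right *= scale
    return np.column_stack([left, right])


def write_wav(path, audio: np.ndarray, sample_rate: float = 44100.0) -> None:
    """Write stereo audio as a 32-bit float WAV file."""
    from scipy.io import wavfile

    wavfile.write(path, int(sample_rate), np.asarray(audio, dtype=np.float32))
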