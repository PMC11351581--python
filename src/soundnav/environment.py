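"""Build and query 3D environments.

Provides the hallway/obstacle-course geometry used by the study protocol
(a roughly 3 m x 20 m hallway with five randomly placed inflatable columns
on a 12 m course), the seeded course generator, and the nearest-hit
ray--mesh intersection primitive that the sonification layer probes with.

Coordinate convention: right-handed, X forward along the course, Y left,
Z up, floor at z = 0, world origin at the course start line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, FormatError, GenerationError
from .transforms import Pose

FACE_CLASSES = ("wall", "floor", "door", "other", "none")

#: Minimum parametric distance along a ray before a hit counts; avoids
#: re-intersecting the surface the ray originates on.
RAY_EPSILON = 1e-6

_DEGENERATE_AREA = 1e-9  # m^2


@dataclass
class LabeledMesh:
    """Triangle mesh with an optional semantic class per face.

    The classes mirror the surface labels a scene-understanding system
    assigns during live reconstruction: ``wall``, ``floor``, ``door``,
    ``other`` (plus ``none`` for unlabeled geometry).
    """

    vertices: np.ndarray  # (V, 3) float, meters
    faces: np.ndarray  # (F, 3) int
    face_class: np.ndarray  # (F,) str, values from FACE_CLASSES

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.face_class = np.asarray(self.face_class, dtype=object).reshape(-1)
        if len(self.face_class) != len(self.faces):
            raise ConfigError(
                f"face_class length {len(self.face_class)} != face count {len(self.faces)}"
            )
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ConfigError("face index out of range")
        if len(self.faces) and self.faces.min() < 0:
            raise ConfigError("negative face index")
        unknown = set(self.face_class) - set(FACE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown face classes: {sorted(unknown)}")
        areas = self.face_areas()
        if np.any(areas <= _DEGENERATE_AREA):
            raise ConfigError("degenerate (zero-area) face in mesh")

    def face_areas(self) -> np.ndarray:
        v0, v1, v2 = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)

    def face_normals(self) -> np.ndarray:
        v0, v1, v2 = (self.vertices[self.faces[:, i]] for i in range(3))
        n = np.cross(v1 - v0, v2 - v0)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def __len__(self) -> int:
        return len(self.faces)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def merge(cls, meshes: list["LabeledMesh"]) -> "LabeledMesh":
        verts, faces, classes = [], [], []
        offset = 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + offset)
            classes.append(m.face_class)
            offset += len(m.vertices)
        return cls(
            np.vstack(verts), np.vstack(faces), np.concatenate(classes)
        )


@dataclass
class Obstacle:
    """A vertical cylindrical column in the course frame."""

    center_xy: np.ndarray  # (2,) meters
    radius: float = 0.25
    height: float = 1.6

    def __post_init__(self):
        self.center_xy = np.asarray(self.center_xy, dtype=float).reshape(2)
        if self.radius <= 0 or self.height <= 0:
            raise ConfigError("obstacle radius and height must be positive")


@dataclass
class ProtocolConfig:
    """Course-generation parameters; defaults follow the study protocol:
    a ~3 m x 20 m hallway, a 12 m course, five person-sized inflatable
    columns of height 1.6 m.

    The clearance constraints are the generator's own guarantees that a
    course stays completable: obstacle centers keep ``clearance`` meters
    of surface-to-surface separation from each other and every obstacle
    leaves a wall gap of at least ``min_wall_gap`` on one side.
    """

    hallway_width: float = 3.0
    hallway_length: float = 20.0
    course_length: float = 12.0
    obstacle_count: int = 5
    obstacle_radius: float = 0.25
    obstacle_height: float = 1.6
    clearance: float = 0.7
    min_wall_gap: float = 0.8
    x_min: float = 1.5
    x_margin_end: float = 1.0  # centers at most course_length - this
    max_attempts: int = 10_000
    fiducial_pose: Pose = field(default_factory=Pose)

    def __post_init__(self):
        for name in ("hallway_width", "hallway_length", "course_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.obstacle_count < 0:
            raise ConfigError("obstacle_count must be >= 0")
        if self.course_length > self.hallway_length:
            raise ConfigError("course longer than hallway")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "hallway_width",
                "hallway_length",
                "course_length",
                "obstacle_count",
                "obstacle_radius",
                "obstacle_height",
                "clearance",
                "min_wall_gap",
                "x_min",
                "x_margin_end",
                "max_attempts",
            )
        }
        d["fiducial_pose"] = self.fiducial_pose.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        if "fiducial_pose" in d:
            d["fiducial_pose"] = Pose.from_dict(d["fiducial_pose"])
        return cls(**d)


@dataclass
class CourseLayout:
    """A concrete obstacle course: hallway footprint, obstacles, fiducial.

    The fiducial pose is the calibration panel's ground-truth pose in the
    course frame; it is held constant across seeds so every trial can be
    registered into this common frame.
    """

    hallway_width: float
    hallway_length: float
    course_length: float
    obstacles: list[Obstacle]
    fiducial_pose: Pose = field(default_factory=Pose)
    seed: int = 0

    def __post_init__(self):
        half = self.hallway_width / 2.0
        for i, ob in enumerate(self.obstacles):
            x, y = ob.center_xy
            if not (0.0 < x < self.course_length):
                raise ConfigError(
                    f"obstacle {i} longitudinal coordinate {x} outside (0, course_length)"
                )
            if half - abs(y) < ob.radius:
                raise ConfigError(f"obstacle {i} not fully inside hallway")

    def to_dict(self) -> dict:
        return {
            "schema": "soundnav-course-v1",
            "units": "meters",
            "hallway_width": self.hallway_width,
            "hallway_length": self.hallway_length,
            "course_length": self.course_length,
            "seed": self.seed,
            "fiducial_pose": self.fiducial_pose.to_dict(),
            "obstacles": [
                {
                    "center_xy": ob.center_xy.tolist(),
                    "radius": ob.radius,
                    "height": ob.height,
                }
                for ob in self.obstacles
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CourseLayout":
        try:
            return cls(
                hallway_width=float(d["hallway_width"]),
                hallway_length=float(d["hallway_length"]),
                course_length=float(d["course_length"]),
                obstacles=[
                    Obstacle(o["center_xy"], float(o["radius"]), float(o["height"]))
                    for o in d["obstacles"]
                ],
                fiducial_pose=Pose.from_dict(d["fiducial_pose"]),
                seed=int(d.get("seed", 0)),
            )
        except KeyError as exc:
            raise FormatError(f"course layout missing field {exc}") from exc

    @classmethod
    def load_json(cls, path) -> "CourseLayout":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"invalid course JSON in {path}: {exc}") from exc
        return cls.from_dict(d)


@dataclass
class RayHit:
    """Nearest intersection of a probe ray with a mesh (or a miss)."""

    hit: bool
    point: np.ndarray | None = None
    distance: float = float("inf")
    face_index: int = -1
    face_class: str = "none"


# ---------------------------------------------------------------------------
# Mesh construction


def build_hallway_mesh(
    width: float, length: float, ceiling_height: float
) -> LabeledMesh:
    """Watertight rectangular hallway interior.

    Floor spans x in [0, length], y in [-width/2, width/2], z = 0; all face
    normals (by winding) point into the interior.  Floor faces are labeled
    ``floor``, the four walls ``wall``, the ceiling ``other``.
    """
    if width <= 0 or length <= 0 or ceiling_height <= 0:
        raise ConfigError("hallway dimensions must be positive")
    y0, y1 = -width / 2.0, width / 2.0
    L, h = length, ceiling_height
    verts = np.array(
        [
            [0, y0, 0], [L, y0, 0], [L, y1, 0], [0, y1, 0],
            [0, y0, h], [L, y0, h], [L, y1, h], [0, y1, h],
        ],
        dtype=float,
    )
    # winding chosen so right-hand-rule normals point into the interior
    faces = np.array(
        [
            [0, 1, 2], [0, 2, 3],          # floor (+Z)
            [4, 6, 5], [4, 7, 6],          # ceiling (-Z)
            [0, 4, 5], [0, 5, 1],          # wall y = -w/2 (+Y)
            [3, 6, 7], [3, 2, 6],          # wall y = +w/2 (-Y)
            [0, 3, 7], [0, 7, 4],          # end wall x = 0 (+X)
            [1, 5, 6], [1, 6, 2],          # end wall x = L (-X)
        ],
        dtype=np.int64,
    )
    classes = np.array(
        ["floor"] * 2 + ["other"] * 2 + ["wall"] * 8, dtype=object
    )
    return LabeledMesh(verts, faces, classes)


def _cylinder_mesh(
    center_xy, radius: float, height: float, sides: int
) -> LabeledMesh:
    """Closed cylinder (side + both caps), outward winding, class ``other``."""
    cx, cy = center_xy
    ang = 2.0 * np.pi * np.arange(sides) / sides
    ring = np.stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)], axis=1)
    bottom = np.column_stack([ring, np.zeros(sides)])
    top = np.column_stack([ring, np.full(sides, height)])
    centers = np.array([[cx, cy, 0.0], [cx, cy, height]])
    verts = np.vstack([bottom, top, centers])
    bc, tc = 2 * sides, 2 * sides + 1
    faces = []
    for i in range(sides):
        j = (i + 1) % sides
        faces.append([i, j, sides + j])          # side lower
        faces.append([i, sides + j, sides + i])  # side upper
        faces.append([tc, sides + i, sides + j])  # top cap (+Z)
        faces.append([bc, j, i])                 # bottom cap (-Z)
    classes = np.full(len(faces), "other", dtype=object)
    return LabeledMesh(verts, np.array(faces, dtype=np.int64), classes)


def course_to_mesh(
    layout: CourseLayout,
    ceiling_height: float = 3.0,
    sides_per_cylinder: int = 32,
) -> LabeledMesh:
    """Hallway mesh plus one closed cylinder per obstacle (labeled ``other``)."""
    if sides_per_cylinder < 8:
        raise ConfigError("sides_per_cylinder must be >= 8")
    meshes = [
        build_hallway_mesh(layout.hallway_width, layout.hallway_length, ceiling_height)
    ]
    for ob in layout.obstacles:
        meshes.append(_cylinder_mesh(ob.center_xy, ob.radius, ob.height, sides_per_cylinder))
    return LabeledMesh.merge(meshes)


# ---------------------------------------------------------------------------
# Course generation


def generate_course(config: ProtocolConfig, seed: int) -> CourseLayout:
    """Rejection-sample an obstacle layout satisfying the protocol constraints.

    Deterministic for a given ``(config, seed)``.  Raises
    :class:`GenerationError` when ``max_attempts`` placements cannot satisfy
    the clearance constraints (infeasible configuration).
    """
    rng = np.random.default_rng(seed)
    half = config.hallway_width / 2.0
    r = config.obstacle_radius
    y_max = half - r  # fully inside hallway
    x_lo = config.x_min
    x_hi = config.course_length - config.x_margin_end
    if x_hi <= x_lo or y_max <= 0:
        raise GenerationError(
            f"infeasible course config: x range [{x_lo}, {x_hi}], y half-range {y_max}"
        )
    min_center_dist = 2.0 * r + config.clearance
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < config.obstacle_count:
        if attempts >= config.max_attempts:
            raise GenerationError(
                f"could not place {config.obstacle_count} obstacles after "
                f"{attempts} attempts (placed {len(placed)}); relax clearance "
                "or reduce the count"
            )
        attempts += 1
        cand = np.array(
            [rng.uniform(x_lo, x_hi), rng.uniform(-y_max, y_max)]
        )
        # a traversable gap of min_wall_gap must remain on at least one side
        gap_left = half - (cand[1] + r)
        gap_right = half - (-cand[1] + r)
        if max(gap_left, gap_right) < config.min_wall_gap:
            continue
        if any(np.linalg.norm(cand - p) < min_center_dist for p in placed):
            continue
        placed.append(cand)
    obstacles = [
        Obstacle(p, config.obstacle_radius, config.obstacle_height) for p in placed
    ]
    return CourseLayout(
        hallway_width=config.hallway_width,
        hallway_length=config.hallway_length,
        course_length=config.course_length,
        obstacles=obstacles,
        fiducial_pose=config.fiducial_pose,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ray intersection


def ray_mesh_intersect(
    mesh: LabeledMesh,
    origin,
    direction,
    max_range: float = 10.0,
    epsilon: float = RAY_EPSILON,
) -> RayHit:
    """Nearest ray--triangle intersection within ``(epsilon, max_range]``.

    Vectorized Moller--Trumbore over all faces; ties on distance resolve to
    the smallest face index.  The direction must be unit length.
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    d = np.asarray(direction, dtype=float).reshape(3)
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ConfigError("ray direction must be non-zero")
    if abs(norm - 1.0) > 1e-9:
        raise ConfigError(f"ray direction must be unit length (|d| = {norm})")
    if max_range <= 0:
        raise ConfigError("max_range must be positive")
    if len(mesh) == 0:
        return RayHit(hit=False)

    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    tol = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 / a
        s = origin - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ d)
        t = f * np.einsum("ij,ij->i", e2, q)
        valid = (
            (np.abs(a) > 1e-12)
            & (u >= -tol)
            & (v >= -tol)
            & (u + v <= 1.0 + tol)
            & (t > epsilon)
            & (t <= max_range)
        )
    if not np.any(valid):
        return RayHit(hit=False)
    t = np.where(valid, t, np.inf)
    idx = int(np.argmin(t))  # argmin returns the first (smallest) index on ties
    dist = float(t[idx])
    return RayHit(
        hit=True,
        point=origin + dist * d,
        distance=dist,
        face_index=idx,
        face_class=str(mesh.face_class[idx]),
    )


# ---------------------------------------------------------------------------
# Mesh I/O

_CLASS_TO_INT = {c: i for i, c in enumerate(FACE_CLASSES)}


def save_obj(mesh: LabeledMesh, path) -> None:
    """Write OBJ with face classes encoded as ``usemtl`` material names."""
    with open(path, "w") as fh:
        fh.write("# soundnav labeled mesh\n")
        for v in mesh.vertices:
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        current = None
        for face, cls in zip(mesh.faces, mesh.face_class):
            if cls != current:
                fh.write(f"usemtl {cls}\n")
                current = cls
            fh.write(f"f {face[0] + 1} {face[1] + 1} {face[2] + 1}\n")


def load_obj(path) -> LabeledMesh:
    """Read an OBJ written by :func:`save_obj` (or any triangulated OBJ);
    unknown or absent materials become class ``none``."""
    verts, faces, classes = [], [], []
    current = "none"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            tag = parts[0]
            if tag == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif tag == "usemtl":
                name = parts[1] if len(parts) > 1 else "none"
                current = name if name in FACE_CLASSES else "none"
            elif tag == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) != 3:
                    raise FormatError(
                        f"{path}:{lineno}: only triangular faces supported"
                    )
                faces.append(idx)
                classes.append(current)
    if not verts or not faces:
        raise FormatError(f"{path}: no mesh data found")
    return LabeledMesh(np.array(verts), np.array(faces), np.array(classes, dtype=object))


def save_ply(mesh: LabeledMesh, path) -> None:
    """Write ascii PLY with an integer ``face_class`` property per face."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write("comment soundnav labeled mesh; face_class indexes "
                 + ",".join(FACE_CLASSES) + "\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("property int face_class\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for face, cls in zip(mesh.faces, mesh.face_class):
            fh.write(f"3 {face[0]} {face[1]} {face[2]} {_CLASS_TO_INT[cls]}\n")


def load_ply(path) -> LabeledMesh:
    """Read an ascii PLY written by :func:`save_ply`."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    if not lines or lines[0] != "ply":
        raise FormatError(f"{path}: not a PLY file")
    n_vert = n_face = None
    try:
        header_end = lines.index("end_header")
    except ValueError:
        raise FormatError(f"{path}: missing end_header") from None
    for ln in lines[:header_end]:
        parts = ln.split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
    if n_vert is None or n_face is None:
        raise FormatError(f"{path}: missing vertex/face elements")
    body = lines[header_end + 1 :]
    verts = np.array([[float(x) for x in body[i].split()] for i in range(n_vert)])
    faces, classes = [], []
    for i in range(n_face):
        parts = body[n_vert + i].split()
        count = int(parts[0])
        if count != 3:
            raise FormatError(f"{path}: face {i} is not a triangle")
        faces.append([int(p) for p in parts[1:4]])
        cls_idx = int(parts[4]) if len(parts) > 4 else FACE_CLASSES.index("none")
        classes.append(FACE_CLASSES[cls_idx])
    return LabeledMesh(verts, np.array(faces), np.array(classes, dtype=object))


def load_mesh(path) -> LabeledMesh:
    """Load a user-supplied mesh.

    ``.obj``/``.ply`` files written by this package round-trip their face
    classes; anything else is loaded through trimesh with class ``none``.
    """
    p = str(path)
    if p.endswith(".obj"):
        return load_obj(p)
    if p.endswith(".ply"):
        return load_ply(p)
    import trimesh

    tm = trimesh.load(p, force="mesh")
    return LabeledMesh(
        np.asarray(tm.vertices, float),
        np.asarray(tm.faces, np.int64),
        np.full(len(tm.faces), "none", dtype=object),
    )
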