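"""World geometry: corridor, obstacle plates, flight tracks, pulse events.

Everything downstream (FDTD grids, ellipse localization, behavioral
analyses) works in a single world frame: x runs along the corridor's long
axis, y across it, the origin sits at one corridor corner, units are
meters, and angles are radians measured counterclockwise from +x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Material",
    "AIR",
    "ACRYLIC",
    "ACRYLIC_PRINTED",
    "ObstaclePlate",
    "CircleObstacle",
    "Scene",
    "FlightTrack",
    "PulseEvent",
    "EarGeometry",
    "build_corridor_scene",
    "occlude_behind",
    "edge_distance",
    "assign_to_obstacle",
    "load_scene",
    "save_scene",
    "load_track",
    "save_track",
    "load_pulses",
    "save_pulses",
]


class InvalidGeometryError(ValueError):
    """Raised when a scene description is geometrically impossible."""


@dataclass(frozen=True)
class Material:
    """Acoustic medium described by density and bulk modulus."""

    name: str
    density: float  # kg/m^3
    bulk_modulus: float  # Pa

    def __post_init__(self) -> None:
        if self.density <= 0 or self.bulk_modulus <= 0:
            raise ValueError("density and bulk_modulus must be positive")

    @property
    def sound_speed(self) -> float:
        """Intrinsic speed sqrt(K/rho) in m/s."""
        return float(np.sqrt(self.bulk_modulus / self.density))


#: Air at the tabulated simulation values (c = sqrt(K/rho) ~ 331.8 m/s).
AIR = Material("air", 1.29, 142.0e3)
#: Acrylic with the physically plausible density 1.18e3 kg/m^3.
ACRYLIC = Material("acrylic", 1180.0, 8.79e9)
#: Acrylic with the literal tabulated density (strict-reproduction mode);
#: physically implausible (lighter than air) but kept available.
ACRYLIC_PRINTED = Material("acrylic-printed", 1.18, 8.79e9)


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2D point, got shape {a.shape}")
    return a


@dataclass
class ObstaclePlate:
    """Thin rectangular plate given by its long axis and a thickness.

    ``p_start`` is the attached (wall) end, ``p_end`` the end protruding
    into the corridor by default; ``inner_edge_end`` selects which endpoint
    is the free inner edge (0 = p_start, 1 = p_end).
    """

    id: int
    p_start: np.ndarray
    p_end: np.ndarray
    thickness: float = 5e-3
    material: Material = ACRYLIC
    inner_edge_end: int = 1

    def __post_init__(self) -> None:
        self.p_start = _as_point(self.p_start)
        self.p_end = _as_point(self.p_end)
        if self.thickness <= 0:
            raise InvalidGeometryError("plate thickness must be positive")
        if self.length == 0:
            raise InvalidGeometryError("plate endpoints coincide")
        if self.inner_edge_end not in (0, 1):
            raise ValueError("inner_edge_end must be 0 or 1")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p_end - self.p_start))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from p_start to p_end."""
        return (self.p_end - self.p_start) / self.length

    @property
    def inner_edge(self) -> np.ndarray:
        return self.p_end if self.inner_edge_end == 1 else self.p_start

    @property
    def attached_end(self) -> np.ndarray:
        return self.p_start if self.inner_edge_end == 1 else self.p_end

    def corners(self) -> np.ndarray:
        """The four rectangle corners, shape (4, 2)."""
        ax = self.axis
        n = np.array([-ax[1], ax[0]]) * (self.thickness / 2.0)
        return np.array(
            [
                self.p_start + n,
                self.p_end + n,
                self.p_end - n,
                self.p_start - n,
            ]
        )

    def local_coords(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(along-axis, across-axis) coordinates of points relative to p_start."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts - self.p_start
        ax = self.axis
        s = d @ ax
        t = d @ np.array([-ax[1], ax[0]])
        return s, t

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points lie inside the plate rectangle."""
        s, t = self.local_coords(points)
        return (s >= 0) & (s <= self.length) & (np.abs(t) <= self.thickness / 2.0)

    def distance(self, point) -> float:
        """Euclidean distance from a point to the plate rectangle (0 if inside)."""
        s, t = self.local_coords(_as_point(point))
        ds = np.maximum(np.maximum(-s, s - self.length), 0.0)
        dt = np.maximum(np.abs(t) - self.thickness / 2.0, 0.0)
        return float(np.hypot(ds, dt)[0])


@dataclass
class CircleObstacle:
    """Circular scatterer (used by demo scenes and the geometric oracle)."""

    id: int
    center: np.ndarray
    radius: float
    material: Material = ACRYLIC

    def __post_init__(self) -> None:
        self.center = _as_point(self.center)
        if self.radius <= 0:
            raise InvalidGeometryError("circle radius must be positive")


@dataclass
class Scene:
    """A corridor with obstacles, in the world frame.

    ``extent`` is the axis-aligned corridor rectangle (xmin, ymin, xmax,
    ymax) in meters. ``c0`` is the reference sound speed used for delay
    arithmetic (the printed 340 m/s by default); the acoustic field itself
    is driven by the media. ``ambient_c0()`` gives the ambient medium's
    intrinsic speed, which the localization stage uses for consistency
    with the simulated field.
    """

    extent: tuple[float, float, float, float]
    plates: list[ObstaclePlate] = field(default_factory=list)
    circles: list[CircleObstacle] = field(default_factory=list)
    ambient: Material = AIR
    c0: float = 340.0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise InvalidGeometryError("corridor extent must have positive area")
        for p in self.plates:
            if not all(self.inside(c) for c in p.corners()):
                raise InvalidGeometryError(f"plate {p.id} extends outside corridor")

    @property
    def length(self) -> float:
        return self.extent[2] - self.extent[0]

    @property
    def width(self) -> float:
        return self.extent[3] - self.extent[1]

    def ambient_c0(self) -> float:
        return self.ambient.sound_speed

    def inside(self, point, margin: float = 0.0) -> bool:
        x, y = _as_point(point)
        x0, y0, x1, y1 = self.extent
        return (x0 + margin <= x <= x1 - margin) and (y0 + margin <= y <= y1 - margin)

    def plate_by_id(self, plate_id: int) -> ObstaclePlate:
        for p in self.plates:
            if p.id == plate_id:
                return p
        raise KeyError(f"no plate with id {plate_id}")


@dataclass
class FlightTrack:
    """Time-stamped 2D positions of one flight, nominally 125 frames/s."""

    times: np.ndarray
    positions: np.ndarray
    frame_rate: float = 125.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("a track needs at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")
        if self.positions.shape != (len(self.times), 2):
            raise ValueError("positions must be (n, 2)")


@dataclass
class PulseEvent:
    """One sonar emission: when, where, and which way it was aimed."""

    id: int
    t_emit: float
    position: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.position = _as_point(self.position)
        d = _as_point(self.direction)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("pulse direction must be nonzero")
        self.direction = d / n

    @property
    def heading(self) -> float:
        return float(np.arctan2(self.direction[1], self.direction[0]))


@dataclass
class EarGeometry:
    """Nostril source pair and ear receiver pair derived from a pulse.

    The two nostril sources sit ``nostril_offset`` to each side of the
    emission point, perpendicular to the emission direction (1.25 mm by
    default: half the half-wavelength of the 68 kHz CF2 component). The
    two ear receivers sit ``ear_offset`` to each side (10 mm: the
    inter-ear half distance). Left is +90 deg from the heading.
    """

    pulse: PulseEvent
    nostril_offset: float = 1.25e-3
    ear_offset: float = 10e-3

    def __post_init__(self) -> None:
        if self.nostril_offset <= 0 or self.ear_offset <= 0:
            raise ValueError("offsets must be positive")

    @property
    def left_dir(self) -> np.ndarray:
        dx, dy = self.pulse.direction
        return np.array([-dy, dx])

    @property
    def source_positions(self) -> np.ndarray:
        """Two nostril source points, shape (2, 2): (left, right)."""
        off = self.nostril_offset * self.left_dir
        return np.array([self.pulse.position + off, self.pulse.position - off])

    @property
    def receiver_positions(self) -> np.ndarray:
        """Two ear receiver points, shape (2, 2): (left, right)."""
        off = self.ear_offset * self.left_dir
        return np.array([self.pulse.position + off, self.pulse.position - off])


def build_corridor_scene(
    length_m: float,
    width_m: float,
    plate_width_m: float,
    plate_spacing_m: float,
    n_plates: int,
    ambient: Material = AIR,
    plate_material: Material = ACRYLIC,
    plate_thickness: float = 5e-3,
    c0: float = 340.0,
) -> Scene:
    """Corridor with plates attached alternately to the two long walls.

    Plate k hangs from the wall on side (-1)^k (+1 = the y = width wall),
    protrudes ``plate_width_m`` into the corridor, and consecutive plates
    are ``plate_spacing_m`` apart along x, centered in the corridor.
    """
    if min(length_m, width_m, plate_spacing_m) <= 0 or (
        n_plates > 0 and plate_width_m <= 0
    ):
        raise InvalidGeometryError("all dimensions must be positive")
    if n_plates < 0:
        raise InvalidGeometryError("n_plates must be >= 0")
    if n_plates > 0 and plate_width_m >= width_m:
        raise InvalidGeometryError("plate longer than corridor width")
    span = (n_plates - 1) * plate_spacing_m if n_plates else 0.0
    if span >= length_m:
        raise InvalidGeometryError("plates exceed corridor length")
    x_first = (length_m - span) / 2.0
    plates = []
    for k in range(n_plates):
        x = x_first + k * plate_spacing_m
        side = 1 if k % 2 == 0 else -1
        y_wall = width_m if side == 1 else 0.0
        y_tip = y_wall - side * plate_width_m
        plates.append(
            ObstaclePlate(
                id=k,
                p_start=np.array([x, y_wall]),
                p_end=np.array([x, y_tip]),
                thickness=plate_thickness,
                material=plate_material,
            )
        )
    return Scene(
        extent=(0.0, 0.0, length_m, width_m), plates=plates, ambient=ambient, c0=c0
    )


def occlude_behind(scene: Scene, pulse: PulseEvent) -> Scene:
    """Drop plates lying entirely behind the emitter.

    "Behind" means the open half-plane on the negative side of the line
    through the emission point perpendicular to the emission direction;
    plates straddling that line are kept. Circles are treated the same
    way via their bounding extremes along the heading.
    """
    d = pulse.direction
    kept_plates = [
        p
        for p in scene.plates
        if np.max((p.corners() - pulse.position) @ d) >= 0.0
    ]
    kept_circles = [
        c
        for c in scene.circles
        if (c.center - pulse.position) @ d + c.radius >= 0.0
    ]
    return replace(scene, plates=kept_plates, circles=kept_circles)


def edge_distance(point, plate: ObstaclePlate) -> float:
    """Along-plate distance from a point's axis projection to the inner edge.

    The point is projected onto the plate's long axis; the returned value
    is the distance from that projection to the free inner-edge endpoint,
    clipped to [0, plate length].
    """
    inner = plate.inner_edge
    toward_attached = (plate.attached_end - inner) / plate.length
    s = float((_as_point(point) - inner) @ toward_attached)
    return float(np.clip(s, 0.0, plate.length))


def assign_to_obstacle(point, scene: Scene, tol: float = 0.02) -> int | None:
    """Id of the nearest plate within ``tol`` meters, or None (unlocalized)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    best_id, best_d = None, np.inf
    for p in scene.plates:
        d = p.distance(point)
        if d < best_d:
            best_id, best_d = p.id, d
    return best_id if best_d <= tol else None


# ---------------------------------------------------------------------------
# File formats: YAML/JSON scenes, CSV tracks and pulse tables.

def _scene_to_dict(scene: Scene) -> dict:
    mats = {}
    for m in [scene.ambient] + [p.material for p in scene.plates]:
        mats[m.name] = {"density": m.density, "bulk_modulus": m.bulk_modulus}
    return {
        "corridor": {"length": scene.length, "width": scene.width},
        "origin": [scene.extent[0], scene.extent[1]],
        "c0": scene.c0,
        "ambient": scene.ambient.name,
        "materials": mats,
        "plates": [
            {
                "id": p.id,
                "start": [float(p.p_start[0]), float(p.p_start[1])],
                "end": [float(p.p_end[0]), float(p.p_end[1])],
                "thickness": p.thickness,
                "material": p.material.name,
                "inner_edge_end": p.inner_edge_end,
            }
            for p in scene.plates
        ],
        "circles": [
            {
                "id": c.id,
                "center": [float(c.center[0]), float(c.center[1])],
                "radius": c.radius,
                "material": c.material.name,
            }
            for c in scene.circles
        ],
    }


def _scene_from_dict(d: dict) -> Scene:
    mats = {
        name: Material(name, spec["density"], spec["bulk_modulus"])
        for name, spec in d.get("materials", {}).items()
    }
    ox, oy = d.get("origin", [0.0, 0.0])
    corr = d["corridor"]
    ambient = mats.get(d.get("ambient", "air"), AIR)
    plates = [
        ObstaclePlate(
            id=p.get("id", i),
            p_start=np.asarray(p["start"], dtype=float),
            p_end=np.asarray(p["end"], dtype=float),
            thickness=p.get("thickness", 5e-3),
            material=mats.get(p.get("material", "acrylic"), ACRYLIC),
            inner_edge_end=p.get("inner_edge_end", 1),
        )
        for i, p in enumerate(d.get("plates", []))
    ]
    circles = [
        CircleObstacle(
            id=c.get("id", i),
            center=np.asarray(c["center"], dtype=float),
            radius=c["radius"],
            material=mats.get(c.get("material", "acrylic"), ACRYLIC),
        )
        for i, c in enumerate(d.get("circles", []))
    ]
    return Scene(
        extent=(ox, oy, ox + corr["length"], oy + corr["width"]),
        plates=plates,
        circles=circles,
        ambient=ambient,
        c0=d.get("c0", 340.0),
    )


def save_scene(scene: Scene, path) -> None:
    d = _scene_to_dict(scene)
    text = (
        json.dumps(d, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(d, sort_keys=False)
    )
    with open(path, "w") as fh:
        fh.write(text)


def load_scene(path) -> Scene:
    with open(path) as fh:
        text = fh.read()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return _scene_from_dict(d)


def save_track(track: FlightTrack, path) -> None:
    pd.DataFrame(
        {"time_s": track.times, "x_m": track.positions[:, 0], "y_m": track.positions[:, 1]}
    ).to_csv(path, index=False)


def load_track(path, frame_rate: float = 125.0) -> FlightTrack:
    df = pd.read_csv(path)
    return FlightTrack(
        times=df["time_s"].to_numpy(),
        positions=df[["x_m", "y_m"]].to_numpy(),
        frame_rate=frame_rate,
    )


def save_pulses(pulses: list[PulseEvent], path) -> None:
    pd.DataFrame(
        {
            "pulse_id": [p.id for p in pulses],
            "time_s": [p.t_emit for p in pulses],
            "x_m": [p.position[0] for p in pulses],
            "y_m": [p.position[1] for p in pulses],
            "dir_rad": [p.heading for p in pulses],
        }
    ).to_csv(path, index=False)


def load_pulses(path) -> list[PulseEvent]:
    df = pd.read_csv(path)
    return [
        PulseEvent(
            id=int(r.pulse_id),
            t_emit=float(r.time_s),
            position=np.array([r.x_m, r.y_m]),
            direction=np.array([np.cos(r.dir_rad), np.sin(r.dir_rad)]),
        )
        for r in df.itertuples()
    ]
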