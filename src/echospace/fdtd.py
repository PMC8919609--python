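"""Two-dimensional staggered-grid FDTD solver for linear acoustics.

Pressure lives on cell centers, particle velocity on the half-index cell
faces; both are advanced leapfrog-style:

    p_ij^{n+1}   = p_ij^n - (kappa dt / dx) (div u)^{n+1/2}
    u_face^{n+1/2} = u_face^{n-1/2} - (dt / (rho dx)) (grad p)^n

with kappa = rho c0^2 per cell. Note that by construction every medium
propagates at the reference speed c0 and differs only in its acoustic
impedance rho*c0: a dense obstacle cell behaves as a (nearly rigid)
impedance discontinuity. This keeps the scheme stable at a single CFL
number regardless of the obstacle material; the physically tabulated
bulk moduli can be switched on explicitly, at the price of a stability
bound governed by the fastest medium.

The outer boundary absorbs outgoing waves with the Mur second-order
one-way condition (first-order diagonal updates at the corners).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import EarGeometry, PulseEvent, Scene

__all__ = [
    "SimConfig",
    "MediumGrid",
    "FieldState",
    "ReceiverTrace",
    "cfl_number",
    "rasterize_scene",
    "run_fdtd",
    "simulate_impulse_responses",
]

_CFL_2D_BOUND = 1.0 / np.sqrt(2.0)


class StabilityError(RuntimeError):
    """Raised when a configuration violates the 2D explicit stability bound."""


@dataclass
class SimConfig:
    """Grid spacing, sampling rate and reference speed for one run.

    Defaults are the full-resolution values (dx = 0.3 mm, fs = 2 MHz,
    c0 = 340 m/s, CFL 0.57). Scaled desk runs pass coarser values.
    """

    dx: float = 0.3e-3
    fs: float = 2e6
    c0: float = 340.0
    duration: float = 10e-3
    boundary: str = "mur2"
    use_material_modulus: bool = False
    rigid_obstacles: bool = False

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.fs <= 0 or self.c0 <= 0 or self.duration <= 0:
            raise ValueError("dx, fs, c0 and duration must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def cfl(self) -> float:
        return self.c0 / (self.fs * self.dx)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def stable(self) -> bool:
        return self.cfl <= _CFL_2D_BOUND + 1e-12


def cfl_number(config: SimConfig) -> float:
    """Courant number c0 * dt / dx = c0 / (fs * dx)."""
    return config.cfl


@dataclass
class MediumGrid:
    """Per-cell density and bulk modulus covering the scene extent."""

    density: np.ndarray  # (nx, ny)
    bulk_modulus: np.ndarray  # (nx, ny)
    dx: float
    origin: tuple[float, float]
    solid: np.ndarray | None = None  # bool mask of rigid cells

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape

    def cell_of(self, point) -> tuple[int, int]:
        """Index of the cell whose center is nearest to a world point."""
        x, y = np.asarray(point, dtype=float)
        i = int(round((x - self.origin[0]) / self.dx - 0.5))
        j = int(round((y - self.origin[1]) / self.dx - 0.5))
        nx, ny = self.shape
        if not (0 <= i < nx and 0 <= j < ny):
            raise ValueError(f"point {point} outside the simulation grid")
        return i, j

    def max_speed(self) -> float:
        return float(np.sqrt(self.bulk_modulus / self.density).max())


@dataclass
class FieldState:
    """Snapshot of the staggered fields at step n."""

    p: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    n: int = 0


@dataclass
class ReceiverTrace:
    """Pressure time series recorded at one point, fs samples/s from t0."""

    position: np.ndarray
    samples: np.ndarray
    fs: float
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


def rasterize_scene(scene: Scene, config: SimConfig) -> MediumGrid:
    """Paint the scene's media onto the grid by cell-center containment."""
    x0, y0, x1, y1 = scene.extent
    # round up, but absorb float fuzz: a scene spanning an integer number
    # of cells must not grow an extra row (an obstacle attached to the
    # wall would otherwise be separated from the boundary by a spurious
    # one-cell slit)
    nx = int(np.ceil((x1 - x0) / config.dx - 1e-9))
    ny = int(np.ceil((y1 - y0) / config.dx - 1e-9))
    if nx < 3 or ny < 3:
        raise ValueError("scene too small for the grid spacing")
    rho = np.full((nx, ny), scene.ambient.density, dtype=np.float64)
    if config.use_material_modulus:
        kappa = np.full((nx, ny), scene.ambient.bulk_modulus, dtype=np.float64)
    else:
        kappa = rho * config.c0**2
    solid = np.zeros((nx, ny), dtype=bool) if config.rigid_obstacles else None

    xs = x0 + (np.arange(nx) + 0.5) * config.dx
    ys = y0 + (np.arange(ny) + 0.5) * config.dx

    def paint(mask_fn, material):
        # evaluate only inside the obstacle's bounding box
        XX, YY = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        mask = mask_fn(pts).reshape(nx, ny)
        if config.rigid_obstacles:
            solid[mask] = True
        else:
            rho[mask] = material.density
            kappa[mask] = (
                material.bulk_modulus
                if config.use_material_modulus
                else material.density * config.c0**2
            )

    for plate in scene.plates:
        paint(plate.contains, plate.material)
    for circ in scene.circles:
        paint(
            lambda pts, c=circ: np.linalg.norm(pts - c.center, axis=1) <= c.radius,
            circ.material,
        )
    return MediumGrid(rho, kappa, config.dx, (x0, y0), solid)


def _check_stability(medium: MediumGrid, config: SimConfig) -> None:
    courant = medium.max_speed() * config.dt / config.dx
    if courant > _CFL_2D_BOUND + 1e-12:
        raise StabilityError(
            f"Courant number {courant:.3f} exceeds the 2D bound 1/sqrt(2); "
            "refusing to run an unstable configuration"
        )


def run_fdtd(
    medium: MediumGrid,
    sources: list[tuple[tuple[int, int], np.ndarray]],
    receiver_cells: list[tuple[int, int]],
    n_steps: int,
    config: SimConfig,
    record_energy: bool = False,
    snapshot_every: int = 0,
):
    """Advance the leapfrog scheme and record pressure at receiver cells.

    ``sources`` is a list of (cell, waveform) additive ("soft") pressure
    sources. Returns (traces, energy, snapshots); energy/snapshots are
    None unless requested.
    """
    _check_stability(medium, config)
    nx, ny = medium.shape
    dx, dt = config.dx, config.dt

    rho = medium.density
    # face densities: arithmetic mean of the two adjacent cells
    rho_x = 0.5 * (rho[1:, :] + rho[:-1, :])
    rho_y = 0.5 * (rho[:, 1:] + rho[:, :-1])
    cu_x = (dt / (rho_x * dx)).astype(np.float32)
    cu_y = (dt / (rho_y * dx)).astype(np.float32)
    cp = (medium.bulk_modulus * dt / dx).astype(np.float32)

    if medium.solid is not None and medium.solid.any():
        solid = medium.solid
        open_x = ~(solid[1:, :] | solid[:-1, :])
        open_y = ~(solid[:, 1:] | solid[:, :-1])
        cu_x *= open_x
        cu_y *= open_y

    p = np.zeros((nx, ny), dtype=np.float32)
    p_prev = np.zeros_like(p)  # p at step n-1 (for Mur)
    ux = np.zeros((nx - 1, ny), dtype=np.float32)
    uy = np.zeros((nx, ny - 1), dtype=np.float32)

    c_b = config.c0  # boundary wave speed (ambient)
    cdt = c_b * dt
    k1 = (cdt - dx) / (cdt + dx)
    k2 = 2.0 * dx / (cdt + dx)
    k3 = cdt**2 / (2.0 * dx * (cdt + dx))
    kd = (cdt - np.sqrt(2.0) * dx) / (cdt + np.sqrt(2.0) * dx)
    k1st = (cdt - dx) / (cdt + dx)
    mur2 = config.boundary == "mur2"
    # the second-order condition is unstable where a dense obstacle
    # touches the boundary (e.g. plates attached to the corridor wall);
    # fall back to first-order Mur on tangential stretches whose stencil
    # sees non-ambient cells
    rho_amb = float(np.median(rho))
    dense = rho > 2.0 * rho_amb

    def _tangential_ok(strip: np.ndarray) -> np.ndarray:
        bad = strip[0] | strip[1]
        bad = bad | np.roll(bad, 1) | np.roll(bad, -1)
        return ~bad[1:-1]

    ok_x0 = _tangential_ok(dense[0:2, :])
    ok_x1 = _tangential_ok(dense[-2:, :][::-1])
    ok_y0 = _tangential_ok(dense[:, 0:2].T)
    ok_y1 = _tangential_ok(dense[:, -2:].T[::-1])
    # a dense cell on the boundary itself (an obstacle meeting the wall)
    # is truncated rigidly: its pressure mirrors the interior neighbor
    rig_x0, rig_x1 = dense[0, 1:-1], dense[-1, 1:-1]
    rig_y0, rig_y1 = dense[1:-1, 0], dense[1:-1, -1]

    src = [
        (cell, np.asarray(w, dtype=np.float32)) for cell, w in sources
    ]
    traces = np.zeros((len(receiver_cells), n_steps), dtype=np.float64)
    energy = np.zeros(n_steps) if record_energy else None
    snapshots = [] if snapshot_every else None

    for n in range(n_steps):
        # velocity update (interior faces), u^{n+1/2} from p^n
        ux -= cu_x * (p[1:, :] - p[:-1, :])
        uy -= cu_y * (p[:, 1:] - p[:, :-1])

        pm1 = p.copy()  # p^n
        # pressure update on interior cells from div u^{n+1/2}
        div = (
            ux[1:, 1:-1]
            - ux[:-1, 1:-1]
            + uy[1:-1, 1:]
            - uy[1:-1, :-1]
        )
        p[1:-1, 1:-1] -= cp[1:-1, 1:-1] * div

        if mur2:
            # Mur second order on the four edges (tangential index 1..-2),
            # first order where the stencil touches dense cells
            new = (
                -p_prev[1, 1:-1]
                + k1 * (p[1, 1:-1] + p_prev[0, 1:-1])
                + k2 * (pm1[0, 1:-1] + pm1[1, 1:-1])
                + k3
                * (
                    pm1[0, 2:] - 2 * pm1[0, 1:-1] + pm1[0, :-2]
                    + pm1[1, 2:] - 2 * pm1[1, 1:-1] + pm1[1, :-2]
                )
            )
            first = pm1[1, 1:-1] + k1st * (p[1, 1:-1] - pm1[0, 1:-1])
            first = np.where(rig_x0, p[1, 1:-1], first)
            p[0, 1:-1] = np.where(ok_x0, new, first)
            new = (
                -p_prev[-2, 1:-1]
                + k1 * (p[-2, 1:-1] + p_prev[-1, 1:-1])
                + k2 * (pm1[-1, 1:-1] + pm1[-2, 1:-1])
                + k3
                * (
                    pm1[-1, 2:] - 2 * pm1[-1, 1:-1] + pm1[-1, :-2]
                    + pm1[-2, 2:] - 2 * pm1[-2, 1:-1] + pm1[-2, :-2]
                )
            )
            first = pm1[-2, 1:-1] + k1st * (p[-2, 1:-1] - pm1[-1, 1:-1])
            first = np.where(rig_x1, p[-2, 1:-1], first)
            p[-1, 1:-1] = np.where(ok_x1, new, first)
            new = (
                -p_prev[1:-1, 1]
                + k1 * (p[1:-1, 1] + p_prev[1:-1, 0])
                + k2 * (pm1[1:-1, 0] + pm1[1:-1, 1])
                + k3
                * (
                    pm1[2:, 0] - 2 * pm1[1:-1, 0] + pm1[:-2, 0]
                    + pm1[2:, 1] - 2 * pm1[1:-1, 1] + pm1[:-2, 1]
                )
            )
            first = pm1[1:-1, 1] + k1st * (p[1:-1, 1] - pm1[1:-1, 0])
            first = np.where(rig_y0, p[1:-1, 1], first)
            p[1:-1, 0] = np.where(ok_y0, new, first)
            new = (
                -p_prev[1:-1, -2]
                + k1 * (p[1:-1, -2] + p_prev[1:-1, -1])
                + k2 * (pm1[1:-1, -1] + pm1[1:-1, -2])
                + k3
                * (
                    pm1[2:, -1] - 2 * pm1[1:-1, -1] + pm1[:-2, -1]
                    + pm1[2:, -2] - 2 * pm1[1:-1, -2] + pm1[:-2, -2]
                )
            )
            first = pm1[1:-1, -2] + k1st * (p[1:-1, -2] - pm1[1:-1, -1])
            first = np.where(rig_y1, p[1:-1, -2], first)
            p[1:-1, -1] = np.where(ok_y1, new, first)
            # first-order diagonal corners
            p[0, 0] = pm1[1, 1] + kd * (p[1, 1] - pm1[0, 0])
            p[0, -1] = pm1[1, -2] + kd * (p[1, -2] - pm1[0, -1])
            p[-1, 0] = pm1[-2, 1] + kd * (p[-2, 1] - pm1[-1, 0])
            p[-1, -1] = pm1[-2, -2] + kd * (p[-2, -2] - pm1[-1, -1])
        else:  # rigid box: leave boundary pressure untouched
            pass

        for (ci, cj), w in src:
            if n < len(w):
                p[ci, cj] += w[n]

        p_prev = pm1

        for r, (ci, cj) in enumerate(receiver_cells):
            traces[r, n] = p[ci, cj]
        if record_energy:
            energy[n] = float(np.sum(p.astype(np.float64) ** 2))
        if snapshot_every and n % snapshot_every == 0:
            snapshots.append(p.copy())

        if not np.isfinite(p[nx // 2, ny // 2]):
            raise StabilityError(f"field blew up at step {n}")

    return traces, energy, snapshots


def simulate_impulse_responses(
    scene: Scene,
    pulse: PulseEvent,
    impulse: "Waveform",
    config: SimConfig,
    ears: EarGeometry | None = None,
    normalize_direct: bool = True,
) -> tuple[ReceiverTrace, ReceiverTrace]:
    """Impulse responses at the two ears for one emission.

    The impulse waveform is injected additively at the two nostril cells;
    pressure is recorded at the two ear cells. With ``normalize_direct``
    both traces are divided by the peak of the direct wave (a common
    factor, so interaural level differences survive): echo amplitudes are
    then expressed relative to the emitted pulse as heard at the ear,
    which is what the downstream detection threshold is calibrated
    against.
    """
    if abs(impulse.fs - config.fs) > 1e-6:
        raise ValueError("impulse fs must match the simulation fs")
    if ears is None:
        ears = EarGeometry(pulse)
    medium = rasterize_scene(scene, config)

    src_cells = [medium.cell_of(pos) for pos in ears.source_positions]
    rec_cells = [medium.cell_of(pos) for pos in ears.receiver_positions]
    for (ci, cj), pos in zip(rec_cells, ears.receiver_positions):
        inside_plate = any(p.contains(pos[None, :])[0] for p in scene.plates)
        if inside_plate or (medium.solid is not None and medium.solid[ci, cj]):
            raise ValueError("receiver position lies inside an obstacle")

    sources = [(cell, impulse.samples) for cell in src_cells]
    traces, _, _ = run_fdtd(medium, sources, rec_cells, config.n_steps, config)

    if normalize_direct:
        # direct path <= ear_offset + nostril_offset, plus the impulse length
        c_amb = scene.c0
        t_direct = (ears.ear_offset + ears.nostril_offset) / c_amb + impulse.duration
        n_direct = min(int(np.ceil(t_direct * config.fs)) + 2, traces.shape[1])
        peak = np.max(np.abs(traces[:, :n_direct]))
        if peak > 0:
            traces = traces / peak

    left = ReceiverTrace(ears.receiver_positions[0], traces[0], config.fs)
    right = ReceiverTrace(ears.receiver_positions[1], traces[1], config.fs)
    return left, right
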