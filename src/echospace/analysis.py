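"""Behavioral analyses over tracks, pulses and echo incidence points.

Covers the downstream statistics of the echo-space workflow: turn rate
at 1 ms resolution, pulse/echo direction series relative to the
instantaneous flight direction, lagged Pearson correlation between a
direction series and the turn rate with Fisher-transform confidence
bands (+/- z_{a/2} / sqrt(n - 3) on the z scale), the lag of maximum
correlation tau_max, edge-distance tables restricted to the inner half
of each obstacle plate, and the "how many pulses does an echo influence"
estimate (lag difference divided by the mean inter-pulse interval).

Model-based contrasts (GLMM/LMM) are intentionally out of scope; the
tables emitted here are shaped for external mixed-model fitting, and
descriptive means with standard errors stand in for those fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.stats import norm

from .localize import EchoIncidencePoint
from .scene import FlightTrack, PulseEvent, Scene, edge_distance

__all__ = [
    "TurnRateSeries",
    "DirectionSeries",
    "LagCorrelation",
    "turn_rate_series",
    "flight_heading",
    "echo_direction_series",
    "pulse_direction_series",
    "direction_series",
    "lagged_correlation",
    "edge_distance_summary",
    "pulses_affected",
]


@dataclass
class TurnRateSeries:
    """Time derivative of the flight heading, on a uniform 1 ms grid."""

    times: np.ndarray
    values: np.ndarray  # rad/s

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation; NaN outside the support."""
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.times, self.values)
        out = np.where(
            (t < self.times[0]) | (t > self.times[-1]), np.nan, out
        )
        return out


@dataclass
class DirectionSeries:
    """Angles (rad, in (-pi, pi], left positive) sampled at pulse times."""

    times: np.ndarray
    values: np.ndarray


@dataclass
class LagCorrelation:
    lags: np.ndarray  # s
    r: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: np.ndarray

    @property
    def tau_max(self) -> float:
        return float(self.lags[np.nanargmax(self.r)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau_s": self.lags,
                "r": self.r,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n": self.n,
            }
        )


def _heading_splines(track: FlightTrack, smoothing: float | None):
    if smoothing is None:
        sx = CubicSpline(track.times, track.positions[:, 0])
        sy = CubicSpline(track.times, track.positions[:, 1])
    else:
        sx = make_smoothing_spline(track.times, track.positions[:, 0], lam=smoothing)
        sy = make_smoothing_spline(track.times, track.positions[:, 1], lam=smoothing)
    return sx, sy


def turn_rate_series(
    track: FlightTrack, dt: float = 1e-3, smoothing: float | None = None
) -> TurnRateSeries:
    """Turn rate (rad/s) at ``dt`` spacing from an interpolated track.

    The positions are interpolated with cubic splines (optionally
    smoothing splines, lam = ``smoothing``), the heading is the angle of
    the velocity, and the turn rate is the centered finite difference of
    the unwrapped heading.
    """
    if len(track.times) < 3:
        raise ValueError("need at least three track samples")
    sx, sy = _heading_splines(track, smoothing)
    t = np.arange(track.times[0], track.times[-1] + dt / 2, dt)
    vx, vy = sx(t, 1), sy(t, 1)
    speed = np.hypot(vx, vy)
    if np.any(speed < 1e-9):
        raise ValueError("stationary track: heading undefined at zero speed")
    heading = np.unwrap(np.arctan2(vy, vx))
    rate = np.gradient(heading, t)
    return TurnRateSeries(times=t, values=rate)


def flight_heading(track: FlightTrack, t, smoothing: float | None = None):
    """Heading angle(s) of the flight at time(s) t."""
    sx, sy = _heading_splines(track, smoothing)
    t = np.asarray(t, dtype=float)
    return np.arctan2(sy(t, 1), sx(t, 1))


def _wrap(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


def echo_direction_series(
    points: list[EchoIncidencePoint],
    pulses: list[PulseEvent],
    track: FlightTrack,
    smoothing: float | None = None,
) -> DirectionSeries:
    """Bearing of the strongest echo per pulse, relative to flight direction.

    For each pulse the incidence point with the highest amplitude is
    selected; pulses with no incidence point contribute no sample (a gap,
    not a zero). Leftward angles are positive.
    """
    by_pulse: dict[int, EchoIncidencePoint] = {}
    for p in points:
        cur = by_pulse.get(p.pulse_id)
        if cur is None or p.amplitude > cur.amplitude:
            by_pulse[p.pulse_id] = p
    times, values = [], []
    for pulse in pulses:
        pt = by_pulse.get(pulse.id)
        if pt is None:
            continue
        bearing = np.arctan2(pt.y - pulse.position[1], pt.x - pulse.position[0])
        h = flight_heading(track, pulse.t_emit, smoothing)
        times.append(pulse.t_emit)
        values.append(_wrap(bearing - h))
    return DirectionSeries(np.asarray(times), np.asarray(values, dtype=float))


def pulse_direction_series(
    pulses: list[PulseEvent], track: FlightTrack, smoothing: float | None = None
) -> DirectionSeries:
    """Emission heading relative to flight direction, one sample per pulse."""
    times = np.array([p.t_emit for p in pulses])
    h = flight_heading(track, times, smoothing)
    values = _wrap(np.array([p.heading for p in pulses]) - h)
    return DirectionSeries(times, values)


def direction_series(obj, track: FlightTrack, pulses=None, **kw) -> DirectionSeries:
    """Dispatch to echo_direction_series or pulse_direction_series."""
    if obj and isinstance(obj[0], EchoIncidencePoint):
        if pulses is None:
            raise ValueError("echo direction series needs the pulse events")
        return echo_direction_series(obj, pulses, track, **kw)
    return pulse_direction_series(obj, track, **kw)


def lagged_correlation(
    direction: DirectionSeries,
    turn_rate: TurnRateSeries,
    lag_min: float = -0.1,
    lag_max: float = 0.6,
    step: float = 0.01,
    alpha: float = 0.05,
) -> LagCorrelation:
    """Pearson r between a direction series and the lag-shifted turn rate.

    For each lag tau the turn rate is read at (pulse time + tau) and
    correlated against the direction samples; lags with fewer than 4
    overlapping samples are reported as NaN. The confidence band comes
    from the Fisher z transform: z(r) +/- z_{a/2}/sqrt(n-3), mapped back
    through tanh.
    """
    n_lags = int(round((lag_max - lag_min) / step)) + 1
    lags = lag_min + step * np.arange(n_lags)
    z_crit = norm.ppf(1 - alpha / 2)
    r = np.full(n_lags, np.nan)
    lo = np.full(n_lags, np.nan)
    hi = np.full(n_lags, np.nan)
    ns = np.zeros(n_lags, dtype=int)
    for k, tau in enumerate(lags):
        tr = turn_rate.at(direction.times + tau)
        ok = np.isfinite(tr) & np.isfinite(direction.values)
        ns[k] = int(ok.sum())
        if ns[k] < 4:
            continue
        d, t = direction.values[ok], tr[ok]
        if np.std(d) == 0 or np.std(t) == 0:
            continue
        rk = float(np.corrcoef(d, t)[0, 1])
        r[k] = rk
        half = z_crit / np.sqrt(ns[k] - 3)
        z = np.arctanh(np.clip(rk, -1 + 1e-15, 1 - 1e-15))
        lo[k], hi[k] = np.tanh(z - half), np.tanh(z + half)
    return LagCorrelation(lags=lags, r=r, ci_lo=lo, ci_hi=hi, n=ns)


def edge_distance_summary(
    points: list[EchoIncidencePoint],
    scene: Scene,
    labels: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distances of on-plate incidence points to the inner plate edge.

    Points assigned to a plate get their along-plate distance to the
    free inner edge; only points within the inner half of the plate
    (distance <= length/2, boundary inclusive) are retained. Returns the
    per-point table and a per-group summary (mean, standard error, n).
    ``labels`` optionally maps pulse_id to a grouping label (e.g. flight
    identity); the default grouping is the plate id.
    """
    rows = []
    for p in points:
        if p.obstacle_id is None:
            continue
        plate = scene.plate_by_id(p.obstacle_id)
        d = edge_distance((p.x, p.y), plate)
        if d <= plate.length / 2.0:
            rows.append(
                {
                    "pulse_id": p.pulse_id,
                    "obstacle_id": p.obstacle_id,
                    "distance_m": d,
                    "amplitude": p.amplitude,
                    "group": (
                        labels.get(p.pulse_id, "all") if labels else str(p.obstacle_id)
                    ),
                }
            )
    table = pd.DataFrame(
        rows, columns=["pulse_id", "obstacle_id", "distance_m", "amplitude", "group"]
    )
    if len(table):
        summary = (
            table.groupby("group")["distance_m"]
            .agg(
                mean_m="mean",
                se_m=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
                n="count",
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["group", "mean_m", "se_m", "n"])
    return table, summary


def pulses_affected(lag_difference: float, inter_pulse_intervals) -> float:
    """How many emissions fit into a lag difference, on average.

    The ratio of a correlation-peak lag difference to the mean
    inter-pulse interval estimates which subsequent pulse an echo's
    information shows up in.
    """
    ipis = np.asarray(inter_pulse_intervals, dtype=float)
    if ipis.size == 0:
        raise ValueError("need at least one inter-pulse interval")
    if np.any(ipis <= 0):
        raise ValueError("inter-pulse intervals must be positive")
    if lag_difference < 0:
        raise ValueError("lag difference must be >= 0")
    return float(lag_difference / ipis.mean())
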