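"""Binaural echo localization: from ear waveforms to echo incidence points.

The chain mirrors classic active-sonar processing. Each ear's echo is
matched-filtered against the emitted call (cross-correlation normalized
so the call's autocorrelation peak equals 1), correlation peaks above a
threshold of 0.02 are extracted, left/right peaks are paired within the
maximum interaural travel-time window (2.5 mm / 340 m/s = 7.4 us by
default), and each (t_r, t_l) pair is inverted geometrically: the locus
of scatterers with round-trip delay t to one ear is an ellipse with the
emission point and that ear as foci and semi-major axis t*c0/2, so the
echo incidence point is the forward intersection of the left and right
ellipses.

In the emission-local frame the ears lie on the x axis (right ear at
+d), the emission direction is +y, and both ellipses are axis-aligned
with centers on the x axis; eliminating y^2 leaves a quadratic in x,
which is solved in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import correlate, find_peaks, hilbert

from .fdtd import SimConfig, rasterize_scene, run_fdtd, simulate_impulse_responses
from .scene import (
    EarGeometry,
    FlightTrack,
    PulseEvent,
    Scene,
    assign_to_obstacle,
    occlude_behind,
)
from .signals import Waveform, fm_pulse, sinc_impulse, synthesize_echoes

__all__ = [
    "Peak",
    "PeakPair",
    "EchoIncidencePoint",
    "CorrelationTrace",
    "DegenerateDelayError",
    "matched_filter_peaks",
    "pair_peaks",
    "solve_incidence_point",
    "LocalizeConfig",
    "localize_echoes",
    "points_to_frame",
]

log = logging.getLogger(__name__)

#: Printed interaural pairing window (2.5 mm / 340 m/s).
PAIRING_WINDOW_S = 2.5e-3 / 340.0
#: Geometric alternative derived from the 20 mm ear separation.
PAIRING_WINDOW_GEOMETRIC_S = 20e-3 / 340.0


class DegenerateDelayError(ValueError):
    """Delay too short for the emitter-ear separation (b^2 <= 0)."""


@dataclass(frozen=True)
class Peak:
    t: float  # delay since emission onset (s)
    amplitude: float  # normalized correlation envelope value


@dataclass(frozen=True)
class PeakPair:
    t_r: float
    t_l: float
    amplitude: float


@dataclass
class EchoIncidencePoint:
    pulse_id: int
    time_s: float
    x: float
    y: float
    amplitude: float
    obstacle_id: int | None = None


@dataclass
class CorrelationTrace:
    """Normalized cross-correlation of one ear's echo with the call."""

    lags: np.ndarray  # seconds
    values: np.ndarray  # normalized correlation
    envelope: np.ndarray  # magnitude of the analytic correlation


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample vertex of the parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i), float(b)
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return i + delta, float(b - 0.25 * (a - c) * delta)


def correlation_trace(echo: Waveform, pulse: Waveform) -> CorrelationTrace:
    if abs(echo.fs - pulse.fs) > 1e-6:
        raise ValueError("echo and pulse sampling rates differ")
    norm = float(np.dot(pulse.samples, pulse.samples))
    if norm == 0:
        raise ValueError("all-zero pulse cannot be used as a matched filter")
    corr = correlate(echo.samples, pulse.samples, mode="full") / norm
    lags = (np.arange(len(corr)) - (len(pulse.samples) - 1)) / pulse.fs
    env = np.abs(hilbert(corr))
    return CorrelationTrace(lags, corr, env)


def _unit_echo_template(pulse: Waveform, excitation: Waveform | None):
    """Complex reference response of a unit point echo, and its peak lag.

    Without an excitation this is the analytic autocorrelation of the
    call (peak at index len(call)-1, zero delay offset). With the
    excitation that drove the field, a unit echo contributes the
    excitation wavelet convolved with the call's autocorrelation; its
    envelope peak sits half the excitation length after the true arrival
    and the returned fractional peak index accounts for that.
    """
    norm = float(np.dot(pulse.samples, pulse.samples))
    if excitation is None:
        ref = correlate(pulse.samples, pulse.samples, mode="full") / norm
        start = -(len(pulse.samples) - 1)
    else:
        wavelet = np.convolve(excitation.samples, pulse.samples)
        ref = correlate(wavelet, pulse.samples, mode="full") / norm
        start = -(len(pulse.samples) - 1)
    ref_a = hilbert(ref)
    env = np.abs(ref_a)
    i = int(np.argmax(env))
    pos, peak = _parabolic_refine(env, i)
    return ref_a, start + pos, float(peak)


def matched_filter_peaks(
    echo: Waveform,
    pulse: Waveform,
    threshold: float = 0.02,
    gate: float = 0.0,
    method: str = "clean",
    max_peaks: int = 200,
    excitation: Waveform | None = None,
    alt_refs: list[np.ndarray] | None = None,
) -> list[Peak]:
    """Delays and amplitudes of echoes in a matched-filter output.

    The echo is cross-correlated with the call, normalized by the call's
    autocorrelation peak. ``method="clean"`` (default) iteratively
    extracts the strongest envelope peak and subtracts the unit-echo
    reference response shifted to that delay, so the range sidelobes of
    strong echoes (about -13 dB for a linear FM sweep, i.e. above the
    0.02 threshold whenever an echo is strong) do not spawn spurious
    detections, while genuinely weak echoes away from a stronger one
    survive. ``method="local-max"`` is plain thresholded local-maximum
    picking on the correlation envelope.

    When the field ``excitation`` waveform is supplied, the reference
    response includes it, which both whitens its side-lobe structure out
    of the residual and removes the constant delay offset of half the
    excitation length; reported amplitudes are then relative to a
    unit-amplitude point echo. Peaks at delays <= ``gate`` are discarded
    after extraction (the emitted call reaching the ear directly
    dominates the early correlation).
    """
    if gate < 0:
        raise ValueError("gate must be >= 0")
    tr = correlation_trace(echo, pulse)
    fs = pulse.fs
    ref_a, ref_peak_idx, ref_peak = _unit_echo_template(pulse, excitation)
    t_off = ref_peak_idx / fs if excitation is not None else 0.0
    amp_scale = ref_peak if excitation is not None else 1.0

    if method == "local-max":
        idxs, _ = find_peaks(tr.envelope, height=threshold * amp_scale)
        peaks = []
        for i in idxs:
            pos, amp = _parabolic_refine(tr.envelope, i)
            peaks.append(
                Peak(t=tr.lags[0] + pos / fs - t_off, amplitude=amp / amp_scale)
            )
    elif method == "clean":
        peaks = _clean_extract(
            tr, ref_a, fs, threshold * amp_scale, max_peaks, alt_refs=alt_refs
        )
        peaks = [Peak(p.t - t_off, p.amplitude / amp_scale) for p in peaks]
    else:
        raise ValueError(f"unknown peak-picking method {method!r}")

    # half-sample tolerance so a peak exactly at a zero gate survives
    out = [p for p in peaks if p.t > gate - 0.5 / fs and p.amplitude >= threshold]
    out.sort(key=lambda p: p.t)
    return out


def _clean_extract(
    tr: CorrelationTrace,
    ref_a: np.ndarray,
    fs: float,
    threshold: float,
    max_peaks: int,
    alt_refs: list[np.ndarray] | None = None,
) -> list[Peak]:
    """Iterative peak extraction with complex template subtraction.

    ``alt_refs`` are alternative unit-echo responses (same length and
    zero-lag alignment as ``ref_a``, e.g. diffraction-colored variants);
    during the least-squares polish each component keeps whichever
    template fits its neighborhood best.
    """
    ref_env = np.abs(ref_a)
    center = int(np.argmax(ref_env))
    # main-lobe half width: first drop below half the reference peak
    below = np.nonzero(ref_env[center:] < 0.5 * ref_env[center])[0]
    halfwidth = max(int(below[0]) if len(below) else 2, 2)
    c_pos, _ = _parabolic_refine(ref_env, center)
    idx_ref = np.arange(len(ref_a))

    def _cplx_at(arr: np.ndarray, x: float) -> complex:
        return complex(
            np.interp(x, np.arange(len(arr)), arr.real),
            np.interp(x, np.arange(len(arr)), arr.imag),
        )

    # normalize by the complex value at the fractional peak so that a
    # subtraction at the estimated position cancels exactly in phase
    ref_unit = ref_a / _cplx_at(ref_a, c_pos)

    residual = hilbert(tr.values).astype(complex)
    n = len(residual)
    raw: list[tuple[float, float]] = []  # (fractional index, amplitude)
    peak0 = None
    for _ in range(10 * max_peaks):
        env = np.abs(residual)
        i = int(np.argmax(env))
        if peak0 is None:
            peak0 = env[i]
        elif env[i] > 2.0 * peak0:  # runaway guard: template mismatch
            break
        if env[i] < threshold or len(raw) >= 10 * max_peaks:
            break
        pos, amp = _parabolic_refine(env, i)
        coeff = _cplx_at(residual, pos)
        # subtract the reference response shifted to the fractional lag
        lo = max(0, i - len(ref_unit) - 2)
        hi = min(n, i + len(ref_unit) + 2)
        k = np.arange(lo, hi)
        shifted = np.interp(
            k - pos + c_pos, idx_ref, ref_unit.real, left=0.0, right=0.0
        ) + 1j * np.interp(
            k - pos + c_pos, idx_ref, ref_unit.imag, left=0.0, right=0.0
        )
        residual[lo:hi] -= coeff * shifted
        # guarantee progress even if the subtraction is imperfect
        residual[max(0, i - 1) : i + 2] = 0.0
        raw.append((pos, amp))
    # imperfect subtraction leaves debris around strong peaks; keep the
    # strongest member of each main-lobe-sized cluster
    raw.sort(key=lambda q: -q[1])
    accepted: list[tuple[float, float]] = []
    for pos, amp in raw:
        if all(abs(pos - q) > halfwidth for q, _ in accepted):
            accepted.append((pos, amp))
        if len(accepted) >= max_peaks:
            break

    # least-squares polish: coordinate descent on (position, complex
    # amplitude, template choice) of every component against the original
    # correlation; single-pass greedy estimates are biased by overlapping
    # responses
    corr_a = hilbert(tr.values)
    k_all = np.arange(n)
    # candidate unit-echo responses; index 0 is the main template. All
    # share the zero-lag alignment, so one shift formula serves them all.
    refs = [ref_a] + list(alt_refs or [])
    ref_peaks = [float(np.abs(r).max()) for r in refs]

    def shifted_template(p: float, j: int = 0) -> np.ndarray:
        r = refs[j]
        return np.interp(
            k_all - p + c_pos, np.arange(len(r)), r.real, left=0.0, right=0.0
        ) + 1j * np.interp(
            k_all - p + c_pos, np.arange(len(r)), r.imag, left=0.0, right=0.0
        )

    positions = [pos for pos, _ in accepted]
    if not positions:
        return []
    choices = [0] * len(positions)

    def joint_amplitudes() -> np.ndarray:
        T = np.column_stack(
            [shifted_template(p, j) for p, j in zip(positions, choices)]
        )
        G = T.conj().T @ T
        b = T.conj().T @ corr_a
        return np.linalg.solve(G, b)

    coeffs = joint_amplitudes() if positions else np.array([])
    for _ in range(6):
        templates = [shifted_template(p, j) for p, j in zip(positions, choices)]
        for m, p in enumerate(positions):
            res = corr_a - sum(
                coeffs[j] * templates[j] for j in range(len(positions)) if j != m
            )
            # judge the fit on the component's own neighborhood so that
            # remote mismatch from stronger components cannot drag it
            i_c = int(round(p))
            win = slice(max(0, i_c - 2 * halfwidth), min(n, i_c + 2 * halfwidth))

            def _fit(p_try, j_try):
                T = shifted_template(p_try, j_try)
                denom = np.vdot(T[win], T[win]).real
                if denom <= 0:
                    return np.inf, p_try, 0.0 + 0.0j, j_try
                c = np.vdot(T[win], res[win]) / denom
                err = float(np.sum(np.abs(res[win] - c * T[win]) ** 2))
                return err, p_try, c, j_try

            trials = []
            for j_try in range(len(refs)):
                coarse = [_fit(p + dp, j_try) for dp in np.arange(-3.0, 3.5, 1.0)]
                _, p_best, _, _ = min(coarse, key=lambda t: t[0])
                fine = [
                    _fit(p_best + dp, j_try) for dp in np.linspace(-1.0, 1.0, 17)
                ]
                trials.append(min(fine, key=lambda t: t[0]))
            _, p_new, c_new, j_new = min(trials, key=lambda t: t[0])
            positions[m] = p_new
            choices[m] = j_new
            templates[m] = shifted_template(p_new, j_new)
            coeffs[m] = c_new
        coeffs = joint_amplitudes()
    comps = list(zip(positions, coeffs, choices))
    # merge components that collapsed onto each other
    comps.sort(key=lambda q: -abs(q[1]))
    merged: list[tuple[float, complex, int]] = []
    for p, c, j in comps:
        if all(abs(p - q) > 1.0 for q, _, _ in merged):
            merged.append((p, c, j))
    return [
        Peak(t=tr.lags[0] + p / fs, amplitude=float(abs(c) * ref_peaks[j]))
        for p, c, j in merged
        if abs(c) * ref_peaks[j] >= threshold
    ]


_CAL_CACHE: dict[tuple, Waveform] = {}


def calibration_wavelet(
    sim: SimConfig,
    impulse: Waveform,
    nostril_offset: float = 1.25e-3,
    r_cal: float | None = None,
) -> Waveform:
    """In-situ unit-echo wavelet from a free-field calibration run.

    The excitation injected at the two nostril cells does not arrive at
    a distant point as the pristine waveform: the soft source, the 2D
    cylindrical-wave afterglow and grid dispersion all color it. A
    matched filter (and especially the CLEAN subtraction template) works
    markedly better with the wavelet the field actually produces, so
    this runs the solver once on an empty strip, with the same source
    pair, and records the waveform ``r_cal`` meters down-range. The
    returned waveform starts exactly at the nominal arrival time
    r_cal/c0, so using it as the unit-echo reference also absorbs the
    solver's small propagation-delay bias. Cached per configuration.
    """
    if r_cal is None:
        r_cal = sim.c0 * sim.duration / 4.0
    key = (
        sim.dx,
        sim.fs,
        sim.c0,
        len(impulse.samples),
        float(np.sum(impulse.samples**2)),
        nostril_offset,
        round(r_cal, 6),
    )
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]

    margin = 0.05
    width = 0.4
    extent = (0.0, 0.0, r_cal + 2 * margin, width)
    cal_scene = Scene(extent=extent)
    medium = rasterize_scene(cal_scene, sim)
    y_mid = width / 2.0
    src = [
        (medium.cell_of((margin, y_mid + nostril_offset)), impulse.samples),
        (medium.cell_of((margin, y_mid - nostril_offset)), impulse.samples),
    ]
    rec = [medium.cell_of((margin + r_cal, y_mid))]
    t_arr = r_cal / sim.c0
    n_keep = int(round(3.2 * impulse.duration * sim.fs))
    n_steps = int(round(t_arr * sim.fs)) + n_keep
    traces, _, _ = run_fdtd(medium, src, rec, n_steps, sim)
    start = int(round(t_arr * sim.fs))
    wavelet = traces[0][start:]
    peak = np.max(np.abs(wavelet))
    if peak > 0:
        wavelet = wavelet / peak
    out = Waveform(wavelet, sim.fs)
    _CAL_CACHE[key] = out
    return out


def remove_direct_wave(samples: np.ndarray, fs: float, t_cut: float) -> np.ndarray:
    """Zero an impulse response before ``t_cut`` (short cosine ramp-in).

    The emitted wavelet reaches the ears within the head geometry's
    travel time plus the excitation length, well before the first
    obstacle echo, so the direct wave can be excised in the
    impulse-response domain where it does not yet overlap any echo.
    """
    out = np.array(samples, dtype=float)
    n_cut = int(round(t_cut * fs))
    if n_cut <= 0:
        return out
    n_cut = min(n_cut, len(out))
    out[:n_cut] = 0.0
    ramp = min(16, len(out) - n_cut)
    if ramp > 0:
        w = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        out[n_cut : n_cut + ramp] *= w
    return out


def _diffraction_colored_refs(
    ac: np.ndarray, fs: float, f_ref: float
) -> list[np.ndarray]:
    """Edge-diffraction variants of a unit-echo correlation response.

    Diffraction from a rigid edge colors the wave by roughly 1/sqrt(f)
    with a +-45 degree phase, so a diffracted echo is slightly mis-timed
    when fitted with the plain reflection response. Applying that
    coloring to the response (zero-phase, so the zero-lag alignment is
    preserved) gives alternative templates a component can select.
    """
    L = len(ac)
    pad = 2 * L
    S = np.fft.rfft(ac, pad)
    f = np.fft.rfftfreq(pad, 1.0 / fs)
    f_lo = 0.25 * f_ref
    mag = (np.maximum(f, f_lo) / f_ref) ** -0.5
    out = []
    for sign in (+1.0, -1.0):
        H = mag * np.exp(-1j * sign * np.pi / 4.0)
        H[0] = mag[0]
        colored = np.fft.irfft(S * H, pad)[:L]
        out.append(hilbert(colored))
    return out


def refine_peak_times(
    peaks: list[Peak],
    ir: np.ndarray,
    wavelet: Waveform,
    gate: float,
    match_window: float = 60e-6,
    threshold: float = 3e-3,
) -> list[Peak]:
    """Re-time detected peaks against the broadband impulse response.

    The call's matched filter fixes which echoes exist and how strong
    they are, but its narrow band limits delay precision. The impulse
    response retains the excitation's full bandwidth, so matched
    filtering it with the calibration wavelet and snapping each detected
    delay to the nearest broadband component recovers nearly an order
    of magnitude in timing precision. Peaks with no broadband partner
    within ``match_window`` keep their original time.
    """
    if not peaks:
        return peaks
    ir_wave = Waveform(ir, wavelet.fs)
    # spectral centroid of the wavelet sets the coloring reference
    W = np.abs(np.fft.rfft(wavelet.samples)) ** 2
    fgrid = np.fft.rfftfreq(len(wavelet.samples), 1.0 / wavelet.fs)
    f_ref = float(np.sum(fgrid * W) / np.sum(W))
    ac = correlate(wavelet.samples, wavelet.samples, mode="full") / float(
        np.dot(wavelet.samples, wavelet.samples)
    )
    alt_refs = _diffraction_colored_refs(ac, wavelet.fs, f_ref)
    fine = matched_filter_peaks(
        ir_wave,
        wavelet,
        threshold=threshold,
        gate=gate,
        method="clean",
        max_peaks=40,
        alt_refs=alt_refs,
    )
    if not fine:
        return peaks
    t_fine = np.array([p.t for p in fine])
    a_fine = np.array([p.amplitude for p in fine])
    out = []
    for p in peaks:
        near = np.abs(t_fine - p.t) <= match_window
        if near.any():
            # the strongest broadband component in the window is the
            # echo itself; weaker satellites are secondary scattering
            j = int(np.argmax(np.where(near, a_fine, -np.inf)))
            out.append(Peak(t=float(t_fine[j]), amplitude=p.amplitude))
        else:
            out.append(p)
    return out


def refine_pair_itds(
    pairs: list[PeakPair],
    ir_l: np.ndarray,
    ir_r: np.ndarray,
    wavelet: Waveform,
    half_window: float | None = None,
) -> list[PeakPair]:
    """Refine each pair's interaural delay by binaural cross-correlation.

    The same echo arrives at the two ears as nearly identical waveforms
    (same path coloring, slightly different delay), so cross-correlating
    the two ears' broadband matched-filter outputs around the paired
    delays measures the interaural difference with the waveform-shape
    biases cancelled. Components belonging to other pairs are projected
    out of each window first so a strong neighbor's side lobes cannot
    drag the estimate. The pair's mean delay (range) is kept; only the
    left/right split is updated.
    """
    if not pairs:
        return pairs
    fs = wavelet.fs
    norm = float(np.dot(wavelet.samples, wavelet.samples))
    lag0 = -(len(wavelet.samples) - 1)
    ac = correlate(wavelet.samples, wavelet.samples, mode="full") / norm
    T_a = hilbert(ac)
    T_env = np.abs(T_a)
    c_idx = int(np.argmax(T_env))
    c_pos, _ = _parabolic_refine(T_env, c_idx)

    if half_window is None:
        # about twice the broadband correlation main lobe: wide enough
        # for the whole compressed echo, narrow enough to exclude most
        # of the neighbors' side-lobe structure
        below = np.nonzero(T_env[c_idx:] < 0.5 * T_env[c_idx])[0]
        hw_samples = int(below[0]) if len(below) else 4
        half_window = 2.0 * hw_samples / fs

    def analytic_corr(ir):
        c = correlate(ir, wavelet.samples, mode="full") / norm
        return hilbert(c)

    def fit_components(a, times):
        n = len(a)
        k_all = np.arange(n)
        idx_t = np.arange(len(T_a))
        cols = []
        for t in times:
            p = t * fs - lag0
            cols.append(
                np.interp(k_all - p + c_pos, idx_t, T_a.real, left=0.0, right=0.0)
                + 1j * np.interp(k_all - p + c_pos, idx_t, T_a.imag, left=0.0, right=0.0)
            )
        M = np.column_stack(cols)
        coeff = np.linalg.lstsq(M, a, rcond=None)[0]
        return M, coeff

    aL = analytic_corr(ir_l)
    aR = analytic_corr(ir_r)
    ML, cL = fit_components(aL, [p.t_l for p in pairs])
    MR, cR = fit_components(aR, [p.t_r for p in pairs])
    W = max(int(half_window * fs), 4)

    out = []
    for k, pair in enumerate(pairs):
        # project out only components much stronger than this one: their
        # (near zero interaural delay) side lobes bias the window, while
        # subtracting comparable components injects more fit error than
        # it removes
        big_l = [j for j in range(len(pairs)) if j != k and abs(cL[j]) > 3 * abs(cL[k])]
        big_r = [j for j in range(len(pairs)) if j != k and abs(cR[j]) > 3 * abs(cR[k])]
        resL = aL - sum(cL[j] * ML[:, j] for j in big_l) if big_l else aL
        resR = aR - sum(cR[j] * MR[:, j] for j in big_r) if big_r else aR
        il = int(round(pair.t_l * fs - lag0))
        ir_i = int(round(pair.t_r * fs - lag0))
        if il - W < 0 or il + W + 1 > len(resL) or ir_i - W < 0 or ir_i + W + 1 > len(resR):
            out.append(pair)
            continue
        xc = np.abs(correlate(resL[il - W : il + W + 1], resR[ir_i - W : ir_i + W + 1]))
        j = int(np.argmax(xc))
        pos, _ = _parabolic_refine(xc, j)
        lam = (pos - (2 * W)) / fs
        diff_xc = (il - ir_i) / fs + lam  # binaural estimate of t_l - t_r
        # the per-ear component fits and the binaural cross-correlation
        # err through different mechanisms (template mismatch vs window
        # truncation); their mean is the steadier estimate
        diff = 0.5 * (diff_xc + (pair.t_l - pair.t_r))
        mean = 0.5 * (pair.t_l + pair.t_r)
        out.append(
            PeakPair(
                t_r=mean - diff / 2.0, t_l=mean + diff / 2.0, amplitude=pair.amplitude
            )
        )
    return out


def echo_reference_scale(
    echoes: tuple[Waveform, ...],
    call: Waveform,
    mode: str,
    gate: float,
    excitation: Waveform | None = None,
) -> float:
    """Common amplitude reference for a pair of ear echoes.

    ``mode="strongest-echo"`` returns the largest correlation envelope
    value after the gate across both ears: thresholding at 0.02 then
    keeps everything within 34 dB of the strongest echo, which detects
    almost all genuine peaks regardless of absolute source level.
    ``mode="direct"`` uses the direct wave (lags before the gate)
    instead, making amplitudes relative to the emitted call heard at the
    ear. ``mode="none"`` returns 1.
    """
    if mode == "none":
        return 1.0
    _, ref_peak_idx, ref_peak = _unit_echo_template(call, excitation)
    t_off = ref_peak_idx / call.fs if excitation is not None else 0.0
    scale = 0.0
    for echo in echoes:
        tr = correlation_trace(echo, call)
        mask = (tr.lags - t_off) > gate if mode == "strongest-echo" else (
            (tr.lags - t_off) <= gate
        )
        if mask.any():
            scale = max(scale, float(tr.envelope[mask].max()))
    if excitation is not None and scale > 0:
        scale /= ref_peak
    return scale if scale > 0 else 1.0


def pair_peaks(
    left: list[Peak], right: list[Peak], window: float = PAIRING_WINDOW_S
) -> list[PeakPair]:
    """Match left/right peaks within the interaural window.

    One-to-one matching minimizing the total |t_r - t_l| (computed with
    the Hungarian algorithm); peaks further apart than ``window`` are
    never paired and each peak is used at most once.
    """
    if not left or not right:
        return []
    tl = np.array([p.t for p in left])
    tr = np.array([p.t for p in right])
    cost = np.abs(tl[:, None] - tr[None, :])
    big = 1e6 * (cost.max() + window + 1.0)
    cost = np.where(cost <= window, cost, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    for i, j in zip(rows, cols):
        if abs(tl[i] - tr[j]) <= window:
            pairs.append(
                PeakPair(
                    t_r=float(tr[j]),
                    t_l=float(tl[i]),
                    amplitude=max(left[i].amplitude, right[j].amplitude),
                )
            )
    pairs.sort(key=lambda p: (p.t_r + p.t_l) / 2)
    return pairs


def solve_incidence_point(
    pair: PeakPair,
    pulse: PulseEvent,
    ears: EarGeometry,
    c0: float,
    prev_point: np.ndarray | None = None,
) -> EchoIncidencePoint | None:
    """Forward intersection of the left and right delay ellipses.

    Returns None when the two ellipses have no real intersection on the
    forward (emission-direction) side; raises DegenerateDelayError when a
    delay is shorter than the emitter-ear separation allows.
    """
    d = ears.ear_offset
    x_r, x_l = d, -d  # ear coordinates on the local inter-ear axis
    xr0, xl0 = x_r / 2.0, x_l / 2.0

    a_r = pair.t_r * c0 / 2.0
    a_l = pair.t_l * c0 / 2.0
    br2 = a_r**2 - (x_r - xr0) ** 2
    bl2 = a_l**2 - (x_l - xl0) ** 2
    if br2 <= 0 or bl2 <= 0:
        raise DegenerateDelayError(
            "delay shorter than the emitter-ear separation permits"
        )
    Ar, Al = a_r**2, a_l**2
    Br, Bl = br2, bl2

    # eliminate y^2 between the two axis-aligned ellipses -> quadratic in x
    c2 = Bl / Al - Br / Ar
    c1 = 2.0 * (Br * xr0 / Ar - Bl * xl0 / Al)
    c0_ = Bl * xl0**2 / Al - Br * xr0**2 / Ar + Br - Bl

    scale = max(abs(c2), abs(c1) / d, 1e-300)
    if abs(c2) < 1e-9 * scale * d:
        if c1 == 0:
            return None
        roots = np.array([-c0_ / c1])
    else:
        disc = c1**2 - 4 * c2 * c0_
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        roots = np.array([(-c1 + sq) / (2 * c2), (-c1 - sq) / (2 * c2)])

    candidates = []
    for x in roots:
        y2 = Br * (1.0 - (x - xr0) ** 2 / Ar)
        if y2 >= 0:
            candidates.append((float(x), float(np.sqrt(y2))))
    if not candidates:
        return None

    right_dir = -ears.left_dir
    fwd = pulse.direction

    def to_world(xy):
        return pulse.position + xy[0] * right_dir + xy[1] * fwd

    if len(candidates) > 1:
        if prev_point is not None:
            candidates.sort(key=lambda xy: np.linalg.norm(to_world(xy) - prev_point))
        else:
            candidates.sort(key=lambda xy: abs(xy[0]))
    x_loc, y_loc = candidates[0]
    w = to_world((x_loc, y_loc))
    return EchoIncidencePoint(
        pulse_id=pulse.id,
        time_s=pulse.t_emit,
        x=float(w[0]),
        y=float(w[1]),
        amplitude=pair.amplitude,
    )


@dataclass
class LocalizeConfig:
    """Parameters for the per-pulse simulate/detect/localize chain."""

    sim: SimConfig = field(default_factory=SimConfig)
    threshold: float = 0.02
    window: float = PAIRING_WINDOW_S
    gate: float | None = None  # None -> direct-wave window (see localize_pulse)
    assign_tol: float = 0.02
    nostril_offset: float = 1.25e-3
    ear_offset: float = 10e-3
    impulse_cutoff: float = 110e3
    impulse_duration: float = 0.073e-3
    call_duration: float = 2e-3
    call_f1_start: float = 34e3
    call_f1_end: float = 25e3
    call_levels_db: tuple[float, float, float] = (-40.0, 0.0, -40.0)
    peak_method: str = "clean"
    normalize: str = "strongest-echo"  # or "direct" / "none"
    calibrate: bool = True
    calibration_range: float | None = None  # None -> c0 * duration / 4
    refine_timing: bool = True
    min_echo_level: float = 0.01  # strongest echo below this (re direct) = no echoes

    def impulse(self) -> Waveform:
        return sinc_impulse(self.sim.fs, self.impulse_cutoff, self.impulse_duration)

    def call(self) -> Waveform:
        return fm_pulse(
            self.sim.fs,
            self.call_duration,
            self.call_f1_start,
            self.call_f1_end,
            self.call_levels_db,
        )

    def scaled(self, band_scale: float) -> "LocalizeConfig":
        """Copy with the call/excitation band multiplied by ``band_scale``.

        The excitation duration is stretched by the inverse factor so the
        sinc keeps the same number of side lobes.
        """
        return dc_replace(
            self,
            impulse_cutoff=self.impulse_cutoff * band_scale,
            impulse_duration=self.impulse_duration / band_scale,
            call_f1_start=self.call_f1_start * band_scale,
            call_f1_end=self.call_f1_end * band_scale,
        )


def localize_pulse(
    scene: Scene, pulse: PulseEvent, config: LocalizeConfig
) -> list[EchoIncidencePoint]:
    """Full chain for a single emission; see ``localize_echoes``."""
    return analyze_pulse(scene, pulse, config)["points"]


def analyze_pulse(scene: Scene, pulse: PulseEvent, config: LocalizeConfig) -> dict:
    """Like ``localize_pulse`` but returning the intermediate products.

    The dict carries "peaks_l"/"peaks_r" (detected matched-filter peaks),
    "pairs" (matched left/right delay pairs) and "points" (localized
    incidence points) for inspection and validation.
    """
    ears = EarGeometry(pulse, config.nostril_offset, config.ear_offset)
    visible = occlude_behind(scene, pulse)
    impulse = config.impulse()
    call = config.call()
    ir_l, ir_r = simulate_impulse_responses(visible, pulse, impulse, config.sim, ears)
    c_amb = scene.c0
    # the direct wave ends within the head geometry's travel time plus
    # the excitation length (25% margin for the numerical tail); cut it
    # out of the impulse responses before the call is convolved in, so
    # the matched filter sees echoes only
    t_cut = (ears.ear_offset + 2 * ears.nostril_offset) / c_amb + 1.25 * impulse.duration
    fs = config.sim.fs
    ir_l.samples = remove_direct_wave(ir_l.samples, fs, t_cut)
    ir_r.samples = remove_direct_wave(ir_r.samples, fs, t_cut)
    echo_l, echo_r = synthesize_echoes(ir_l, ir_r, call)
    gate = config.gate if config.gate is not None else t_cut
    if config.calibrate:
        wavelet = calibration_wavelet(
            config.sim, impulse, config.nostril_offset, config.calibration_range
        )
    else:
        wavelet = impulse
    if config.normalize == "strongest-echo":
        scale = echo_reference_scale(
            (echo_l, echo_r), call, config.normalize, gate, excitation=wavelet
        )
        # the impulse responses are direct-wave-normalized, so the scale
        # is also the strongest echo's level relative to the emitted call
        # at the ear; below the floor it is boundary/grid debris that
        # must not be amplified up to full scale
        if scale < config.min_echo_level:
            return {"peaks_l": [], "peaks_r": [], "pairs": [], "points": []}
    else:
        # impulse responses are already normalized to the direct wave
        scale = 1.0
    echo_l = Waveform(echo_l.samples / scale, echo_l.fs)
    echo_r = Waveform(echo_r.samples / scale, echo_r.fs)
    kw = dict(
        threshold=config.threshold,
        gate=gate,
        method=config.peak_method,
        excitation=wavelet,
    )
    peaks_l = matched_filter_peaks(echo_l, call, **kw)
    peaks_r = matched_filter_peaks(echo_r, call, **kw)
    if config.refine_timing and config.calibrate:
        peaks_l = refine_peak_times(peaks_l, ir_l.samples, wavelet, gate)
        peaks_r = refine_peak_times(peaks_r, ir_r.samples, wavelet, gate)
    pairs = pair_peaks(peaks_l, peaks_r, config.window)
    if config.refine_timing and config.calibrate:
        pairs = refine_pair_itds(pairs, ir_l.samples, ir_r.samples, wavelet)
    points: list[EchoIncidencePoint] = []
    prev = None
    for pair in pairs:
        try:
            pt = solve_incidence_point(pair, pulse, ears, c_amb, prev_point=prev)
        except DegenerateDelayError:
            log.warning("pulse %d: degenerate delay pair %s", pulse.id, pair)
            continue
        if pt is None:
            log.info("pulse %d: pair %s has no forward intersection", pulse.id, pair)
            continue
        pt.obstacle_id = assign_to_obstacle((pt.x, pt.y), scene, config.assign_tol)
        points.append(pt)
        prev = np.array([pt.x, pt.y])
    return {"peaks_l": peaks_l, "peaks_r": peaks_r, "pairs": pairs, "points": points}


def localize_echoes(
    scene: Scene,
    track: FlightTrack | None,
    pulses: list[PulseEvent],
    config: LocalizeConfig,
) -> list[EchoIncidencePoint]:
    """Echo incidence points for every pulse of a flight.

    Per-pulse failures are logged and skipped so one bad emission does
    not abort the batch. ``track`` is accepted for interface symmetry
    with the analysis stage (the localization itself only needs the
    pulse events).
    """
    points: list[EchoIncidencePoint] = []
    for pulse in pulses:
        try:
            points.extend(localize_pulse(scene, pulse, config))
        except Exception:  # noqa: BLE001 - deliberate per-pulse isolation
            log.exception("pulse %d failed; continuing", pulse.id)
    return points


def points_to_frame(points: list[EchoIncidencePoint]):
    """Incidence points as a tidy DataFrame (unlocalized -> 'unlocalized')."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pulse_id": [p.pulse_id for p in points],
            "time_s": [p.time_s for p in points],
            "x_m": [p.x for p in points],
            "y_m": [p.y for p in points],
            "amplitude": [p.amplitude for p in points],
            "obstacle_id": [
                p.obstacle_id if p.obstacle_id is not None else "unlocalized"
                for p in points
            ],
        }
    )
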