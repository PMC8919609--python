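import numpy as np
import pytest
from scipy.signal import hilbert

from echospace.fdtd import (
    SimConfig,
    StabilityError,
    cfl_number,
    rasterize_scene,
    run_fdtd,
    simulate_impulse_responses,
)
from echospace.localize import correlation_trace
from echospace.scene import (
    CircleObstacle,
    EarGeometry,
    ObstaclePlate,
    PulseEvent,
    Scene,
)
from echospace.signals import Waveform, sinc_impulse


def small_config(**kw):
    kw.setdefault("dx", 2e-3)
    kw.setdefault("fs", 0.25e6)
    kw.setdefault("duration", 1.5e-3)
    return SimConfig(**kw)


def probe(fs):
    return sinc_impulse(fs, cutoff=20e3, duration=0.4e-3)


def arrival_time(trace, template, fs):
    """Matched-filter envelope peak of a receiver trace (sub-sample)."""
    tr = correlation_trace(Waveform(trace, fs), Waveform(template.samples, fs))
    i = int(np.argmax(tr.envelope))
    a, b, c = tr.envelope[i - 1 : i + 2]
    delta = 0.5 * (a - c) / (a - 2 * b + c)
    return tr.lags[0] + (i + delta) / fs


class TestCfl:
    def test_full_resolution_parameters(self):
        cfg = SimConfig(dx=0.3e-3, fs=2e6, c0=340.0)
        assert round(cfl_number(cfg), 2) == 0.57
        assert cfg.stable

    def test_simple_arithmetic(self):
        assert cfl_number(SimConfig(dx=1e-3, fs=1e6, c0=340.0)) == pytest.approx(0.34)

    def test_unstable_flagged_and_refused(self):
        cfg = SimConfig(dx=1e-3, fs=0.4e6, c0=340.0, duration=1e-4)
        assert cfg.cfl > 1 / np.sqrt(2)
        assert not cfg.stable
        scene = Scene(extent=(0, 0, 0.1, 0.1))
        med = rasterize_scene(scene, cfg)
        with pytest.raises(StabilityError):
            run_fdtd(med, [], [(5, 5)], 10, cfg)


class TestRasterize:
    def test_empty_scene_uniform_air(self):
        cfg = small_config()
        scene = Scene(extent=(0, 0, 0.1, 0.2))
        med = rasterize_scene(scene, cfg)
        assert med.shape == (50, 100)
        assert np.all(med.density == scene.ambient.density)
        # constant-speed scheme: kappa = rho c0^2 everywhere
        assert np.allclose(med.bulk_modulus, med.density * cfg.c0**2)

    def test_plate_cell_count_matches_bruteforce(self):
        cfg = SimConfig(dx=1e-3, fs=0.5e6)
        plate = ObstaclePlate(
            id=0, p_start=np.array([0.5, 0.02]), p_end=np.array([0.5, 1.02]),
            thickness=5e-3,
        )
        scene = Scene(extent=(0, 0, 1.2, 1.2), plates=[plate])
        med = rasterize_scene(scene, cfg)
        n_acrylic = int(np.sum(med.density > 2))
        xs = (np.arange(med.shape[0]) + 0.5) * cfg.dx
        ys = (np.arange(med.shape[1]) + 0.5) * cfg.dx
        XX, YY = np.meshgrid(xs, ys, indexing="ij")
        inside = plate.contains(np.column_stack([XX.ravel(), YY.ravel()]))
        assert n_acrylic == int(inside.sum())
        assert n_acrylic >= 1000  # a 1 m x 5 mm plate at 1 mm spacing


class TestPropagation:
    def test_free_field_arrival(self):
        cfg = small_config()
        scene = Scene(extent=(0, 0, 0.4, 0.4))
        med = rasterize_scene(scene, cfg)
        imp = probe(cfg.fs)
        src = med.cell_of((0.1, 0.2))
        rec = med.cell_of((0.27, 0.2))
        traces, _, _ = run_fdtd(med, [(src, imp.samples)], [rec], cfg.n_steps, cfg)
        t = arrival_time(traces[0], imp, cfg.fs)
        assert t == pytest.approx(0.17 / cfg.c0, rel=0.02)

    def test_plate_echo_arrival(self):
        cfg = small_config(duration=2.4e-3)
        plate = ObstaclePlate(
            id=0, p_start=np.array([0.36, 0.05]), p_end=np.array([0.36, 0.35]),
            thickness=4e-3,
        )
        scene = Scene(extent=(0, 0, 0.5, 0.4), plates=[plate])
        med = rasterize_scene(scene, cfg)
        imp = probe(cfg.fs)
        src = med.cell_of((0.108, 0.2))
        rec = med.cell_of((0.108, 0.21))
        traces, _, _ = run_fdtd(med, [(src, imp.samples)], [rec], cfg.n_steps, cfg)
        # gate out the direct wave, then the echo dominates
        trace = traces[0].copy()
        trace[: int(0.9e-3 * cfg.fs)] = 0.0
        t = arrival_time(trace, imp, cfg.fs)
        # reflection at the near face (0.358), source 0.108 -> 0.25 m away
        assert t == pytest.approx(2 * 0.25 / cfg.c0, rel=0.02)

    def test_mur_boundary_absorbs(self):
        cfg = small_config(duration=3.0e-3)
        scene = Scene(extent=(0, 0, 0.3, 0.3))
        med = rasterize_scene(scene, cfg)
        imp = probe(cfg.fs)
        src = med.cell_of((0.15, 0.15))
        _, energy, _ = run_fdtd(
            med, [(src, imp.samples)], [src], cfg.n_steps, cfg, record_energy=True
        )
        # after the wavefront leaves (~0.21 m to the corner and out),
        # residual field energy is below 1% of the peak
        assert energy[-1] < 0.01 * energy.max()

    def test_reciprocity(self):
        cfg = small_config(duration=1.2e-3)
        # heterogeneous medium: a dense circular inclusion off-center
        scene = Scene(
            extent=(0, 0, 0.3, 0.3),
            circles=[CircleObstacle(id=0, center=np.array([0.18, 0.2]), radius=0.03)],
        )
        med = rasterize_scene(scene, cfg)
        imp = probe(cfg.fs)
        a = med.cell_of((0.07, 0.1))
        b = med.cell_of((0.23, 0.12))
        t_ab, _, _ = run_fdtd(med, [(a, imp.samples)], [b], cfg.n_steps, cfg)
        t_ba, _, _ = run_fdtd(med, [(b, imp.samples)], [a], cfg.n_steps, cfg)
        diff = np.sqrt(np.mean((t_ab[0] - t_ba[0]) ** 2))
        ref = np.sqrt(np.mean(t_ab[0] ** 2))
        assert diff < 0.01 * ref

    def test_pair_directivity_broadside(self):
        # two in-phase sources half a wavelength apart: louder broadside
        # (the emission direction) than end-fire (along the pair axis)
        cfg = SimConfig(dx=0.5e-3, fs=1e6, duration=0.65e-3)
        scene = Scene(extent=(0, 0, 0.2, 0.2))
        med = rasterize_scene(scene, cfg)
        f0 = 68e3
        sep = cfg.c0 / f0 / 2.0  # half wavelength
        n = int(0.2e-3 * cfg.fs)
        tone = np.sin(2 * np.pi * f0 * np.arange(n) / cfg.fs) * np.hanning(n)
        srcs = [
            (med.cell_of((0.1, 0.1 + sep / 2)), tone),
            (med.cell_of((0.1, 0.1 - sep / 2)), tone),
        ]
        rec_fwd = med.cell_of((0.17, 0.1))
        rec_side = med.cell_of((0.1, 0.17))
        traces, _, _ = run_fdtd(med, srcs, [rec_fwd, rec_side], cfg.n_steps, cfg)
        assert np.max(np.abs(traces[0])) > 2.0 * np.max(np.abs(traces[1]))

    def test_long_run_stays_finite(self):
        cfg = SimConfig(dx=2e-3, fs=0.25e6, c0=340.0)
        assert round(cfg.cfl, 2) == 0.68
        scene = Scene(extent=(0, 0, 0.12, 0.12))
        med = rasterize_scene(scene, cfg)
        imp = probe(cfg.fs)
        src = med.cell_of((0.06, 0.06))
        traces, _, _ = run_fdtd(med, [(src, imp.samples)], [src], 10_000, cfg)
        assert np.all(np.isfinite(traces))

    def test_convergence_under_refinement(self):
        scene = Scene(extent=(0, 0, 0.3, 0.2))
        times = {}
        for dx in (2e-3, 1e-3):
            fs = 0.25e6 * (2e-3 / dx)  # fixed CFL
            cfg = SimConfig(dx=dx, fs=fs, duration=1.0e-3)
            med = rasterize_scene(scene, cfg)
            # ~14 cells per wavelength on the coarse grid keeps the
            # comparison about convergence rather than raw dispersion
            imp = sinc_impulse(fs, cutoff=12e3, duration=0.6e-3)
            src = med.cell_of((0.05, 0.1))
            rec = med.cell_of((0.25, 0.1))
            traces, _, _ = run_fdtd(med, [(src, imp.samples)], [rec], cfg.n_steps, cfg)
            times[dx] = arrival_time(traces[0], imp, fs)
        coarse_sample = 1.0 / 0.25e6
        assert abs(times[2e-3] - times[1e-3]) < coarse_sample


class TestImpulseResponses:
    def test_receiver_inside_plate_rejected(self):
        cfg = small_config()
        plate = ObstaclePlate(
            id=0, p_start=np.array([0.2, 0.05]), p_end=np.array([0.2, 0.35]),
            thickness=30e-3,
        )
        scene = Scene(extent=(0, 0, 0.4, 0.4), plates=[plate])
        pulse = PulseEvent(
            id=0, t_emit=0.0, position=np.array([0.195, 0.2]),
            direction=np.array([1.0, 0.0]),
        )
        with pytest.raises(ValueError):
            simulate_impulse_responses(scene, pulse, probe(cfg.fs), cfg)

    def test_direct_wave_normalization(self):
        cfg = small_config(duration=0.8e-3)
        scene = Scene(extent=(0, 0, 0.3, 0.3))
        pulse = PulseEvent(
            id=0, t_emit=0.0, position=np.array([0.15, 0.15]),
            direction=np.array([1.0, 0.0]),
        )
        left, right = simulate_impulse_responses(scene, pulse, probe(cfg.fs), cfg)
        peak = max(np.max(np.abs(left.samples)), np.max(np.abs(right.samples)))
        assert peak == pytest.approx(1.0)
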