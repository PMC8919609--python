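"""Excitation and call waveforms, and echo synthesis by convolution.

Two waveforms matter here: the broadband sinc used to excite the FDTD
grid (flat to ~110 kHz, 0.073 ms), whose receiver traces are therefore
impulse responses, and the bat's terminal-FM call (three harmonics, the
fundamental sweeping linearly 34 -> 25 kHz over 2 ms) that gets convolved
with those impulse responses to produce the echoes the ears would hear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "sinc_impulse",
    "fm_pulse",
    "synthesize_echoes",
    "save_wav",
    "load_wav",
    "save_csv",
    "load_csv",
]


@dataclass
class Waveform:
    """Uniformly sampled pressure-proportional signal (arbitrary units)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def sinc_impulse(
    fs: float, cutoff: float = 110e3, duration: float = 0.073e-3, taper: bool = False
) -> Waveform:
    """Time-symmetric truncated sinc, spectrally flat up to ``cutoff``.

    Peak amplitude is 1. Truncation uses a plain rectangular window at
    the stated duration; ``taper`` applies a Hann window instead (reduces
    spectral ripple at the cost of a slightly narrower flat band).
    """
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    n = int(round(duration * fs))
    if n < 3:
        raise ValueError("duration too short for the sampling rate")
    t = (np.arange(n) - (n - 1) / 2) / fs
    x = np.sinc(2.0 * cutoff * t)
    if taper:
        x *= np.hanning(n)
    return Waveform(x / np.max(np.abs(x)), fs)


def fm_pulse(
    fs: float,
    duration: float = 2e-3,
    f1_start: float = 34e3,
    f1_end: float = 25e3,
    rel_levels_db: tuple[float, float, float] = (-40.0, 0.0, -40.0),
) -> Waveform:
    """Three-harmonic downward FM call.

    The fundamental's instantaneous frequency falls linearly from
    ``f1_start`` to ``f1_end`` over ``duration``; harmonics 2 and 3 track
    at twice and three times that frequency. ``rel_levels_db`` gives the
    level of each harmonic relative to the strongest one (defaults: first
    and third at -40 dB re the second).
    """
    if 3 * max(f1_start, f1_end) >= fs / 2:
        raise ValueError("third harmonic would alias at this sampling rate")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # phase of the fundamental: integral of the linear frequency ramp
    phase1 = 2 * np.pi * (f1_start * t + (f1_end - f1_start) / (2 * duration) * t**2)
    amps = 10.0 ** (np.asarray(rel_levels_db, dtype=float) / 20.0)
    x = sum(a * np.sin(k * phase1) for k, a in zip((1, 2, 3), amps))
    return Waveform(x, fs)


def synthesize_echoes(ir_left, ir_right, pulse: Waveform):
    """Convolve the two ear impulse responses with the call waveform.

    Accepts ReceiverTrace-like objects (``.samples``, ``.fs``); returns a
    pair of Waveforms aligned to the impulse responses' time origin (the
    call starts at its first sample, so delays are preserved).
    """
    for ir in (ir_left, ir_right):
        if abs(ir.fs - pulse.fs) > 1e-6:
            raise ValueError("impulse response and pulse sampling rates differ")
    out = tuple(
        Waveform(np.convolve(ir.samples, pulse.samples), pulse.fs)
        for ir in (ir_left, ir_right)
    )
    return out


def save_wav(wave: Waveform, path) -> None:
    wavfile.write(path, int(round(wave.fs)), wave.samples.astype(np.float32))


def load_wav(path) -> Waveform:
    fs, data = wavfile.read(path)
    return Waveform(np.asarray(data, dtype=float), float(fs))


def save_csv(wave: Waveform, path) -> None:
    pd.DataFrame({"time_s": wave.times, "pressure": wave.samples}).to_csv(
        path, index=False
    )


def load_csv(path) -> Waveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return Waveform(df["pressure"].to_numpy(), fs)
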