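"""Additive-harmonic synthesis of tonal pup calls.

Grey seal pup calls are tonal and harmonic: a fundamental around 100-300 Hz
with several harmonics, the fundamental carrying most of the energy. The
synthesizer builds such calls from an arbitrary fundamental-frequency (F0)
contour by summing harmonics with a 1/k^2 amplitude roll-off under a
raised-cosine onset/offset envelope, which keeps spectral energy compact so
that peak-frequency measurements are not corrupted by edge splatter.
"""

from __future__ import annotations

import numpy as np

from .waveform import Waveform

#: Minimum attack/decay length of the amplitude envelope (seconds).
EDGE_RAMP_S = 0.02


def _contour_per_sample(f0_contour, n: int) -> np.ndarray:
    """Resample an F0 contour (scalar or sequence of Hz) to n samples."""
    f0 = np.atleast_1d(np.asarray(f0_contour, dtype=np.float64))
    if f0.size == 1:
        return np.full(n, f0[0])
    x_old = np.linspace(0.0, 1.0, f0.size)
    x_new = np.linspace(0.0, 1.0, n)
    return np.interp(x_new, x_old, f0)


def raised_cosine_envelope(n: int, rate: float, ramp_s: float = EDGE_RAMP_S) -> np.ndarray:
    """Unit envelope with raised-cosine attack and decay of ``ramp_s`` seconds."""
    ramp = min(int(round(ramp_s * rate)), n // 2)
    env = np.ones(n)
    if ramp > 0:
        edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = edge
        env[-ramp:] = edge[::-1]
    return env


def synthesize_call(
    f0_contour,
    duration: float,
    n_harmonics: int = 6,
    rate: float = 96_000.0,
    harmonic_rolloff: float = 2.0,
    seed: int | None = None,
) -> Waveform:
    """Synthesize a tonal harmonic call.

    Parameters
    ----------
    f0_contour
        Fundamental frequency in Hz: a scalar for a constant-pitch call or a
        sequence of values spread evenly over the call (linearly
        interpolated per sample).
    duration
        Call length in seconds (> 0).
    n_harmonics
        Number of harmonic partials (>= 1) including the fundamental.
    rate
        Sampling rate in Hz.
    harmonic_rolloff
        Amplitude of harmonic k is ``1 / k**harmonic_rolloff``; the default
        keeps the fundamental dominant, as in natural pup calls.
    seed
        Optional seed for the (randomised) starting phase of each partial.
        ``None`` gives zero phases.

    Returns
    -------
    Waveform
        ``round(duration * rate)`` samples, peak-normalized to 0.9.

    Raises
    ------
    ValueError
        If duration is non-positive, ``n_harmonics < 1``, or the contour
        times ``n_harmonics`` reaches the Nyquist frequency.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    n = int(round(duration * rate))
    f0 = _contour_per_sample(f0_contour, n)
    if np.any(f0 <= 0):
        raise ValueError("F0 contour must be strictly positive")
    if np.max(f0) * n_harmonics >= rate / 2:
        raise ValueError(
            f"contour max {np.max(f0):.1f} Hz x {n_harmonics} harmonics "
            f"reaches Nyquist ({rate / 2:.0f} Hz)"
        )
    phase = 2.0 * np.pi * np.cumsum(f0) / rate
    rng = np.random.default_rng(seed) if seed is not None else None
    x = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        phi0 = rng.uniform(0, 2 * np.pi) if rng is not None else 0.0
        x += np.sin(k * phase + phi0) / k**harmonic_rolloff
    x *= raised_cosine_envelope(n, rate)
    return Waveform(x, rate).normalized(0.9)


def autocorrelation_f0(
    wave: Waveform, fmin: float = 60.0, fmax: float = 800.0
) -> float:
    """Whole-call F0 estimate by global autocorrelation (test oracle).

    Deliberately simple and independent of the framewise pitch tracker:
    one normalized autocorrelation over the full signal, maximum in the
    ``[1/fmax, 1/fmin]`` lag band, parabolic refinement.
    """
    x = wave.samples - np.mean(wave.samples)
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    lag_lo = int(np.floor(wave.rate / fmax))
    lag_hi = min(int(np.ceil(wave.rate / fmin)), n - 2)
    if lag_hi <= lag_lo:
        raise ValueError("signal too short for the requested F0 band")
    seg = ac[lag_lo : lag_hi + 1]
    k = int(np.argmax(seg)) + lag_lo
    # parabolic interpolation around the autocorrelation peak
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return wave.rate / (k + delta)
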