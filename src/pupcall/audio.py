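"""Segmentation and acoustic feature extraction.

Replicates the study's measurement chain on clean audio: a 100 Hz zero-phase
high-pass, a Hamming spectrogram (FFT 2048 -> 46.875 Hz bins at 96 kHz),
energy-based call segmentation with the 5 ms gap rule (silent breaks of up
to 5 ms stay inside one call; larger gaps split calls), and per-call
features measured every 5 ms: fundamental frequency (F0) by autocorrelation
with parabolic interpolation and peak frequency as the interpolated argmax
of the Hamming power spectrum. Formant estimation by LPC root analysis is
included as an optional feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.linalg import solve_toeplitz

from .waveform import Waveform

F0_BAND = (60.0, 800.0)  # Hz search band for the fundamental
FRAME_STEP_MS = 5.0
UNVOICED_QUALITY = 0.5  # autocorrelation peak / lag-0 below this -> unvoiced


@dataclass(frozen=True)
class SpectrogramParams:
    """Spectrographic settings (defaults mirror the study's analysis tool)."""

    fft_size: int = 2048
    window: str = "hamming"
    hop: int | None = None  # default fft_size // 2
    highpass_cutoff: float = 100.0

    def __post_init__(self) -> None:
        if self.fft_size < 2 or self.fft_size & (self.fft_size - 1):
            raise ValueError("fft_size must be a power of two")
        hop = self.hop if self.hop is not None else self.fft_size // 2
        if not 0 < hop <= self.fft_size:
            raise ValueError("hop must be in (0, fft_size]")
        object.__setattr__(self, "hop", hop)


@dataclass(frozen=True)
class CallSegment:
    """One segmented call: a slice of a parent session waveform."""

    onset_s: float
    offset_s: float
    wave: Waveform
    parent_file: str = ""

    @property
    def duration(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class CallFeatures:
    """Per-call acoustic measurements on 5 ms frames.

    ``f0_contour`` entries are NaN for unvoiced frames; unvoiced frames are
    excluded from the F0 summary statistics.
    """

    duration: float
    f0_contour: np.ndarray
    peak_contour: np.ndarray
    mean_f0: float
    min_f0: float
    max_f0: float
    mean_peak: float
    onset_s: float = 0.0
    offset_s: float = 0.0
    formants: list[float] | None = None


def highpass(wave: Waveform, cutoff: float = 100.0, order: int = 4) -> Waveform:
    """Zero-phase Butterworth high-pass.

    Order-4 forward-backward filtering gives ~48 dB attenuation one octave
    below the cutoff and < 0.1 dB ripple above twice the cutoff, with no
    group delay (onsets are preserved).
    """
    if not 0 < cutoff < wave.rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="highpass", fs=wave.rate, output="sos")
    return Waveform(signal.sosfiltfilt(sos, wave.samples), wave.rate)


def spectrogram(
    wave: Waveform, params: SpectrogramParams = SpectrogramParams()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hamming magnitude spectrogram.

    Returns
    -------
    freqs, times, magnitude
        ``freqs`` has bin width exactly ``rate / fft_size``; ``magnitude``
        is ``(len(freqs), n_frames)``.
    """
    if len(wave) < params.fft_size:
        raise ValueError("signal shorter than one analysis frame")
    freqs, times, spec = signal.stft(
        wave.samples,
        fs=wave.rate,
        window=params.window,
        nperseg=params.fft_size,
        noverlap=params.fft_size - params.hop,
        boundary=None,
        padded=False,
    )
    return freqs, times, np.abs(spec)


def _frame_rms(x: np.ndarray, frame: int) -> np.ndarray:
    n = len(x) // frame
    if n == 0:
        return np.zeros(0)
    return np.sqrt(np.mean(x[: n * frame].reshape(n, frame) ** 2, axis=1))


def segment_calls(
    wave: Waveform,
    threshold_db: float = -30.0,
    max_gap_ms: float = 5.0,
    min_call_ms: float = 50.0,
    parent_file: str = "",
) -> list[CallSegment]:
    """Energy-based call segmentation with gap merging.

    Frames of 1 ms RMS are compared against ``threshold_db`` relative to the
    95th-percentile frame RMS of the file. Supra-threshold runs separated by
    at most ``max_gap_ms`` are merged into one call; shorter runs than
    ``min_call_ms`` are discarded. Empty or silent input yields an empty
    list.
    """
    frame = max(int(round(wave.rate * 1e-3)), 1)  # 1 ms energy frames
    rms = _frame_rms(wave.samples, frame)
    if len(rms) == 0 or np.max(rms) == 0:
        return []
    ref = np.percentile(rms[rms > 0], 95)
    active = rms > ref * 10 ** (threshold_db / 20.0)
    if not np.any(active):
        return []
    # run-length extraction of active frames
    edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    # merge runs separated by <= max_gap_ms
    max_gap = max_gap_ms * 1e-3 * wave.rate / frame
    merged: list[list[float]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        onset = s * frame / wave.rate
        offset = e * frame / wave.rate
        if (offset - onset) * 1e3 >= min_call_ms:
            out.append(
                CallSegment(onset, offset, wave.slice(onset, offset), parent_file)
            )
    return out


def _feature_window(rate: float, target_s: float = 0.08) -> int:
    """Power-of-two analysis window of roughly ``target_s`` seconds."""
    return int(2 ** round(np.log2(target_s * rate)))


def _sliding_frames(x: np.ndarray, win: int, step: float, n_frames: int) -> np.ndarray:
    """(n_frames, win) matrix of windows centred every ``step`` samples.

    The signal is reflection-padded so frames centred near the edges stay
    defined; this keeps the contour length at floor(duration / step).
    """
    pad = win // 2
    xp = np.pad(x, pad, mode="reflect") if len(x) > 1 else np.pad(x, pad)
    centers = ((np.arange(n_frames) + 0.5) * step).astype(np.intp)
    idx = centers[:, None] + np.arange(win)[None, :]
    return xp[np.clip(idx, 0, len(xp) - 1)]


def _parabolic(y0: np.ndarray, y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom != 0, 0.5 * (y0 - y2) / denom, 0.0)
    return np.clip(d, -0.5, 0.5)


def frame_f0(
    frames: np.ndarray, rate: float, band: tuple[float, float] = F0_BAND
) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation F0 per frame with parabolic refinement.

    Returns (f0, quality); quality is the normalized autocorrelation at the
    chosen lag, in [0, 1] for periodic signals.
    """
    n_frames, win = frames.shape
    x = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * win)))
    spec = np.fft.rfft(x, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), axis=1)[:, :win]
    lag_lo = max(int(np.floor(rate / band[1])), 2)
    lag_hi = min(int(np.ceil(rate / band[0])), win - 2)
    if lag_hi <= lag_lo:
        raise ValueError("analysis window too short for the F0 band")
    seg = ac[:, lag_lo : lag_hi + 1]
    k = np.argmax(seg, axis=1) + lag_lo
    rows = np.arange(n_frames)
    delta = _parabolic(ac[rows, k - 1], ac[rows, k], ac[rows, k + 1])
    f0 = rate / (k + delta)
    with np.errstate(divide="ignore", invalid="ignore"):
        quality = np.where(ac[:, 0] > 0, ac[rows, k] / ac[:, 0], 0.0)
    return f0, quality


def frame_peak_frequency(
    frames: np.ndarray, rate: float, fmin: float = 60.0
) -> np.ndarray:
    """Peak frequency per frame: interpolated argmax of the Hamming power
    spectrum (searched above ``fmin`` to skip residual low-frequency noise).
    """
    n_frames, win = frames.shape
    w = np.hamming(win)
    power = np.abs(np.fft.rfft(frames * w, axis=1)) ** 2
    df = rate / win
    lo = max(int(np.ceil(fmin / df)), 1)
    k = np.argmax(power[:, lo:-1], axis=1) + lo
    rows = np.arange(n_frames)
    logp = np.log(np.maximum(power, 1e-300))
    delta = _parabolic(logp[rows, k - 1], logp[rows, k], logp[rows, k + 1])
    return (k + delta) * df


def extract_features(
    segment: CallSegment,
    frame_step_ms: float = FRAME_STEP_MS,
    f0_band: tuple[float, float] = F0_BAND,
) -> CallFeatures:
    """Measure F0 and peak frequency every ``frame_step_ms`` over a call.

    Unvoiced frames (autocorrelation quality < 0.5) get NaN in the F0
    contour and are excluded from mean/min/max F0. Raises ``ValueError``
    for segments shorter than two frames.
    """
    wave = segment.wave
    step = frame_step_ms * 1e-3 * wave.rate
    n_frames = int(np.floor(len(wave) / step))
    if n_frames < 2:
        raise ValueError("segment shorter than two analysis frames")
    win = min(_feature_window(wave.rate), int(2 ** np.floor(np.log2(len(wave)))))
    frames = _sliding_frames(wave.samples, win, step, n_frames)
    f0, quality = frame_f0(frames, wave.rate, f0_band)
    peak = frame_peak_frequency(frames, wave.rate, fmin=f0_band[0])
    voiced = quality >= UNVOICED_QUALITY
    if len(f0) >= 5:
        # 5-point median smoothing removes isolated octave/edge errors
        f0 = signal.medfilt(f0, 5)
    f0 = np.where(voiced, f0, np.nan)
    if np.any(voiced):
        mean_f0 = float(np.nanmean(f0))
        min_f0 = float(np.nanmin(f0))
        max_f0 = float(np.nanmax(f0))
    else:
        mean_f0 = min_f0 = max_f0 = float("nan")
    return CallFeatures(
        duration=segment.duration,
        f0_contour=f0,
        peak_contour=peak,
        mean_f0=mean_f0,
        min_f0=min_f0,
        max_f0=max_f0,
        mean_peak=float(np.mean(peak)),
        onset_s=segment.onset_s,
        offset_s=segment.offset_s,
    )


def estimate_formants(
    segment: CallSegment,
    lpc_order: int = 12,
    max_bandwidth: float = 400.0,
) -> list[float]:
    """Formant frequencies by LPC root analysis (optional feature).

    Linear-prediction coefficients are solved from the autocorrelation
    sequence (Yule-Walker); formants are the angles of complex poles with
    bandwidth below ``max_bandwidth`` Hz, sorted ascending.
    """
    if not 1 <= lpc_order:
        raise ValueError("lpc_order must be >= 1")
    x = segment.wave.samples
    if lpc_order >= len(x):
        raise ValueError("lpc_order must be below the segment length")
    x = (x - np.mean(x)) * np.hamming(len(x))
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :][: lpc_order + 1]
    if ac[0] <= 0:
        return []
    a = solve_toeplitz(ac[:-1], ac[1:])
    roots = np.roots(np.concatenate(([1.0], -a)))
    roots = roots[np.imag(roots) > 0]
    rate = segment.wave.rate
    freqs = np.angle(roots) * rate / (2 * np.pi)
    bw = -np.log(np.maximum(np.abs(roots), 1e-12)) * rate / np.pi
    keep = (bw < max_bandwidth) & (freqs > 50.0) & (freqs < 0.95 * rate / 2)
    return sorted(float(f) for f in freqs[keep])
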