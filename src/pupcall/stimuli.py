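"""Playback stimulus construction.

The playback stimuli are sequences of pitch-shifted copies of one baseline
pup call: a two-call up step (template ``a``), a two-call down step
(``b``), and a three-call up-then-down step (``ab``), with average peak
frequencies alternating between 119 and 153 Hz, 0.7 s calls and 0.05 s
inter-call intervals, played in blocks of 50 sequences with 1 s between
sequences.

Pitch shifting is duration-preserving: a phase-vocoder time stretch by the
shift ratio followed by resampling back to the original length scales all
frequencies (fundamental and harmonics alike) by the ratio while keeping
the call length constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .synth import synthesize_call
from .waveform import Waveform, concatenate

BASE_PEAK_HZ = 119.0
SHIFTED_PEAK_HZ = 153.0
CALL_DURATION_S = 0.7
INTER_CALL_INTERVAL_S = 0.05


@dataclass(frozen=True)
class StimulusTemplate:
    """A playback call-sequence specification."""

    template_id: str
    call_peak_freqs: tuple[float, ...]
    call_duration: float = CALL_DURATION_S
    inter_call_interval: float = INTER_CALL_INTERVAL_S

    def __post_init__(self) -> None:
        if len(self.call_peak_freqs) < 2:
            raise ValueError("a template needs at least two calls")
        if self.call_duration <= 0 or self.inter_call_interval <= 0:
            raise ValueError("durations and intervals must be positive")
        if any(
            f1 == f2
            for f1, f2 in zip(self.call_peak_freqs, self.call_peak_freqs[1:])
        ):
            raise ValueError("consecutive peak frequencies must differ")

    @property
    def n_calls(self) -> int:
        return len(self.call_peak_freqs)

    @property
    def direction_pattern(self) -> tuple[str, ...]:
        """Successive frequency-step directions, e.g. ``('up', 'down')``."""
        return tuple(
            "up" if f2 > f1 else "down"
            for f1, f2 in zip(self.call_peak_freqs, self.call_peak_freqs[1:])
        )

    @property
    def total_duration(self) -> float:
        n = self.n_calls
        return n * self.call_duration + (n - 1) * self.inter_call_interval


TEMPLATES: dict[str, StimulusTemplate] = {
    "a": StimulusTemplate("a", (BASE_PEAK_HZ, SHIFTED_PEAK_HZ)),
    "b": StimulusTemplate("b", (SHIFTED_PEAK_HZ, BASE_PEAK_HZ)),
    "ab": StimulusTemplate("ab", (BASE_PEAK_HZ, SHIFTED_PEAK_HZ, BASE_PEAK_HZ)),
}


def get_template(template_id: str) -> StimulusTemplate:
    try:
        return TEMPLATES[template_id]
    except KeyError:
        raise ValueError(
            f"unknown template {template_id!r}; expected one of {sorted(TEMPLATES)}"
        ) from None


@dataclass(frozen=True)
class PlaybackSchedule:
    """Repetition schedule of one playback session."""

    repetitions: int = 50
    inter_sequence_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.inter_sequence_interval < 0:
            raise ValueError("inter-sequence interval must be >= 0")


def _spectral_rolloff(x: np.ndarray, rate: float, q: float = 0.99) -> float:
    """Frequency below which a fraction ``q`` of the spectral energy lies."""
    power = np.abs(np.fft.rfft(x)) ** 2
    c = np.cumsum(power)
    if c[-1] == 0:
        return 0.0
    k = int(np.searchsorted(c, q * c[-1]))
    return k * rate / (2 * (len(power) - 1))


def _phase_vocoder_stretch(x: np.ndarray, n_out: int, nfft: int) -> np.ndarray:
    """Time-stretch ``x`` to ``n_out`` samples at constant pitch.

    Standard phase-vocoder: constant synthesis hop of ``nfft // 4`` (Hann,
    75% overlap), analysis frames read from positions spread uniformly over
    the input, with per-bin instantaneous-frequency phase propagation.
    """
    hop = nfft // 4
    win = np.hanning(nfft)
    m_frames = max(2, int(np.ceil((n_out - nfft) / hop)) + 1)
    out_len = (m_frames - 1) * hop + nfft
    # analysis positions span the input exactly
    pos = np.round(np.linspace(0, len(x) - nfft, m_frames)).astype(int)
    spec = np.fft.rfft(win * np.lib.stride_tricks.sliding_window_view(x, nfft)[pos], axis=1)
    mag = np.abs(spec)
    phase = np.angle(spec)
    omega = 2 * np.pi * np.arange(nfft // 2 + 1) / nfft  # rad / sample

    out = np.zeros(out_len)
    norm = np.zeros(out_len)
    acc = phase[0].copy()
    wsq = win**2
    for m in range(m_frames):
        if m:
            d = max(int(pos[m] - pos[m - 1]), 1)
            dev = phase[m] - phase[m - 1] - omega * d
            dev -= 2 * np.pi * np.round(dev / (2 * np.pi))
            acc = acc + (omega + dev / d) * hop
        frame = np.fft.irfft(mag[m] * np.exp(1j * acc), nfft)
        i = m * hop
        out[i : i + nfft] += frame * win
        norm[i : i + nfft] += wsq
    # zero out edge samples where the window-sum is too small to normalize
    return np.where(norm > 1e-2, out / np.maximum(norm, 1e-2), 0.0)


def pitch_shift(wave: Waveform, ratio: float) -> Waveform:
    """Shift all frequencies by ``ratio`` while preserving duration.

    Time-stretches the signal by ``ratio`` with a phase vocoder and
    resamples back to the original sample count, so the fundamental, its
    harmonics and the peak frequency all scale proportionally and the call
    length is unchanged to the sample.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n0 = len(wave)
    if n0 < 32:
        raise ValueError("signal too short to pitch-shift")
    if _spectral_rolloff(wave.samples, wave.rate) * ratio >= wave.rate / 2:
        raise ValueError("shift would push dominant energy past Nyquist")
    if ratio == 1.0:
        return wave
    # ~30 ms analysis window (2048 samples at 96 kHz), capped by signal length
    nfft = int(
        min(2 ** round(np.log2(0.03 * wave.rate)), 2 ** np.floor(np.log2(n0 / 4)))
    )
    n_stretched = int(round(n0 * ratio))
    stretched = _phase_vocoder_stretch(wave.samples, n_stretched, nfft)
    shifted = sp_signal.resample(stretched, n0)
    return Waveform(shifted, wave.rate).normalized(float(np.max(np.abs(wave.samples))))


def make_source_call(
    rate: float = 96_000.0,
    peak_hz: float = BASE_PEAK_HZ,
    duration: float = CALL_DURATION_S,
    n_harmonics: int = 6,
) -> Waveform:
    """Synthesize the baseline template call.

    A constant-F0 harmonic call whose fundamental carries the most energy,
    so its average peak frequency equals its fundamental (119 Hz by
    default). Stands in for the recorded 4-day-old pup call the original
    stimuli were cut from, which is not distributed.
    """
    return synthesize_call(peak_hz, duration, n_harmonics=n_harmonics, rate=rate)


def build_stimulus(
    template: StimulusTemplate | str,
    source_call: Waveform | None = None,
    source_peak_hz: float = BASE_PEAK_HZ,
) -> tuple[Waveform, list[dict]]:
    """Assemble one stimulus sequence from pitch-shifted copies of a call.

    Each template call is the source call shifted to the template's peak
    frequency; calls are separated by ``inter_call_interval`` of silence.

    Returns
    -------
    (waveform, annotations)
        ``annotations`` lists one dict per call with ``onset_s``,
        ``offset_s`` and ``peak_hz``.
    """
    if isinstance(template, str):
        template = get_template(template)
    if source_call is None:
        source_call = make_source_call(peak_hz=source_peak_hz)
    calls = []
    for f in template.call_peak_freqs:
        calls.append(pitch_shift(source_call, f / source_peak_hz))
    wave = concatenate(calls, gap_s=template.inter_call_interval)
    annotations = []
    t = 0.0
    for f, c in zip(template.call_peak_freqs, calls):
        annotations.append(
            {"onset_s": t, "offset_s": t + c.duration, "peak_hz": f}
        )
        t += c.duration + template.inter_call_interval
    return wave, annotations


def build_block(stimulus: Waveform, schedule: PlaybackSchedule) -> Waveform:
    """Repeat a stimulus into a playback block with silent gaps between
    repetitions."""
    if len(stimulus) == 0:
        raise ValueError("empty stimulus")
    reps = [stimulus] * schedule.repetitions
    return concatenate(reps, gap_s=schedule.inter_sequence_interval)
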