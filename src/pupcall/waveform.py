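"""Sampled-audio container and WAV I/O.

A :class:`Waveform` is the common currency of the package: synthesized pup
calls, playback stimuli and recorded sessions are all mono float arrays in
[-1, 1] with an explicit sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class Waveform:
    """Mono audio signal.

    Parameters
    ----------
    samples
        1-D float array of dimensionless amplitudes. Normalized waveforms
        satisfy ``max(|samples|) <= 1``.
    rate
        Sampling rate in Hz (> 0).
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)

    def slice(self, onset_s: float, offset_s: float) -> "Waveform":
        """Extract ``[onset_s, offset_s)`` as a new waveform."""
        i0 = int(round(onset_s * self.rate))
        i1 = int(round(offset_s * self.rate))
        if not 0 <= i0 < i1 <= len(self.samples):
            raise ValueError(f"slice [{onset_s}, {offset_s}) outside waveform")
        return Waveform(self.samples[i0:i1], self.rate)

    def normalized(self, peak: float = 0.9) -> "Waveform":
        """Scale so the absolute peak equals ``peak`` (no-op on silence)."""
        m = np.max(np.abs(self.samples)) if len(self.samples) else 0.0
        if m == 0:
            return self
        return Waveform(self.samples * (peak / m), self.rate)


def write_wav(path: str | Path, wave: Waveform, subtype: str = "PCM_16") -> None:
    """Write a mono PCM WAV file (16- or 24-bit equivalent int encoding)."""
    if subtype not in ("PCM_16", "PCM_32"):
        raise ValueError(f"unsupported subtype {subtype!r}")
    x = np.clip(wave.samples, -1.0, 1.0)
    if subtype == "PCM_16":
        data = (x * 32767.0).astype(np.int16)
    else:
        data = (x * 2147483647.0).astype(np.int32)
    wavfile.write(str(path), int(round(wave.rate)), data)


def read_wav(path: str | Path) -> Waveform:
    """Read a mono PCM WAV file into a float waveform in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        x = data / 32767.0
    elif data.dtype == np.int32:
        x = data / 2147483647.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 127.0
    else:  # float WAV
        x = data.astype(np.float64)
    return Waveform(x, float(rate))


def concatenate(waves: list[Waveform], gap_s: float = 0.0) -> Waveform:
    """Concatenate waveforms with ``gap_s`` seconds of silence between them."""
    if not waves:
        raise ValueError("nothing to concatenate")
    rate = waves[0].rate
    if any(w.rate != rate for w in waves):
        raise ValueError("sampling rates differ")
    gap = np.zeros(int(round(gap_s * rate)))
    parts: list[np.ndarray] = []
    for i, w in enumerate(waves):
        if i:
            parts.append(gap)
        parts.append(w.samples)
    return Waveform(np.concatenate(parts), rate)
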