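"""Mono audio container and WAV I/O.

All processing in this package operates on :class:`AudioSignal`, a thin
immutable wrapper around a 1-D float64 sample array plus its sample rate.
WAV files (PCM16 or float32) are read and written with :mod:`scipy.io.wavfile`;
arbitrary input rates are handled by polyphase resampling on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["AudioSignal", "read_wav", "write_wav"]


@dataclass(frozen=True)
class AudioSignal:
    """A finite mono waveform.

    Parameters
    ----------
    samples : ndarray
        1-D array of dimensionless amplitudes (float64).
    sample_rate : float
        Sampling frequency in Hz, > 0.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"expected mono 1-D samples, got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite values")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", float(self.sample_rate))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0

    def resample(self, new_rate: float) -> "AudioSignal":
        """Polyphase resample to ``new_rate`` Hz."""
        if new_rate == self.sample_rate:
            return self
        frac = Fraction(new_rate / self.sample_rate).limit_denominator(1000)
        out = resample_poly(self.samples, frac.numerator, frac.denominator)
        return AudioSignal(out, new_rate)

    def normalized_to_rms(self, target_rms: float) -> "AudioSignal":
        """Scale so the output RMS equals ``target_rms`` (no-op on silence)."""
        cur = self.rms
        if cur == 0.0:
            return self
        return AudioSignal(self.samples * (target_rms / cur), self.sample_rate)


def read_wav(path: str | Path, target_rate: float | None = None) -> AudioSignal:
    """Read a mono WAV file (PCM16, PCM32 or float), optionally resampling.

    Multichannel files are mixed down by averaging channels.
    """
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    sig = AudioSignal(data, float(rate))
    if target_rate is not None:
        sig = sig.resample(target_rate)
    return sig


def write_wav(path: str | Path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write a mono WAV file as ``"float32"`` or ``"pcm16"``."""
    if subtype == "float32":
        wavfile.write(str(path), int(round(signal.sample_rate)), signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 32767.0 / 32768.0)
        wavfile.write(
            str(path),
            int(round(signal.sample_rate)),
            np.round(clipped * 32768.0).astype(np.int16),
        )
    else:
        raise ValueError(f"unknown subtype {subtype!r}")
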