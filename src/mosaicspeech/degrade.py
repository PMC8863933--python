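"""Temporal/spectral degradation of speech: mosaicking, noise vocoding,
local time reversal.

Mosaic speech averages each band's sound energy density within fixed-length
time segments (the *segment duration*, the manipulated variable), then drives
matched band-noise carriers so each time x critical-band patch of the output
carries the averaged power of the original.  Noise-vocoded speech is the
limiting case without temporal segmentation (tagged 0 ms).  Locally
time-reversed speech reverses each consecutive segment of the raw waveform
in place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio import AudioSignal
from .filterbank import (
    BandSpec,
    EnvelopeMatrix,
    SmootherSpec,
    band_decompose,
    band_noise,
    energy_density,
    envelope_matrix,
)

__all__ = [
    "MosaicGrid",
    "DegradedStimulus",
    "segment_boundaries",
    "mosaic_envelope",
    "step_expand",
    "synthesize_from_target",
    "make_mosaic_speech",
    "make_noise_vocoded",
    "local_time_reverse",
]

#: relative floor applied to carrier reference energy before gain division
GAIN_EPS_REL = 1e-10


@dataclass(frozen=True)
class MosaicGrid:
    """Per-band x per-segment averaged power plus segmentation metadata."""

    patch_power: np.ndarray  # (n_bands, n_segments), >= 0
    segment_duration_ms: float
    segment_boundaries: np.ndarray  # sample indices, first 0, last n_samples
    ramp_duration_ms: float = 5.0

    def __post_init__(self) -> None:
        power = np.asarray(self.patch_power, dtype=np.float64)
        bounds = np.asarray(self.segment_boundaries, dtype=np.int64)
        if np.any(power < 0):
            raise ValueError("patch_power must be non-negative")
        if bounds[0] != 0 or not np.all(np.diff(bounds) > 0):
            raise ValueError("boundaries must start at 0 and strictly increase")
        if power.shape[1] != bounds.size - 1:
            raise ValueError("patch count does not match boundaries")
        object.__setattr__(self, "patch_power", power)
        object.__setattr__(self, "segment_boundaries", bounds)

    @property
    def n_bands(self) -> int:
        return self.patch_power.shape[0]

    @property
    def n_segments(self) -> int:
        return self.patch_power.shape[1]

    @property
    def n_samples(self) -> int:
        return int(self.segment_boundaries[-1])


@dataclass(frozen=True)
class DegradedStimulus:
    """A degraded waveform plus the parameters that produced it.

    ``segment_duration_ms == 0`` denotes noise-vocoded speech (no temporal
    segmentation), following the convention of tagging the vocoder control
    condition as 0 ms.
    """

    audio: AudioSignal
    kind: str  # mosaic | noise_vocoded | locally_time_reversed
    segment_duration_ms: float
    band_spec: BandSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mosaic", "noise_vocoded", "locally_time_reversed"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if (self.kind == "noise_vocoded") != (self.segment_duration_ms == 0):
            raise ValueError("segment_duration_ms == 0 if and only if noise_vocoded")

    def sidecar(self) -> dict:
        """Provenance record for a JSON sidecar next to the written WAV."""
        return {
            "kind": self.kind,
            "segment_duration_ms": self.segment_duration_ms,
            "band_edges_hz": None if self.band_spec is None else self.band_spec.edges.tolist(),
            "seed": self.seed,
            "sample_rate": self.audio.sample_rate,
            "n_samples": len(self.audio),
        }

    def write_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sidecar(), indent=2))


def segment_boundaries(n_samples: int, segment_duration_ms: float, sample_rate: float) -> np.ndarray:
    """Sample indices delimiting consecutive segments; final one may be short."""
    if segment_duration_ms <= 0:
        raise ValueError("segment_duration_ms must be > 0")
    seg_len = max(1, int(round(segment_duration_ms * 1e-3 * sample_rate)))
    bounds = np.arange(0, n_samples, seg_len, dtype=np.int64)
    return np.append(bounds, n_samples)


def mosaic_envelope(env: EnvelopeMatrix, segment_duration_ms: float) -> MosaicGrid:
    """Average sound energy density within each band x segment patch.

    A final partial segment is averaged over its actual length, so total
    energy is preserved and the grand mean of the stepwise reconstruction
    equals the grand mean of the input for equal-length segments.
    """
    bounds = segment_boundaries(env.n_samples, segment_duration_ms, env.sample_rate)
    sums = np.add.reduceat(env.values, bounds[:-1], axis=1)
    lengths = np.diff(bounds)
    return MosaicGrid(sums / lengths, segment_duration_ms, bounds)


def step_expand(grid: MosaicGrid) -> np.ndarray:
    """Stepwise (piecewise-constant) envelope matrix implied by a grid."""
    reps = np.diff(grid.segment_boundaries)
    return np.repeat(grid.patch_power, reps, axis=1)


def _smooth_gain_track(
    gains: np.ndarray, boundaries: np.ndarray, ramp_samples: int, n_samples: int
) -> np.ndarray:
    """Per-sample amplitude gain from per-segment gains.

    Raised-cosine transitions of width ``ramp_samples`` centred on each
    interior boundary interpolate between neighbouring gains (zero power dip
    when the gains are equal, since segments share one coherent carrier), and
    the track fades in/out over one ramp at the signal edges.  The transition
    half-width is clipped to the shortest adjacent segment so the construction
    stays valid down to one-sample segments.
    """
    track = np.repeat(gains, np.diff(boundaries))
    x_full = None
    for i in range(1, boundaries.size - 1):
        b = boundaries[i]
        half = min(ramp_samples // 2, boundaries[i] - boundaries[i - 1], boundaries[i + 1] - b)
        if half < 1:
            continue
        lo, hi = b - half, min(b + half, n_samples)
        x = np.arange(lo, hi)
        s = np.sin(0.5 * np.pi * (x - lo) / (2 * half)) ** 2  # 0 -> 1 raised cosine
        track[lo:hi] = gains[i - 1] + (gains[i] - gains[i - 1]) * s
    # global fade in / out
    r = min(ramp_samples, n_samples)
    if r >= 2:
        fade = np.sin(0.5 * np.pi * np.arange(r) / (r - 1)) ** 2
        track[:r] *= fade
        track[-r:] *= fade[::-1]
    return track


def synthesize_from_target(
    target: MosaicGrid | np.ndarray,
    carriers: list[AudioSignal],
    smoother: SmootherSpec = SmootherSpec(),
    ramp_ms: float = 5.0,
) -> AudioSignal:
    """Amplitude-modulate noise carriers to carry a target energy density.

    For a :class:`MosaicGrid` target, each carrier's own energy density is
    averaged over the same segments and the per-segment amplitude gain is
    ``sqrt(patch / segment-averaged carrier energy)``, gated with 5-ms
    raised-cosine transitions at every boundary.  For a smooth per-sample
    target (noise vocoding), the gain is the pointwise ratio against the
    carrier's smoothed instantaneous energy density.  Band outputs are summed
    into one waveform.
    """
    if not carriers:
        raise ValueError("need at least one carrier")
    sample_rate = carriers[0].sample_rate
    n_samples = len(carriers[0])
    ramp_samples = max(2, int(round(ramp_ms * 1e-3 * sample_rate)))

    if isinstance(target, MosaicGrid):
        if target.n_bands != len(carriers):
            raise ValueError(
                f"band count mismatch: target {target.n_bands}, carriers {len(carriers)}"
            )
        bounds = target.segment_boundaries
        lengths = np.diff(bounds)
        out = np.zeros(n_samples)
        for b, carrier in enumerate(carriers):
            noise_env = energy_density(carrier, smoother)
            noise_ref = np.add.reduceat(noise_env, bounds[:-1]) / lengths
            eps = GAIN_EPS_REL * max(noise_ref.max(), 1e-300)
            gains = np.sqrt(target.patch_power[b] / np.maximum(noise_ref, eps))
            out += _smooth_gain_track(gains, bounds, ramp_samples, n_samples) * carrier.samples
        return AudioSignal(out, sample_rate)

    target = np.asarray(target, dtype=np.float64)
    if target.shape[0] != len(carriers) or target.shape[1] != n_samples:
        raise ValueError(
            f"target shape {target.shape} does not match {len(carriers)} carriers x {n_samples}"
        )
    out = np.zeros(n_samples)
    for b, carrier in enumerate(carriers):
        noise_ref = energy_density(carrier, smoother)
        eps = GAIN_EPS_REL * max(noise_ref.max(), 1e-300)
        out += np.sqrt(target[b] / np.maximum(noise_ref, eps)) * carrier.samples
    # onset/offset gates only: no interior segmentation for smooth targets
    r = min(ramp_samples, n_samples)
    if r >= 2:
        fade = np.sin(0.5 * np.pi * np.arange(r) / (r - 1)) ** 2
        out[:r] *= fade
        out[-r:] *= fade[::-1]
    return AudioSignal(out, sample_rate)


def _finalize(samples: np.ndarray, source: AudioSignal) -> AudioSignal:
    """RMS-match to the source and guard against full-scale overflow."""
    out = AudioSignal(samples, source.sample_rate).normalized_to_rms(source.rms)
    peak = np.abs(out.samples).max()
    if peak > 1.0:
        out = AudioSignal(out.samples * (0.999 / peak), source.sample_rate)
    return out


def make_mosaic_speech(
    signal: AudioSignal,
    bands: BandSpec,
    segment_duration_ms: float,
    seed: int,
    smoother: SmootherSpec = SmootherSpec(),
    ramp_ms: float = 5.0,
) -> DegradedStimulus:
    """Full mosaicking chain: filterbank -> energy density -> patch averaging
    -> noise resynthesis.  Output length and RMS match the input."""
    if segment_duration_ms <= 0:
        raise ValueError("segment_duration_ms must be > 0 (use make_noise_vocoded for 0)")
    env = envelope_matrix(signal, bands, smoother)
    grid = mosaic_envelope(env, segment_duration_ms)
    carriers = band_noise(bands, len(signal), signal.sample_rate, seed)
    raw = synthesize_from_target(grid, carriers, smoother, ramp_ms)
    return DegradedStimulus(
        _finalize(raw.samples, signal), "mosaic", segment_duration_ms, bands, seed
    )


def make_noise_vocoded(
    signal: AudioSignal,
    bands: BandSpec,
    seed: int,
    smoother: SmootherSpec = SmootherSpec(),
    ramp_ms: float = 5.0,
) -> DegradedStimulus:
    """Noise vocoding: band envelopes drive band noise without segmentation."""
    env = envelope_matrix(signal, bands, smoother)
    carriers = band_noise(bands, len(signal), signal.sample_rate, seed)
    raw = synthesize_from_target(env.values, carriers, smoother, ramp_ms)
    return DegradedStimulus(_finalize(raw.samples, signal), "noise_vocoded", 0.0, bands, seed)


def local_time_reverse(signal: AudioSignal, segment_duration_ms: float) -> AudioSignal:
    """Reverse each consecutive fixed-length segment of the waveform in place.

    An involution: applying it twice returns the input bit-exactly.  The
    final partial segment is reversed as-is; the sample multiset and signal
    length are preserved.
    """
    bounds = segment_boundaries(len(signal), segment_duration_ms, signal.sample_rate)
    out = signal.samples.copy()
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out[lo:hi] = out[lo:hi][::-1]
    return AudioSignal(out, signal.sample_rate)
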