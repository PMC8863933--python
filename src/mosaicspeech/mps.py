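"""Modulation power spectra and the pixelwise two-way mixed ANOVA confound
check.

The modulation power spectrum (MPS) of a stimulus is the squared magnitude of
the 2-D Fourier transform of its mean-removed log-amplitude spectrogram,
computed on a log-spaced frequency axis and averaged over overlapping
analysis chunks.  Its axes are temporal modulation (Hz, signed: upward and
downward spectrotemporal sweeps are distinct) and spectral modulation
(cycles/octave, non-negative half-plane).

``pixelwise_anova`` runs, at every MPS pixel, a two-way mixed ANOVA with
segment duration as the within-replicate factor and language as the
between-replicate factor (sentences are the replicates), yielding p-value
maps for both main effects and their interaction plus sign maps encoding
which direction of each effect dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import gaussian
from scipy.stats import f as f_dist

from .audio import AudioSignal

__all__ = ["MPSParams", "MPSMap", "PValueMapSet", "compute_mps", "pixelwise_anova"]


@dataclass(frozen=True)
class MPSParams:
    """Spectrogram and chunking parameters for the MPS.

    Defaults: Gaussian STFT window sigma 16 ms, hop 2 ms, frequency axis
    log-spaced 50-6400 Hz at 12 bins/octave, 1-s chunks with 50% overlap.
    """

    window_sigma_s: float = 0.016
    hop_s: float = 0.002
    f_min: float = 50.0
    f_max: float = 6400.0
    bins_per_octave: int = 12
    chunk_s: float = 1.0
    chunk_overlap: float = 0.5
    power_floor_rel: float = 1e-10

    @property
    def n_freq(self) -> int:
        n_oct = np.log2(self.f_max / self.f_min)
        return int(round(n_oct * self.bins_per_octave)) + 1

    def log_freqs(self) -> np.ndarray:
        n_oct = np.log2(self.f_max / self.f_min)
        return self.f_min * 2.0 ** np.linspace(0.0, n_oct, self.n_freq)


@dataclass(frozen=True)
class MPSMap:
    """2-D modulation power over (spectral modulation x temporal modulation).

    ``power[i, j]`` is the chunk-averaged modulation power at spectral
    modulation ``spectral_freqs[i]`` (cyc/oct, >= 0) and temporal modulation
    ``temporal_freqs[j]`` (Hz, signed).  ``logspec_variance`` stores the
    chunk-averaged variance of the mean-removed log-spectrogram, against
    which ``total_power()`` satisfies a Parseval identity.
    """

    power: np.ndarray
    temporal_freqs: np.ndarray
    spectral_freqs: np.ndarray
    params: MPSParams
    logspec_variance: float
    n_freq_full: int

    def spectral_multiplicity(self) -> np.ndarray:
        """Row weights restoring the full plane from the half-plane (2 for
        interior spectral rows, 1 for the zero and Nyquist rows)."""
        mult = np.full(self.spectral_freqs.size, 2.0)
        mult[0] = 1.0
        if self.n_freq_full % 2 == 0:
            mult[-1] = 1.0
        return mult

    def total_power(self) -> float:
        return float((self.power * self.spectral_multiplicity()[:, None]).sum())

    def temporal_marginal(self) -> np.ndarray:
        """Power summed over spectral modulation, as a function of signed
        temporal modulation."""
        return (self.power * self.spectral_multiplicity()[:, None]).sum(axis=0)

    def to_npz(self, path) -> None:
        np.savez(
            path,
            power=self.power,
            temporal_freqs_hz=self.temporal_freqs,
            spectral_freqs_cyc_per_oct=self.spectral_freqs,
            logspec_variance=self.logspec_variance,
            n_freq_full=self.n_freq_full,
        )


def _log_spectrogram(signal: AudioSignal, params: MPSParams) -> np.ndarray:
    """Log-power spectrogram on the log-spaced frequency axis (n_freq x n_frames)."""
    fs = signal.sample_rate
    sigma = params.window_sigma_s * fs
    m = int(round(6 * sigma)) | 1  # odd length, +-3 sigma support
    win = gaussian(m, sigma, sym=True)
    hop = max(1, int(round(params.hop_s * fs)))
    stft = ShortTimeFFT(win, hop=hop, fs=fs, scale_to="magnitude")
    spec = np.abs(stft.stft(signal.samples)) ** 2
    lin_freqs = stft.f
    log_freqs = params.log_freqs()
    # linear interpolation of power onto the log-spaced axis (vectorised
    # over frames: the interpolation weights are frame-independent)
    hi = np.clip(np.searchsorted(lin_freqs, log_freqs), 1, lin_freqs.size - 1)
    lo = hi - 1
    w = (log_freqs - lin_freqs[lo]) / (lin_freqs[hi] - lin_freqs[lo])
    interp = spec[lo] * (1.0 - w[:, None]) + spec[hi] * w[:, None]
    floor = params.power_floor_rel * max(interp.max(), 1e-300)
    return np.log(np.maximum(interp, floor))


def compute_mps(signal: AudioSignal, params: MPSParams = MPSParams()) -> MPSMap:
    """Modulation power spectrum of a stimulus.

    Pipeline: log-amplitude spectrogram (Gaussian window, log-spaced
    frequency axis) -> mean removal per chunk -> 2-D FFT -> squared
    magnitude, averaged over 50%-overlapping chunks.  Invariant to overall
    input gain.  Requires at least 500 ms of signal.
    """
    if signal.duration < 0.5:
        raise ValueError(f"signal too short for MPS ({signal.duration * 1e3:.0f} ms < 500 ms)")
    logspec = _log_spectrogram(signal, params)
    n_freq, n_frames = logspec.shape
    chunk_len = min(n_frames, int(round(params.chunk_s / params.hop_s)))
    step = max(1, int(round(chunk_len * (1.0 - params.chunk_overlap))))
    n_chunks = 1 + max(0, (n_frames - chunk_len) // step)
    # centre the chunk coverage so leftover frames split evenly at both ends
    offset = (n_frames - (chunk_len + (n_chunks - 1) * step)) // 2
    starts = [offset + i * step for i in range(n_chunks)]

    acc = None
    variances = []
    for s in starts:
        chunk = logspec[:, s : s + chunk_len]
        chunk = chunk - chunk.mean()
        variances.append(float(np.mean(chunk**2)))
        spec2d = np.fft.fft2(chunk)
        p = np.abs(spec2d) ** 2 / (chunk.shape[0] * chunk.shape[1]) ** 2
        acc = p if acc is None else acc + p
    power_full = acc / len(starts)

    # axes: spectral modulation non-negative half, temporal modulation signed
    n_spec_half = n_freq // 2 + 1
    temporal = np.fft.fftshift(np.fft.fftfreq(chunk_len, d=params.hop_s))
    spectral = np.fft.fftfreq(n_freq, d=1.0 / params.bins_per_octave)[:n_spec_half]
    if n_freq % 2 == 0:
        spectral[-1] = abs(spectral[-1])
    power = np.fft.fftshift(power_full, axes=1)[:n_spec_half, :]
    # temporal-modulation sign convention: positive = power drifting upward
    # in frequency over time (fft2 pairs +spectral with -temporal for that)
    power = power[:, ::-1] if chunk_len % 2 == 1 else np.roll(power[:, ::-1], 1, axis=1)
    return MPSMap(power, temporal, spectral, params, float(np.mean(variances)), n_freq)


@dataclass(frozen=True)
class PValueMapSet:
    """Pixelwise p-value and sign maps for the two main effects and their
    interaction.  Signs follow the hot/cold display convention: +1 where the
    MPS is more prominent at shorter segment durations (sd), in the
    designated hot language (lg), or where the two effects correlate
    positively (interaction)."""

    p_sd: np.ndarray
    p_lg: np.ndarray
    p_interaction: np.ndarray
    sign_sd: np.ndarray
    sign_lg: np.ndarray
    sign_interaction: np.ndarray
    f_sd: np.ndarray = None
    f_lg: np.ndarray = None
    f_interaction: np.ndarray = None


def pixelwise_anova(
    power: np.ndarray,
    segment_duration: np.ndarray,
    language: np.ndarray,
    sentence: np.ndarray,
    hot_language: str | None = None,
    log_power: bool = True,
) -> PValueMapSet:
    """Two-way mixed ANOVA at every MPS pixel.

    Parameters
    ----------
    power : ndarray, shape (n_maps, ...)
        Stacked MPS grids (any trailing pixel shape), one per stimulus.
    segment_duration, language, sentence : arrays of length n_maps
        Within-replicate factor (ms), between-replicate factor, and the
        replicate id.  Each sentence must appear at every segment duration
        and in exactly one language, with equal sentence counts per language
        (balanced design).
    hot_language :
        Language plotted hot (+1) in the sign maps; defaults to the
        lexicographically last of the two labels.

    Sentences are the random replicates: the language effect is tested
    against between-sentence variation within languages, segment duration
    and the interaction against the sentence x duration residual.
    """
    power = np.asarray(power, dtype=np.float64)
    segment_duration = np.asarray(segment_duration, dtype=np.float64)
    language = np.asarray(language)
    sentence = np.asarray(sentence)
    pix_shape = power.shape[1:]
    x = power.reshape(power.shape[0], -1)
    if log_power:
        floor = 1e-10 * max(x.max(), 1e-300)
        x = np.log(np.maximum(x, floor))

    langs = sorted(np.unique(language).tolist())
    sds = np.sort(np.unique(segment_duration))
    a, b = len(langs), len(sds)
    if a < 2 or b < 2:
        raise ValueError("need >= 2 levels of both language and segment duration")
    if hot_language is None:
        hot_language = langs[-1]
    if hot_language not in langs:
        raise ValueError(f"hot_language {hot_language!r} not among {langs}")

    # organise as (subject, level, pixel); subjects grouped by language
    subj_ids, groups = [], []
    for g, lang in enumerate(langs):
        sents = np.unique(sentence[language == lang])
        subj_ids.extend([(lang, s) for s in sents])
        groups.extend([g] * len(sents))
    n_per_group = [groups.count(g) for g in range(a)]
    if min(n_per_group) < 2:
        raise ValueError("degenerate design: need >= 2 replicate sentences per language")
    if len(set(n_per_group)) != 1:
        raise ValueError("unbalanced design: equal sentence counts per language required")
    n = n_per_group[0]

    cube = np.empty((len(subj_ids), b, x.shape[1]))
    for i, (lang, s) in enumerate(subj_ids):
        for j, sd in enumerate(sds):
            sel = (language == lang) & (sentence == s) & (segment_duration == sd)
            if sel.sum() != 1:
                raise ValueError(
                    f"sentence {s!r} ({lang}) must appear exactly once at {sd} ms"
                )
            cube[i, j] = x[sel][0]
    groups = np.asarray(groups)

    grand = cube.mean(axis=(0, 1))
    subj_means = cube.mean(axis=1)  # (S, pix)
    level_means = cube.mean(axis=0)  # (b, pix)
    group_means = np.stack([subj_means[groups == g].mean(axis=0) for g in range(a)])
    cell_means = np.stack(
        [cube[groups == g].mean(axis=0) for g in range(a)]
    )  # (a, b, pix)

    n_subj = a * n
    ss_lg = n * b * ((group_means - grand) ** 2).sum(axis=0)
    ss_subj = b * ((subj_means - group_means[groups]) ** 2).sum(axis=0)
    ss_sd = n_subj * ((level_means - grand) ** 2).sum(axis=0)
    ss_int = n * (
        (cell_means - group_means[:, None, :] - level_means[None] + grand) ** 2
    ).sum(axis=(0, 1))
    resid = cube - cell_means[groups] - subj_means[:, None, :] + group_means[groups][:, None, :]
    ss_err = (resid**2).sum(axis=(0, 1))

    df_lg, df_subj = a - 1, a * (n - 1)
    df_sd, df_int = b - 1, (a - 1) * (b - 1)
    df_err = a * (n - 1) * (b - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_lg = (ss_lg / df_lg) / (ss_subj / df_subj)
        f_sd = (ss_sd / df_sd) / (ss_err / df_err)
        f_int = (ss_int / df_int) / (ss_err / df_err)
    p_lg = f_dist.sf(f_lg, df_lg, df_subj)
    p_sd = f_dist.sf(f_sd, df_sd, df_err)
    p_int = f_dist.sf(f_int, df_int, df_err)

    # sign maps: linear trend of power over segment duration, and the
    # hot-language minus other-language mean difference
    sd_c = sds - sds.mean()
    slope = np.tensordot(sd_c, level_means, axes=(0, 0)) / (sd_c**2).sum()
    sign_sd = np.where(slope < 0, 1.0, -1.0)  # hot = more power at shorter SD
    hot_idx = langs.index(hot_language)
    lang_diff = group_means[hot_idx] - np.delete(group_means, hot_idx, axis=0).mean(axis=0)
    sign_lg = np.where(lang_diff > 0, 1.0, -1.0)
    slope_by_group = np.stack(
        [np.tensordot(sd_c, cell_means[g], axes=(0, 0)) / (sd_c**2).sum() for g in range(a)]
    )
    hot_slope_adv = np.delete(slope_by_group, hot_idx, axis=0).mean(axis=0) - slope_by_group[hot_idx]
    sign_int = np.where(hot_slope_adv * lang_diff > 0, 1.0, -1.0)

    def rs(arr):
        return arr.reshape(pix_shape)

    return PValueMapSet(
        rs(p_sd), rs(p_lg), rs(p_int),
        rs(sign_sd), rs(sign_lg), rs(sign_int),
        rs(f_sd), rs(f_lg), rs(f_int),
    )
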