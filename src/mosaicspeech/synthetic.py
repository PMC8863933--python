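"""Synthetic pseudo-speech and a simulated listener.

Real stimuli come from a licensed speech database, so the package carries a
generator that emulates the statistical structure every other module
assumes:

* **Pseudo-speech audio** — a harmonic source with per-unit pitch contours
  (four lexical-tone templates for the tonal profile, flat declination for
  the non-tonal one), shaped by two or three time-varying formant
  resonances and gated by a syllable-rate envelope, with unit-boundary
  annotations.  It is speech-*like* (syllable-rate amplitude modulation,
  formant structure, tonal vs. flat pitch), not intelligible speech.
* **Simulated listeners** — per-unit binary responses following a
  ceiling-slope-floor psychometric curve over normalised segment duration,
  with a participant random intercept on the logit scale, a language
  offset, and (for tonal units) an extra tone-only error rate.

Default profiles mirror the study design: a non-tonal language with
200 sentences of ~19 units and a tonal one with 78 sentences of ~10 units,
each read by 10 speakers whose unit rates scatter a few percent around the
language mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .audio import AudioSignal
from .experiment import RateNormalization, UnitToken, normalize_segment_duration

__all__ = [
    "LanguageProfile",
    "PsychometricParams",
    "japanese_profile",
    "mandarin_profile",
    "generate_pseudo_speech",
    "generate_sentence_inventory",
    "simulate_listener",
    "simulate_betabinomial",
    "expand_units",
]

_CONSONANTS = "kstnhmr"
_VOWELS = "aiueo"

# per-unit f0 multiplier templates (start, mid, end) for the four lexical
# tone classes: high level, rising, dipping, falling
_TONE_TEMPLATES = {
    1: (1.15, 1.15, 1.15),
    2: (0.90, 0.95, 1.15),
    3: (1.00, 0.80, 1.05),
    4: (1.20, 1.05, 0.85),
}


@dataclass(frozen=True)
class LanguageProfile:
    """What the generator needs to know about a (pseudo-)language."""

    name: str
    tonal: bool
    unit_rate: float  # units/s
    n_sentences: int
    mean_units: float
    sd_units: float
    n_speakers: int = 10
    speaker_rate_sd: float = 0.05  # relative SD of speaker unit rates
    f0_hz: float = 220.0  # female-range base pitch
    formant_f1_range: tuple[float, float] = (300.0, 800.0)
    formant_f2_range: tuple[float, float] = (900.0, 2200.0)
    formant_f3_hz: float = 2800.0

    def __post_init__(self) -> None:
        if self.unit_rate <= 0:
            raise ValueError("unit_rate must be > 0")


def japanese_profile(**overrides) -> LanguageProfile:
    """Non-tonal profile: ~19 morae per sentence, 200 sentences."""
    return replace(
        LanguageProfile("japanese", False, 8.0, 200, 19.0, 3.1), **overrides
    )


def mandarin_profile(**overrides) -> LanguageProfile:
    """Tonal profile: ~10 syllables per sentence, 78 sentences, 4 tone classes."""
    return replace(
        LanguageProfile("mandarin", True, 5.5, 78, 10.0, 1.3), **overrides
    )


def _resonator(freq: float, bw: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-pole resonator coefficients (formant filter)."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * freq / fs
    a = np.array([1.0, -2.0 * r * np.cos(theta), r**2])
    return np.array([1.0 - r]), a


def generate_pseudo_speech(
    profile: LanguageProfile,
    n_units: int,
    seed: int | np.random.SeedSequence,
    sample_rate: float = 44100.0,
) -> tuple[AudioSignal, pd.DataFrame]:
    """One pseudo-sentence of ``n_units`` syllable-like units.

    Returns the waveform (RMS 0.1) and an annotation frame with columns
    unit, surface, tone, t_start, t_end.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    fs = sample_rate
    unit_dur = 1.0 / profile.unit_rate
    pieces, rows = [], []
    t_cursor = 0.0
    for i in range(n_units):
        dur = unit_dur * rng.uniform(0.9, 1.1)
        n = max(32, int(round(dur * fs)))
        surface = rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        tone = int(rng.integers(1, 5)) if profile.tonal else None

        # pitch contour: tone template or flat with sentence declination
        if tone is not None:
            knots = np.array(_TONE_TEMPLATES[tone])
        else:
            decl = 1.1 - 0.2 * (i / max(n_units - 1, 1))
            knots = decl * np.array([1.0, 1.0, 1.0]) * rng.uniform(0.97, 1.03)
        contour = np.interp(np.linspace(0, 1, n), [0.0, 0.5, 1.0], knots)
        f0 = profile.f0_hz * contour

        # harmonic source (1/h rolloff) up to 6 kHz
        phase = 2.0 * np.pi * np.cumsum(f0) / fs
        src = np.zeros(n)
        n_harm = int(6000.0 / profile.f0_hz)
        for h in range(1, n_harm + 1):
            src += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h
        # small aspiration component
        src += 0.05 * rng.standard_normal(n)

        # formant shaping: F1, F2 drawn per unit with a linear glide, F3 fixed
        out = src
        for lo, hi_ in (profile.formant_f1_range, profile.formant_f2_range):
            f_start, f_end = rng.uniform(lo, hi_, size=2)
            # two half-unit stationary resonators approximate the glide
            half = n // 2
            b1, a1 = _resonator(f_start, 120.0, fs)
            b2, a2 = _resonator(f_end, 120.0, fs)
            out = np.concatenate([lfilter(b1, a1, out[:half]), lfilter(b2, a2, out[half:])])
        b3, a3 = _resonator(profile.formant_f3_hz, 200.0, fs)
        out = lfilter(b3, a3, out)

        # syllable gate: raised-cosine rise/fall of 10% unit duration
        ramp = max(2, int(0.1 * n))
        gate = np.ones(n)
        edge = np.sin(0.5 * np.pi * np.arange(ramp) / (ramp - 1)) ** 2
        gate[:ramp] = edge
        gate[-ramp:] = edge[::-1]
        out = out * gate
        rms = np.sqrt(np.mean(out**2))
        if rms > 0:
            out = out / rms * rng.uniform(0.8, 1.2)
        pieces.append(out)
        rows.append(
            {
                "unit": i,
                "surface": surface,
                "tone": tone,
                "t_start": t_cursor,
                "t_end": t_cursor + n / fs,
            }
        )
        t_cursor += n / fs
    samples = np.concatenate(pieces)
    samples = samples / np.sqrt(np.mean(samples**2)) * 0.1
    return AudioSignal(samples, fs), pd.DataFrame(rows)


def generate_sentence_inventory(
    profile: LanguageProfile, seed: int | np.random.SeedSequence
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sentence metadata and unit annotations for a whole language inventory.

    Sentences are assigned round-robin to ``n_speakers`` speakers whose unit
    rates scatter around the profile rate; each sentence row carries its
    speaker's rate ratio (speaker rate / mean speaker rate) used for segment
    duration normalisation.  Returns ``(sentences, units)`` frames.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rates = profile.unit_rate * (
        1.0 + profile.speaker_rate_sd * rng.standard_normal(profile.n_speakers)
    )
    rates = np.maximum(rates, 0.1 * profile.unit_rate)
    ref_rate = float(rates.mean())
    sent_rows, unit_rows = [], []
    for sid in range(profile.n_sentences):
        speaker = sid % profile.n_speakers
        n_units = max(2, int(round(rng.normal(profile.mean_units, profile.sd_units))))
        sent_rows.append(
            {
                "sentence": sid,
                "language": profile.name,
                "speaker": speaker,
                "speaker_rate": float(rates[speaker]),
                "reference_rate": ref_rate,
                "rate_ratio": float(rates[speaker] / ref_rate),
                "n_units": n_units,
            }
        )
        for i in range(n_units):
            unit_rows.append(
                {
                    "sentence": sid,
                    "language": profile.name,
                    "unit": i,
                    "surface": rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS)),
                    "tone": int(rng.integers(1, 5)) if profile.tonal else None,
                }
            )
    return pd.DataFrame(sent_rows), pd.DataFrame(unit_rows)


@dataclass(frozen=True)
class PsychometricParams:
    """Ceiling-slope-floor curve driving the simulated listener.

    Probability of a correct unit at normalised segment duration ``d``:

        p = floor + (ceiling - floor) * logistic((midpoint - d)/slope
                                                 + language_offset + u)

    with participant intercept u ~ N(0, participant_sd^2).  Tonal units
    that would be correct flip to a tone-only error with probability
    ``tone_error_rate``.  Defaults are calibrated to the studied curve
    shape: ceiling near-perfect at 40 ms, floor below 15% beyond 160 ms,
    and a 12-18% tonal-language deficit from offset plus tone errors.
    """

    ceiling: float = 0.99
    floor: float = 0.08
    midpoint_ms: float = 85.0
    slope_ms: float = 11.0
    language_offsets: dict = field(
        default_factory=lambda: {"japanese": 0.0, "mandarin": -0.6}
    )
    participant_sd: float = 0.5
    tone_error_rate: float = 0.12

    def __post_init__(self) -> None:
        if not (0.0 <= self.floor < self.ceiling <= 1.0):
            raise ValueError("need 0 <= floor < ceiling <= 1")
        if self.slope_ms <= 0:
            raise ValueError("slope must be > 0")

    def p_correct(self, d_ms, language: str = "japanese", u: float = 0.0):
        """Expected proportion correct before tone errors."""
        d = np.asarray(d_ms, dtype=float)
        logit = (self.midpoint_ms - d) / self.slope_ms + self.language_offsets.get(
            language, 0.0
        ) + u
        return self.floor + (self.ceiling - self.floor) / (1.0 + np.exp(-logit))


def simulate_listener(
    design: pd.DataFrame,
    sentences: pd.DataFrame,
    params: PsychometricParams,
    seed: int | np.random.SeedSequence,
    tonal: bool | None = None,
) -> pd.DataFrame:
    """Simulated per-trial responses for a design over one language.

    ``design`` comes from :func:`mosaicspeech.experiment.generate_design`;
    ``sentences`` from :func:`generate_sentence_inventory` (needs columns
    sentence, language, rate_ratio, speaker_rate, reference_rate, n_units).
    Unit outcomes are independent Bernoulli draws given the trial; tone-only
    errors are drawn among correct tonal units.  Returns one row per trial:
    participant, language, sentence, block, is_practice, segment_duration_ms,
    norm_segment_duration_ms, n_units, n_correct, n_tone_only_errors.
    """
    rng = np.random.default_rng(seed)
    language = sentences["language"].iloc[0]
    if tonal is None:
        tonal = language == "mandarin"
    sent = sentences.set_index("sentence")
    intercepts = {
        p: rng.normal(0.0, params.participant_sd)
        for p in sorted(design["participant"].unique())
    }
    rows = []
    for rec in design.itertuples(index=False):
        srow = sent.loc[rec.sentence]
        rate = RateNormalization(srow["speaker_rate"], srow["reference_rate"])
        d = normalize_segment_duration(rec.segment_duration_ms, rate)
        p = float(params.p_correct(d, language, intercepts[rec.participant]))
        n_units = int(srow["n_units"])
        correct = rng.random(n_units) < p
        tone_flips = 0
        if tonal and params.tone_error_rate > 0:
            flips = correct & (rng.random(n_units) < params.tone_error_rate)
            tone_flips = int(flips.sum())
            correct = correct & ~flips
        rows.append(
            {
                "participant": rec.participant,
                "language": language,
                "sentence": rec.sentence,
                "block": rec.block,
                "is_practice": rec.is_practice,
                "segment_duration_ms": rec.segment_duration_ms,
                "norm_segment_duration_ms": d,
                "n_units": n_units,
                "n_correct": int(correct.sum()),
                "n_tone_only_errors": tone_flips,
            }
        )
    return pd.DataFrame(rows)


def expand_units(responses: pd.DataFrame) -> pd.DataFrame:
    """Unit-level binary table (one row per scored unit) from trial counts;
    the observation level of the logistic GLMM."""
    reps = responses["n_units"].to_numpy(int)
    base = responses.loc[responses.index.repeat(reps)].reset_index(drop=True)
    correct = np.concatenate(
        [
            np.repeat([1, 0], [k, n - k])
            for k, n in zip(responses["n_correct"], responses["n_units"])
        ]
    )
    base["correct"] = correct
    return base.drop(columns=["n_units", "n_correct", "n_tone_only_errors"])


def simulate_betabinomial(
    exog: np.ndarray,
    beta: np.ndarray,
    rho: float,
    totals: np.ndarray,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Draw trial success counts from the beta-binomial regression model
    (mu = logistic(X beta), correlation rho); the generator behind the
    parameter-recovery checks."""
    rng = np.random.default_rng(seed)
    mu = 1.0 / (1.0 + np.exp(-(np.asarray(exog) @ np.asarray(beta))))
    if rho <= 0:
        return rng.binomial(np.asarray(totals, int), mu)
    s = (1.0 - rho) / rho
    p = rng.beta(mu * s, (1.0 - mu) * s)
    return rng.binomial(np.asarray(totals, int), p)
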