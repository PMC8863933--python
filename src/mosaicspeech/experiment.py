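"""Experimental design, speech-rate normalisation, and response scoring.

The behavioural paradigm: each participant hears one sentence per trial at
one of five segment-duration conditions (0 ms = noise-vocoded control),
arranged in blocks that contain every condition exactly once in random
order; the first block is practice.  Transcribed responses are scored per
mora (Japanese) or per tone-marked syllable (Mandarin) by order-preserving
global alignment against the reference annotation; a blank response scores
zero, homophone substitutions are permitted, and a tonal syllable is
incorrect if its tone sign is wrong.  Nominal segment durations are
normalised by the ratio of a speaker's unit rate to the mean rate across
speakers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignInfeasibleError",
    "UnitToken",
    "RateNormalization",
    "ScoreResult",
    "parse_unit",
    "generate_design",
    "design_universe_size",
    "normalize_segment_duration",
    "score_response",
    "aggregate",
]


class DesignInfeasibleError(ValueError):
    """Not enough sentences to fill the requested blocks without repeats."""


@dataclass(frozen=True)
class UnitToken:
    """One scoring unit: a mora or a pinyin syllable with optional tone."""

    surface: str
    tone: int | None = None
    position: int = 0

    def __post_init__(self) -> None:
        if self.tone is not None and self.tone not in (1, 2, 3, 4):
            raise ValueError(f"tone must be 1-4 or None, got {self.tone}")


def parse_unit(text: str, position: int = 0) -> UnitToken:
    """Parse ``"ma3"`` into surface ``"ma"`` + tone 3; no digit means no tone."""
    if text and text[-1].isdigit():
        return UnitToken(text[:-1], int(text[-1]), position)
    return UnitToken(text, None, position)


@dataclass(frozen=True)
class RateNormalization:
    """A speaker's unit rate relative to the reference (mean-of-speakers) rate."""

    speaker_rate: float
    reference_rate: float

    def __post_init__(self) -> None:
        if self.speaker_rate <= 0 or self.reference_rate <= 0:
            raise ValueError("rates must be > 0")

    @property
    def ratio(self) -> float:
        return self.speaker_rate / self.reference_rate


def normalize_segment_duration(nominal_ms: float, rate: RateNormalization) -> float:
    """Effective segment duration: nominal x (speaker rate / reference rate).

    A faster-than-average speaker packs more linguistic units into each
    segment, so the effective duration grows; 0 ms (the vocoder control)
    maps to 0 for any ratio.
    """
    if nominal_ms < 0:
        raise ValueError("nominal duration must be >= 0")
    return nominal_ms * rate.ratio


def design_universe_size(n_sentences: int, conditions: list[float]) -> int:
    """Size of the sentence x condition universe trials are drawn from."""
    return n_sentences * len(conditions)


def generate_design(
    n_sentences: int,
    conditions: list[float],
    n_blocks: int,
    seed: int | np.random.SeedSequence,
    n_participants: int = 1,
    practice_blocks: int = 1,
) -> pd.DataFrame:
    """Randomised block design.

    Each participant receives ``n_blocks`` blocks of ``len(conditions)``
    trials; within a block every condition appears exactly once in random
    order, sentences are drawn without replacement (no sentence repeats
    within a participant), and the first ``practice_blocks`` blocks are
    flagged as practice.

    Returns a tidy frame with columns participant, block, trial, sentence,
    segment_duration_ms, is_practice.
    """
    conditions = list(conditions)
    n_cond = len(conditions)
    if n_cond == 0:
        raise ValueError("conditions must be non-empty")
    if n_sentences < n_blocks * n_cond:
        raise DesignInfeasibleError(
            f"{n_sentences} sentences cannot fill {n_blocks} blocks x {n_cond} conditions"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        sentence_ids = rng.choice(n_sentences, size=n_blocks * n_cond, replace=False)
        t = 0
        for blk in range(n_blocks):
            order = rng.permutation(n_cond)
            for cond_idx in order:
                rows.append(
                    {
                        "participant": p,
                        "block": blk,
                        "trial": t,
                        "sentence": int(sentence_ids[t]),
                        "segment_duration_ms": conditions[cond_idx],
                        "is_practice": blk < practice_blocks,
                    }
                )
                t += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScoreResult:
    """Per-trial scoring outcome at the unit level."""

    n_units: int
    n_correct: int
    correct_flags: tuple[bool, ...]
    n_tone_only_errors: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_units):
            raise ValueError("n_correct out of range")


def _align(ref_classes: list[str], resp_classes: list[str]) -> list[tuple[int, int]]:
    """Global alignment maximising segmental-class matches.

    Match scores 1, mismatch and gap 0; ties break toward the leftmost
    (earliest-reference) pairing by preferring diagonal moves, then
    reference gaps, during traceback.
    """
    n, m = len(ref_classes), len(resp_classes)
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = dp[i - 1, j - 1] + (1 if ref_classes[i - 1] == resp_classes[j - 1] else 0)
            dp[i, j] = max(match, dp[i - 1, j], dp[i, j - 1])
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        match = ref_classes[i - 1] == resp_classes[j - 1]
        if dp[i, j] == dp[i - 1, j - 1] + (1 if match else 0):
            if match:
                pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif dp[i, j] == dp[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def score_response(
    reference: list[UnitToken],
    response: list[UnitToken],
    homophone_classes: dict[str, str] | None = None,
    tonal: bool = False,
) -> ScoreResult:
    """Score a transcribed response against the reference unit sequence.

    Units are aligned order-preservingly by segmental (homophone) class; an
    aligned unit is correct if its class matches and — for tonal languages —
    its tone also matches.  A class match with a wrong tone counts as a
    tone-only error (incorrect).  An empty response scores zero.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    homophone_classes = homophone_classes or {}

    def cls(u: UnitToken) -> str:
        return homophone_classes.get(u.surface, u.surface)

    ref_classes = [cls(u) for u in reference]
    resp_classes = [cls(u) for u in response]
    pairs = _align(ref_classes, resp_classes)

    flags = [False] * len(reference)
    tone_only = 0
    for ri, qi in pairs:
        if tonal and reference[ri].tone != response[qi].tone:
            tone_only += 1
        else:
            flags[ri] = True
    return ScoreResult(len(reference), sum(flags), tuple(flags), tone_only)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Pooled percent-correct with between-participant standard errors.

    ``records`` needs columns language, segment_duration_ms, participant,
    n_units, n_correct.  Returns one row per language x condition with the
    pooled percentage (100 x sum correct / sum units) and the standard error
    of participant-level percentages.
    """
    out = []
    for (lang, sd), cell in records.groupby(["language", "segment_duration_ms"]):
        pct = 100.0 * cell["n_correct"].sum() / cell["n_units"].sum()
        per_part = cell.groupby("participant").apply(
            lambda d: 100.0 * d["n_correct"].sum() / d["n_units"].sum(),
            include_groups=False,
        )
        se = float(per_part.std(ddof=1) / np.sqrt(len(per_part))) if len(per_part) > 1 else np.nan
        out.append(
            {
                "language": lang,
                "segment_duration_ms": sd,
                "percent_correct": pct,
                "se": se,
                "n_participants": per_part.size,
            }
        )
    return pd.DataFrame(out).sort_values(["language", "segment_duration_ms"]).reset_index(drop=True)
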