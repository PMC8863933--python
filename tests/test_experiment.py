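"""Block designs, rate normalisation, and response scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mosaicspeech.experiment import (
    DesignInfeasibleError,
    RateNormalization,
    UnitToken,
    aggregate,
    design_universe_size,
    generate_design,
    normalize_segment_duration,
    parse_unit,
    score_response,
)

CONDITIONS = [0.0, 40.0, 80.0, 160.0, 320.0]


class TestGenerateDesign:
    def test_study_design_shape(self):
        df = generate_design(200, CONDITIONS, 6, seed=0)
        assert len(df) == 30  # 6 blocks x 5 conditions
        assert df["is_practice"].sum() == 5  # first block
        assert set(df.loc[df["is_practice"], "block"]) == {0}

    def test_design_universe_sizes(self):
        assert design_universe_size(200, CONDITIONS) == 1000
        assert design_universe_size(78, CONDITIONS) == 390

    def test_same_seed_reproducible(self):
        a = generate_design(200, CONDITIONS, 6, seed=42, n_participants=3)
        b = generate_design(200, CONDITIONS, 6, seed=42, n_participants=3)
        pd.testing.assert_frame_equal(a, b)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_balance_and_no_repeats_for_any_seed(self, seed):
        df = generate_design(40, CONDITIONS, 6, seed=seed, n_participants=2)
        for _, part in df.groupby("participant"):
            assert part["sentence"].is_unique
            for _, block in part.groupby("block"):
                assert sorted(block["segment_duration_ms"]) == sorted(CONDITIONS)

    def test_too_few_sentences_rejected(self):
        with pytest.raises(DesignInfeasibleError):
            generate_design(29, CONDITIONS, 6, seed=0)


class TestNormalizeSegmentDuration:
    def test_unit_ratio_unchanged(self):
        assert normalize_segment_duration(80, RateNormalization(7.0, 7.0)) == 80

    def test_faster_speaker_longer_effective_duration(self):
        # 10% faster speaker packs more units per segment
        assert normalize_segment_duration(40, RateNormalization(8.8, 8.0)) == pytest.approx(44.0)

    def test_zero_stays_zero(self):
        assert normalize_segment_duration(0, RateNormalization(5.0, 8.0)) == 0

    def test_linearity(self):
        rate = RateNormalization(6.3, 7.7)
        a = normalize_segment_duration(40, rate)
        b = normalize_segment_duration(80, rate)
        assert b == pytest.approx(2 * a)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            RateNormalization(0.0, 8.0)
        with pytest.raises(ValueError):
            normalize_segment_duration(-1, RateNormalization(8.0, 8.0))


def units(text, tonal=False):
    return [parse_unit(u, i) for i, u in enumerate(text.split())]


def bruteforce_best_alignment(ref_classes, resp_classes):
    """Exhaustive maximal order-preserving matching (oracle for <= 8 units)."""
    best = 0
    n, m = len(ref_classes), len(resp_classes)
    for k in range(min(n, m), -1, -1):
        for ridx in itertools.combinations(range(n), k):
            for qidx in itertools.combinations(range(m), k):
                if all(ref_classes[i] == resp_classes[j] for i, j in zip(ridx, qidx)):
                    return k
    return best


class TestScoreResponse:
    def test_identical_response_all_correct(self):
        ref = units("ka su te no")
        res = score_response(ref, ref)
        assert res.n_correct == res.n_units == 4

    def test_blank_response_scores_zero(self):
        res = score_response(units("ka su te"), [])
        assert res.n_correct == 0 and res.n_units == 3

    def test_wrong_tone_is_incorrect_and_counted(self):
        res = score_response(units("ma2", tonal=True), units("ma3"), tonal=True)
        assert res.n_correct == 0
        assert res.n_tone_only_errors == 1

    def test_correct_tone_required_only_for_tonal(self):
        ref, resp = units("ma2"), units("ma3")
        assert score_response(ref, resp, tonal=False).n_correct == 1

    def test_mid_sentence_deletion_recovers_remaining(self):
        ref = units("ka su te no ha mi")
        resp = units("ka su no ha mi")  # "te" dropped
        assert score_response(ref, resp).n_correct == 5

    def test_homophone_classes_permit_substitution(self):
        res = score_response(units("ka"), units("ga"), homophone_classes={"ka": "K", "ga": "K"})
        assert res.n_correct == 1

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_alignment_oracle(self, data):
        alphabet = ["ka", "su", "te", "no"]
        ref = data.draw(st.lists(st.sampled_from(alphabet), min_size=1, max_size=8))
        resp = data.draw(st.lists(st.sampled_from(alphabet), min_size=0, max_size=8))
        got = score_response(
            [UnitToken(s, None, i) for i, s in enumerate(ref)],
            [UnitToken(s, None, i) for i, s in enumerate(resp)],
        ).n_correct
        assert got == bruteforce_best_alignment(ref, resp)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_adding_a_unit_never_decreases_score(self, data):
        alphabet = ["ka", "su", "te"]
        ref_s = data.draw(st.lists(st.sampled_from(alphabet), min_size=1, max_size=6))
        resp_s = data.draw(st.lists(st.sampled_from(alphabet), min_size=0, max_size=6))
        pos = data.draw(st.integers(0, len(resp_s)))
        extra = data.draw(st.sampled_from(alphabet))
        ref = [UnitToken(s, None, i) for i, s in enumerate(ref_s)]
        before = score_response(ref, [UnitToken(s, None, i) for i, s in enumerate(resp_s)])
        grown = resp_s[:pos] + [extra] + resp_s[pos:]
        after = score_response(ref, [UnitToken(s, None, i) for i, s in enumerate(grown)])
        assert after.n_correct >= before.n_correct


class TestAggregate:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(
            rows,
            columns=["language", "segment_duration_ms", "participant", "n_units", "n_correct"],
        )

    def test_all_correct_is_100(self):
        df = self.frame([["jp", 40, p, 10, 10] for p in range(3)])
        out = aggregate(df)
        assert out.loc[0, "percent_correct"] == 100.0

    def test_half_correct_zero_se(self):
        df = self.frame([["jp", 40, p, 10, 5] for p in range(4)])
        out = aggregate(df)
        assert out.loc[0, "percent_correct"] == 50.0
        assert out.loc[0, "se"] == 0.0

    def test_pooled_mixture_matches_hand_computation(self):
        df = self.frame(
            [["jp", 40, 0, 10, 9], ["jp", 40, 1, 20, 10], ["jp", 80, 0, 10, 2]]
        )
        out = aggregate(df).set_index("segment_duration_ms")
        assert out.loc[40, "percent_correct"] == pytest.approx(100 * 19 / 30)
        assert out.loc[80, "percent_correct"] == pytest.approx(20.0)
        # SE across participant percentages at 40 ms: sd(90, 50)/sqrt(2)
        assert out.loc[40, "se"] == pytest.approx(np.std([90, 50], ddof=1) / np.sqrt(2))


def test_parse_unit_tone_handling():
    assert parse_unit("ma3").tone == 3 and parse_unit("ma3").surface == "ma"
    assert parse_unit("ka").tone is None
    with pytest.raises(ValueError):
        UnitToken("ma", 7)
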