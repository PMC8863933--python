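"""Mosaicking, noise vocoding, and local time reversal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mosaicspeech import AudioSignal
from mosaicspeech.degrade import (
    MosaicGrid,
    local_time_reverse,
    make_mosaic_speech,
    make_noise_vocoded,
    mosaic_envelope,
    segment_boundaries,
    synthesize_from_target,
)
from mosaicspeech.filterbank import (
    BandSpec,
    SmootherSpec,
    band_noise,
    energy_density,
    envelope_matrix,
)

FS = 44100.0


class TestMosaicEnvelope:
    def test_constant_envelope_gives_identical_patches(self, bands20, speech_1s):
        sig, _ = speech_1s
        env = envelope_matrix(sig, bands20)
        const = env.__class__(
            np.full_like(env.values, 0.25), env.sample_rate, env.band_spec, env.smoother
        )
        grid = mosaic_envelope(const, 40)
        np.testing.assert_allclose(grid.patch_power, 0.25)

    def test_full_length_segment_is_band_mean(self, bands20, speech_1s):
        sig, _ = speech_1s
        env = envelope_matrix(sig, bands20)
        grid = mosaic_envelope(env, 1e6)  # longer than signal -> one segment
        assert grid.n_segments == 1
        np.testing.assert_allclose(grid.patch_power[:, 0], env.values.mean(axis=1))

    def test_patches_equal_bruteforce_window_means(self, rng, bands20, speech_1s):
        sig, _ = speech_1s
        env = envelope_matrix(sig, bands20)
        grid = mosaic_envelope(env, 40)
        # direct loop oracle
        bounds = grid.segment_boundaries
        for b in range(0, env.n_bands, 5):
            for k in range(grid.n_segments):
                expected = env.values[b, bounds[k] : bounds[k + 1]].mean()
                assert grid.patch_power[b, k] == pytest.approx(expected)

    def test_grand_mean_preserved_for_equal_segments(self, bands20):
        from mosaicspeech.degrade import step_expand
        from mosaicspeech.filterbank import EnvelopeMatrix

        rng = np.random.default_rng(0)
        n = int(round(0.04 * FS)) * 25  # exactly 25 equal segments
        values = rng.random((20, n))
        env = EnvelopeMatrix(values, FS, BandSpec(np.linspace(50, 6400, 21)), SmootherSpec())
        grid = mosaic_envelope(env, 40)
        step = step_expand(grid)
        np.testing.assert_allclose(step.mean(axis=1), values.mean(axis=1), rtol=1e-12)

    def test_boundaries_arithmetic(self):
        bounds = segment_boundaries(int(2 * FS), 40, FS)
        assert len(bounds) - 1 == 50  # 2 s / 40 ms


class TestSynthesizeFromTarget:
    def test_zero_target_gives_silence(self):
        wide = BandSpec(np.array([50.0, 6400.0]))
        carriers = band_noise(wide, 10000, FS, seed=1)
        grid = MosaicGrid(np.zeros((1, 5)), 40, np.array([0, 2000, 4000, 6000, 8000, 10000]))
        out = synthesize_from_target(grid, carriers)
        assert np.allclose(out.samples, 0)

    def test_constant_target_energy_density(self):
        """A wide-band carrier driven to constant power P holds P within 5%."""
        wide = BandSpec(np.array([50.0, 6400.0]))
        n = int(4 * FS)
        carriers = band_noise(wide, n, FS, seed=2)
        p_target = 0.01
        bounds = np.array([0, n])
        grid = MosaicGrid(np.full((1, 1), p_target), 4000, bounds)
        out = synthesize_from_target(grid, carriers)
        env = energy_density(out)
        interior = env[int(0.2 * FS) : -int(0.2 * FS)]
        assert np.mean(interior) == pytest.approx(p_target, rel=0.05)
        # pointwise stability for a ~6 kHz-wide carrier
        assert np.percentile(np.abs(interior - p_target) / p_target, 95) < 0.2

    def test_band_count_mismatch_rejected(self, bands20):
        carriers = band_noise(bands20, 5000, FS, seed=0)
        grid = MosaicGrid(np.ones((3, 1)), 100, np.array([0, 5000]))
        with pytest.raises(ValueError, match="band count"):
            synthesize_from_target(grid, carriers)


class TestMosaicSpeech:
    def test_output_length_and_rms_match_input(self, bands20, speech_1s):
        sig, _ = speech_1s
        stim = make_mosaic_speech(sig, bands20, 80, seed=11)
        assert len(stim.audio) == len(sig)
        assert stim.audio.rms == pytest.approx(sig.rms, rel=0.01)
        assert np.abs(stim.audio.samples).max() <= 1.0

    def test_segment_tagging(self, bands20, speech_1s):
        sig, _ = speech_1s
        assert make_mosaic_speech(sig, bands20, 40, seed=0).kind == "mosaic"
        assert make_noise_vocoded(sig, bands20, seed=0).segment_duration_ms == 0

    def test_carrier_independence_at_long_segments(self, bands20, speech_1s):
        """Different carrier seeds change the waveform but re-analysis
        recovers the same patch grid (320-ms segments, where the smoothing
        kernel's boundary flux is small)."""
        sig, _ = speech_1s
        a = make_mosaic_speech(sig, bands20, 320, seed=1)
        b = make_mosaic_speech(sig, bands20, 320, seed=2)
        assert not np.allclose(a.audio.samples, b.audio.samples)
        ga = mosaic_envelope(envelope_matrix(a.audio, bands20), 320).patch_power
        gb = mosaic_envelope(envelope_matrix(b.audio, bands20), 320).patch_power
        rel = np.abs(ga - gb) / np.maximum((ga + gb) / 2, 1e-18)
        assert np.median(rel) < 0.05

    def test_patch_conservation_at_long_segments(self, bands20, speech_1s):
        """Re-analysed patch energy matches the grid at 320 ms for most
        patches; at shorter segments the 5-ms smoothing kernel's boundary
        flux makes exact recovery impossible (see methods note)."""
        sig, _ = speech_1s
        stim = make_mosaic_speech(sig, bands20, 320, seed=4)
        src = mosaic_envelope(envelope_matrix(sig, bands20), 320).patch_power
        out = mosaic_envelope(envelope_matrix(stim.audio, bands20), 320).patch_power
        scale = (stim.audio.rms / sig.rms) ** 2
        rel = np.abs(out - src * scale) / np.maximum(src * scale, 1e-18)
        assert np.median(rel) < 0.05

    def test_zero_duration_rejected(self, bands20, speech_1s):
        sig, _ = speech_1s
        with pytest.raises(ValueError):
            make_mosaic_speech(sig, bands20, 0, seed=0)


class TestNoiseVocoded:
    def test_silent_input_silent_output(self, bands20):
        out = make_noise_vocoded(AudioSignal(np.zeros(int(FS)), FS), bands20, seed=0)
        assert np.allclose(out.audio.samples, 0)

    def test_band_envelopes_track_source(self, bands20, speech_1s):
        """Output band envelopes correlate with source band envelopes in
        every band that actually carries energy."""
        sig, _ = speech_1s
        stim = make_noise_vocoded(sig, bands20, seed=3)
        es = envelope_matrix(sig, bands20).values
        eo = envelope_matrix(stim.audio, bands20).values
        weights = es.mean(axis=1)
        cors = np.array(
            [np.corrcoef(es[b], eo[b])[0, 1] for b in range(bands20.n_bands)]
        )
        energetic = weights > 1e-3 * weights.max()
        assert np.all(cors[energetic] > 0.9)
        assert np.average(cors, weights=weights) > 0.95

    def test_equals_mosaic_in_one_sample_segment_limit(self, bands20, speech_1s):
        sig, _ = speech_1s
        short = AudioSignal(sig.samples[: int(FS / 2)], FS)
        nvs = make_noise_vocoded(short, bands20, seed=5)
        mosaic = make_mosaic_speech(short, bands20, 1000.0 / FS, seed=5)
        env_n = envelope_matrix(nvs.audio, bands20).values
        env_m = envelope_matrix(mosaic.audio, bands20).values
        rel = np.linalg.norm(env_n - env_m) / np.linalg.norm(env_n)
        assert rel < 0.01


class TestLocalTimeReverse:
    @given(st.integers(0, 2**31 - 1), st.floats(5, 500))
    @settings(max_examples=25, deadline=None)
    def test_involution_and_multiset(self, seed, seg_ms):
        r = np.random.default_rng(seed)
        sig = AudioSignal(r.standard_normal(r.integers(10, 4000)), FS)
        twice = local_time_reverse(local_time_reverse(sig, seg_ms), seg_ms)
        np.testing.assert_array_equal(twice.samples, sig.samples)
        once = local_time_reverse(sig, seg_ms)
        np.testing.assert_array_equal(np.sort(once.samples), np.sort(sig.samples))

    def test_segment_longer_than_signal_reverses_whole(self, rng):
        sig = AudioSignal(rng.standard_normal(500), FS)
        out = local_time_reverse(sig, 1e6)
        np.testing.assert_array_equal(out.samples, sig.samples[::-1])

    def test_matches_naive_loop_oracle(self, rng):
        sig = AudioSignal(rng.standard_normal(5000), FS)
        seg_ms = 17.0
        out = local_time_reverse(sig, seg_ms)
        # brute-force oracle
        seg = int(round(seg_ms / 1000 * FS))
        expected = sig.samples.copy()
        for lo in range(0, len(expected), seg):
            expected[lo : lo + seg] = expected[lo : lo + seg][::-1]
        np.testing.assert_array_equal(out.samples, expected)


def test_stimulus_sidecar_roundtrip(tmp_path, bands20, speech_1s):
    import json

    sig, _ = speech_1s
    stim = make_mosaic_speech(sig, bands20, 160, seed=9)
    path = tmp_path / "stim.json"
    stim.write_sidecar(path)
    payload = json.loads(path.read_text())
    assert payload["kind"] == "mosaic"
    assert payload["segment_duration_ms"] == 160
    assert len(payload["band_edges_hz"]) == 21
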