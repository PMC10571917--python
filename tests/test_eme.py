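import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import speechedge as se
from speechedge.eme import EMEConfig, build_gain_profile
from speechedge.envelope import EnvelopeSet

from conftest import TEST_FS


class TestModulationFactors:
    def test_rms_ratio(self):
        env = EnvelopeSet(
            np.vstack([np.full(100, 0.2), np.full(100, 0.5)]), TEST_FS, smoothed=True
        )
        mf = se.modulation_factors(env)
        np.testing.assert_allclose(mf.mf, [0.4, 1.0])

    def test_identical_channels_all_one(self):
        env = EnvelopeSet(np.ones((4, 100)), TEST_FS, smoothed=True)
        np.testing.assert_array_equal(se.modulation_factors(env).mf, 1.0)

    def test_silent_channel_zero(self):
        env = EnvelopeSet(
            np.vstack([np.zeros(100), np.ones(100)]), TEST_FS, smoothed=True
        )
        np.testing.assert_allclose(se.modulation_factors(env).mf, [0.0, 1.0])

    def test_all_silent_rejected(self):
        env = EnvelopeSet(np.zeros((2, 100)), TEST_FS, smoothed=True)
        with pytest.raises(ValueError):
            se.modulation_factors(env)

    def test_requires_smoothed(self):
        env = EnvelopeSet(np.ones((2, 100)), TEST_FS, smoothed=False)
        with pytest.raises(ValueError):
            se.modulation_factors(env)


class TestChannelGain:
    @pytest.mark.parametrize(
        "mf,expected",
        [(0.05, 20.0), (1.0, 0.0), (0.55, 10.0), (0.0, 20.0), (0.1, 20.0)],
    )
    def test_gain_curve(self, mf, expected):
        assert se.channel_gain(mf) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        for bad in (-0.1, 1.5):
            with pytest.raises(ValueError):
                se.channel_gain(bad)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None)
    def test_bounded_and_plateau(self, mf):
        g = se.channel_gain(mf)
        assert 0.0 <= g <= 20.0
        if mf < 0.1:
            assert g == 20.0

    def test_monotone_nonincreasing_and_continuous(self):
        grid = np.linspace(0, 1, 2001)
        gains = np.array([se.channel_gain(v) for v in grid])
        assert np.all(np.diff(gains) <= 1e-12)
        assert np.max(np.abs(np.diff(gains))) < 0.05  # no jumps at the knee


class TestGainProfile:
    def test_gain_only_multipliers(self):
        env = EnvelopeSet(
            np.vstack([np.full(100, 1.0), np.full(100, 0.04)]), TEST_FS, smoothed=True
        )
        prof = build_gain_profile(env, se.modulation_factors(env), EMEConfig(mode="gain_only"))
        np.testing.assert_allclose(prof.multiplier[0], 1.0)  # mf = 1 -> 0 dB
        np.testing.assert_allclose(prof.multiplier[1], 10.0)  # mf < knee -> 20 dB

    def test_noise_floor_suppresses_gain(self):
        e = np.full(1000, 1.0)
        e[:100] = 10 ** (-70 / 20)  # 70 dB below channel peak
        env = EnvelopeSet(np.vstack([e, np.full(1000, 20.0)]), TEST_FS, smoothed=True)
        prof = build_gain_profile(env, se.modulation_factors(env), EMEConfig(mode="gain_only"))
        assert prof.multiplier[0, 0] == pytest.approx(1.0)  # floor: 0 dB
        assert prof.multiplier[0, -1] == pytest.approx(10.0)  # above floor: 20 dB

    def test_bounds(self):
        rng = np.random.default_rng(0)
        env = EnvelopeSet(np.abs(rng.standard_normal((5, 500))), TEST_FS, smoothed=True)
        prof = build_gain_profile(env, se.modulation_factors(env), EMEConfig())
        assert np.all(prof.channel_gain_db >= 0) and np.all(prof.channel_gain_db <= 20)
        assert np.all(prof.multiplier >= 0)


class TestLoudnessEqualize:
    def test_rms_ratio_scaling(self):
        fs = TEST_FS
        cand = se.AudioSignal(np.full(100, 0.2), fs)
        ref = se.AudioSignal(np.full(100, 0.1), fs)
        out = se.loudness_equalize(cand, ref)
        np.testing.assert_allclose(out.samples, cand.samples * 0.5)

    def test_identity(self):
        sig = se.AudioSignal(np.sin(np.linspace(0, 30, 500)), TEST_FS)
        out = se.loudness_equalize(sig, sig)
        np.testing.assert_allclose(out.samples, sig.samples)

    def test_random_noise_rms_match(self):
        rng = np.random.default_rng(3)
        cand = se.AudioSignal(rng.standard_normal(5000) * 3.7, TEST_FS)
        ref = se.AudioSignal(rng.standard_normal(5000) * 0.2, TEST_FS)
        out = se.loudness_equalize(cand, ref)
        ratio = np.sqrt(np.mean(out.samples**2)) / np.sqrt(np.mean(ref.samples**2))
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_silent_reference_rejected(self):
        with pytest.raises(ValueError):
            se.loudness_equalize(
                se.AudioSignal(np.ones(10), TEST_FS), se.AudioSignal(np.zeros(10), TEST_FS)
            )


class TestEnhance:
    def test_tone_passthrough(self, faded_tone):
        """Constant-envelope input: 0 dB gain path returns the input."""
        res = se.enhance(faded_tone)
        fs = faded_tone.sample_rate
        interior = slice(int(0.7 * fs), int(-0.7 * fs))
        x, y = faded_tone.samples[interior], res.audio.samples[interior]
        rel = np.sqrt(np.mean((y - x) ** 2)) / np.sqrt(np.mean(x**2))
        assert rel < 0.01

    def test_idempotent_for_constant_envelopes(self, faded_tone):
        res1 = se.enhance(faded_tone)
        res2 = se.enhance(res1.audio)
        fs = faded_tone.sample_rate
        interior = slice(int(0.7 * fs), int(-0.7 * fs))
        a, b = res1.audio.samples[interior], res2.audio.samples[interior]
        assert np.sqrt(np.mean((b - a) ** 2)) / np.sqrt(np.mean(a**2)) < 0.01

    def test_increases_low_frequency_modulation(self, cds_audio, cds_enhanced):
        p_in = se.band_modulation_power(cds_audio)
        p_out = se.band_modulation_power(cds_enhanced.audio)
        assert p_out > p_in

    def test_output_matched_and_finite(self, cds_audio, cds_enhanced):
        out = cds_enhanced.audio
        assert out.n_samples == cds_audio.n_samples
        assert np.all(np.isfinite(out.samples))
        rms_ratio = np.sqrt(np.mean(out.samples**2)) / np.sqrt(np.mean(cds_audio.samples**2))
        assert rms_ratio == pytest.approx(1.0, abs=1e-6)
        # representable in float WAV without clipping
        assert np.abs(out.samples).max() < np.finfo(np.float32).max

    def test_deepens_modulation_in_active_channels(self, cds_audio, cds_enhanced):
        """Peak-to-trough envelope ratio grows in every active channel."""
        spec = se.design_erb_filterbank(sample_rate=cds_audio.sample_rate)

        def depth_per_channel(sig):
            sb = se.analyze(sig, spec)
            env = se.smooth_envelope(se.hilbert_envelope(sb)).envelopes
            interior = env[:, int(sig.sample_rate) : -int(sig.sample_rate)]
            return interior.max(axis=1) / np.maximum(interior.min(axis=1), 1e-12), np.sqrt(
                np.mean(env**2, axis=1)
            )

        d_in, rms_in = depth_per_channel(cds_audio)
        d_out, _ = depth_per_channel(cds_enhanced.audio)
        active = rms_in > 0.05 * rms_in.max()
        assert active.sum() >= 5
        assert np.all(d_out[active] > d_in[active])

    def test_silence_passthrough(self):
        sig = se.AudioSignal(np.zeros(int(2 * TEST_FS)), TEST_FS)
        res = se.enhance(sig)
        assert not np.any(res.audio.samples)

    def test_rejects_low_sample_rate(self):
        with pytest.raises(ValueError):
            se.enhance(se.AudioSignal(np.ones(8000), 8000.0))

    def test_sectioning_reports(self, cds_audio):
        config = EMEConfig(section_length_s=10.0)
        res = se.enhance(cds_audio, config)
        assert len(res.sections) == 3
        assert [s.start_s for s in res.sections] == [0.0, 10.0, 20.0]
        for s in res.sections:
            assert s.mf.max() == pytest.approx(1.0)
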