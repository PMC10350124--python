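import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import periodogram

from vocsim import (
    AudioSignal,
    BandEdges,
    EnvelopeMatrix,
    VocoderParams,
    equal_octave_edges,
    extract_envelopes,
    limit_dynamic_range,
    quantization_levels,
    quantize_envelopes,
    synthesize,
    vocode,
)
from vocsim.fixtures import delay_compensated_correlation

FS = 16000.0


def _env(values):
    return EnvelopeMatrix(np.atleast_2d(np.asarray(values, dtype=float)), FS)


class TestExtractEnvelopes:
    def test_am_modulator_recovered(self, am_tone):
        sig, mod = am_tone
        env = extract_envelopes([sig], 50.0)
        skip = int(0.1 * FS)
        corr = delay_compensated_correlation(
            env.values[0][skip:], mod[skip:], max_lag_samples=int(0.05 * FS)
        )
        assert corr >= 0.95

    def test_steady_tone_gives_flat_envelope(self):
        t = np.arange(int(FS)) / FS
        sig = AudioSignal(np.sin(2 * np.pi * 1000.0 * t), FS)
        env = extract_envelopes([sig], 50.0).values[0][int(0.1 * FS):]
        assert env.std() / env.mean() < 0.05

    def test_zero_input_zero_envelope(self):
        env = extract_envelopes([AudioSignal(np.zeros(1000), FS)], 100.0)
        assert np.all(env.values == 0)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            extract_envelopes([AudioSignal(np.zeros(100), FS)], 9000.0)

    def test_envelopes_nonnegative(self, harmonic_stimulus):
        sig, _ = harmonic_stimulus
        env = extract_envelopes([sig], 100.0)
        assert np.all(env.values >= 0)


class TestLimitDynamicRange:
    def test_forty_db_floor(self):
        out = limit_dynamic_range(_env([1.0, 0.1, 0.001]), 40.0)
        np.testing.assert_allclose(out.values, [[1.0, 0.1, 0.0]])

    def test_full_range_is_identity(self):
        env = _env([1.0, 0.1, 0.001])
        assert limit_dynamic_range(env, "full") is env

    def test_global_max_governs_all_channels(self):
        env = EnvelopeMatrix(np.array([[1.0, 0.5], [0.005, 0.005]]), FS)
        out = limit_dynamic_range(env, 40.0)
        assert np.all(out.values[1] == 0.0)
        np.testing.assert_allclose(out.values[0], [1.0, 0.5])

    def test_value_exactly_at_floor_retained(self):
        out = limit_dynamic_range(_env([1.0, 0.01]), 40.0)
        np.testing.assert_allclose(out.values, [[1.0, 0.01]])

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            limit_dynamic_range(_env([1.0]), 0.0)

    @given(
        dr_small=st.floats(5, 60),
        extra=st.floats(1, 60),
        values=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_monotone_in_dynamic_range(self, dr_small, extra, values):
        """Widening the dynamic range never zeroes a value a narrower one kept."""
        env = _env(values)
        narrow = limit_dynamic_range(env, dr_small).values
        wide = limit_dynamic_range(env, dr_small + extra).values
        assert np.all(wide[narrow > 0] > 0)


class TestQuantizeEnvelopes:
    def test_two_levels_forty_db(self):
        # levels {1.0, 0.01}; 0.5 is -6 dB, nearer the top level
        out = quantize_envelopes(_env([1.0, 0.5, 0.01]), 2, 40.0)
        np.testing.assert_allclose(out.values, [[1.0, 1.0, 0.01]])

    def test_infinite_steps_is_identity(self):
        env = _env([1.0, 0.37, 0.002])
        assert quantize_envelopes(env, "infinite", 40.0) is env

    def test_zeros_preserved(self):
        out = quantize_envelopes(_env([1.0, 0.0]), 4, 40.0)
        assert out.values[0, 1] == 0.0

    def test_midpoint_rounds_to_louder_level(self):
        # levels at 0 and -40 dB; midpoint is -20 dB
        mid = 10 ** (-20 / 20)
        out = quantize_envelopes(_env([1.0, mid]), 2, 40.0)
        assert out.values[0, 1] == pytest.approx(1.0)

    def test_single_step_collapses_to_max(self):
        out = quantize_envelopes(_env([1.0, 0.3, 0.02]), 1, 40.0)
        np.testing.assert_allclose(out.values, [[1.0, 1.0, 1.0]])

    def test_quantization_with_full_range_rejected(self):
        with pytest.raises(ValueError, match="finite dynamic range"):
            quantize_envelopes(_env([1.0, 0.5]), 4, "full")

    def test_invalid_step_count_rejected(self):
        with pytest.raises(ValueError):
            quantize_envelopes(_env([1.0]), 0, 40.0)

    @given(
        values=st.lists(st.floats(1e-5, 1.0), min_size=1, max_size=30),
        n_steps=st.integers(1, 20),
        dr=st.floats(10, 100),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_idempotent_and_in_level_set(self, values, n_steps, dr):
        """Quantized values lie in the level set (plus zero); re-quantizing
        changes nothing."""
        env = limit_dynamic_range(_env(values), dr)
        once = quantize_envelopes(env, n_steps, dr)
        levels = quantization_levels(env.global_max(), dr, n_steps)
        nz = once.values[once.values > 0]
        assert np.all(np.isclose(nz[:, None], levels[None, :], rtol=1e-12).any(axis=1))
        twice = quantize_envelopes(once, n_steps, dr)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)


class TestSynthesize:
    def test_zero_envelope_zero_output(self):
        out = synthesize(EnvelopeMatrix(np.zeros((2, 1000)), FS),
                         BandEdges([500, 1000, 2000]), seed=1)
        assert np.all(out.samples == 0)

    def test_energy_confined_to_band(self):
        env = EnvelopeMatrix(np.ones((1, int(FS))), FS)
        out = synthesize(env, BandEdges([500, 2000]), seed=5)
        f, pxx = periodogram(out.samples, FS)
        frac = pxx[(f >= 400) & (f <= 2500)].sum() / pxx.sum()
        assert frac >= 0.90

    def test_fixed_seed_bit_identical(self):
        env = EnvelopeMatrix(np.abs(np.random.default_rng(0).standard_normal((2, 4000))), FS)
        edges = BandEdges([500, 1000, 2000])
        a = synthesize(env, edges, seed=42)
        b = synthesize(env, edges, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            synthesize(EnvelopeMatrix(np.ones((3, 100)), FS), BandEdges([500, 2000]))


class TestVocode:
    def test_identity_degradations_match_classic_vocoder(self, harmonic_stimulus):
        """dr=full + infinite steps is exactly the classic noise vocoder:
        the manually composed undegraded chain gives the same samples."""
        from vocsim import split_bands

        sig, _ = harmonic_stimulus
        params = VocoderParams(n_channels=6, carrier_seed=9)
        full = vocode(sig, params)

        edges = params.band_edges()
        env = extract_envelopes(split_bands(sig, edges, params.filter_spec),
                                params.env_cutoff, params.filter_spec)
        classic = synthesize(env, edges, params.filter_spec, seed=9)
        classic = classic.scaled(sig.rms() / classic.rms())
        np.testing.assert_array_equal(full.samples, classic.samples)

    def test_duration_and_rms_preserved(self, harmonic_stimulus):
        sig, _ = harmonic_stimulus
        out = vocode(sig, VocoderParams(n_channels=8))
        assert len(out) == len(sig)
        assert out.rms() == pytest.approx(sig.rms(), rel=1e-6)

    def test_am_tone_energy_stays_in_its_band(self, am_tone):
        sig, _ = am_tone
        params = VocoderParams(n_channels=6, carrier_seed=2)
        out = vocode(sig, params)
        edges = params.band_edges()
        lo, hi = edges.band(edges.band_containing(1000.0))
        f, pxx = periodogram(out.samples, FS)
        assert pxx[(f >= lo) & (f <= hi)].sum() / pxx.sum() >= 0.80

    def test_degraded_chain_runs_with_all_stages(self, harmonic_stimulus):
        sig, _ = harmonic_stimulus
        out = vocode(sig, VocoderParams(n_channels=6, dynamic_range_db=40.0,
                                        quant_steps=8))
        assert len(out) == len(sig)
        assert out.rms() > 0


class TestVocoderParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_channels": 0},
            {"n_channels": 8, "env_cutoff": 0},
            {"n_channels": 8, "dynamic_range_db": -10},
            {"n_channels": 8, "quant_steps": 0},
            {"n_channels": 8, "quant_steps": 2.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VocoderParams(**kwargs)

    def test_cochlear_mode_edges(self):
        p = VocoderParams(n_channels=22, edge_mode="cochlear_standard")
        edges = p.band_edges()
        assert edges.edges[0] == 188.0 and edges.edges[-1] == 7938.0
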