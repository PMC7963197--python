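"""Preprocessing chain: filters, phase detection, normalization, assembly."""

import numpy as np
import pytest

from synergycoach.preprocess import (CycleEnvelope, assemble_matrix,
                                     detect_phases, emg_envelope,
                                     normalization_reference, normalize_cycles,
                                     smooth_barbell)


class TestSmoothBarbell:
    def test_dc_gain_unity(self):
        out = smooth_barbell(np.full(500, 3.7), fs=200)
        np.testing.assert_allclose(out, 3.7, rtol=1e-9)

    def test_stopband_attenuation_50hz(self):
        t = np.arange(2000) / 200.0
        out = smooth_barbell(np.sin(2 * np.pi * 50 * t), fs=200)
        # forward-backward 4th-order at 8 Hz: > 40 dB down at 50 Hz
        assert np.sqrt(np.mean(out[200:-200] ** 2)) < 10 ** (-40 / 20) / np.sqrt(2)

    def test_passes_slow_component(self):
        t = np.arange(2000) / 200.0
        slow = np.sin(2 * np.pi * 1.0 * t)
        out = smooth_barbell(slow + 0.5 * np.sin(2 * np.pi * 50 * t), fs=200)
        assert np.corrcoef(out, slow)[0, 1] > 0.999

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            smooth_barbell(np.zeros(10), fs=200)

    def test_zero_phase_symmetric_impulse(self):
        """A symmetric input must give a symmetric response (no filter lag)."""
        x = np.zeros(801)
        x[400] = 1.0
        out = smooth_barbell(x, fs=200)
        np.testing.assert_allclose(out, out[::-1], atol=1e-12)


class TestDetectPhases:
    def test_cosine_cycles(self):
        # n full min->max->min repetitions, splits at the analytic maxima
        n, period = 5, 200
        t = np.arange(n * period)
        x = 1 - np.cos(2 * np.pi * t / period)
        reps = detect_phases(x)
        assert len(reps) == n
        for i, (a, m, b) in enumerate(reps):
            assert m == pytest.approx(i * period + period // 2, abs=1)
            assert a == pytest.approx(i * period, abs=1)
            assert b == pytest.approx((i + 1) * period, abs=1)

    def test_monotone_ramp_errors(self):
        with pytest.raises(ValueError, match="no repetitions"):
            detect_phases(np.linspace(0, 1, 500))

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            detect_phases(np.ones(100))


class TestEmgEnvelope:
    def test_zero_in_zero_out(self):
        out = emg_envelope(np.zeros((2, 4000)), fs=2000)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_rectified_sine_mean(self):
        """Envelope of a 100 Hz sine of amplitude a approaches 2a/pi."""
        a, fs = 1.5, 2000.0
        t = np.arange(int(4 * fs)) / fs
        out = emg_envelope(a * np.sin(2 * np.pi * 100 * t), fs=fs)[0]
        mid = out[int(fs):-int(fs)]
        assert np.mean(mid) == pytest.approx(2 * a / np.pi, rel=0.05)

    def test_stopband_low_frequency(self):
        fs = 2000.0
        t = np.arange(int(4 * fs)) / fs
        out = emg_envelope(np.sin(2 * np.pi * 5 * t), fs=fs)[0]
        assert np.max(out[int(fs):-int(fs)]) < 0.05

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            emg_envelope(np.zeros((1, 1000)), fs=800)


class TestNormalizationReference:
    def test_constant_envelope(self):
        ref = normalization_reference(np.full((1, 1000), 2.5), fs=1000)
        assert ref[0] == pytest.approx(2.5)

    def test_triangular_peak_closed_form(self):
        """Mean of the 101 samples centered on a unit triangle apex at fs=1000.

        Oracle: the triangle drops by `slope` per sample on both sides, so the
        window mean is 1 - slope * mean(|k|) over k = -50..50.
        """
        fs, slope = 1000.0, 0.004
        n = 500
        tri = np.clip(1.0 - slope * np.abs(np.arange(n) - n // 2), 0, None)
        expected = 1.0 - slope * np.mean(np.abs(np.arange(-50, 51)))
        ref = normalization_reference(tri[None, :], fs=fs)
        assert ref[0] == pytest.approx(expected, rel=1e-12)

    def test_self_normalization_is_idempotent(self):
        rng = np.random.default_rng(0)
        env = rng.random((3, 2000)) + 0.1
        fs = 1000.0
        ref = normalization_reference(env, fs)
        ref2 = normalization_reference(env / ref[:, None], fs)
        np.testing.assert_allclose(ref2, 1.0, rtol=1e-12)

    def test_zero_channel_named_in_error(self):
        env = np.ones((2, 1000))
        env[1] = 0.0
        with pytest.raises(ValueError, match="PM"):
            normalization_reference(env, fs=1000)


class TestNormalizeCycles:
    @staticmethod
    def _phases(n_reps, period=200):
        return [(i * period, i * period + period // 2, (i + 1) * period)
                for i in range(n_reps)]

    def test_first_last_excluded(self):
        env = np.abs(np.random.default_rng(0).random((4, 1600)))
        cycles = normalize_cycles(env, self._phases(8), np.ones(4), 200, 200)
        assert len(cycles) == 6

    def test_three_reps_boundary(self):
        env = np.abs(np.random.default_rng(0).random((4, 600)))
        cycles = normalize_cycles(env, self._phases(3), np.ones(4), 200, 200)
        assert len(cycles) == 1

    def test_too_few_reps_rejected(self):
        env = np.ones((4, 400))
        with pytest.raises(ValueError, match="exclusion"):
            normalize_cycles(env, self._phases(2), np.ones(4), 200, 200)

    def test_identity_resample(self):
        """A cycle already sampled at 100 points per phase passes through.

        The ascendant phase (whose 100 samples map onto themselves) is exact;
        the descendant phase shares its first sample with the phase split, so
        a smooth cycle is reproduced to interpolation accuracy.
        """
        t = np.linspace(0, 2 * np.pi, 200)
        one = np.vstack([1 + np.sin(t), 1 + np.cos(2 * t)])
        env = np.hstack([one, one, one])
        phases = [(0, 99, 199), (200, 299, 399), (400, 499, 599)]
        cycles = normalize_cycles(env, phases, np.ones(2), 200, 200)
        np.testing.assert_allclose(cycles[0].values[:, :100], one[:, :100],
                                   atol=1e-12)
        np.testing.assert_allclose(cycles[0].values, one, atol=0.05)

    def test_reference_scaling(self):
        env = np.ones((2, 600))
        ref = np.array([2.0, 4.0])
        cycles = normalize_cycles(env, self._phases(3), ref, 200, 200)
        np.testing.assert_allclose(cycles[0].values[0], 0.5)
        np.testing.assert_allclose(cycles[0].values[1], 0.25)


class TestAssembleMatrix:
    @pytest.mark.parametrize("n,cols", [(8, 1600), (4, 800), (1, 200)])
    def test_shapes(self, n, cols):
        cycles = [CycleEnvelope(np.ones((16, 200))) for _ in range(n)]
        assert assemble_matrix(cycles).shape == (16, cols)

    def test_inconsistent_channels_rejected(self):
        cycles = [CycleEnvelope(np.ones((16, 200))),
                  CycleEnvelope(np.ones((8, 200)))]
        with pytest.raises(ValueError, match="channel"):
            assemble_matrix(cycles)

    def test_temporal_order_preserved(self):
        a = CycleEnvelope(np.zeros((2, 200)))
        b = CycleEnvelope(np.ones((2, 200)))
        E = assemble_matrix([a, b])
        assert E[:, :200].sum() == 0 and E[:, 200:].sum() == 400
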