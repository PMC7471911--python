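"""Spectral analysis, filtering, normalization and envelopes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import reamsim as rs
from reamsim.records import SAMPLE_DT


def _record(force, torque=None, kind="dynamic1", feed=0.03):
    t = np.arange(len(force)) * SAMPLE_DT
    torque = np.zeros_like(t) if torque is None else torque
    return rs.ReamingRecord("x", kind, feed, 52.0, t, feed * t, force, torque)


class TestComputeSpectrum:
    def test_single_tone_peak(self, sine_recording):
        report = rs.compute_spectrum(sine_recording, "force")
        peak = report.frequencies[1:][np.argmax(report.amplitudes[1:])]
        assert peak == pytest.approx(2.0, abs=report.frequencies[1])

    def test_cutoff_lands_between_separated_bands(self):
        # ramp + 0.5 Hz + 20 Hz tones: the cutoff must separate the bands
        t = np.arange(2000) * SAMPLE_DT
        force = 5.0 * t + 50 * np.sin(2 * np.pi * 0.5 * t) + 50 * np.sin(2 * np.pi * 20.0 * t)
        report = rs.compute_spectrum(_record(force), "force")
        assert 0.5 < report.chosen_cutoff < 20.0
        # verify band energies with a direct DFT: both tones are dominant bins
        amp = np.abs(np.fft.rfft(force - np.polyval(np.polyfit(t, force, 1), t)))
        freqs = np.fft.rfftfreq(len(t), SAMPLE_DT)
        top2 = freqs[np.argsort(amp)[-2:]]
        assert set(np.round(top2, 1)) == {0.5, 20.0}

    def test_constant_signal_degenerates_to_floor(self):
        report = rs.compute_spectrum(_record(np.full(2000, 80.0)), "force")
        assert report.chosen_cutoff == pytest.approx(1.0)

    def test_static_torque_rejected(self):
        t = np.arange(100) * SAMPLE_DT
        rec = rs.ReamingRecord("s", "static", 0.07, 52.0, t, 0.07 * t,
                               np.linspace(20, 120, 100), np.zeros(100))
        with pytest.raises(rs.ParameterError):
            rs.compute_spectrum(rec, "torque")

    def test_cutoff_strictly_inside_nyquist(self, short_dynamic_recording):
        report = rs.compute_spectrum(short_dynamic_recording, "force")
        assert 0.0 < report.chosen_cutoff < 50.0


class TestLowpassFilter:
    def test_constant_force_unchanged(self):
        rec = _record(np.full(2000, 100.0))
        out = rs.lowpass_filter(rec, 5.0)
        assert np.max(np.abs(out.force - 100.0)) < 1e-9

    def test_stopband_attenuation(self):
        t = np.arange(2000) * SAMPLE_DT
        rec = _record(np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 30.0 * t))
        out = rs.lowpass_filter(rec, 5.0)
        spectrum = np.abs(np.fft.rfft(out.force)) / (len(t) / 2)
        bin30 = int(round(30.0 * len(t) * SAMPLE_DT))
        bin1 = int(round(1.0 * len(t) * SAMPLE_DT))
        assert spectrum[bin30] < 0.05  # 30 Hz residual < 5% of unit input
        assert spectrum[bin1] == pytest.approx(1.0, abs=0.02)  # passband intact

    def test_double_filtering_bounded_by_first_pass_residual(self):
        t = np.arange(4000) * SAMPLE_DT
        rec = _record(200.0 + np.sin(2 * np.pi * 30.0 * t) * 10)
        once = rs.lowpass_filter(rec, 5.0)
        twice = rs.lowpass_filter(once, 5.0)
        first_residual = np.max(np.abs(once.force - 200.0))
        assert np.max(np.abs(twice.force - once.force)) <= first_residual + 1e-9

    def test_displacement_and_time_untouched(self, short_dynamic_recording):
        out = rs.lowpass_filter(short_dynamic_recording, 5.0)
        assert out.displacement is short_dynamic_recording.displacement or \
            np.array_equal(out.displacement, short_dynamic_recording.displacement)
        assert np.array_equal(out.time, short_dynamic_recording.time)
        assert len(out) == len(short_dynamic_recording)

    @pytest.mark.parametrize("cutoff", [0.0, -1.0, 50.0, 80.0])
    def test_cutoff_out_of_range(self, short_dynamic_recording, cutoff):
        with pytest.raises(rs.ParameterError):
            rs.lowpass_filter(short_dynamic_recording, cutoff)

    def test_static_recording_bypasses_filtering(self):
        profile = rs.static_profile(max_depth=5.0, seed=1)
        rec = rs.generate_recording(profile)
        out, spectrum = rs.filter_recording(rec)
        assert spectrum is None
        np.testing.assert_array_equal(out.force, rec.force)


class TestNormalizeCurve:
    def test_domain_is_unit_interval(self, short_dynamic_recording):
        curve = rs.normalize_curve(short_dynamic_recording, "force")
        assert curve.normalized_displacement[0] == 0.0
        assert curve.normalized_displacement[-1] == 1.0

    def test_duplicate_displacements_averaged(self):
        t = np.arange(4) * SAMPLE_DT
        disp = np.array([0.0, 1.0, 1.0, 2.0])
        force = np.array([0.0, 10.0, 20.0, 30.0])
        rec = rs.ReamingRecord("x", "dynamic1", 0.01, 52.0, t, disp, force,
                               np.zeros(4))
        curve = rs.normalize_curve(rec, "force")
        assert len(curve.value) == 3
        assert curve.value[1] == pytest.approx(15.0)

    def test_output_not_longer_than_input(self, short_dynamic_recording):
        curve = rs.normalize_curve(short_dynamic_recording, "force")
        assert len(curve.value) <= len(short_dynamic_recording)

    def test_scale_equivariance(self, short_dynamic_recording):
        curve = rs.normalize_curve(short_dynamic_recording, "force")
        doubled = rs.ReamingRecord(
            short_dynamic_recording.sample_id, short_dynamic_recording.test_kind,
            short_dynamic_recording.feed_rate, short_dynamic_recording.reamer_diameter,
            short_dynamic_recording.time, 2.0 * short_dynamic_recording.displacement,
            short_dynamic_recording.force, short_dynamic_recording.torque)
        curve2 = rs.normalize_curve(doubled, "force")
        np.testing.assert_array_equal(curve.normalized_displacement,
                                      curve2.normalized_displacement)
        np.testing.assert_array_equal(curve.value, curve2.value)

    def test_zero_displacement_rejected(self):
        t = np.arange(10) * SAMPLE_DT
        rec = rs.ReamingRecord("x", "dynamic1", 0.01, 52.0, t, np.zeros(10),
                               np.ones(10), np.zeros(10))
        with pytest.raises(rs.ValidationError):
            rs.normalize_curve(rec, "force")


def _constant_curve(level, n=50, source="c"):
    return rs.MaterialCurve(np.linspace(0, 1, n), np.full(n, float(level)),
                            "force", source)


class TestEnvelopes:
    def test_singleton(self):
        c = _constant_curve(100.0)
        env = rs.compute_envelopes([c], grid_size=64)
        np.testing.assert_allclose(env.maximum, env.minimum)
        np.testing.assert_allclose(env.average, 100.0)

    def test_two_constant_curves(self):
        env = rs.compute_envelopes([_constant_curve(100), _constant_curve(300)],
                                   grid_size=32)
        np.testing.assert_allclose(env.maximum, 300.0)
        np.testing.assert_allclose(env.average, 200.0)
        np.testing.assert_allclose(env.minimum, 100.0)

    def test_permutation_invariance(self, short_dynamic_recording):
        curves = [rs.normalize_curve(short_dynamic_recording, "force"),
                  _constant_curve(50), _constant_curve(400)]
        a = rs.compute_envelopes(curves, 128)
        b = rs.compute_envelopes(curves[::-1], 128)
        np.testing.assert_array_equal(a.maximum, b.maximum)
        np.testing.assert_array_equal(a.minimum, b.minimum)
        # the mean is permutation-invariant up to float summation order
        np.testing.assert_allclose(a.average, b.average, rtol=1e-12)

    def test_empty_and_mixed_channel_rejected(self):
        with pytest.raises(rs.ParameterError):
            rs.compute_envelopes([])
        torque_curve = rs.MaterialCurve(np.linspace(0, 1, 8), np.ones(8),
                                        "torque", "t")
        with pytest.raises(rs.ParameterError):
            rs.compute_envelopes([_constant_curve(1), torque_curve])

    @given(st.lists(st.integers(0, 2 ** 31 - 1), min_size=1, max_size=5),
           st.integers(8, 64))
    def test_ordering_invariant_random_curves(self, seeds, grid_size):
        curves = []
        for s in seeds:
            rng = np.random.default_rng(s)
            n = rng.integers(4, 40)
            curves.append(rs.MaterialCurve(np.linspace(0, 1, n),
                                           rng.normal(100, 50, n), "force", str(s)))
        env = rs.compute_envelopes(curves, grid_size)
        assert np.all(env.minimum <= env.average + 1e-12)
        assert np.all(env.average <= env.maximum + 1e-12)
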