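import numpy as np
import pytest
from conftest import fit_sinusoid, make_tone
from csfdyn.datatypes import ICPTrace
from csfdyn.synthetic import ScenarioParams, gen_icp_trace
from csfdyn.waveform import (MeanWaveAmplitude, WaveformConfig,
                             antialias_downsample, bandpass_tukey,
                             baseline_icp, instantaneous_p2p,
                             mean_wave_amplitude, remove_artifacts)


class TestRemoveArtifacts:
    def test_clean_trace_untouched(self, clean_trace):
        out = remove_artifacts(clean_trace)
        assert out.mask.sum() == 0
        np.testing.assert_array_equal(out.pressure, clean_trace.pressure)

    def test_single_out_of_range_sample_interpolated(self):
        tr = make_tone(1.3, amp=1.0, duration=5.0, offset=4.0)
        p = tr.pressure.copy()
        p[2500] = 500.0
        tr = tr.with_pressure(p)
        out = remove_artifacts(tr)
        assert out.mask[2500]
        expected = 0.5 * (p[2499] + p[2501])
        assert out.pressure[2500] == pytest.approx(expected, abs=1e-9)

    def test_in_range_spike_caught_by_zscore(self):
        tr = make_tone(1.3, amp=1.0, duration=10.0, offset=4.0)
        p = tr.pressure.copy()
        p[5000] += 50.0  # 54-ish mmHg: inside physio range
        out = remove_artifacts(tr.with_pressure(p))
        assert out.mask[5000]
        assert abs(out.pressure[5000] - tr.pressure[5000]) < 0.05

    def test_nonfinite_masked(self):
        tr = make_tone(1.3, duration=5.0, offset=4.0)
        p = tr.pressure.copy()
        p[100] = np.nan
        out = remove_artifacts(ICPTrace(tr.time, p, tr.sampling_rate,
                                        mask=np.isnan(p)))
        assert out.mask[100] and np.isfinite(out.pressure).all()

    def test_unusable_recording_rejected(self):
        rng = np.random.default_rng(0)
        t = np.arange(2000) / 1000.0
        p = np.where(rng.random(2000) < 0.5, 500.0, 4.0)
        with pytest.raises(ValueError, match="unusable"):
            remove_artifacts(ICPTrace(t, p, 1000.0))


class TestAntialiasDownsample:
    def test_inband_amplitude_preserved(self):
        tr = make_tone(3.0, amp=1.0, duration=30.0)
        out = antialias_downsample(tr, 100.0)
        assert out.sampling_rate == 100.0
        inner = (out.time > 2) & (out.time < 28)
        amp, _ = fit_sinusoid(out.time[inner], out.pressure[inner], 3.0)
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_stopband_rejection(self):
        tr = make_tone(200.0, amp=1.0, duration=10.0)
        out = antialias_downsample(tr, 100.0)
        assert np.sqrt(np.mean(out.pressure**2)) < 0.01 * np.sqrt(np.mean(tr.pressure**2))

    def test_dc_preserved(self):
        t = np.arange(5000) / 1000.0
        tr = ICPTrace(t, np.full(5000, 4.33), 1000.0)
        out = antialias_downsample(tr, 100.0)
        np.testing.assert_allclose(out.pressure, 4.33, rtol=1e-9)

    def test_non_integer_factor_rejected(self):
        tr = make_tone(3.0, fs=250.0, duration=10.0)
        with pytest.raises(ValueError, match="integer"):
            antialias_downsample(tr, 100.0)


class TestBandpassTukey:
    def test_composite_signal_separation(self):
        fs, dur = 100.0, 60.0
        t = np.arange(int(fs * dur)) / fs
        x = 4.0 + 1.0 * np.sin(2 * np.pi * 1.3 * t) + 0.06 * np.sin(2 * np.pi * 3.5 * t)
        out = bandpass_tukey(ICPTrace(t, x, fs))
        inner = (t > 2) & (t < dur - 2)
        amp35, dc = fit_sinusoid(t[inner], out.pressure[inner], 3.5)
        amp13, _ = fit_sinusoid(t[inner], out.pressure[inner], 1.3)
        assert amp35 == pytest.approx(0.06, rel=0.02)
        assert abs(dc) < 4.0 / 40
        assert amp13 < 1.0 / 40

    def test_passband_identity(self):
        tr = make_tone(3.0, fs=100.0, duration=60.0, offset=2.0)
        out = bandpass_tukey(tr)
        inner = (tr.time > 2) & (tr.time < 58)
        expected = tr.pressure[inner] - 2.0
        err = np.abs(out.pressure[inner] - expected)
        assert err.max() < 0.01

    def test_stopband_rejection(self):
        tr = make_tone(0.2, fs=100.0, duration=60.0)
        out = bandpass_tukey(tr)
        assert (np.sqrt(np.mean(out.pressure**2))
                < 0.02 * np.sqrt(np.mean(tr.pressure**2)))

    def test_output_zero_mean(self):
        tr = make_tone(3.0, fs=100.0, duration=30.0, offset=7.0)
        out = bandpass_tukey(tr)
        assert abs(out.pressure.mean()) < 1e-10

    def test_too_short_rejected(self):
        tr = make_tone(3.0, fs=100.0, duration=2.0)
        with pytest.raises(ValueError, match="short"):
            bandpass_tukey(tr)


class TestInstantaneousP2P:
    def test_pure_tone_envelope(self):
        tr = make_tone(3.5, amp=0.07, fs=100.0, duration=30.0)
        _, p2p = instantaneous_p2p(tr, "envelope")
        np.testing.assert_allclose(p2p, 0.14, rtol=0.01)

    def test_am_tone_tracks_modulation(self):
        fs, dur = 100.0, 60.0
        t = np.arange(int(fs * dur)) / fs
        x = 0.05 * (1 + 0.5 * np.sin(2 * np.pi * 0.1 * t)) * np.sin(2 * np.pi * 4.0 * t)
        times, p2p = instantaneous_p2p(ICPTrace(t, x, fs), "envelope")
        expected = 0.10 * (1 + 0.5 * np.sin(2 * np.pi * 0.1 * times))
        assert np.max(np.abs(p2p - expected) / expected) < 0.05

    def test_cycle_method_agrees_with_envelope(self, clean_params):
        tr = gen_icp_trace(clean_params, duration=60.0)
        band = bandpass_tukey(antialias_downsample(remove_artifacts(tr), 100.0))
        _, env = instantaneous_p2p(band, "envelope")
        _, cyc = instantaneous_p2p(band, "cycle")
        assert env.mean() == pytest.approx(cyc.mean(), rel=0.05)

    def test_empty_retained_region_rejected(self):
        tr = make_tone(3.5, fs=100.0, duration=3.0)
        with pytest.raises(ValueError, match="retained"):
            instantaneous_p2p(tr, "envelope", edge_trim=2.0)


class TestMeanWaveAmplitude:
    def test_recovers_cardiac_p2p(self, clean_trace):
        m = mean_wave_amplitude(clean_trace)
        assert m.mwa == pytest.approx(0.12, rel=0.05)
        assert m.mwa == pytest.approx(float(m.p2p_series.mean()), abs=1e-12)

    def test_no_cardiac_component(self, clean_params):
        from dataclasses import replace
        tr = gen_icp_trace(replace(clean_params, cardiac_amp=0.0), duration=60.0)
        assert mean_wave_amplitude(tr).mwa < 0.005

    def test_linearity_in_cardiac_amplitude(self, clean_params):
        from dataclasses import replace
        m1 = mean_wave_amplitude(gen_icp_trace(clean_params, duration=120.0))
        m2 = mean_wave_amplitude(
            gen_icp_trace(replace(clean_params, cardiac_amp=0.12), duration=120.0))
        assert m2.mwa == pytest.approx(2 * m1.mwa, rel=0.02)

    def test_pressure_scaling_scales_mwa(self, clean_params):
        tr = gen_icp_trace(clean_params, duration=60.0)
        m1 = mean_wave_amplitude(tr)
        m2 = mean_wave_amplitude(tr.with_pressure(2.5 * tr.pressure))
        assert m2.mwa == pytest.approx(2.5 * m1.mwa, rel=1e-6)

    def test_dc_offset_invariance_exact(self, clean_params):
        tr = gen_icp_trace(clean_params, duration=60.0)
        m1 = mean_wave_amplitude(tr)
        m2 = mean_wave_amplitude(tr.with_pressure(tr.pressure + 3.0))
        assert m2.mwa == pytest.approx(m1.mwa, rel=1e-12)

    def test_out_of_band_component_barely_moves_mwa(self, clean_params):
        tr = gen_icp_trace(clean_params, duration=120.0)
        m1 = mean_wave_amplitude(tr)
        extra = (1.0 * np.sin(2 * np.pi * 0.8 * tr.time)
                 + 1.0 * np.sin(2 * np.pi * 8.0 * tr.time))
        m2 = mean_wave_amplitude(tr.with_pressure(tr.pressure + extra))
        assert abs(m2.mwa - m1.mwa) / m1.mwa < 0.05

    def test_estimator_protocol(self, clean_trace):
        est = MeanWaveAmplitude(band_low=1.6, band_high=5.5)
        assert est.get_params()["band_low"] == 1.6
        est.set_params(p2p_method="cycle").fit(clean_trace)
        assert est.mwa_ == pytest.approx(0.12, rel=0.05)


class TestBaselineICP:
    def test_constant_trace(self):
        t = np.arange(0, 16 * 60, 1e-2)
        tr = ICPTrace(t, np.full(t.size, 4.33), 100.0)
        assert baseline_icp(tr, 15.0) == pytest.approx(4.33)

    def test_linear_ramp_closed_form(self):
        # 0 -> 10 mmHg over 30 min; mean of final 15 min is 7.5.
        t = np.arange(0, 30 * 60, 1e-2)
        tr = ICPTrace(t, 10.0 * t / (30 * 60), 100.0)
        assert baseline_icp(tr, 15.0) == pytest.approx(7.5, abs=2e-3)

    def test_generated_trace_oscillations_average_out(self):
        p = ScenarioParams(baseline_icp=3.51, icp_noise_sd=0.02, seed=4)
        tr = gen_icp_trace(p, duration=16 * 60.0, sampling_rate=250.0)
        assert baseline_icp(tr, 15.0) == pytest.approx(3.51, abs=0.05)

    def test_short_trace_rejected(self):
        tr = make_tone(1.3, duration=60.0, offset=4.0)
        with pytest.raises(ValueError, match="shorter"):
            baseline_icp(tr, 15.0)
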