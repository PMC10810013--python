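import numpy as np
import pytest

from conftest import fit_sinusoid
from csfdyn.datatypes import InfusionProtocol
from csfdyn.flow import flow_rate, normalize_series
from csfdyn.resistance import estimate_rout
from csfdyn.secretion import estimate_secretion
from csfdyn.stats import unpaired_t
from csfdyn.synthetic import (SCENARIOS, ScenarioParams, gen_cohort,
                              gen_dilution_series, gen_flow_series,
                              gen_icp_trace, gen_infusion_experiment)
from csfdyn.waveform import mean_wave_amplitude


class TestGenICPTrace:
    def test_component_amplitudes_recoverable(self):
        p = ScenarioParams(vent_amp=0.8, cardiac_amp=0.07, cardiac_freq=3.6,
                           icp_noise_sd=0.0, seed=1)
        tr = gen_icp_trace(p, duration=60.0)
        amp_v, _ = fit_sinusoid(tr.time, tr.pressure, 1.3)
        amp_c, _ = fit_sinusoid(tr.time, tr.pressure, 3.6)
        assert amp_v == pytest.approx(0.8, abs=1e-6)
        assert amp_c == pytest.approx(0.07, abs=1e-6)

    def test_seed_determinism(self):
        p = ScenarioParams(icp_noise_sd=0.05, spike_rate=0.1, seed=42)
        a = gen_icp_trace(p, duration=5.0)
        b = gen_icp_trace(p, duration=5.0)
        np.testing.assert_array_equal(a.pressure, b.pressure)

    def test_downstream_mwa_matches_truth(self):
        p = ScenarioParams(cardiac_amp=0.07, cardiac_freq=4.0, icp_noise_sd=0.0)
        tr = gen_icp_trace(p, duration=120.0)
        assert mean_wave_amplitude(tr).mwa == pytest.approx(0.14, rel=0.05)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError, match="cardiac"):
            ScenarioParams(cardiac_freq=10.0)


class TestGenDilutionSeries:
    def test_noise_free_identity(self):
        s = gen_dilution_series(4.0, cv=0.0, ramp_tau=0.0)
        assert estimate_secretion(s).vp == pytest.approx(4.0, abs=1e-9)

    def test_zero_secretion_means_no_dilution(self):
        s = gen_dilution_series(0.0, cv=0.0, ramp_tau=0.0, Ci=2.0)
        np.testing.assert_allclose(s.outflow_triplicates, 2.0)

    def test_seed_determinism(self):
        a = gen_dilution_series(4.0, cv=0.03, seed=3)
        b = gen_dilution_series(4.0, cv=0.03, seed=3)
        np.testing.assert_array_equal(a.outflow_triplicates, b.outflow_triplicates)

    def test_early_samples_under_read_dye(self):
        s = gen_dilution_series(4.0, cv=0.0, ramp_tau=8.0)
        co = s.outflow_triplicates.mean(axis=1)
        assert co[0] < co[-1]
        assert np.all(np.diff(co) >= 0)


class TestGenInfusionExperiment:
    def test_noise_free_recovery(self):
        params = ScenarioParams(icp_noise_sd=0.0, baseline_icp=4.0)
        tr = gen_infusion_experiment(0.6, params, tau=60.0, sampling_rate=50.0)
        assert estimate_rout(tr).rout == pytest.approx(0.6, rel=0.01)

    def test_zero_resistance_plateaus_at_baseline(self):
        params = ScenarioParams(icp_noise_sd=0.0, vent_amp=0.0, cardiac_amp=0.0,
                                baseline_icp=4.0)
        tr = gen_infusion_experiment(0.0, params, tau=60.0, sampling_rate=20.0)
        est = estimate_rout(tr)
        np.testing.assert_allclose(est.icp_f_per_rate, 4.0, atol=1e-9)

    def test_seed_determinism(self):
        params = ScenarioParams(icp_noise_sd=0.1)
        a = gen_infusion_experiment(0.5, params, seed=9, sampling_rate=20.0)
        b = gen_infusion_experiment(0.5, params, seed=9, sampling_rate=20.0)
        np.testing.assert_array_equal(a.pressure, b.pressure)


class TestGenFlowSeries:
    def test_exact_linear_recovery(self):
        s = gen_flow_series(0.13, noise_sd=0.0)
        assert flow_rate(normalize_series(s)).slope == pytest.approx(0.13, abs=1e-12)

    def test_flat(self):
        s = gen_flow_series(0.0, noise_sd=0.0)
        assert flow_rate(normalize_series(s)).slope == 0.0

    def test_seed_determinism(self):
        a = gen_flow_series(0.06, noise_sd=0.01, seed=5)
        b = gen_flow_series(0.06, noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestGenCohort:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            gen_cohort("sumo", 2)

    def test_truths_emitted_and_artifacts_render(self):
        animals = gen_cohort("lean", 2, seed=1, render_infusion=False)
        for a in animals:
            assert {"vp", "rout", "icp", "mwa", "flow_slope"} <= set(a.truths)
            assert a.icp_trace is not None and a.dilution is not None
            # every artifact satisfies its consumer's preconditions
            estimate_secretion(a.dilution)
            flow_rate(normalize_series(a.flow))

    def test_determinism(self):
        a = gen_cohort("obese", 2, seed=7, render_infusion=False)
        b = gen_cohort("obese", 2, seed=7, render_infusion=False)
        np.testing.assert_array_equal(a[0].icp_trace.pressure,
                                      b[0].icp_trace.pressure)
        assert a[1].truths == b[1].truths

    def test_scenarios_share_structure(self):
        assert set(SCENARIOS["lean"]) == set(SCENARIOS["obese_tt"])

    def test_flow_slope_groups_separable(self):
        # Small-scale power check: lean vs testosterone-treated truths
        # (0.06 vs 0.13 a.u./min) separate in most replicate cohorts.
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            lean = gen_cohort("lean", 5, seed=seed, render=False)
            tt = gen_cohort("obese_tt", 5, seed=1000 + seed, render=False)
            a = [x.truths["flow_slope"] for x in lean]
            b = [x.truths["flow_slope"] for x in tt]
            if unpaired_t(a, b).significant:
                hits += 1
        assert hits >= 0.7 * n_rep
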