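"""Synthetic generators for every input the pipeline consumes, with the
ground-truth parameters emitted alongside the data.

The generators emulate the study conditions of a ventilated-rodent CSF
physiology experiment:

* ICP traces at 1 kHz: baseline pressure + ~1.3 Hz ventilation component
  + cardiac component in the 2.5–5 Hz band + white sensor noise +
  optional spike artifacts and slow drift;
* dye-dilution outflow series on a 5-min grid: steady state
  ``Co* = ri·Ci/(ri + Vp)`` approached through an exponential
  equilibration ramp, triplicates carrying multiplicative noise;
* stepped-infusion pressure responses: first-order approach to
  ``Rout·I`` within each step, relaxation toward baseline in pauses;
* imaging intensity series: linear-in-time with additive noise;
* two-group cohorts whose per-animal truths are drawn from normal
  distributions parameterized by the published group summaries
  (SEM·√n converted to per-animal sd).

Every generator is deterministic given its seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .datatypes import DyeDilutionSeries, ICPTrace, InfusionProtocol, ROIIntensitySeries
from .morphometrics import AnimalRecord

__all__ = [
    "ScenarioParams",
    "AnimalData",
    "SCENARIOS",
    "gen_icp_trace",
    "gen_dilution_series",
    "gen_infusion_experiment",
    "gen_flow_series",
    "gen_cohort",
]


@dataclass
class ScenarioParams:
    """Ground-truth parameters for one synthetic animal."""

    group: str = "lean"
    true_vp: float = 4.22  # µl/min
    true_rout: float = 0.74  # mmHg·min/µl
    baseline_icp: float = 4.33  # mmHg
    cardiac_freq: float = 4.0  # Hz, physiological band [2.5, 5]
    cardiac_amp: float = 0.06  # mmHg (MWA truth = 2 × this)
    vent_freq: float = 1.3  # Hz, artificial ventilation
    vent_amp: float = 1.0  # mmHg
    flow_slope: float = 0.06  # a.u./min
    icp_noise_sd: float = 0.05  # mmHg, white
    dilution_cv: float = 0.03  # triplicate multiplicative CV
    flow_noise_sd: float = 0.01  # a.u. on the normalized scale
    spike_rate: float = 0.0  # spikes per second
    spike_amp: float = 50.0  # mmHg
    drift_amp: float = 0.0  # mmHg peak of a slow (1/duration Hz) drift
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2.5 <= self.cardiac_freq <= 5.0):
            raise ValueError("cardiac_freq must lie in the 2.5–5 Hz band")
        if not (1.0 <= self.vent_freq <= 1.6):
            raise ValueError("vent_freq must be near the 1.3 Hz ventilation rate")
        if self.cardiac_amp < 0 or self.vent_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.icp_noise_sd < 0 or self.dilution_cv < 0 or self.flow_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")


def gen_icp_trace(params: ScenarioParams, duration: float = 300.0,
                  sampling_rate: float = 1000.0,
                  seed: Optional[int] = None) -> ICPTrace:
    """Synthesize a raw ICP recording.

    ``pressure = baseline + vent_amp·sin(2π·vent_freq·t)
    + cardiac_amp·sin(2π·cardiac_freq·t + φ) + noise [+ spikes] [+ drift]``
    with φ drawn once per trace. The MWA ground truth of the clean signal
    is ``2 × cardiac_amp``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    phi = rng.uniform(0, 2 * np.pi)
    p = (params.baseline_icp
         + params.vent_amp * np.sin(2 * np.pi * params.vent_freq * t)
         + params.cardiac_amp * np.sin(2 * np.pi * params.cardiac_freq * t + phi))
    if params.drift_amp:
        p += params.drift_amp * np.sin(2 * np.pi * t / (2 * duration))
    if params.icp_noise_sd:
        p += rng.normal(0.0, params.icp_noise_sd, size=n)
    if params.spike_rate > 0:
        n_spikes = rng.poisson(params.spike_rate * duration)
        idx = rng.integers(0, n, size=n_spikes)
        p[idx] += params.spike_amp
    return ICPTrace(time=t, pressure=p, sampling_rate=sampling_rate,
                    label=f"synthetic/{params.group}")


def gen_dilution_series(true_vp: float, ri: float = 9.0, Ci: float = 1.0,
                        cv: float = 0.03, duration: float = 90.0,
                        ramp_tau: float = 8.0, seed: int = 0,
                        sample_interval: float = 5.0) -> DyeDilutionSeries:
    """Synthesize a ventriculo-cisternal dilution experiment.

    The steady-state outflow fluorescence is ``Co* = ri·Ci/(ri + Vp)``;
    each sample's expectation approaches it through an exponential
    equilibration ramp ``Co(t) = Co*·(1 − e^(−t/ramp_tau))`` (early samples
    under-read dye while the ventricular volume mixes). Triplicates are
    the expectation times ``(1 + ε)``, ε mean-zero normal with sd ``cv``,
    floored away from zero so readings stay positive.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if true_vp < 0 or ri <= 0 or Ci <= 0:
        raise ValueError("need true_vp >= 0, ri > 0, Ci > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(sample_interval, duration + 1e-9, sample_interval)
    co_star = ri * Ci / (ri + true_vp)
    if ramp_tau > 0:
        expectation = co_star * (1.0 - np.exp(-times / ramp_tau))
    else:
        expectation = np.full_like(times, co_star)
    trip = expectation[:, None] * (1.0 + rng.normal(0.0, cv, size=(times.size, 3))
                                   if cv > 0 else np.ones((times.size, 3)))
    trip = np.maximum(trip, 1e-9 * Ci)
    return DyeDilutionSeries(sample_times=times, outflow_triplicates=trip,
                             inflow_reference=Ci, infusion_rate=ri)


def gen_infusion_experiment(true_rout: float, params: ScenarioParams,
                            protocol: Optional[InfusionProtocol] = None,
                            tau: float = 60.0, seed: Optional[int] = None,
                            sampling_rate: float = 1000.0) -> ICPTrace:
    """Synthesize a stepped-infusion recording.

    The oscillatory baseline from :func:`gen_icp_trace` is superimposed on
    a first-order pressure response: within each step the offset relaxes
    toward ``Rout·I`` with time constant ``tau`` (seconds), and toward the
    baseline during pauses, continuously from step to step.
    """
    if true_rout < 0:
        raise ValueError("true_rout must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    protocol = protocol or InfusionProtocol()
    duration = protocol.total_duration
    trace = gen_icp_trace(params, duration=duration, sampling_rate=sampling_rate,
                          seed=seed)
    t = trace.time
    delta = np.zeros_like(t)
    # Piecewise-constant targets: Rout·I inside steps, 0 elsewhere.
    events = [(0.0, 0.0)]
    for rate, (start, end) in zip(protocol.rates, protocol.step_bounds()):
        events.append((start, true_rout * rate))
        events.append((end, 0.0))
    level = 0.0
    for (start, target), nxt in zip(events, events[1:] + [(t[-1] + 1.0 / sampling_rate, 0.0)]):
        seg = (t >= start) & (t < nxt[0])
        ts = t[seg] - start
        delta[seg] = target + (level - target) * np.exp(-ts / tau)
        level = target + (level - target) * np.exp(-(nxt[0] - start) / tau)
    return trace.with_pressure(trace.pressure + delta)


def gen_flow_series(flow_slope: float, n_frames: int = 11,
                    interval: float = 30.0, noise_sd: float = 0.0,
                    seed: int = 0, i0: float = 1.0) -> ROIIntensitySeries:
    """Synthesize a raw (un-normalized) ROI intensity series:
    ``I(t) = I0·(1 + flow_slope·t_min) + noise``."""
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * interval
    t_min = t / 60.0
    intensity = i0 * (1.0 + flow_slope * t_min)
    if noise_sd > 0:
        intensity = intensity + i0 * rng.normal(0.0, noise_sd, size=n_frames)
    return ROIIntensitySeries(frame_times=t, intensity=intensity, normalized=False)


# Published group summaries used as generator parameters (mean, SEM, n).
# Per-animal sd = SEM·√n. Rout and flow slope were measured only in the
# lean vs testosterone-treated comparison and dye-dilution Vp only in the
# lean vs obese comparison; the unmeasured cells are filled from the lean
# values (no group difference was claimed for them).
SCENARIOS: Dict[str, Dict[str, tuple]] = {
    "lean": {
        "weight": (236.0, 3.0, 16), "bmi": (0.47, 0.01, 16),
        "icp": (4.33, 0.42, 5), "mwa": (0.12, 0.04, 5),
        "vp": (4.22, 1.08, 6), "rout": (0.74, 0.09, 6),
        "flow_slope": (0.06, 0.01, 5),
        "brain_water": (78.1, 0.7, 4), "brain_weight": (1.88, 0.06, 4),
        "weight_gain": (8.0, 0.8, 16),
    },
    "obese": {
        "weight": (406.0, 9.0, 15), "bmi": (0.87, 0.02, 15),
        "icp": (3.51, 0.36, 5), "mwa": (0.14, 0.04, 5),
        "vp": (3.84, 0.89, 4), "rout": (0.74, 0.09, 6),
        "flow_slope": (0.06, 0.01, 5),
        "brain_water": (77.7, 0.3, 5), "brain_weight": (1.81, 0.02, 5),
        "weight_gain": (10.5, 0.8, 16),
    },
    "obese_tt": {
        "weight": (373.0, 5.0, 20), "bmi": (0.87, 0.02, 15),
        "icp": (3.46, 0.57, 5), "mwa": (0.13, 0.02, 5),
        "vp": (4.22, 1.08, 6), "rout": (0.47, 0.04, 6),
        "flow_slope": (0.13, 0.01, 5),
        "brain_water": (77.3, 0.1, 4), "brain_weight": (1.77, 0.02, 4),
        "weight_gain": (23.0, 1.2, 20),
    },
}

# Physiological floors keep drawn truths usable by the downstream stages
# (a negative secretion rate or amplitude is not a renderable animal).
_FLOORS = {"mwa": 0.01, "vp": 0.3, "rout": 0.05, "flow_slope": 0.005,
           "icp": 0.5, "weight": 50.0, "brain_weight": 0.5,
           "brain_water": 50.0, "bmi": 0.1, "weight_gain": 0.0}


@dataclass
class AnimalData:
    """One synthetic animal: morphometric record, ground truths, and the
    rendered raw inputs for every assay."""

    record: AnimalRecord
    truths: Dict[str, float]
    icp_trace: Optional[ICPTrace] = None
    dilution: Optional[DyeDilutionSeries] = None
    flow: Optional[ROIIntensitySeries] = None
    infusion_trace: Optional[ICPTrace] = None


def _draw_truths(scenario: str, rng: np.random.Generator) -> Dict[str, float]:
    table = SCENARIOS[scenario]
    truths = {}
    for key, (mean, sem_v, n) in table.items():
        sd = sem_v * np.sqrt(n)
        truths[key] = max(float(rng.normal(mean, sd)), _FLOORS[key])
    return truths


def gen_cohort(scenario: str, n_per_group: int = 5, seed: int = 0,
               render: bool = True, icp_duration: float = 300.0,
               icp_sampling_rate: float = 1000.0,
               infusion_sampling_rate: float = 100.0,
               render_infusion: bool = True) -> List[AnimalData]:
    """Generate a cohort of synthetic animals for one scenario.

    Per-animal ground truths are drawn from normal distributions whose
    means and SEM-implied sds come from the published group summaries
    (``SCENARIOS``); the raw inputs (ICP trace, dilution series, flow
    series, stepped-infusion trace) are then rendered from those truths.
    ``render=False`` returns truths and morphometric records only.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {sorted(SCENARIOS)}")
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    rng = np.random.default_rng(seed)
    animals: List[AnimalData] = []
    for i in range(n_per_group):
        truths = _draw_truths(scenario, rng)
        sub = int(rng.integers(0, 2**31 - 1))
        length = float(np.sqrt(truths["weight"] / truths["bmi"]))
        gain = truths["weight_gain"] / 100.0
        final = truths["weight"]
        start = final / (1.0 + gain)
        weekly = list(np.linspace(start, final, 5))
        wet = truths["brain_weight"]
        dry = wet * (1.0 - truths["brain_water"] / 100.0)
        record = AnimalRecord(id=f"{scenario}-{i + 1:02d}", group=scenario,
                              weekly_weights=weekly, naso_anal_length=length,
                              brain_wet=wet, brain_dry=dry)
        params = ScenarioParams(
            group=scenario, true_vp=truths["vp"], true_rout=truths["rout"],
            baseline_icp=truths["icp"],
            cardiac_freq=float(rng.uniform(2.5, 5.0)),
            cardiac_amp=truths["mwa"] / 2.0,
            flow_slope=truths["flow_slope"], seed=sub,
        )
        animal = AnimalData(record=record, truths=dict(truths))
        animal.truths["cardiac_freq"] = params.cardiac_freq
        if render:
            animal.icp_trace = gen_icp_trace(params, duration=icp_duration,
                                             sampling_rate=icp_sampling_rate,
                                             seed=sub)
            animal.dilution = gen_dilution_series(truths["vp"], seed=sub + 1)
            animal.flow = gen_flow_series(truths["flow_slope"],
                                          noise_sd=params.flow_noise_sd,
                                          seed=sub + 2)
            if render_infusion:
                animal.infusion_trace = gen_infusion_experiment(
                    truths["rout"], params, seed=sub + 3,
                    sampling_rate=infusion_sampling_rate)
        animals.append(animal)
    return animals
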