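"""Resistance to CSF outflow (Rout) from a stepped infusion test.

Artificial CSF is pumped into a lateral ventricle at increasing constant
rates while ICP is recorded. For each rate I the pressure settles to a
plateau ICPf; with a stable pre-infusion baseline ICPi the per-rate
resistance is

    Rout = (ICPf − ICPi) / I   [mmHg·min/µl]

and the reported Rout is the mean across the infusion rates. The
least-squares slope of ICPf against I (intercept free) is computed as a
built-in cross-check: on exactly linear pressure–flow data the two
estimators coincide.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import ICPTrace, InfusionProtocol
from .waveform import WaveformConfig, remove_artifacts

__all__ = ["RoutEstimate", "OutflowResistance", "rout_single",
           "plateau_icp", "estimate_rout"]


@dataclass
class RoutEstimate:
    icp_i: float  # mmHg, pre-infusion stable baseline
    icp_f_per_rate: np.ndarray  # mmHg, plateau per step
    rout_per_rate: np.ndarray  # mmHg·min/µl
    rout: float  # mean across rates
    rout_regression: float  # slope of icp_f vs rate
    plateau_window: float  # minutes
    rates: Tuple[float, ...]


def rout_single(icp_f: float, icp_i: float, rate: float) -> float:
    """Per-rate outflow resistance ``(ICPf − ICPi)/I`` in mmHg·min/µl."""
    if not rate > 0:
        raise ValueError("infusion rate must be positive")
    return (icp_f - icp_i) / rate


def plateau_icp(trace: ICPTrace, step_start: float, step_end: float,
                plateau_window: float = 2.0, cleaned: bool = False,
                config: Optional[WaveformConfig] = None) -> float:
    """Mean cleaned pressure over the final ``plateau_window`` minutes of a
    step spanning ``[step_start, step_end]`` seconds."""
    win = plateau_window * 60.0
    if win > step_end - step_start:
        raise ValueError(
            f"{plateau_window:g}-min plateau window longer than the "
            f"{(step_end - step_start) / 60.0:g}-min step"
        )
    slack = 1.5 / trace.sampling_rate
    if step_start < trace.time[0] - slack or step_end > trace.time[-1] + slack:
        raise ValueError(
            f"step [{step_start:g}, {step_end:g}] s outside trace span "
            f"[{trace.time[0]:g}, {trace.time[-1]:g}] s"
        )
    if not cleaned:
        trace = remove_artifacts(trace, config)
    # Half-open window so the sample at step_end (already in the pause)
    # never leaks into the plateau mean.
    sel = (trace.time >= step_end - win) & (trace.time < step_end)
    if not sel.any():
        raise ValueError("no samples inside the plateau window")
    return float(trace.pressure[sel].mean())


class OutflowResistance(BaseEstimator):
    """Outflow-resistance estimator over a full stepped-infusion recording
    (scikit-learn protocol).

    Step boundaries are derived from the protocol timing (baseline, step
    and pause durations), or supplied explicitly via ``step_bounds`` at
    fit time. Pauses between steps are excluded from every window: the
    pressure is relaxing there, not stable.

    Parameters
    ----------
    rates, step_duration, pause, baseline_duration :
        Protocol fields, see :class:`~csfdyn.datatypes.InfusionProtocol`.
    plateau_window : float
        Minutes at the end of each step averaged as the plateau (default 2).
    baseline_window : float
        Minutes at the end of the pre-infusion period averaged as ICPi
        (default 5).

    Attributes (after :meth:`fit`)
    ------------------------------
    icp_i_, icp_f_per_rate_, rout_per_rate_, rout_, rout_regression_
    """

    def __init__(self, rates: Sequence[float] = (5.0, 10.0, 15.0, 20.0),
                 step_duration: float = 10.0, pause: float = 1.0,
                 baseline_duration: float = 30.0,
                 plateau_window: float = 2.0, baseline_window: float = 5.0):
        self.rates = rates
        self.step_duration = step_duration
        self.pause = pause
        self.baseline_duration = baseline_duration
        self.plateau_window = plateau_window
        self.baseline_window = baseline_window

    def _protocol(self) -> InfusionProtocol:
        return InfusionProtocol(rates=tuple(self.rates),
                                step_duration=self.step_duration,
                                pause=self.pause,
                                baseline_duration=self.baseline_duration)

    def fit(self, trace: ICPTrace, y=None,
            step_bounds: Optional[List[Tuple[float, float]]] = None
            ) -> "OutflowResistance":
        protocol = self._protocol()
        bounds = step_bounds if step_bounds is not None else protocol.step_bounds()
        if len(bounds) != len(protocol.rates):
            raise ValueError("one (start, end) pair required per infusion rate")
        cleaned = remove_artifacts(trace)
        t0 = cleaned.time[0]
        base_end = t0 + protocol.baseline_duration * 60.0
        base_start = base_end - self.baseline_window * 60.0
        if base_start < t0 - 1e-9:
            raise ValueError("baseline window longer than the baseline period")
        sel = (cleaned.time >= base_start) & (cleaned.time < base_end)
        self.icp_i_ = float(cleaned.pressure[sel].mean())

        icp_f = []
        for rate, (start, end) in zip(protocol.rates, bounds):
            if end > cleaned.time[-1] + 1.5 / cleaned.sampling_rate:
                raise ValueError(
                    f"step at {rate:g} µl/min ([{start:g}, {end:g}] s) "
                    "missing from the trace"
                )
            icp_f.append(plateau_icp(cleaned, start, end,
                                     self.plateau_window, cleaned=True))
        self.icp_f_per_rate_ = np.asarray(icp_f)
        rates = np.asarray(protocol.rates)
        self.rout_per_rate_ = (self.icp_f_per_rate_ - self.icp_i_) / rates
        self.rout_ = float(self.rout_per_rate_.mean())
        slope, _ = np.polyfit(rates, self.icp_f_per_rate_, 1)
        self.rout_regression_ = float(slope)
        return self

    def estimate_(self) -> RoutEstimate:
        return RoutEstimate(
            icp_i=self.icp_i_, icp_f_per_rate=self.icp_f_per_rate_,
            rout_per_rate=self.rout_per_rate_, rout=self.rout_,
            rout_regression=self.rout_regression_,
            plateau_window=self.plateau_window,
            rates=tuple(self._protocol().rates),
        )


def estimate_rout(trace: ICPTrace,
                  protocol: Optional[InfusionProtocol] = None,
                  plateau_window: float = 2.0,
                  baseline_window: float = 5.0,
                  step_bounds: Optional[List[Tuple[float, float]]] = None
                  ) -> RoutEstimate:
    """Functional wrapper over :class:`OutflowResistance`."""
    protocol = protocol or InfusionProtocol()
    est = OutflowResistance(
        rates=protocol.rates, step_duration=protocol.step_duration,
        pause=protocol.pause, baseline_duration=protocol.baseline_duration,
        plateau_window=plateau_window, baseline_window=baseline_window,
    ).fit(trace, step_bounds=step_bounds)
    return est.estimate_()
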