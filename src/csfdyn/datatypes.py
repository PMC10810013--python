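"""Core containers for CSF-hydrodynamics data.

All containers are plain dataclasses over numpy arrays, validated on
construction. Pressure is in mmHg, time in seconds unless a field says
otherwise; fluorescence is in arbitrary units (a.u.).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "ICPTrace",
    "DyeDilutionSeries",
    "ROIIntensitySeries",
    "InfusionProtocol",
]


@dataclass
class ICPTrace:
    """A uniformly sampled intracranial-pressure recording.

    Parameters
    ----------
    time : ndarray
        Seconds from recording start, strictly increasing.
    pressure : ndarray
        Pressure in mmHg, same length as ``time``.
    sampling_rate : float
        Nominal sampling rate in Hz; the nominal spacing ``1/sampling_rate``
        must match the median observed spacing to within 1 part in 1e3.
    label : str
        Free-text description.
    mask : ndarray of bool, optional
        Per-sample artifact flag (True = sample identified as artifact).
        Initialized clear when omitted.
    """

    time: np.ndarray
    pressure: np.ndarray
    sampling_rate: float
    label: str = ""
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.time.ndim != 1 or self.pressure.ndim != 1:
            raise ValueError("time and pressure must be 1-D arrays")
        if self.time.size != self.pressure.size:
            raise ValueError(
                f"time ({self.time.size}) and pressure ({self.pressure.size}) "
                "must have equal length"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0))
                raise ValueError(f"time must be strictly increasing (index {bad + 1})")
            nominal = 1.0 / self.sampling_rate
            if abs(float(np.median(dt)) - nominal) > 1e-3 * nominal:
                raise ValueError(
                    "median sample spacing inconsistent with sampling_rate "
                    f"({np.median(dt):.6g} s vs nominal {nominal:.6g} s)"
                )
        if self.mask is None:
            self.mask = np.zeros(self.time.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.size != self.time.size:
                raise ValueError("mask length must match time length")
        if not np.all(np.isfinite(self.pressure[~self.mask])):
            raise ValueError("pressure must be finite wherever mask is clear")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        if len(self) < 2:
            return 0.0
        return float(self.time[-1] - self.time[0])

    def with_pressure(self, pressure: np.ndarray, mask: Optional[np.ndarray] = None) -> "ICPTrace":
        """Return a copy with replaced pressure (and optionally mask)."""
        return replace(self, pressure=np.asarray(pressure, dtype=float),
                       mask=self.mask.copy() if mask is None else mask)


@dataclass
class DyeDilutionSeries:
    """Timed outflow fluorescence triplicates from a ventriculo-cisternal
    perfusion, plus the inflow reference and infusion rate.

    ``sample_times`` are minutes from infusion start (nominally a 5-min
    grid); ``outflow_triplicates`` has shape (n_samples, 3) holding the
    three plate-reader replicates of each collected outflow sample (Co);
    ``inflow_reference`` is the inflow-solution fluorescence (Ci) and
    ``infusion_rate`` the pump rate ri in µl/min.
    """

    sample_times: np.ndarray
    outflow_triplicates: np.ndarray
    inflow_reference: float
    infusion_rate: float

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.outflow_triplicates = np.asarray(self.outflow_triplicates, dtype=float)
        if self.outflow_triplicates.ndim != 2 or self.outflow_triplicates.shape[1] != 3:
            raise ValueError("outflow_triplicates must have shape (n_samples, 3)")
        if self.sample_times.size != self.outflow_triplicates.shape[0]:
            raise ValueError("sample_times length must match triplicate rows")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        bad = np.where(~(self.outflow_triplicates > 0))[0]
        if bad.size:
            t = self.sample_times[bad[0]]
            raise ValueError(
                f"non-positive fluorescence in sample at t={t:g} min"
            )
        if not self.inflow_reference > 0:
            raise ValueError("inflow_reference must be positive")
        if not self.infusion_rate > 0:
            raise ValueError("infusion_rate must be positive")

    def __len__(self) -> int:
        return int(self.sample_times.size)


@dataclass
class ROIIntensitySeries:
    """Mean ROI grayscale intensity per imaging frame.

    ``frame_times`` are seconds on the acquisition grid (nominally 30 s);
    ``normalized`` records whether the series has been divided by its
    first-frame value.
    """

    frame_times: np.ndarray
    intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.frame_times.size != self.intensity.size:
            raise ValueError("frame_times and intensity must have equal length")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.normalized and self.intensity.size and self.intensity[0] != 1.0:
            raise ValueError("normalized series must start at exactly 1")

    def __len__(self) -> int:
        return int(self.frame_times.size)


@dataclass
class InfusionProtocol:
    """Stepped constant-rate infusion design.

    Defaults follow the standard rodent outflow-resistance protocol:
    30 min of baseline recording, then 10 min at each of 5, 10, 15 and
    20 µl/min with a 1-min pause between rate increases.
    """

    rates: tuple = (5.0, 10.0, 15.0, 20.0)
    step_duration: float = 10.0  # minutes
    pause: float = 1.0  # minutes
    baseline_duration: float = 30.0  # minutes

    def __post_init__(self) -> None:
        self.rates = tuple(float(r) for r in self.rates)
        if not self.rates:
            raise ValueError("protocol needs at least one infusion rate")
        if any(r <= 0 for r in self.rates):
            raise ValueError("infusion rates must be positive")
        if any(b <= a for a, b in zip(self.rates, self.rates[1:])):
            raise ValueError("infusion rates must be strictly increasing")
        if self.step_duration <= 0 or self.baseline_duration <= 0:
            raise ValueError("durations must be positive")
        if self.pause < 0:
            raise ValueError("pause must be non-negative")

    def step_bounds(self) -> list:
        """(start, end) of each infusion step, in seconds from recording start."""
        bounds = []
        t = self.baseline_duration * 60.0
        for _ in self.rates:
            bounds.append((t, t + self.step_duration * 60.0))
            t += (self.step_duration + self.pause) * 60.0
        return bounds

    @property
    def total_duration(self) -> float:
        """Full protocol span in seconds (final pause omitted)."""
        n = len(self.rates)
        mins = self.baseline_duration + n * self.step_duration + (n - 1) * self.pause
        return mins * 60.0
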