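"""CSF secretion rate from ventriculo-cisternal dye dilution.

Dye-laden artificial CSF is infused into a lateral ventricle at rate
``ri`` (µl/min) while fluid is collected at the cisterna magna. During
passage the impermeant dye is diluted by endogenously secreted CSF, so at
steady state the outflow fluorescence Co relates to the inflow reference
Ci by mass balance ``ri·Ci = (ri + Vp)·Co``, giving the secretion rate

    Vp = ri · (Ci − Co) / Co   [µl/min].

Each collected 5-min sample is read in triplicate on a plate reader; the
triplicates are averaged first (they are replicate readings of one
physical sample), Vp is computed per sample, and the estimate is the mean
± SEM over the samples inside the quantification window (by default the
final 30 min, past the mixing-volume equilibration ramp).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import DyeDilutionSeries

__all__ = ["SecretionEstimate", "SecretionRateEstimator",
           "vp_from_dilution", "estimate_secretion"]


@dataclass
class SecretionEstimate:
    vp_per_sample: np.ndarray  # µl/min, per collected sample in window
    vp: float  # µl/min, mean over window
    sem: float  # µl/min
    window: Tuple[float, float]  # minutes
    n_samples_used: int
    has_negative: bool  # any per-sample Vp < 0 (outflow above inflow)


def vp_from_dilution(ri: float, Ci: float, Co: float):
    """Secretion rate from one dilution reading: ``ri·(Ci − Co)/Co``.

    Negative results are permitted (outflow more concentrated than
    inflow reads as negative secretion); callers flag them.
    Accepts scalars or arrays for ``Co``.
    """
    if not ri > 0:
        raise ValueError("infusion rate ri must be positive")
    if not Ci > 0:
        raise ValueError("inflow fluorescence Ci must be positive")
    Co = np.asarray(Co, dtype=float)
    if np.any(Co <= 0):
        raise ValueError("outflow fluorescence Co must be positive")
    out = ri * (Ci - Co) / Co
    return float(out) if out.ndim == 0 else out


class SecretionRateEstimator(BaseEstimator):
    """Dye-dilution secretion-rate estimator (scikit-learn protocol).

    Parameters
    ----------
    window_minutes : float
        Length of the quantification window, anchored at the end of the
        recording (default 30 min).
    aggregate : {"fluorescence_first", "per_replicate"}
        Whether triplicates are averaged before applying the dilution
        equation (default; matches replicate readings of one sample) or
        each replicate is converted to a rate and the rates averaged
        (sensitivity check).

    Attributes (after :meth:`fit`)
    ------------------------------
    vp_ : float            Mean secretion rate in the window, µl/min.
    sem_ : float           Standard error over window samples.
    vp_per_sample_ : ndarray
    window_ : (start, end) minutes actually used.
    n_samples_used_ : int
    has_negative_ : bool   Any window sample implied negative secretion.
    """

    def __init__(self, window_minutes: float = 30.0,
                 aggregate: str = "fluorescence_first"):
        self.window_minutes = window_minutes
        self.aggregate = aggregate

    def fit(self, series: DyeDilutionSeries, y=None) -> "SecretionRateEstimator":
        if self.aggregate not in ("fluorescence_first", "per_replicate"):
            raise ValueError(f"unknown aggregate mode {self.aggregate!r}")
        t = series.sample_times
        span = float(t[-1] - t[0])
        if span < self.window_minutes - 1e-9:
            raise ValueError(
                f"series spans {span:g} min, shorter than the "
                f"{self.window_minutes:g}-min quantification window"
            )
        start = float(t[-1]) - self.window_minutes
        sel = t >= start - 1e-9
        if sel.sum() < 2:
            raise ValueError("fewer than 2 samples inside the window")
        trip = series.outflow_triplicates[sel]
        if self.aggregate == "fluorescence_first":
            co = trip.mean(axis=1)
            vp = vp_from_dilution(series.infusion_rate, series.inflow_reference, co)
        else:
            vp = vp_from_dilution(series.infusion_rate, series.inflow_reference,
                                  trip.ravel()).reshape(trip.shape).mean(axis=1)
        self.vp_per_sample_ = np.asarray(vp, dtype=float)
        self.vp_ = float(self.vp_per_sample_.mean())
        n = int(sel.sum())
        sd = float(self.vp_per_sample_.std(ddof=1)) if n > 1 else 0.0
        self.sem_ = sd / np.sqrt(n)
        self.window_ = (start, float(t[-1]))
        self.n_samples_used_ = n
        self.has_negative_ = bool(np.any(self.vp_per_sample_ < 0))
        return self

    def estimate_(self) -> SecretionEstimate:
        return SecretionEstimate(
            vp_per_sample=self.vp_per_sample_, vp=self.vp_, sem=self.sem_,
            window=self.window_, n_samples_used=self.n_samples_used_,
            has_negative=self.has_negative_,
        )


def estimate_secretion(series: DyeDilutionSeries,
                       window_minutes: float = 30.0,
                       aggregate: str = "fluorescence_first") -> SecretionEstimate:
    """Functional wrapper over :class:`SecretionRateEstimator`."""
    return SecretionRateEstimator(window_minutes, aggregate).fit(series).estimate_()
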