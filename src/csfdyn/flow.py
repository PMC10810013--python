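"""Relative CSF flow rate from ventricular dye imaging.

A near-infrared dye bolus is injected into a lateral ventricle and imaged
at 30-s intervals for 5 min; caudal CSF flow carries dye into a region of
interest placed in line with the lambda landmark. Each frame's mean ROI
intensity is normalized to the first frame, and the relative flow rate is
the ordinary least-squares slope of normalized intensity against time in
minutes (a.u./min). The measure is relative — it compares groups, it does
not yield µl/min.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import ROIIntensitySeries

__all__ = ["FlowRateEstimate", "FlowRateEstimator", "normalize_series", "flow_rate"]


@dataclass
class FlowRateEstimate:
    slope: float  # a.u./min
    intercept: float  # a.u.
    r_squared: float
    n_frames: int
    window: Tuple[float, float]  # minutes


def normalize_series(series: ROIIntensitySeries) -> ROIIntensitySeries:
    """Divide every intensity by the first-frame value.

    Rejects double normalization and non-positive first frames. The first
    value of the result is exactly 1.
    """
    if series.normalized:
        raise ValueError("series is already first-frame normalized")
    if len(series) == 0:
        raise ValueError("empty series")
    first = float(series.intensity[0])
    if first <= 0:
        raise ValueError(f"first-frame intensity {first:g} is not positive")
    out = series.intensity / first
    out[0] = 1.0  # exact by definition
    return ROIIntensitySeries(frame_times=series.frame_times.copy(),
                              intensity=out, normalized=True)


class FlowRateEstimator(BaseEstimator):
    """OLS flow-rate estimator over a normalized ROI intensity series
    (scikit-learn protocol).

    Parameters
    ----------
    window_minutes : (start, end)
        Regression window in minutes from the first frame (default the
        full 0–5 min acquisition).

    Attributes (after :meth:`fit`)
    ------------------------------
    slope_ : float       a.u./min.
    intercept_ : float
    r_squared_ : float   0 for a perfectly flat response.
    n_frames_ : int
    """

    def __init__(self, window_minutes: Tuple[float, float] = (0.0, 5.0)):
        self.window_minutes = window_minutes

    def fit(self, series: ROIIntensitySeries, y=None) -> "FlowRateEstimator":
        if not series.normalized:
            raise ValueError("series must be first-frame normalized; "
                             "call normalize_series first")
        start, end = self.window_minutes
        t_min = (series.frame_times - series.frame_times[0]) / 60.0
        sel = (t_min >= start - 1e-9) & (t_min <= end + 1e-9)
        if sel.sum() < 3:
            raise ValueError(
                f"{int(sel.sum())} frames inside window [{start:g}, {end:g}] "
                "min; need at least 3"
            )
        x = t_min[sel]
        yv = series.intensity[sel]
        if np.allclose(yv, yv[0]):
            # Flat response: slope 0, R^2 undefined -> reported as 0.
            self.slope_, self.intercept_, self.r_squared_ = 0.0, float(yv[0]), 0.0
        else:
            res = stats.linregress(x, yv)
            self.slope_ = float(res.slope)
            self.intercept_ = float(res.intercept)
            self.r_squared_ = float(res.rvalue ** 2)
        self.n_frames_ = int(sel.sum())
        self.window_ = (float(start), float(end))
        return self

    def estimate_(self) -> FlowRateEstimate:
        return FlowRateEstimate(slope=self.slope_, intercept=self.intercept_,
                                r_squared=self.r_squared_,
                                n_frames=self.n_frames_, window=self.window_)


def flow_rate(series: ROIIntensitySeries,
              window_minutes: Tuple[float, float] = (0.0, 5.0)) -> FlowRateEstimate:
    """Functional wrapper over :class:`FlowRateEstimator`."""
    return FlowRateEstimator(window_minutes).fit(series).estimate_()
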