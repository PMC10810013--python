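"""Scalar morphometric measures: rodent BMI, brain water percentage,
relative brain weight, and percentage weight gain."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["AnimalRecord", "bmi", "brain_water_pct",
           "relative_brain_weight", "pct_weight_gain"]


@dataclass
class AnimalRecord:
    """Per-animal morphometrics and group assignment."""

    id: str
    group: str
    weekly_weights: Sequence[float] = field(default_factory=list)  # g
    naso_anal_length: Optional[float] = None  # cm
    brain_wet: Optional[float] = None  # g
    brain_dry: Optional[float] = None  # g

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weekly_weights):
            raise ValueError("weekly weights must be positive")
        if self.brain_wet is not None and self.brain_dry is not None:
            if self.brain_dry > self.brain_wet:
                raise ValueError("dry brain weight exceeds wet weight")


def bmi(weight: float, length: float) -> float:
    """Rodent body mass index: weight (g) / naso-anal length (cm) squared."""
    if weight <= 0 or length <= 0:
        raise ValueError("weight and length must be positive")
    return weight / length**2


def brain_water_pct(wet: float, dry: float) -> float:
    """Brain water content as a percentage: 100·(wet − dry)/wet."""
    if wet <= 0:
        raise ValueError("wet weight must be positive")
    if dry < 0 or dry > wet:
        raise ValueError("need 0 <= dry <= wet")
    return 100.0 * (wet - dry) / wet


def relative_brain_weight(brain: float, body: float) -> float:
    """Brain weight relative to body weight, in g brain per kg body
    (numerically equal to mg brain per g body)."""
    if brain <= 0 or body <= 0:
        raise ValueError("brain and body weight must be positive")
    return 1000.0 * brain / body


def pct_weight_gain(weekly_weights: Sequence[float], window_weeks: int = 4) -> float:
    """Percentage weight gain over the final ``window_weeks`` weeks:
    100·(final − earlier)/earlier."""
    w = np.asarray(weekly_weights, dtype=float)
    if window_weeks < 1:
        raise ValueError("window_weeks must be at least 1")
    if w.size < window_weeks + 1:
        raise ValueError(
            f"need {window_weeks + 1} weekly entries, got {w.size}"
        )
    if not np.all(np.isfinite(w[-(window_weeks + 1):])):
        raise ValueError("missing entries inside the window")
    ref = w[-(window_weeks + 1)]
    return 100.0 * (w[-1] - ref) / ref
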