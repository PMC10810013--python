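"""End-to-end cohort analysis: run every applicable stage per animal,
then compare groups measure by measure (mean ± SEM, unpaired t-test) and
regress each measure against bodyweight."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .flow import flow_rate, normalize_series
from .morphometrics import bmi, brain_water_pct, pct_weight_gain, relative_brain_weight
from .resistance import estimate_rout
from .secretion import estimate_secretion
from .stats import GroupComparison, RegressionResult, simple_linreg, unpaired_t
from .synthetic import AnimalData
from .waveform import mean_wave_amplitude

__all__ = ["animal_measures", "cohort_table", "CohortReport", "compare_cohorts"]

#: Measures compared across groups when present.
MEASURES = ["bodyweight", "bmi", "baseline_icp", "mwa", "vp", "rout",
            "flow_slope", "brain_water", "relative_brain_weight", "weight_gain"]


def animal_measures(animal: AnimalData) -> Dict[str, float]:
    """Run each stage on one animal's raw inputs; morphometrics from the
    record. Stages whose input is absent are skipped."""
    rec = animal.record
    out: Dict[str, float] = {"id": rec.id, "group": rec.group}
    if rec.weekly_weights:
        out["bodyweight"] = float(rec.weekly_weights[-1])
        if len(rec.weekly_weights) >= 5:
            out["weight_gain"] = pct_weight_gain(rec.weekly_weights, 4)
        if rec.naso_anal_length:
            out["bmi"] = bmi(rec.weekly_weights[-1], rec.naso_anal_length)
    if rec.brain_wet is not None and rec.brain_dry is not None:
        out["brain_water"] = brain_water_pct(rec.brain_wet, rec.brain_dry)
        if rec.weekly_weights:
            out["relative_brain_weight"] = relative_brain_weight(
                rec.brain_wet, rec.weekly_weights[-1])
    if animal.icp_trace is not None:
        metrics = mean_wave_amplitude(animal.icp_trace)
        out["mwa"] = metrics.mwa
        out["baseline_icp"] = metrics.baseline_icp
    if animal.dilution is not None:
        out["vp"] = estimate_secretion(animal.dilution).vp
    if animal.flow is not None:
        out["flow_slope"] = flow_rate(normalize_series(animal.flow)).slope
    if animal.infusion_trace is not None:
        out["rout"] = estimate_rout(animal.infusion_trace).rout
    return out


def cohort_table(animals: List[AnimalData]) -> pd.DataFrame:
    """Per-animal derived measures as a DataFrame (one row per animal)."""
    return pd.DataFrame([animal_measures(a) for a in animals])


@dataclass
class CohortReport:
    """Group-comparison report over a two-group cohort table."""

    group_a: str
    group_b: str
    comparisons: Dict[str, GroupComparison] = field(default_factory=dict)
    regressions_vs_weight: Dict[str, RegressionResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for measure, c in self.comparisons.items():
            rows.append({"measure": measure,
                         f"mean_{self.group_a}": c.mean_a,
                         f"sem_{self.group_a}": c.sem_a,
                         f"mean_{self.group_b}": c.mean_b,
                         f"sem_{self.group_b}": c.sem_b,
                         "t": c.t_statistic, "df": c.df, "p": c.p_value,
                         "significant": c.significant})
        return pd.DataFrame(rows)


def compare_cohorts(table: pd.DataFrame, group_a: str, group_b: str,
                    alpha: float = 0.05) -> CohortReport:
    """Unpaired t-test per measure between two groups, plus a simple
    linear regression of each measure against bodyweight (pooled)."""
    for g in (group_a, group_b):
        if (table["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 animals")
    report = CohortReport(group_a=group_a, group_b=group_b)
    sub = table[table["group"].isin([group_a, group_b])]
    for measure in MEASURES:
        if measure not in table.columns:
            continue
        a = table.loc[table["group"] == group_a, measure].dropna().to_numpy()
        b = table.loc[table["group"] == group_b, measure].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        report.comparisons[measure] = unpaired_t(a, b, alpha=alpha)
        if measure != "bodyweight" and "bodyweight" in sub.columns:
            pooled = sub[["bodyweight", measure]].dropna()
            if len(pooled) >= 3 and pooled["bodyweight"].nunique() > 1:
                report.regressions_vs_weight[measure] = simple_linreg(
                    pooled["bodyweight"], pooled[measure])
    return report
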