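"""Glycemic and beta-cell indices from standard meal-test curves.

Glucose (mmol/L) and insulin (uU/mL) are sampled at 0, 10, 20, 30, 60,
90 and 120 min after a standard food load.  Derived indices:

* HOMA-beta = 20 * FINS / (FPG - 3.5)          (insulin secretion)
* HOMA-IR   = FPG * FINS / 22.5                (insulin resistance)
* Matsuda   = 10000 / sqrt(Glu0 * Ins0 * meanGlu * meanIns)
* ISSI-2    = (AUC_ins / AUC_glu) * Matsuda    (beta-cell function)

AUCs are trapezoidal over minutes divided by 60, i.e. value-units x
hours; mean glucose/insulin are unweighted arithmetic means of the seven
samples.  Delta values are percent change post vs pre.  Glycemic
remission at the one-year visit is FPG < 7 mmol/L AND HbA1c < 7%;
non-remission is FPG >= 7 OR HbA1c >= 7 (an exact partition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MEAL_TIMES = (0.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0)


class UndefinedIndexError(ValueError):
    """An index is undefined for these inputs (e.g. FPG at the HOMA pole)."""


@dataclass(frozen=True)
class MealTest:
    """One patient's glucose-insulin curves at one timepoint."""

    patient_id: str
    timepoint: str
    glucose: tuple[float, ...]
    insulin: tuple[float, ...]
    FPG: float
    HbA1c: float
    times: tuple[float, ...] = MEAL_TIMES

    def __post_init__(self) -> None:
        if len(self.glucose) != len(self.times) \
                or len(self.insulin) != len(self.times):
            raise ValueError(f"expected {len(self.times)} paired values")
        if any(g <= 0 for g in self.glucose) or any(v <= 0 for v in self.insulin):
            raise ValueError("glucose and insulin must be positive")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    @property
    def glu0(self) -> float:
        return self.glucose[0]

    @property
    def ins0(self) -> float:
        return self.insulin[0]

    @property
    def two_hour_glucose(self) -> float:
        return self.glucose[-1]


@dataclass(frozen=True)
class ClinicalIndices:
    patient_id: str
    timepoint: str
    FPG: float
    HbA1c: float
    two_hour_glucose: float
    HOMA_beta: float
    HOMA_IR: float
    Matsuda: float
    ISSI2: float
    AUC_glu: float
    AUC_ins: float
    AUC_ins_glu: float


def auc(times, values) -> float:
    """Trapezoidal area under the curve, in value-units x hours."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two points")
    if (np.diff(times) <= 0).any():
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(values, times) / 60.0)


def homa_beta(FPG: float, FINS: float) -> float:
    if FPG <= 3.5:
        raise UndefinedIndexError(
            f"HOMA-beta undefined for FPG <= 3.5 (got {FPG})")
    return 20.0 * FINS / (FPG - 3.5)


def homa_ir(FPG: float, FINS: float) -> float:
    if FPG <= 0 or FINS <= 0:
        raise ValueError("FPG and FINS must be positive")
    return FPG * FINS / 22.5


def matsuda(meal: MealTest) -> float:
    mean_glu = float(np.mean(meal.glucose))
    mean_ins = float(np.mean(meal.insulin))
    prod = meal.glu0 * meal.ins0 * mean_glu * mean_ins
    if prod <= 0:
        raise ValueError("all curve values must be positive")
    return 10_000.0 / math.sqrt(prod)


def issi2(meal: MealTest) -> float:
    a_glu = auc(meal.times, meal.glucose)
    a_ins = auc(meal.times, meal.insulin)
    if a_glu <= 0:
        raise ValueError("glucose AUC must be positive")
    return (a_ins / a_glu) * matsuda(meal)


def delta(pre_value: float, post_value: float) -> float:
    """Percent change after treatment: (post - pre) / pre * 100."""
    if pre_value == 0:
        raise UndefinedIndexError("delta undefined for pre value 0")
    return (post_value - pre_value) / pre_value * 100.0


def classify_remission(FPG: float, HbA1c: float) -> str:
    """'remission' iff FPG < 7 mmol/L AND HbA1c < 7%; else 'non_remission'."""
    if FPG is None or HbA1c is None \
            or not (np.isfinite(FPG) and np.isfinite(HbA1c)):
        raise ValueError("both FPG and HbA1c are required")
    return "remission" if (FPG < 7.0 and HbA1c < 7.0) else "non_remission"


def compute_indices(meal: MealTest) -> ClinicalIndices:
    a_glu = auc(meal.times, meal.glucose)
    a_ins = auc(meal.times, meal.insulin)
    return ClinicalIndices(
        patient_id=meal.patient_id,
        timepoint=meal.timepoint,
        FPG=meal.FPG,
        HbA1c=meal.HbA1c,
        two_hour_glucose=meal.two_hour_glucose,
        HOMA_beta=homa_beta(meal.FPG, meal.ins0),
        HOMA_IR=homa_ir(meal.FPG, meal.ins0),
        Matsuda=matsuda(meal),
        ISSI2=issi2(meal),
        AUC_glu=a_glu,
        AUC_ins=a_ins,
        AUC_ins_glu=a_ins / a_glu,
    )


INDEX_COLUMNS = ["FPG", "HbA1c", "two_hour_glucose", "HOMA_beta", "HOMA_IR",
                 "Matsuda", "ISSI2", "AUC_glu", "AUC_ins", "AUC_ins_glu"]


def indices_table(meals) -> pd.DataFrame:
    """One row of indices per patient x timepoint."""
    rows = [compute_indices(m).__dict__ for m in meals]
    return pd.DataFrame(rows, columns=["patient_id", "timepoint"] + INDEX_COLUMNS)


def delta_frame(indices: pd.DataFrame) -> pd.DataFrame:
    """Percent-change columns joining each patient's pre and post rows.

    Patients lacking either timepoint are dropped.
    """
    pre = indices[indices["timepoint"] == "pre"].set_index("patient_id")
    post = indices[indices["timepoint"] == "post"].set_index("patient_id")
    common = pre.index.intersection(post.index)
    out = pd.DataFrame(index=common)
    for col in INDEX_COLUMNS:
        out[f"d{col}"] = (post.loc[common, col] - pre.loc[common, col]) \
            / pre.loc[common, col] * 100.0
    return out.reset_index().rename(columns={"index": "patient_id"})
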