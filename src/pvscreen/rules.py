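"""Screening predicates: the WHO 2016 erythrocytosis criterion, the two-step
candidate-selection algorithm, and published comparator rules.

All comparisons are strict (>).  The cut-offs of the second step were derived
as midpoints between observed values, where > and >= coincide on development
data; strictness is therefore part of the algorithm contract and every
predicate here applies it.

Functions accept either a single record (mapping / pandas Series) or a whole
cohort DataFrame, returning a bool or a boolean array respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WHOCriterion",
    "StepTwoRule",
    "ScreeningAlgorithm",
    "RAW_STEP2",
    "ROUNDED_STEP2",
    "STAGES",
    "who_positive",
    "step2_positive",
    "classify",
    "round_thresholds",
    "comparator_rumi",
    "comparator_canadian",
]

#: Classification stages, in screening order.
STAGES = ("not_selected", "step1_only", "eligible_for_testing")


@dataclass(frozen=True)
class WHOCriterion:
    """Sex-specific WHO 2016 Hb/Htc thresholds (strict >)."""

    male_hb_gt: float = 16.5      # g/dL
    male_htc_gt: float = 49.0     # %
    female_hb_gt: float = 16.0    # g/dL
    female_htc_gt: float = 48.0   # %

    def __post_init__(self):
        if min(self.male_hb_gt, self.male_htc_gt,
               self.female_hb_gt, self.female_htc_gt) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class StepTwoRule:
    """Second-step myeloproliferation rule: neutrophils OR platelets above cut-off."""

    neutrophils_gt: float  # x10^9/L
    platelets_gt: float    # x10^9/L

    def __post_init__(self):
        if min(self.neutrophils_gt, self.platelets_gt) <= 0:
            raise ValueError("thresholds must be positive")


#: The derived (raw) and simplified (rounded) second-step rules.
RAW_STEP2 = StepTwoRule(neutrophils_gt=5.98, platelets_gt=248.5)
ROUNDED_STEP2 = StepTwoRule(neutrophils_gt=6.0, platelets_gt=250.0)


@dataclass(frozen=True)
class ScreeningAlgorithm:
    """The sequential two-step rule: WHO criterion, then the count rule."""

    step1: WHOCriterion = field(default_factory=WHOCriterion)
    step2: StepTwoRule = ROUNDED_STEP2


def _sex_masks(sex):
    sex = np.asarray(sex, dtype=object)
    male = sex == "male"
    female = sex == "female"
    bad = ~(male | female)
    if bad.any():
        raise ValueError(f"unknown sex value(s): {set(sex[bad])!r}")
    return male, female


def _scalarize(result, record):
    if isinstance(record, pd.DataFrame):
        return pd.Series(result, index=record.index)
    return bool(np.asarray(result).item())


def who_positive(record, criterion: WHOCriterion = WHOCriterion()):
    """True iff the sex-appropriate Hb OR Htc strict threshold is exceeded."""
    male, female = _sex_masks(record["sex"])
    hb = np.asarray(record["hb"], dtype=float)
    htc = np.asarray(record["htc"], dtype=float)
    pos = (male & ((hb > criterion.male_hb_gt) | (htc > criterion.male_htc_gt))) | (
        female & ((hb > criterion.female_hb_gt) | (htc > criterion.female_htc_gt)))
    return _scalarize(pos, record)


def step2_positive(record, rule: StepTwoRule = ROUNDED_STEP2):
    """True iff neutrophils OR platelets exceed the rule's strict cut-offs."""
    neut = np.asarray(record["neutrophils"], dtype=float)
    plt = np.asarray(record["platelets"], dtype=float)
    return _scalarize((neut > rule.neutrophils_gt) | (plt > rule.platelets_gt),
                      record)


def classify(record, algorithm: ScreeningAlgorithm = ScreeningAlgorithm()):
    """Assign each record its terminal screening stage.

    ``eligible_for_testing`` iff both steps pass; ``step1_only`` iff only the
    WHO criterion passes; ``not_selected`` otherwise.
    """
    s1 = np.asarray(who_positive(record, algorithm.step1))
    s2 = np.asarray(step2_positive(record, algorithm.step2))
    stage = np.where(s1 & s2, "eligible_for_testing",
                     np.where(s1, "step1_only", "not_selected"))
    if isinstance(record, pd.DataFrame):
        return pd.Series(stage, index=record.index, name="stage")
    return str(stage.item())


def _round_to_grid(x: float, grid: float) -> float:
    # half-up on the grid: 5.98 on a 0.5 grid -> 6.0, 248.5 on a 10 grid -> 250
    return math.floor(x / grid + 0.5) * grid


def round_thresholds(raw: StepTwoRule, neut_grid: float = 0.5,
                     plt_grid: float = 10.0) -> StepTwoRule:
    """Round each cut-off to the nearest multiple of its grid (ties up)."""
    if neut_grid <= 0 or plt_grid <= 0:
        raise ValueError("grids must be positive")
    return StepTwoRule(
        neutrophils_gt=_round_to_grid(raw.neutrophils_gt, neut_grid),
        platelets_gt=_round_to_grid(raw.platelets_gt, plt_grid),
    )


def comparator_rumi(record, male_hb_gt: float = 17.0, female_hb_gt: float = 16.0):
    """Raised-haemoglobin comparator: Hb > 17 g/dL in men.

    The source proposal raises only the male threshold; the female threshold
    is kept at the WHO value (documented assumption).
    """
    male, female = _sex_masks(record["sex"])
    hb = np.asarray(record["hb"], dtype=float)
    return _scalarize((male & (hb > male_hb_gt)) | (female & (hb > female_hb_gt)),
                      record)


def comparator_canadian(record, platelets_gt: float = 440.0,
                        neutrophils_gt: float = 7.0):
    """Signs-of-myeloproliferation comparator: platelets > 440 or neutrophils > 7."""
    plt = np.asarray(record["platelets"], dtype=float)
    neut = np.asarray(record["neutrophils"], dtype=float)
    return _scalarize((plt > platelets_gt) | (neut > neutrophils_gt), record)
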