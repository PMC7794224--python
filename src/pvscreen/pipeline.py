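"""Two-phase study orchestration.

Phase 1 derives the screening rule on a development cohort: apply the WHO
Hb/Htc criterion, drop samples unsuitable for DNA extraction, test the rest,
set aside carriers already known to have a myeloproliferative neoplasm, and
derive marker cut-offs on the tested stratum.  Phase 2 freezes the rule and
validates it on an independent cohort, reporting stage-by-stage flow counts
and screening-performance ratios (yield, PPV, NNT, workload).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from . import cutoffs as _cut
from . import stats as _ustats
from .cohort import CohortSpec, MARKERS, generate_cohort
from .rules import (ScreeningAlgorithm, StepTwoRule, WHOCriterion,
                    classify, comparator_canadian, comparator_rumi,
                    round_thresholds, step2_positive, who_positive)

__all__ = [
    "FlowCounts",
    "PerformanceReport",
    "Phase1Result",
    "Phase2Result",
    "DerivationImpossibleError",
    "run_phase1",
    "run_phase2",
    "run_study",
    "proportion",
    "nnt",
    "workload_fraction",
    "survey_prevalence",
]

log = logging.getLogger("pvscreen")


class DerivationImpossibleError(RuntimeError):
    """The development stratum contains no new carriers to derive cut-offs from."""


@dataclass(frozen=True)
class FlowCounts:
    """Stage-by-stage sample counts of one phase's flowchart."""

    total: int
    who_positive: int
    step2_positive: int | None  # None in phase 1 (no second step yet)
    dna_failures: int
    tested: int
    mutation_positive: int
    known_mpn_excluded: int
    new_positives: int

    def __post_init__(self):
        selected = self.who_positive if self.step2_positive is None else self.step2_positive
        assert self.tested == selected - self.dna_failures
        assert self.new_positives == self.mutation_positive - self.known_mpn_excluded

    def terminal_bins(self) -> dict[str, int]:
        """Every record's terminal fate; values sum to ``total`` exactly."""
        selected = self.who_positive if self.step2_positive is None else self.step2_positive
        bins = {
            "not_who_positive": self.total - self.who_positive,
            "who_only": self.who_positive - selected,
            "dna_failure": self.dna_failures,
            "tested_wild_type": self.tested - self.mutation_positive,
            "known_mpn": self.known_mpn_excluded,
            "new_positive": self.new_positives,
        }
        return bins


@dataclass(frozen=True)
class PerformanceReport:
    """Screening-performance ratios of a validation run (all as fractions)."""

    who_rate: float                  # WHO-positive / total
    step2_rate_of_total: float       # algorithm-fulfilling / total
    yield_of_tested: float           # new carriers / tested
    prevalence_in_who_stratum: float # new carriers / WHO-positive
    prevalence_in_total: float       # new carriers / total
    ppv: float                       # carriers / algorithm-fulfilling
    nnt: float                       # tested per new carrier
    workload_fraction: float         # algorithm-fulfilling / WHO-positive


@dataclass
class Phase1Result:
    flow: FlowCounts
    summaries: pd.DataFrame          # per-group descriptives on the tested stratum
    tests: dict[str, _ustats.TestResult]
    cutoffs: list[_cut.CutoffResult]
    raw_rule: StepTwoRule
    rounded_rule: StepTwoRule


@dataclass
class Phase2Result:
    flow: FlowCounts
    performance: PerformanceReport
    algorithm: ScreeningAlgorithm


# -------------------------------------------------------------- arithmetic

def proportion(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding, as printed in flowcharts."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def nnt(tested: int, new_positives: int) -> float:
    """Number needed to test: tested individuals per newly found carrier."""
    if new_positives < 1:
        raise ValueError("nnt needs at least one new positive")
    return tested / new_positives


def workload_fraction(step2_pos: int, who_pos: int) -> float:
    """Fraction of the WHO-positive stratum the second step retains for testing."""
    if who_pos <= 0:
        raise ValueError("who_pos must be positive")
    return step2_pos / who_pos


@dataclass(frozen=True)
class SurveyPrevalence:
    rate: float
    bound: str | None  # "< 1/n" when no new carrier remains after exclusions


def survey_prevalence(positives: int, n: int, exclusions: int = 0) -> SurveyPrevalence:
    """Prevalence from an unselected survey, excluding already-known cases.

    When every positive is excluded the point estimate is 0 and only the
    upper bound "< 1/n" can be stated.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    adjusted = positives - exclusions
    if adjusted < 0:
        raise ValueError("exclusions exceed positives")
    if adjusted == 0:
        return SurveyPrevalence(0.0, f"< 1/{n}")
    return SurveyPrevalence(adjusted / n, None)


# ------------------------------------------------------------------ phases

def run_phase1(cohort: pd.DataFrame, who: WHOCriterion = WHOCriterion(),
               alpha: float = 0.05,
               rule_markers: tuple[str, str] = ("neutrophils", "platelets"),
               neut_grid: float = 0.5, plt_grid: float = 10.0) -> Phase1Result:
    """Development phase: flow accounting plus cut-off derivation.

    The analysis set for the univariate battery and the ROC derivation is the
    tested stratum with known-MPN carriers excluded; positives are the newly
    detected carriers.  The final rule is built from ``rule_markers``
    (configuration: the published algorithm uses neutrophils and platelets).
    """
    s1 = who_positive(cohort, who)
    stratum = cohort[s1]
    tested = stratum[stratum["dna_ok"]]
    flow = FlowCounts(
        total=len(cohort),
        who_positive=int(s1.sum()),
        step2_positive=None,
        dna_failures=int((~stratum["dna_ok"]).sum()),
        tested=len(tested),
        mutation_positive=int(tested["jak2_positive"].sum()),
        known_mpn_excluded=int((tested["jak2_positive"] & tested["known_mpn"]).sum()),
        new_positives=int((tested["jak2_positive"] & ~tested["known_mpn"]).sum()),
    )
    log.info("phase1 flow: %s", flow.terminal_bins())
    analysis = tested[~tested["known_mpn"]]
    n_pos = int(analysis["jak2_positive"].sum())
    if n_pos == 0 or n_pos == len(analysis):
        raise DerivationImpossibleError(
            f"tested stratum has {n_pos} new carriers out of {len(analysis)}; "
            "cut-off derivation needs both classes")

    y = analysis["jak2_positive"].to_numpy(dtype=bool)
    tests: dict[str, _ustats.TestResult] = {}
    sex_table = np.array([
        [int((analysis["sex"][y] == "female").sum()),
         int((analysis["sex"][~y] == "female").sum())],
        [int((analysis["sex"][y] == "male").sum()),
         int((analysis["sex"][~y] == "male").sum())],
    ])
    if sex_table.min(axis=1).min() >= 0 and 0 not in sex_table.sum(axis=0) \
            and 0 not in sex_table.sum(axis=1):
        tests["sex"] = _ustats.chi_square_2x2(sex_table)
    # the t test (and a meaningful univariate screen) needs >= 2 per group
    battery_ok = n_pos >= 2 and len(analysis) - n_pos >= 2
    if battery_ok:
        for m in MARKERS:
            x = analysis[m].to_numpy(dtype=float)
            if m in _cut.NONPARAMETRIC_MARKERS:
                tests[m] = _ustats.mann_whitney_u(x[y], x[~y])
            else:
                tests[m] = _ustats.student_t(x[y], x[~y])

    summaries = _ustats.describe(analysis, group_by="jak2_positive")
    roc_markers = [m for m in MARKERS if m != "age"]
    results = _cut.derive_all(analysis, roc_markers, alpha=alpha) \
        if battery_ok else []

    # The rule markers always get an operating point: the final marker set is
    # fixed by configuration, not by the alpha screen.
    by_marker = {}
    for m in rule_markers:
        r = next((r for r in results if r.marker == m), None)
        if r is None or r.excluded_by_univariate:
            r = _cut.youden_optimal(_cut.roc_curve(
                analysis[m].to_numpy(dtype=float), y, "greater", marker=m))
        by_marker[m] = r
    raw = StepTwoRule(neutrophils_gt=by_marker[rule_markers[0]].optimal_threshold,
                      platelets_gt=by_marker[rule_markers[1]].optimal_threshold)
    rounded = round_thresholds(raw, neut_grid, plt_grid)
    log.info("phase1 rule: raw=%s rounded=%s", raw, rounded)
    return Phase1Result(flow, summaries, tests, results, raw, rounded)


def run_phase2(cohort: pd.DataFrame,
               algorithm: ScreeningAlgorithm) -> Phase2Result:
    """Validation phase: apply the frozen algorithm, count the flow, report
    screening performance.  Never re-derives thresholds."""
    s1 = who_positive(cohort, algorithm.step1)
    s2 = s1 & step2_positive(cohort, algorithm.step2)
    selected = cohort[s2]
    tested = selected[selected["dna_ok"]]
    flow = FlowCounts(
        total=len(cohort),
        who_positive=int(s1.sum()),
        step2_positive=int(s2.sum()),
        dna_failures=int((~selected["dna_ok"]).sum()),
        tested=len(tested),
        mutation_positive=int(tested["jak2_positive"].sum()),
        known_mpn_excluded=int((tested["jak2_positive"] & tested["known_mpn"]).sum()),
        new_positives=int((tested["jak2_positive"] & ~tested["known_mpn"]).sum()),
    )
    log.info("phase2 flow: %s", flow.terminal_bins())
    perf = PerformanceReport(
        who_rate=flow.who_positive / flow.total,
        step2_rate_of_total=flow.step2_positive / flow.total,
        yield_of_tested=(flow.new_positives / flow.tested) if flow.tested else 0.0,
        prevalence_in_who_stratum=(flow.new_positives / flow.who_positive)
        if flow.who_positive else 0.0,
        prevalence_in_total=flow.new_positives / flow.total,
        ppv=(flow.mutation_positive / flow.step2_positive)
        if flow.step2_positive else 0.0,
        nnt=nnt(flow.tested, flow.new_positives) if flow.new_positives else float("inf"),
        workload_fraction=workload_fraction(flow.step2_positive, flow.who_positive)
        if flow.who_positive else 0.0,
    )
    return Phase2Result(flow, perf, algorithm)


def comparator_performance(cohort: pd.DataFrame) -> dict[str, dict[str, int]]:
    """How the published comparator rules fare on a cohort: how many samples
    each selects and how many latent carriers it captures."""
    out = {}
    carriers = cohort["jak2_positive"].to_numpy(dtype=bool)
    for name, fn in (("rumi", comparator_rumi), ("canadian", comparator_canadian)):
        sel = np.asarray(fn(cohort), dtype=bool)
        out[name] = {
            "selected": int(sel.sum()),
            "carriers_captured": int((sel & carriers).sum()),
            "carriers_total": int(carriers.sum()),
        }
    return out


def run_study(spec: CohortSpec, seed_phase1: int, seed_phase2: int,
              who: WHOCriterion = WHOCriterion(), alpha: float = 0.05,
              use_rounded: bool = True) -> dict:
    """Full two-phase study on two independently seeded synthetic cohorts.

    Returns a JSON-serialisable report: both flowcharts, the derived raw and
    rounded rules, the validation performance, and comparator-rule counts.
    """
    if seed_phase1 == seed_phase2:
        raise ValueError("phase 1 and phase 2 cohorts must use distinct seeds")
    cohort1 = generate_cohort(spec, seed=seed_phase1)
    cohort2 = generate_cohort(spec, seed=seed_phase2)
    p1 = run_phase1(cohort1, who=who, alpha=alpha)
    rule = p1.rounded_rule if use_rounded else p1.raw_rule
    p2 = run_phase2(cohort2, ScreeningAlgorithm(step1=who, step2=rule))
    report = {
        "seeds": {"phase1": seed_phase1, "phase2": seed_phase2},
        "phase1": {
            "flow": p1.flow.__dict__,
            "who_rate_pct": proportion(p1.flow.who_positive, p1.flow.total),
            "prevalence_in_tested_pct": proportion(
                p1.flow.new_positives,
                p1.flow.tested - p1.flow.known_mpn_excluded),
            "cutoffs": [{k: (None if isinstance(v, float) and np.isnan(v) else v)
                         for k, v in _cut.results_frame([r]).iloc[0].items()}
                        for r in p1.cutoffs],
            "raw_rule": p1.raw_rule.__dict__,
            "rounded_rule": p1.rounded_rule.__dict__,
        },
        "phase2": {
            "algorithm": {"step1": p2.algorithm.step1.__dict__,
                          "step2": p2.algorithm.step2.__dict__},
            "flow": p2.flow.__dict__,
            "performance": p2.performance.__dict__,
            "who_rate_pct": proportion(p2.flow.who_positive, p2.flow.total),
            "step2_rate_pct": proportion(p2.flow.step2_positive, p2.flow.total),
            "yield_pct": proportion(p2.flow.new_positives, p2.flow.tested)
            if p2.flow.tested else None,
        },
        "comparators": comparator_performance(cohort2),
    }
    return report
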