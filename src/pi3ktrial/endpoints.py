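"""RECIST 1.1 endpoints for a single-arm solid-tumor trial.

Timepoint classification works on the sum of target-lesion diameters:
partial response is a ≥30% decrease from baseline, progression a ≥20% and
≥5 mm increase from nadir or any new lesion, complete response the
disappearance of all target lesions.  Best overall response requires a
confirmatory assessment at least 4 weeks (28 days) later for CR/PR; an
unconfirmed PR is downgraded to stable disease and flagged.

The protocol's primary endpoint is clinical benefit: confirmed CR,
confirmed PR, or stable disease lasting at least 4 months.  Four months is
read as four 28-day protocol cycles = 112 days.  The cohort clinical-benefit
rate keeps non-evaluable patients in the denominator (intent-to-treat) and
carries an exact Clopper–Pearson 95% interval.

PHQ-9 (depression, 0–27) and GAD-7 (anxiety, 0–21) questionnaire scores are
graded on fixed severity bands: 0–4 normal, 5–9 grade 1, 10–14 grade 2,
≥15 grade 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "TumorAssessment",
    "TimepointCategory",
    "TimepointResponse",
    "BorCategory",
    "BestOverallResponse",
    "Instrument",
    "NeuropsychGrade",
    "NeuropsychScore",
    "DEFAULT_CONFIRMATION_WINDOW_DAYS",
    "DEFAULT_MIN_SD_DAYS",
    "sum_of_diameters",
    "classify_timepoint",
    "classify_patient",
    "bor_from_assessments",
    "bor_table",
    "best_overall_response",
    "clinical_benefit",
    "cohort_cbr",
    "grade_neuropsych",
]

DEFAULT_CONFIRMATION_WINDOW_DAYS = 28
DEFAULT_MIN_SD_DAYS = 112  # 4 months = 4 x 28-day protocol cycles

PR_DECREASE_PCT = 30.0
PD_INCREASE_PCT = 20.0
PD_ABSOLUTE_MM = 5.0


@dataclass(frozen=True)
class TumorAssessment:
    """Target-lesion diameters (mm) at one timepoint; day 0 = enrollment."""

    patient_id: str
    day: int
    lesion_diameters_mm: tuple[float, ...]
    new_lesion: bool = False

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        if any(d < 0 for d in self.lesion_diameters_mm):
            raise ValueError("lesion diameters must be non-negative")


class TimepointCategory(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NE = "NE"


@dataclass(frozen=True)
class TimepointResponse:
    category: TimepointCategory
    sum_mm: float
    pct_change_from_baseline: float
    pct_change_from_nadir: float


class BorCategory(str, Enum):
    CR_CONFIRMED = "CR_confirmed"
    PR_CONFIRMED = "PR_confirmed"
    SD = "SD"
    PD = "PD"
    NE = "NE"


@dataclass(frozen=True)
class BestOverallResponse:
    category: BorCategory
    unconfirmed_pr_flag: bool = False
    sd_duration_days: int | None = None

    def __post_init__(self) -> None:
        if self.unconfirmed_pr_flag and self.category is not BorCategory.SD:
            raise ValueError("unconfirmed_pr_flag is only meaningful for SD")
        if (self.sd_duration_days is not None) != (self.category is BorCategory.SD):
            raise ValueError("sd_duration_days present iff category is SD")


class Instrument(str, Enum):
    PHQ9 = "PHQ9"
    GAD7 = "GAD7"


class NeuropsychGrade(str, Enum):
    NORMAL = "NORMAL"
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"


@dataclass(frozen=True)
class NeuropsychScore:
    instrument: Instrument
    score: int
    grade: NeuropsychGrade


def sum_of_diameters(assessment: TumorAssessment) -> float:
    if not assessment.lesion_diameters_mm:
        raise ValueError("assessment has no target lesions")
    return float(sum(assessment.lesion_diameters_mm))


def classify_timepoint(
    baseline_sum: float, nadir_sum: float, assessment: TumorAssessment
) -> TimepointResponse:
    """Classify one tumor assessment against baseline and nadir sums.

    Precedence: progression (new lesion, or ≥20% and ≥5 mm above nadir),
    then complete response (all diameters zero), then partial response
    (≥30% below baseline), else stable disease.
    """
    if baseline_sum <= 0:
        raise ValueError(f"baseline_sum must be positive, got {baseline_sum}")
    if nadir_sum > baseline_sum:
        raise ValueError("nadir_sum cannot exceed baseline_sum (nadir includes baseline)")
    current = sum_of_diameters(assessment)
    pct_base = 100.0 * (current - baseline_sum) / baseline_sum
    # a nadir of 0 (post-CR) makes any reappearance a progression
    pct_nadir = (
        100.0 * (current - nadir_sum) / nadir_sum if nadir_sum > 0
        else (float("inf") if current > 0 else 0.0)
    )
    if assessment.new_lesion or (
        pct_nadir >= PD_INCREASE_PCT and current - nadir_sum >= PD_ABSOLUTE_MM
    ):
        cat = TimepointCategory.PD
    elif all(d == 0 for d in assessment.lesion_diameters_mm):
        cat = TimepointCategory.CR
    elif pct_base <= -PR_DECREASE_PCT:
        cat = TimepointCategory.PR
    else:
        cat = TimepointCategory.SD
    return TimepointResponse(
        category=cat,
        sum_mm=current,
        pct_change_from_baseline=pct_base,
        pct_change_from_nadir=pct_nadir,
    )


_RANK = {
    TimepointCategory.CR: 3,
    TimepointCategory.PR: 2,
    TimepointCategory.SD: 1,
    TimepointCategory.PD: 0,
    TimepointCategory.NE: -1,
}


def best_overall_response(
    timepoints: Sequence[tuple[int, TimepointResponse]],
    confirmation_window_days: int = DEFAULT_CONFIRMATION_WINDOW_DAYS,
) -> BestOverallResponse:
    """Best overall response over an ordered (day, response) timeline.

    CR/PR count as confirmed only when a second assessment of equal or
    better category occurs at least ``confirmation_window_days`` later.  A
    response seen only once is downgraded to SD (flagged if it was a PR).
    Patients with no post-baseline assessment are non-evaluable.  The SD
    duration clock runs from enrollment (day 0) to the last non-PD
    assessment day.
    """
    if confirmation_window_days <= 0:
        raise ValueError("confirmation_window_days must be positive")
    days = [d for d, _ in timepoints]
    if days != sorted(days):
        raise ValueError("timepoints must be sorted by day")
    usable = [(d, tp) for d, tp in timepoints if tp.category is not TimepointCategory.NE]
    if not usable:
        return BestOverallResponse(category=BorCategory.NE)

    def confirmed(cat: TimepointCategory) -> bool:
        hits = [(d, tp) for d, tp in usable if _RANK[tp.category] >= _RANK[cat]]
        return any(
            d2 - d1 >= confirmation_window_days
            for i, (d1, _) in enumerate(hits)
            for d2, _ in hits[i + 1:]
        )

    has = {tp.category for _, tp in usable}
    if TimepointCategory.CR in has and confirmed(TimepointCategory.CR):
        return BestOverallResponse(category=BorCategory.CR_CONFIRMED)
    if TimepointCategory.PR in has and confirmed(TimepointCategory.PR):
        return BestOverallResponse(category=BorCategory.PR_CONFIRMED)

    non_pd_days = [
        d for d, tp in usable
        if tp.category in (TimepointCategory.CR, TimepointCategory.PR, TimepointCategory.SD)
    ]
    if non_pd_days:
        unconfirmed_pr = TimepointCategory.PR in has or TimepointCategory.CR in has
        return BestOverallResponse(
            category=BorCategory.SD,
            unconfirmed_pr_flag=unconfirmed_pr,
            sd_duration_days=max(non_pd_days),
        )
    return BestOverallResponse(category=BorCategory.PD)


def clinical_benefit(
    bor: BestOverallResponse, min_sd_days: int = DEFAULT_MIN_SD_DAYS
) -> bool:
    """Confirmed CR/PR, or SD sustained for at least ``min_sd_days``."""
    if min_sd_days <= 0:
        raise ValueError("min_sd_days must be positive")
    if bor.category in (BorCategory.CR_CONFIRMED, BorCategory.PR_CONFIRMED):
        return True
    return bor.category is BorCategory.SD and (bor.sd_duration_days or 0) >= min_sd_days


def cohort_cbr(
    responses: Sequence[BestOverallResponse],
    min_sd_days: int = DEFAULT_MIN_SD_DAYS,
) -> dict:
    """Clinical-benefit rate over all enrolled patients, NE included.

    Returns count, denominator, rate, and an exact (Clopper–Pearson) 95%
    confidence interval.
    """
    if not responses:
        raise ValueError("empty cohort")
    count = sum(clinical_benefit(b, min_sd_days) for b in responses)
    n = len(responses)
    ci = binomtest(count, n).proportion_ci(confidence_level=0.95, method="exact")
    return {
        "count": count,
        "n": n,
        "rate": count / n,
        "ci95": (float(ci.low), float(ci.high)),
    }


def classify_patient(
    assessments: Sequence[TumorAssessment],
) -> list[tuple[int, TimepointResponse]]:
    """Classify a patient's post-baseline assessments, tracking the nadir.

    The first assessment (day 0) is the baseline; the nadir at each later
    timepoint is the smallest sum seen so far, baseline included.
    """
    if not assessments:
        raise ValueError("no assessments")
    ordered = sorted(assessments, key=lambda a: a.day)
    if ordered[0].day != 0:
        raise ValueError("first assessment must be the baseline at day 0")
    baseline = sum_of_diameters(ordered[0])
    nadir = baseline
    out: list[tuple[int, TimepointResponse]] = []
    for a in ordered[1:]:
        tp = classify_timepoint(baseline, nadir, a)
        out.append((a.day, tp))
        nadir = min(nadir, tp.sum_mm)
    return out


def bor_from_assessments(
    assessments: Sequence[TumorAssessment],
    confirmation_window_days: int = DEFAULT_CONFIRMATION_WINDOW_DAYS,
) -> BestOverallResponse:
    """Best overall response straight from a patient's assessment series."""
    return best_overall_response(
        classify_patient(assessments), confirmation_window_days
    )


def bor_table(
    assessments: pd.DataFrame,
    confirmation_window_days: int = DEFAULT_CONFIRMATION_WINDOW_DAYS,
) -> pd.DataFrame:
    """Per-patient best overall response from a long-format assessment table.

    Expects columns patient_id, day, lesion_id, diameter_mm, new_lesion;
    returns one row per patient with category, unconfirmed_pr_flag and
    sd_duration_days.
    """
    required = {"patient_id", "day", "lesion_id", "diameter_mm", "new_lesion"}
    missing = required - set(assessments.columns)
    if missing:
        raise ValueError(f"assessment table lacks columns: {sorted(missing)}")
    rows = []
    for pid, g in assessments.groupby("patient_id", sort=True):
        series = []
        for day, tg in g.sort_values(["day", "lesion_id"]).groupby("day", sort=True):
            series.append(
                TumorAssessment(
                    patient_id=str(pid),
                    day=int(day),
                    lesion_diameters_mm=tuple(tg["diameter_mm"].astype(float)),
                    new_lesion=bool(tg["new_lesion"].any()),
                )
            )
        bor = bor_from_assessments(series, confirmation_window_days)
        rows.append(
            (pid, bor.category.value, bor.unconfirmed_pr_flag, bor.sd_duration_days)
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "category", "unconfirmed_pr_flag", "sd_duration_days"],
    )


_SCORE_MAX = {Instrument.PHQ9: 27, Instrument.GAD7: 21}


def grade_neuropsych(instrument: Instrument | str, score: int) -> NeuropsychScore:
    """Severity grade for a PHQ-9 or GAD-7 total score."""
    instrument = Instrument(instrument)
    if not 0 <= score <= _SCORE_MAX[instrument]:
        raise ValueError(
            f"{instrument.value} score must lie in [0, {_SCORE_MAX[instrument]}], got {score}"
        )
    if score <= 4:
        grade = NeuropsychGrade.NORMAL
    elif score <= 9:
        grade = NeuropsychGrade.G1
    elif score <= 14:
        grade = NeuropsychGrade.G2
    else:
        grade = NeuropsychGrade.G3
    return NeuropsychScore(instrument=instrument, score=score, grade=grade)
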