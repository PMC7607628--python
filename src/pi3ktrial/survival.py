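"""Right-censored survival endpoints: PFS/OS derivation and Kaplan-Meier.

Progression-free survival runs from enrollment to documented progression or
death from any cause, whichever is first; patients alive and
progression-free are censored at the last radiographic tumor assessment.
Overall survival runs from enrollment to death; survivors are censored at
the last date known alive.

The product-limit estimator is computed from scratch: at each distinct
event time t with d events among n at risk the survival curve multiplies by
(1 − d/n), with events preceding censorings at tied times.  Variance is
Greenwood's formula; the median confidence interval inverts a pointwise
log-log (complementary log-log transformed) 95% band at the event times
(Brookmeyer–Crowley).  Internal time unit is days; months are reported at
1 month = 30.4375 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DAYS_PER_MONTH",
    "SurvivalRecord",
    "PatientTimeline",
    "KMCurve",
    "MedianEstimate",
    "derive_pfs",
    "derive_os",
    "km_fit",
    "km_median",
]

DAYS_PER_MONTH = 30.4375

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time_days: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError(f"time_days must be positive, got {self.time_days}")


@dataclass(frozen=True)
class PatientTimeline:
    """Key dates for one patient, in days since enrollment (day 0)."""

    patient_id: str
    progression_day: int | None = None
    death_day: int | None = None
    last_assessment_day: int | None = None
    last_known_alive_day: int | None = None

    def __post_init__(self) -> None:
        for name in ("progression_day", "death_day", "last_assessment_day",
                     "last_known_alive_day"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be a positive day, got {v}")


def derive_pfs(timeline: PatientTimeline) -> SurvivalRecord:
    """PFS record: event at min(progression, death), else censored at last scan."""
    events = [d for d in (timeline.progression_day, timeline.death_day) if d is not None]
    if events:
        return SurvivalRecord(timeline.patient_id, min(events), True)
    if timeline.last_assessment_day is None:
        raise ValueError(
            f"{timeline.patient_id}: no progression/death and no assessment to censor at"
        )
    return SurvivalRecord(timeline.patient_id, timeline.last_assessment_day, False)


def derive_os(timeline: PatientTimeline) -> SurvivalRecord:
    """OS record: event at death, else censored at the last date known alive."""
    if timeline.death_day is not None:
        return SurvivalRecord(timeline.patient_id, timeline.death_day, True)
    if timeline.last_known_alive_day is None:
        raise ValueError(
            f"{timeline.patient_id}: no death and no last-known-alive date to censor at"
        )
    return SurvivalRecord(timeline.patient_id, timeline.last_known_alive_day, False)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: tuple[float, ...]
    surv: tuple[float, ...]
    n_risk: tuple[int, ...]
    n_event: tuple[int, ...]
    greenwood_var: tuple[float, ...]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for et, sv in zip(self.event_times, self.surv):
            if et <= t:
                s = sv
            else:
                break
        return s


@dataclass(frozen=True)
class MedianEstimate:
    median_days: float | None
    ci_low_days: float | None
    ci_high_days: float | None


def km_fit(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance."""
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)

    event_times: list[float] = []
    surv: list[float] = []
    n_risk: list[int] = []
    n_event: list[int] = []
    gvar: list[float] = []

    s = 1.0
    gw_sum = 0.0
    at_risk = len(records)
    for t in np.unique(times):
        here = times == t
        d = int(np.sum(here & events))
        c = int(np.sum(here & ~events))
        if d > 0:
            s *= 1.0 - d / at_risk
            if at_risk > d:
                gw_sum += d / (at_risk * (at_risk - d))
                var = s * s * gw_sum
            else:
                var = 0.0  # curve hits zero; Greenwood term degenerate
            event_times.append(float(t))
            surv.append(s)
            n_risk.append(at_risk)
            n_event.append(d)
            gvar.append(var)
        at_risk -= d + c  # events precede censorings at tied times
    return KMCurve(
        event_times=tuple(event_times),
        surv=tuple(surv),
        n_risk=tuple(n_risk),
        n_event=tuple(n_event),
        greenwood_var=tuple(gvar),
    )


def _loglog_band(s: float, var: float) -> tuple[float, float]:
    """Pointwise 95% CI for S(t) on the complementary log-log scale."""
    if s <= 0.0:
        return (0.0, 0.0)
    if s >= 1.0 or var <= 0.0:
        return (s, s)
    se_ll = math.sqrt(var) / (s * abs(math.log(s)))
    lo = s ** math.exp(Z_95 * se_ll)
    hi = s ** math.exp(-Z_95 * se_ll)
    return (lo, hi)


def km_median(curve: KMCurve) -> MedianEstimate:
    """Median survival with a Brookmeyer-Crowley 95% interval.

    Median = smallest event time with S(t) ≤ 0.5 (undefined if the curve
    never reaches 0.5).  The CI bounds are the smallest event times at which
    the lower / upper log-log band crosses 0.5; an upper band that never
    crosses leaves the CI upper bound unbounded (None).
    """
    median = None
    ci_low = None
    ci_high = None
    for t, s, v in zip(curve.event_times, curve.surv, curve.greenwood_var):
        lo, hi = _loglog_band(s, v)
        if median is None and s <= 0.5:
            median = t
        if ci_low is None and lo <= 0.5:
            ci_low = t
        if ci_high is None and hi <= 0.5:
            ci_high = t
    if median is None:
        return MedianEstimate(None, None, None)
    return MedianEstimate(median_days=median, ci_low_days=ci_low, ci_high_days=ci_high)
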