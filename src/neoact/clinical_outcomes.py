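"""Trial-level efficacy and safety evaluation.

Implements target-lesion response assessment under RECIST 1.1 (sum of
longest diameters; CR/PR/SD/PD), best overall response, the cohort
objective response rate (ORR = CR+PR) and disease control rate
(DCR = CR+PR+SD), Kaplan–Meier survival curves for progression-free and
overall survival, and treatment-related adverse-event tabulation with
worst-grade-per-patient counting.

RECIST 1.1 thresholds for target lesions:

* CR — all target lesions disappear (diameter 0);
* PR — sum of diameters drops by at least 30% from baseline;
* PD — sum grows by at least 20% from the nadir AND by at least 5 mm in
  absolute terms, or any unequivocal new lesion appears;
* SD — neither PR nor PD.

Only target lesions are assessed (nodal short-axis rules and non-target
lesions are out of scope); best overall response needs no confirmation
scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times


class Response(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


_RESPONSE_ORDER = {Response.CR: 3, Response.PR: 2, Response.SD: 1,
                   Response.PD: 0}


@dataclass(frozen=True)
class LesionRecord:
    patient_id: str
    lesion_id: str
    timepoint_months: float
    diameter_mm: float
    new_lesion: bool = False

    def __post_init__(self) -> None:
        if self.diameter_mm < 0:
            raise ValueError("lesion diameter must be nonnegative")
        if self.timepoint_months < 0:
            raise ValueError("timepoints are measured from first infusion")


@dataclass(frozen=True)
class ResponseAssessment:
    patient_id: str
    timepoint_months: float
    sum_diameters_mm: float
    pct_change_from_baseline: float
    pct_change_from_nadir: float
    category: Response


def _round1(x: float) -> float:
    """Round half-up to one decimal (matches clinical-report conventions)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"),
                                           rounding=ROUND_HALF_UP))


def assess_timepoint(lesions: Sequence[LesionRecord], baseline_sum: float,
                     nadir_sum: float) -> ResponseAssessment:
    """Classify one patient-timepoint from its target-lesion measurements.

    ``baseline_sum`` and ``nadir_sum`` are the sum of target-lesion
    diameters at baseline and the smallest sum seen at any prior
    assessment.  Progression takes precedence: a new lesion, or a sum at
    least 20% AND 5 mm above nadir, is PD even if the targets shrank.
    """
    if not lesions:
        raise ValueError("no lesion measurements at this timepoint")
    if baseline_sum <= 0 and any(l.diameter_mm > 0 for l in lesions):
        raise ValueError("missing or zero baseline sum for measurable disease")
    current = sum(l.diameter_mm for l in lesions)
    new_lesion = any(l.new_lesion for l in lesions)
    pct_base = (100.0 * (current - baseline_sum) / baseline_sum
                if baseline_sum > 0 else 0.0)
    pct_nadir = (100.0 * (current - nadir_sum) / nadir_sum
                 if nadir_sum > 0 else (0.0 if current == 0 else float("inf")))
    if new_lesion or (current >= 1.20 * nadir_sum
                      and current >= nadir_sum + 5.0):
        category = Response.PD
    elif all(l.diameter_mm == 0 for l in lesions):
        category = Response.CR
    elif current <= 0.70 * baseline_sum:
        category = Response.PR
    else:
        category = Response.SD
    pid = lesions[0].patient_id
    tp = lesions[0].timepoint_months
    return ResponseAssessment(pid, tp, current, pct_base, pct_nadir, category)


def assess_patient(lesions: Sequence[LesionRecord]) -> list[ResponseAssessment]:
    """Assess every post-baseline timepoint of one patient's lesion series.

    Baseline is timepoint 0; the nadir is the smallest sum over all
    assessments strictly before the current one (baseline included).
    """
    by_tp: dict[float, list[LesionRecord]] = {}
    for rec in lesions:
        by_tp.setdefault(rec.timepoint_months, []).append(rec)
    if 0.0 not in by_tp:
        raise ValueError("no baseline (timepoint 0) measurements")
    baseline_sum = sum(l.diameter_mm for l in by_tp[0.0]
                       if not l.new_lesion)
    nadir = baseline_sum
    out: list[ResponseAssessment] = []
    for tp in sorted(t for t in by_tp if t > 0.0):
        assessment = assess_timepoint(by_tp[tp], baseline_sum, nadir)
        out.append(assessment)
        nadir = min(nadir, assessment.sum_diameters_mm)
    return out


def best_overall_response(
        assessments: Sequence[ResponseAssessment | Response]) -> Response:
    """Best category achieved before first progression (CR > PR > SD).

    No confirmation scan is required.  PD is returned only when no
    pre-progression assessment reached CR/PR/SD.
    """
    if not assessments:
        raise ValueError("no assessments supplied")
    categories = [a.category if isinstance(a, ResponseAssessment) else a
                  for a in assessments]
    best: Response | None = None
    for cat in categories:
        if cat is Response.PD:
            break
        if best is None or _RESPONSE_ORDER[cat] > _RESPONSE_ORDER[best]:
            best = cat
    return best if best is not None else Response.PD


def orr_dcr(responses: Sequence[Response | str]) -> tuple[float, float, dict, int]:
    """Objective response rate and disease control rate, in percent.

    Returns ``(orr_pct, dcr_pct, numerators, denominator)`` with
    percentages rounded half-up to one decimal; ``numerators`` holds the
    CR+PR and CR+PR+SD counts.
    """
    if not responses:
        raise ValueError("no responses supplied")
    cats = [Response(r) for r in responses]
    n = len(cats)
    n_or = sum(1 for c in cats if c in (Response.CR, Response.PR))
    n_dc = n_or + sum(1 for c in cats if c is Response.SD)
    return (_round1(100.0 * n_or / n), _round1(100.0 * n_dc / n),
            {"objective_response": n_or, "disease_control": n_dc}, n)


# --------------------------------------------------------------------------
# Survival
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalInput:
    patient_id: str
    time_months: float
    event: bool  # True = progression/death observed, False = censored

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError("survival times must be positive")


@dataclass(frozen=True)
class SurvivalCurve:
    times: tuple[float, ...]       # event times, increasing
    survival: tuple[float, ...]    # S(t) at those times, non-increasing
    median: float | None           # smallest t with S(t) <= 0.5
    ci95: tuple[float | None, float | None]  # median CI, bounds may be open


def km_estimate(inputs: Sequence[SurvivalInput]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate with a 95% median CI.

    The step curve is reported at the observed event times.  The median is
    the smallest time at which the curve reaches 0.5 or below (``None`` if
    never reached); its confidence interval comes from the
    Greenwood-variance log-log curve bands (Brookmeyer–Crowley style).
    """
    if not inputs:
        raise ValueError("no subjects supplied")
    times = [s.time_months for s in inputs]
    events = [bool(s.event) for s in inputs]
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = sorted({t for t, e in zip(times, events) if e})
    surv = tuple(float(kmf.predict(t)) for t in event_times)
    # smallest event time with S(t) <= 0.5; small tolerance so a curve
    # reaching exactly one half is counted despite float accumulation
    median_out = next((t for t, s in zip(event_times, surv)
                       if s <= 0.5 + 1e-12), None)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    ci_out = (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)
    return SurvivalCurve(tuple(event_times), surv, median_out, ci_out)


# --------------------------------------------------------------------------
# Adverse events
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdverseEvent:
    patient_id: str
    group: str   # lymphodepletion arm: none / low / high
    term: str
    grade: int   # CTCAE grade 1..5

    def __post_init__(self) -> None:
        if not 1 <= self.grade <= 5:
            raise ValueError(f"CTCAE grade {self.grade} outside 1..5")


def ae_summarize(events: Sequence[AdverseEvent],
                 group_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Per-arm adverse-event table with any-grade and grade >=3 counts.

    Each patient counts once per term per arm at their worst grade;
    percentages are of the arm size, rounded half-up to one decimal.
    """
    worst: dict[tuple[str, str, str], int] = {}
    for ev in events:
        if ev.group not in group_sizes:
            raise ValueError(f"unknown group {ev.group!r}")
        key = (ev.group, ev.term, ev.patient_id)
        worst[key] = max(worst.get(key, 0), ev.grade)
    rows = []
    terms = sorted({ev.term for ev in events})
    for group in group_sizes:
        size = group_sizes[group]
        for term in terms:
            grades = [g for (grp, trm, _pid), g in worst.items()
                      if grp == group and trm == term]
            any_n = len(grades)
            ge3_n = sum(1 for g in grades if g >= 3)
            rows.append({
                "group": group, "term": term,
                "any_grade_count": any_n,
                "any_grade_pct": _round1(100.0 * any_n / size),
                "ge3_count": ge3_n,
                "ge3_pct": _round1(100.0 * ge3_n / size),
            })
    return pd.DataFrame(rows, columns=["group", "term", "any_grade_count",
                                       "any_grade_pct", "ge3_count",
                                       "ge3_pct"])


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def read_lesions_csv(path: str | Path) -> list[LesionRecord]:
    df = pd.read_csv(path)
    return [LesionRecord(str(r.patient_id), str(r.lesion_id),
                         float(r.timepoint_months), float(r.diameter_mm),
                         bool(r.new_lesion)) for r in df.itertuples()]


def read_survival_csv(path: str | Path) -> list[SurvivalInput]:
    df = pd.read_csv(path)
    return [SurvivalInput(str(r.patient_id), float(r.time_months),
                          bool(r.event)) for r in df.itertuples()]


def read_ae_csv(path: str | Path) -> list[AdverseEvent]:
    df = pd.read_csv(path)
    return [AdverseEvent(str(r.patient_id), str(r.group), str(r.term),
                         int(r.grade)) for r in df.itertuples()]


def waterfall_table(patients: Mapping[str, Sequence[LesionRecord]]) -> pd.DataFrame:
    """Best percent change in target-lesion sum per patient (waterfall plot data)."""
    rows = []
    for pid, lesions in patients.items():
        assessments = assess_patient(lesions)
        best_pct = min(a.pct_change_from_baseline for a in assessments)
        rows.append({"patient_id": pid, "best_pct_change": best_pct,
                     "best_overall_response":
                         best_overall_response(assessments).value})
    return pd.DataFrame(rows, columns=["patient_id", "best_pct_change",
                                       "best_overall_response"])
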