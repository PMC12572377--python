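"""Longitudinal screening-cohort data model.

A :class:`PatientTimeline` holds a woman's date-ordered screening exams, her
risk-factor vector, any prior-tumor records, and the outcome (a diagnosis date
with laterality, or the last negative follow-up date).  From a timeline the
package derives :class:`TargetSample` units: one per eligible exam, carrying
the target exam, up to five prior exams, month-resolution intervals, slot
masks and the discrete-time risk labels.

Label convention: future diagnoses are discretized into fifteen one-year bins
(class ``i`` means an event in the half-open interval ``(i-1, i]`` years after
the target exam) plus class 0 for cancer-free; cumulative risk at horizon
``j`` is then the prefix sum of the softmax over classes ``1..j``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Literal, Optional

import numpy as np

MISSING = -1
N_CLASSES = 16  # class 0 = cancer-free, classes 1..15 = event-year bins
MAX_YEARS = 15
DAYS_PER_MONTH = 30.4375
MAX_PRIORS = 5

Laterality = Literal["left", "right"]
View = Literal["CC", "MLO"]
SIDES: tuple[Laterality, Laterality] = ("right", "left")
VIEWS: tuple[View, View] = ("CC", "MLO")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RiskFactorVector:
    """Classical risk factors; any unknown field carries the sentinel -1."""

    age: float = MISSING                     # years at the target exam
    age_at_menarche: float = MISSING
    menopausal_status: int = MISSING         # 0 pre, 1 peri/unknown, 2 post
    family_history_bc: int = MISSING         # 0/1
    family_history_ovarian: int = MISSING
    density_acr: int = MISSING               # ACR 1..4
    race: int = MISSING
    gene_mutation: int = MISSING
    personal_history_bc: int = MISSING
    personal_history_ovarian: int = MISSING

    def validate(self) -> None:
        if self.age != MISSING and self.age < 0:
            raise ValueError("age must be non-negative")
        if self.density_acr != MISSING and self.density_acr not in (1, 2, 3, 4):
            raise ValueError("density_acr must be 1..4 or missing")


@dataclass
class TumorRecord:
    """Prognostic factors of a prior tumor; -1 encodes unknown."""

    laterality: Laterality = "left"
    location_c50: int = MISSING   # grouped C50 sub-site code 0..5
    pT: int = MISSING             # ordinal 0..4
    pN: int = MISSING             # ordinal 0..3
    er: int = MISSING             # 0 neg, 1 pos
    pr: int = MISSING
    her2: int = MISSING
    surgery_type: int = MISSING
    adjuvant_chemo: int = MISSING
    adjuvant_radio: int = MISSING
    anti_hormonal: int = MISSING
    antibody_therapy: int = MISSING
    pcr: int = MISSING            # pathologic complete response flag


@dataclass
class ScreeningExam:
    exam_date: date
    images: dict = field(default_factory=dict)  # (laterality, view) -> array or path
    birads: int = MISSING                       # 0..6
    density_acr: int = MISSING                  # 1..4 or missing
    manufacturer: int = MISSING
    biopsy_benign_within_90d: bool = False

    def validate(self) -> None:
        if self.birads != MISSING and not 0 <= self.birads <= 6:
            raise ValueError("BI-RADS must be in 0..6")
        for key in self.images:
            lat, view = key
            if lat not in SIDES or view not in VIEWS:
                raise ValueError(f"bad image key {key!r}")


@dataclass
class PatientTimeline:
    patient_id: str
    exams: list[ScreeningExam]
    risk_factors: RiskFactorVector = field(default_factory=RiskFactorVector)
    prior_tumors: list[TumorRecord] = field(default_factory=list)
    diagnosis_date: Optional[date] = None
    diagnosis_laterality: Optional[Laterality] = None
    last_followup_date: Optional[date] = None
    # attributes of the diagnosed tumor, when known (training-time aux labels)
    future_tumor: Optional[TumorRecord] = None

    def validate(self) -> None:
        if not self.exams:
            raise ValueError("timeline needs at least one exam")
        dates = [e.exam_date for e in self.exams]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("exams must be strictly date-sorted")
        if self.diagnosis_date is not None:
            if self.diagnosis_laterality not in SIDES:
                raise ValueError("diagnosis requires a laterality")
            if self.diagnosis_date < dates[0]:
                raise ValueError("diagnosis precedes first exam")
        elif self.last_followup_date is None:
            raise ValueError("censored timeline needs last_followup_date")
        self.risk_factors.validate()
        for e in self.exams:
            e.validate()

    @property
    def has_event(self) -> bool:
        return self.diagnosis_date is not None

    def observation_end(self) -> date:
        if self.diagnosis_date is not None:
            return self.diagnosis_date
        assert self.last_followup_date is not None
        return self.last_followup_date


@dataclass
class TargetSample:
    patient_id: str
    target_exam_index: int
    prior_indices: list[int]
    intervals_months: np.ndarray        # (6,) slot 0 = target (0.0), slots 1..5 priors
    slot_mask: np.ndarray               # (6,) bool; True = slot holds a real exam
    patient_class: int                  # 0..15
    breast_class: dict                  # side -> 0..15
    breast_followup_years: dict         # side -> observable follow-up from target
    followup_years: float               # patient-level follow-up from target
    event: bool = False
    time_years: float = 0.0             # time to diagnosis or last follow-up


# ---------------------------------------------------------------------------
# label discretization
# ---------------------------------------------------------------------------

def discretize_time_to_event(time_to_event_years: float | None,
                             followup_years: float) -> int:
    """Map a time-to-event (or censored follow-up) to a 16-class label.

    Events in ``(i-1, i]`` years land in class ``i``; events beyond 15 years
    and event-free observations are class 0.  Censored observations require at
    least one year of follow-up (shorter ones are excluded upstream).
    """
    if time_to_event_years is None:
        if followup_years < 0:
            raise ValueError("negative follow-up")
        if followup_years < 1.0:
            raise ValueError("censored sample with <1 year follow-up is ineligible")
        return 0
    if time_to_event_years < 0:
        raise ValueError("negative time to event")
    if time_to_event_years > MAX_YEARS:
        return 0
    return max(1, int(math.ceil(time_to_event_years)))


def years_between(a: date, b: date) -> float:
    return (b - a).days / 365.25


def months_between(a: date, b: date) -> float:
    return (b - a).days / DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# sample construction
# ---------------------------------------------------------------------------

def make_target_samples(timeline: PatientTimeline) -> list[TargetSample]:
    """One :class:`TargetSample` per exam with a known outcome.

    Eligible exams either precede a diagnosis or have at least one year of
    negative follow-up.  The breast on the diagnosed side gets the event
    class; the contralateral breast is labelled cancer-free with follow-up
    truncated at the diagnosis (its observation simply ends there).  The
    patient-level class is the earliest event over the two breasts.
    """
    timeline.validate()
    end = timeline.observation_end()
    samples: list[TargetSample] = []
    for idx, exam in enumerate(timeline.exams):
        if timeline.has_event:
            assert timeline.diagnosis_date is not None
            t_event = years_between(exam.exam_date, timeline.diagnosis_date)
            if t_event < 0:
                continue  # exam after diagnosis: not a screening target
            followup = t_event
            event_cls = discretize_time_to_event(t_event, followup)
            side_cls = {s: 0 for s in SIDES}
            side_fu = {s: t_event for s in SIDES}
            side_cls[timeline.diagnosis_laterality] = event_cls
            patient_cls = event_cls
            is_event = True  # diagnosis observed (possibly beyond the 15-year bins)
            time_years = t_event
        else:
            followup = years_between(exam.exam_date, end)
            if followup < 1.0:
                continue
            side_cls = {s: 0 for s in SIDES}
            side_fu = {s: followup for s in SIDES}
            patient_cls = 0
            is_event = False
            time_years = followup
        samples.append(
            TargetSample(
                patient_id=timeline.patient_id,
                target_exam_index=idx,
                prior_indices=[],
                intervals_months=np.zeros(MAX_PRIORS + 1),
                slot_mask=np.array([True] + [False] * MAX_PRIORS),
                patient_class=patient_cls,
                breast_class=side_cls,
                breast_followup_years=side_fu,
                followup_years=followup,
                event=is_event,
                time_years=max(time_years, 1e-9),
            )
        )
    return samples


def select_priors(timeline: PatientTimeline, sample: TargetSample, k: int = MAX_PRIORS,
                  mode: str = "eval", rng: np.random.Generator | None = None) -> TargetSample:
    """Fill the prior-exam slots of ``sample``.

    Training randomly picks up to ``k`` distinct priors (uniformly, without
    replacement); evaluation deterministically keeps the ``k`` most recent.
    Unfilled slots stay masked with zero intervals.  Priors are ordered most
    recent first in either mode.
    """
    if k > MAX_PRIORS:
        raise ValueError(f"at most {MAX_PRIORS} priors are supported")
    avail = list(range(sample.target_exam_index))
    if mode == "train":
        if rng is None:
            raise ValueError("train-mode selection needs an rng")
        take = min(k, len(avail))
        chosen = sorted(rng.choice(len(avail), size=take, replace=False).tolist()) if take else []
        chosen = [avail[i] for i in chosen]
    elif mode == "eval":
        chosen = avail[-k:] if k else []
    else:
        raise ValueError(f"unknown mode {mode!r}")
    chosen = sorted(chosen, reverse=True)  # most recent first
    target_date = timeline.exams[sample.target_exam_index].exam_date
    intervals = np.zeros(MAX_PRIORS + 1)
    mask = np.zeros(MAX_PRIORS + 1, dtype=bool)
    mask[0] = True
    for slot, j in enumerate(chosen, start=1):
        gap = months_between(timeline.exams[j].exam_date, target_date)
        if gap <= 0:
            raise ValueError("prior exam not strictly earlier than target")
        intervals[slot] = gap
        mask[slot] = True
    return replace(sample, prior_indices=chosen,
                   intervals_months=intervals, slot_mask=mask)


# ---------------------------------------------------------------------------
# density interpolation
# ---------------------------------------------------------------------------

def interpolate_missing_density(timeline: PatientTimeline) -> PatientTimeline:
    """Nearest-date fill of missing per-exam ACR density (ties -> earlier exam).

    If no exam has a known density everything stays at the -1 sentinel.
    """
    known = [(i, e.exam_date, e.density_acr) for i, e in enumerate(timeline.exams)
             if e.density_acr != MISSING]
    if not known:
        return timeline
    new_exams = []
    for e in timeline.exams:
        if e.density_acr != MISSING:
            new_exams.append(e)
            continue
        best = min(known, key=lambda kv: (abs((kv[1] - e.exam_date).days), kv[1]))
        new_exams.append(replace(e, density_acr=best[2]))
    return replace(timeline, exams=new_exams)


# ---------------------------------------------------------------------------
# fixed-width numeric encodings fed to the network
# ---------------------------------------------------------------------------

def encode_risk_factors(rf: RiskFactorVector) -> np.ndarray:
    """Fixed-length numeric encoding (one-hot categorical blocks, scaled reals)."""
    out = []
    out.append(rf.age / 100.0 if rf.age != MISSING else -1.0)
    out.append(rf.age_at_menarche / 20.0 if rf.age_at_menarche != MISSING else -1.0)
    out.extend(_onehot(rf.menopausal_status, 3))
    out.append(float(rf.family_history_bc) if rf.family_history_bc != MISSING else -1.0)
    out.append(float(rf.family_history_ovarian) if rf.family_history_ovarian != MISSING else -1.0)
    out.extend(_onehot(rf.density_acr - 1 if rf.density_acr != MISSING else MISSING, 4))
    out.extend(_onehot(rf.race, 4))
    out.append(float(rf.gene_mutation) if rf.gene_mutation != MISSING else -1.0)
    out.append(float(rf.personal_history_bc) if rf.personal_history_bc != MISSING else -1.0)
    out.append(float(rf.personal_history_ovarian) if rf.personal_history_ovarian != MISSING else -1.0)
    return np.asarray(out, dtype=np.float64)


def encode_tumor_record(rec: TumorRecord | None, dim: int) -> np.ndarray:
    """Encode a prior-tumor record as one-hot blocks plus scaled ordinals,
    zero-padded to ``dim``.  Absent record -> all minus-one placeholder."""
    if rec is None:
        return np.full(dim, -1.0)
    out = []
    out.extend(_onehot(rec.location_c50, 6))
    out.append(rec.pT / 4.0 if rec.pT != MISSING else -1.0)
    out.append(rec.pN / 3.0 if rec.pN != MISSING else -1.0)
    for v in (rec.er, rec.pr, rec.her2, rec.pcr):
        out.append(float(v) if v != MISSING else -1.0)
    for v in (rec.surgery_type, rec.adjuvant_chemo, rec.adjuvant_radio,
              rec.anti_hormonal, rec.antibody_therapy):
        out.extend(_onehot(v, 3))
    vec = np.asarray(out, dtype=np.float64)
    if vec.size > dim:
        raise ValueError(f"tumor encoding ({vec.size}) exceeds dim {dim}")
    return np.concatenate([vec, np.zeros(dim - vec.size)])


def tumor_for_side(timeline: PatientTimeline, side: Laterality) -> TumorRecord | None:
    recs = [r for r in timeline.prior_tumors if r.laterality == side]
    return recs[-1] if recs else None


def _onehot(value: int, n: int) -> list[float]:
    vec = [0.0] * n
    if value != MISSING and 0 <= value < n:
        vec[value] = 1.0
    elif value == MISSING:
        return [-1.0] * n
    return vec


def riskf_encoding_dim() -> int:
    return encode_risk_factors(RiskFactorVector()).size
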