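"""Participant, visit, 24-h recall, FFQ and GSRS data model and I/O.

The study design this mirrors: two arms (adult, pediatric), three visits
(vt0 at diagnosis, vt3 and vt12 after 3 and 12 months on a gluten-free
diet), dietary intake recorded as 3-day 24-h recalls per visit (two
weekdays, one weekend day), a food-frequency questionnaire at vt0 and
vt12, and a 15-item GSRS symptom questionnaire at every visit.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, ValidationError, model_validator

from .food_db import FoodTable, SencGroup

__all__ = [
    "Cohort", "Sex", "ActivityLevel", "VisitCode", "DayType", "FreqUnit",
    "Participant", "Visit", "IntakeEvent", "FFQResponse", "GSRSResponse",
    "CohortBundle", "LoadReport", "load_cohort", "save_cohort",
    "portions_from_grams", "ACTIVITY_FACTORS", "GSRS_SUBDIMENSIONS",
]


class Cohort(str, Enum):
    adult = "adult"
    pediatric = "pediatric"


class Sex(str, Enum):
    M = "M"
    F = "F"


class ActivityLevel(str, Enum):
    sedentary = "sedentary"
    light = "light"
    moderate = "moderate"
    high = "high"


#: Physical-activity multipliers applied to the resting metabolic rate.
ACTIVITY_FACTORS = {
    ActivityLevel.sedentary: 1.2,
    ActivityLevel.light: 1.4,
    ActivityLevel.moderate: 1.6,
    ActivityLevel.high: 1.8,
}


class VisitCode(str, Enum):
    vt0 = "vt0"
    vt3 = "vt3"
    vt12 = "vt12"


class DayType(str, Enum):
    weekday = "weekday"
    weekend = "weekend"


class FreqUnit(str, Enum):
    per_day = "per_day"
    per_week = "per_week"


class Participant(BaseModel):
    participant_id: str
    cohort: Cohort
    sex: Sex
    age_years: float = Field(gt=0)
    activity_level: ActivityLevel = ActivityLevel.light

    @model_validator(mode="after")
    def _cohort_age(self) -> "Participant":
        pediatric = self.age_years < 18
        if pediatric != (self.cohort == Cohort.pediatric):
            raise ValueError(
                f"{self.participant_id}: cohort {self.cohort.value} inconsistent "
                f"with age {self.age_years}")
        return self


class Visit(BaseModel):
    participant_id: str
    visit_code: VisitCode
    weight_kg: float = Field(gt=0)
    height_m: float = Field(gt=0)
    fat_mass_kg: Optional[float] = Field(None, ge=0)
    muscle_mass_kg: Optional[float] = Field(None, ge=0)
    waist_cm: Optional[float] = Field(None, gt=0)
    hip_cm: Optional[float] = Field(None, gt=0)
    measured_rmr_kcal: Optional[float] = Field(None, gt=0)
    glucose: Optional[float] = Field(None, ge=0)
    total_cholesterol: Optional[float] = Field(None, ge=0)
    hdl_cholesterol: Optional[float] = Field(None, ge=0)
    ldl_cholesterol: Optional[float] = Field(None, ge=0)
    triglycerides: Optional[float] = Field(None, ge=0)
    ferritin: Optional[float] = Field(None, ge=0)
    transferrin: Optional[float] = Field(None, ge=0)

    @property
    def bmi(self) -> float:
        return self.weight_kg / self.height_m ** 2


BIOCHEM_ANALYTES = ("glucose", "total_cholesterol", "hdl_cholesterol",
                    "ldl_cholesterol", "triglycerides", "ferritin",
                    "transferrin")


class IntakeEvent(BaseModel):
    """One consumed item on one recall day."""

    participant_id: str
    visit_code: VisitCode
    day_index: int = Field(ge=1, le=3)
    day_type: DayType
    food_id: str
    amount_g: float = Field(gt=0)


class FFQResponse(BaseModel):
    """Food-group consumption frequencies; administered at vt0 and vt12."""

    participant_id: str
    visit_code: VisitCode
    frequencies: dict[SencGroup, float]
    units: dict[SencGroup, FreqUnit]

    @model_validator(mode="after")
    def _check(self) -> "FFQResponse":
        if self.visit_code == VisitCode.vt3:
            raise ValueError(
                f"{self.participant_id}: FFQ is administered at vt0 and vt12 only")
        for g, v in self.frequencies.items():
            if v < 0:
                raise ValueError(f"{self.participant_id}: negative frequency for {g.value}")
            if g not in self.units:
                raise ValueError(f"{self.participant_id}: missing unit for {g.value}")
        return self


#: Standard published GSRS instrument mapping of the 15 items (1-based) to
#: the five sub-dimensions.
GSRS_SUBDIMENSIONS: dict[str, tuple[int, ...]] = {
    "abdominal_pain": (1, 4, 5),
    "reflux": (2, 3),
    "indigestion": (6, 7, 8, 9),
    "diarrhea": (11, 12, 13),
    "constipation": (10, 14, 15),
}


class GSRSResponse(BaseModel):
    """15 Likert items, 1 (no discomfort) to 7 (most severe)."""

    participant_id: str
    visit_code: VisitCode
    item_scores: list[int]

    @model_validator(mode="after")
    def _check(self) -> "GSRSResponse":
        if len(self.item_scores) != 15:
            raise ValueError(
                f"{self.participant_id}: GSRS requires exactly 15 items, "
                f"got {len(self.item_scores)}")
        bad = [s for s in self.item_scores if not 1 <= s <= 7]
        if bad:
            raise ValueError(
                f"{self.participant_id}: GSRS item scores outside [1,7]: {bad}")
        return self


@dataclass
class LoadReport:
    """Every rejected input row appears here exactly once, with a reason."""

    rejected: list[tuple[str, str]] = field(default_factory=list)  # (entity/id, reason)
    dangling_food_ids: list[str] = field(default_factory=list)
    n_accepted: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.rejected and not self.dangling_food_ids


@dataclass
class CohortBundle:
    participants: list[Participant]
    visits: list[Visit]
    events: list[IntakeEvent]
    ffq: list[FFQResponse]
    gsrs: list[GSRSResponse]

    def participant(self, pid: str) -> Participant:
        for p in self.participants:
            if p.participant_id == pid:
                return p
        raise KeyError(pid)

    def visit(self, pid: str, code: VisitCode) -> Optional[Visit]:
        for v in self.visits:
            if v.participant_id == pid and v.visit_code == code:
                return v
        return None

    def events_for(self, pid: str, code: VisitCode) -> list[IntakeEvent]:
        return [e for e in self.events
                if e.participant_id == pid and e.visit_code == code]

    def participant_visits(self) -> list[tuple[str, VisitCode]]:
        """Distinct (participant, visit) pairs that have recall data."""
        seen: dict[tuple[str, VisitCode], None] = {}
        for e in self.events:
            seen.setdefault((e.participant_id, e.visit_code), None)
        return list(seen)

    def arm(self, cohort: Cohort) -> list[Participant]:
        return [p for p in self.participants if p.cohort == cohort]


def portions_from_grams(event: IntakeEvent, food) -> float:
    """Grams consumed expressed in standard portions (unrounded)."""
    return event.amount_g / food.standard_portion_g


def _recall_structure_errors(events: list[IntakeEvent]) -> list[str]:
    """3 recall days per participant-visit: two weekdays + one weekend day."""
    errs = []
    by_pv: dict[tuple[str, str], dict[int, DayType]] = {}
    for e in events:
        days = by_pv.setdefault((e.participant_id, e.visit_code.value), {})
        prev = days.get(e.day_index)
        if prev is not None and prev != e.day_type:
            errs.append(f"{e.participant_id}/{e.visit_code.value}: day {e.day_index} "
                        "has inconsistent day_type")
        days[e.day_index] = e.day_type
    for (pid, vc), days in by_pv.items():
        if sorted(days) != [1, 2, 3]:
            errs.append(f"{pid}/{vc}: expected day_index 1,2,3, got {sorted(days)}")
            continue
        n_weekend = sum(1 for t in days.values() if t == DayType.weekend)
        if n_weekend != 1:
            errs.append(f"{pid}/{vc}: expected 2 weekday + 1 weekend recall days, "
                        f"got {n_weekend} weekend")
    return errs


def load_cohort(data_dir: str | Path, food_table: FoodTable) -> tuple[CohortBundle, LoadReport]:
    """Load a cohort from delimited files in ``data_dir``.

    Expected files: ``participants.csv``, ``visits.csv``, ``recalls.csv``,
    ``ffq.csv``, ``gsrs.csv`` (the last two optional). The loader is total:
    every row is either accepted into the bundle or listed once in the
    report with its reason; participant-visits violating the 2+1 recall-day
    structure are excluded as a whole.
    """
    data_dir = Path(data_dir)
    report = LoadReport()

    def read(name: str) -> list[dict]:
        p = data_dir / name
        if not p.exists():
            return []
        with open(p, newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))

    participants: list[Participant] = []
    for row in read("participants.csv"):
        try:
            participants.append(Participant(**row))
        except ValidationError as exc:
            report.rejected.append((f"participants:{row.get('participant_id')}", str(exc)))
    pids = {p.participant_id for p in participants}

    visits: list[Visit] = []
    for row in read("visits.csv"):
        row = {k: (v if v != "" else None) for k, v in row.items()}
        try:
            v = Visit(**row)
            if v.participant_id not in pids:
                raise ValueError("unknown participant_id")
            visits.append(v)
        except (ValidationError, ValueError) as exc:
            report.rejected.append((f"visits:{row.get('participant_id')}", str(exc)))

    events: list[IntakeEvent] = []
    for row in read("recalls.csv"):
        try:
            e = IntakeEvent(**row)
            if e.participant_id not in pids:
                raise ValueError("unknown participant_id")
            if e.food_id not in food_table:
                report.dangling_food_ids.append(e.food_id)
                raise ValueError(f"unresolved food_id {e.food_id!r}")
            events.append(e)
        except (ValidationError, ValueError) as exc:
            report.rejected.append(
                (f"recalls:{row.get('participant_id')}/{row.get('food_id')}", str(exc)))

    struct_errs = _recall_structure_errors(events)
    if struct_errs:
        bad_pv = {tuple(err.split(":")[0].split("/")) for err in struct_errs}
        for err in struct_errs:
            report.rejected.append(("recalls:structure", err))
        events = [e for e in events
                  if (e.participant_id, e.visit_code.value) not in bad_pv]

    ffq: list[FFQResponse] = []
    for row in read("ffq.csv"):
        pid, vc = row.get("participant_id"), row.get("visit_code")
        try:
            freqs, units = {}, {}
            for g in SencGroup:
                if row.get(g.value, "") != "":
                    freqs[g] = float(row[g.value])
                    units[g] = FreqUnit(row[f"{g.value}_unit"])
            r = FFQResponse(participant_id=pid, visit_code=vc,
                            frequencies=freqs, units=units)
            if r.participant_id not in pids:
                raise ValueError("unknown participant_id")
            ffq.append(r)
        except (ValidationError, ValueError, KeyError) as exc:
            report.rejected.append((f"ffq:{pid}/{vc}", str(exc)))

    gsrs: list[GSRSResponse] = []
    for row in read("gsrs.csv"):
        pid, vc = row.get("participant_id"), row.get("visit_code")
        try:
            scores = [int(row[f"item_{i:02d}"]) for i in range(1, 16)
                      if row.get(f"item_{i:02d}", "") != ""]
            r = GSRSResponse(participant_id=pid, visit_code=vc, item_scores=scores)
            if r.participant_id not in pids:
                raise ValueError("unknown participant_id")
            gsrs.append(r)
        except (ValidationError, ValueError, KeyError) as exc:
            report.rejected.append((f"gsrs:{pid}/{vc}", str(exc)))

    bundle = CohortBundle(participants, visits, events, ffq, gsrs)
    report.n_accepted = {
        "participants": len(participants), "visits": len(visits),
        "recalls": len(events), "ffq": len(ffq), "gsrs": len(gsrs),
    }
    return bundle, report


def save_cohort(bundle: CohortBundle, data_dir: str | Path) -> None:
    """Write a bundle as the delimited files :func:`load_cohort` reads.

    ``load_cohort(save_cohort(b)) == b`` for valid bundles; output is
    deterministic (fixed column order, no float reformatting beyond repr).
    """
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)

    def write(name: str, cols: list[str], rows: list[dict]) -> None:
        with open(data_dir / name, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            w.writerows(rows)

    write("participants.csv",
          ["participant_id", "cohort", "sex", "age_years", "activity_level"],
          [{"participant_id": p.participant_id, "cohort": p.cohort.value,
            "sex": p.sex.value, "age_years": repr(p.age_years),
            "activity_level": p.activity_level.value}
           for p in bundle.participants])

    vcols = ["participant_id", "visit_code", "weight_kg", "height_m",
             "fat_mass_kg", "muscle_mass_kg", "waist_cm", "hip_cm",
             "measured_rmr_kcal", *BIOCHEM_ANALYTES]
    write("visits.csv", vcols,
          [{c: ("" if getattr(v, c if c not in ("visit_code",) else c) is None
                else (v.visit_code.value if c == "visit_code"
                      else repr(getattr(v, c)) if isinstance(getattr(v, c), float)
                      else getattr(v, c)))
            for c in vcols} for v in bundle.visits])

    write("recalls.csv",
          ["participant_id", "visit_code", "day_index", "day_type",
           "food_id", "amount_g"],
          [{"participant_id": e.participant_id, "visit_code": e.visit_code.value,
            "day_index": e.day_index, "day_type": e.day_type.value,
            "food_id": e.food_id, "amount_g": repr(e.amount_g)}
           for e in bundle.events])

    fcols = ["participant_id", "visit_code"]
    for g in SencGroup:
        fcols += [g.value, f"{g.value}_unit"]
    frows = []
    for r in bundle.ffq:
        row = {"participant_id": r.participant_id, "visit_code": r.visit_code.value}
        for g in SencGroup:
            if g in r.frequencies:
                row[g.value] = repr(r.frequencies[g])
                row[f"{g.value}_unit"] = r.units[g].value
            else:
                row[g.value] = ""
                row[f"{g.value}_unit"] = ""
        frows.append(row)
    write("ffq.csv", fcols, frows)

    gcols = ["participant_id", "visit_code"] + [f"item_{i:02d}" for i in range(1, 16)]
    write("gsrs.csv", gcols,
          [{"participant_id": r.participant_id, "visit_code": r.visit_code.value,
            **{f"item_{i:02d}": s for i, s in enumerate(r.item_scores, 1)}}
           for r in bundle.gsrs])
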