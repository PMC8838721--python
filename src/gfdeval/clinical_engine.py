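"""Anthropometric classification, biochemical range checks and GSRS
gastrointestinal symptom scoring.

BMI is classified with the WHO adult cut-offs (<18.5 underweight,
18.5-24.9 normal, 25-29.9 overweight, >30 obese) or, for children and
adolescents, by BMI-for-age percentile against a growth reference
(underweight below the 3rd percentile, normal from the 3rd to the 85th,
overweight from the 85th to the 95th, obese above the 95th). Cut-points
are inclusive to the heavier class except the strictly ">" obesity bound.

The GSRS questionnaire has 15 items scored 1 (no discomfort) to 7 (most
severe) across five sub-dimensions (reflux, abdominal pain, indigestion,
diarrhea, constipation). Sub-scores are means of their items, the total
the mean of all 15; a participant's symptom burden is additionally
categorised by the number of "marked" items (score above the no-discomfort
floor) into none / 1-5 / 6 or more.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import norm

from .records import (BIOCHEM_ANALYTES, Cohort, GSRS_SUBDIMENSIONS,
                      GSRSResponse, Participant, Sex, Visit, VisitCode)

__all__ = [
    "BMIClass", "BMIClassification", "GrowthReference", "classify_bmi",
    "GSRSResult", "SymptomCategory", "score_gsrs", "symptom_category_counts",
    "RangeCheck", "RangeStatus", "check_ranges", "default_growth_reference",
    "default_biochem_ranges",
]


class BMIClass(str, Enum):
    underweight = "underweight"
    normal = "normal"
    overweight = "overweight"
    obese = "obese"


@dataclass
class BMIClassification:
    bmi_kg_m2: float
    bmi_class: BMIClass
    basis: str                       # "who_adult" | "percentile_pediatric"
    percentile: Optional[float] = None


class GrowthReference:
    """BMI-for-age LMS reference table: columns sex, age_years, L, M, S.

    The packaged default is a synthetic table with plausible smooth curves
    (see its header comment); it is a stand-in so the pediatric pathway is
    runnable and testable offline — supply a published national reference
    for clinical work. L, M and S are interpolated linearly in age within
    sex; ages outside the table range clamp to the nearest tabulated age.
    """

    def __init__(self, rows: list[tuple[str, float, float, float, float]]):
        self._by_sex: dict[str, np.ndarray] = {}
        for sex in ("M", "F"):
            sub = sorted((r[1:] for r in rows if r[0] == sex))
            if not sub:
                raise ValueError(f"growth reference lacks sex {sex}")
            self._by_sex[sex] = np.array(sub)  # age, L, M, S

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthReference":
        rows = []
        with open(path, newline="", encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith("#"):
                fh.seek(0)
            for row in csv.DictReader(fh):
                rows.append((row["sex"], float(row["age_years"]), float(row["L"]),
                             float(row["M"]), float(row["S"])))
        return cls(rows)

    def lms(self, sex, age_years: float) -> tuple[float, float, float]:
        s = getattr(sex, "value", sex)
        tab = self._by_sex[s]
        age = float(np.clip(age_years, tab[0, 0], tab[-1, 0]))
        L = float(np.interp(age, tab[:, 0], tab[:, 1]))
        M = float(np.interp(age, tab[:, 0], tab[:, 2]))
        S = float(np.interp(age, tab[:, 0], tab[:, 3]))
        return L, M, S

    def percentile(self, sex, age_years: float, bmi: float) -> float:
        """BMI-for-age percentile via the LMS z-score."""
        L, M, S = self.lms(sex, age_years)
        if abs(L) < 1e-12:
            z = np.log(bmi / M) / S
        else:
            z = ((bmi / M) ** L - 1.0) / (L * S)
        return 100.0 * float(norm.cdf(z))

    def bmi_at_percentile(self, sex, age_years: float, pct: float) -> float:
        L, M, S = self.lms(sex, age_years)
        z = float(norm.ppf(pct / 100.0))
        if abs(L) < 1e-12:
            return M * float(np.exp(S * z))
        return M * (1.0 + L * S * z) ** (1.0 / L)


def default_growth_reference() -> GrowthReference:
    ref = resources.files("gfdeval.data").joinpath("bmi_lms_synthetic.csv")
    with resources.as_file(ref) as p:
        return GrowthReference.from_csv(p)


def classify_bmi(weight_kg: float, height_m: float, cohort: Cohort,
                 age_years: Optional[float] = None, sex: Optional[Sex] = None,
                 growth_reference: Optional[GrowthReference] = None) -> BMIClassification:
    """Classify BMI for an adult (WHO bands) or a child (percentile bands)."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    bmi = weight_kg / height_m ** 2
    cohort = Cohort(cohort)
    if cohort == Cohort.adult:
        if bmi < 18.5:
            cls = BMIClass.underweight
        elif bmi < 25:
            cls = BMIClass.normal
        elif bmi <= 30:          # obese strictly above 30
            cls = BMIClass.overweight
        else:
            cls = BMIClass.obese
        return BMIClassification(bmi, cls, "who_adult")
    if growth_reference is None:
        raise ValueError("pediatric classification requires a growth reference")
    if age_years is None or sex is None:
        raise ValueError("pediatric classification requires age and sex")
    pct = growth_reference.percentile(sex, age_years, bmi)
    eps = 1e-9                   # guard printed cut-offs against round-trip noise
    if pct < 3 - eps:
        cls = BMIClass.underweight
    elif pct < 85 - eps:
        cls = BMIClass.normal
    elif pct <= 95 + eps:        # obese strictly above the 95th percentile
        cls = BMIClass.overweight
    else:
        cls = BMIClass.obese
    return BMIClassification(bmi, cls, "percentile_pediatric", percentile=pct)


class SymptomCategory(str, Enum):
    none = "none"
    one_to_five = "one_to_five"
    six_plus = "six_plus"


@dataclass
class GSRSResult:
    participant_id: str
    visit_code: str
    subscores: dict[str, float]
    total_score: float
    marked_count: int
    symptom_category: SymptomCategory


def score_gsrs(resp: GSRSResponse, marked_threshold: int = 2) -> GSRSResult:
    """Score a GSRS questionnaire.

    Sub-dimension scores are means of their items and the total the mean
    of all 15 items. An item is "marked" when its score is at least
    ``marked_threshold`` (default 2: any discomfort above the scale
    floor); the marked count is categorised none / 1-5 / 6+.
    """
    scores = resp.item_scores
    subs = {dim: sum(scores[i - 1] for i in items) / len(items)
            for dim, items in GSRS_SUBDIMENSIONS.items()}
    total = sum(scores) / 15.0
    marked = sum(1 for s in scores if s >= marked_threshold)
    if marked == 0:
        cat = SymptomCategory.none
    elif marked <= 5:
        cat = SymptomCategory.one_to_five
    else:
        cat = SymptomCategory.six_plus
    return GSRSResult(resp.participant_id, resp.visit_code.value,
                      subs, total, marked, cat)


def symptom_category_counts(results: list[GSRSResult]) -> dict[SymptomCategory, int]:
    """Counts per symptom category; always partitions the input cohort."""
    counts = {c: 0 for c in SymptomCategory}
    for r in results:
        counts[r.symptom_category] += 1
    return counts


class RangeStatus(str, Enum):
    below = "below"
    within = "within"
    above = "above"


@dataclass
class RangeCheck:
    analyte: str
    value: float
    low: float
    high: float
    status: RangeStatus


def default_biochem_ranges() -> dict[str, dict[str, float]]:
    import yaml
    ref = resources.files("gfdeval.data").joinpath("biochem_ranges.yaml")
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


def check_ranges(visit: Visit,
                 reference: Optional[dict[str, dict[str, float]]] = None
                 ) -> list[RangeCheck]:
    """Compare each measured analyte on a visit to its reference range.

    Reference intervals are closed: a value at either bound is ``within``.
    Missing analytes are skipped.
    """
    reference = reference if reference is not None else default_biochem_ranges()
    out: list[RangeCheck] = []
    for analyte in BIOCHEM_ANALYTES:
        value = getattr(visit, analyte)
        if value is None or analyte not in reference:
            continue
        if value < 0:
            raise ValueError(f"{analyte}: negative value {value}")
        low, high = reference[analyte]["low"], reference[analyte]["high"]
        if value < low:
            status = RangeStatus.below
        elif value > high:
            status = RangeStatus.above
        else:
            status = RangeStatus.within
        out.append(RangeCheck(analyte, value, low, high, status))
    return out
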