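"""Energy, macronutrient, fibre and cholesterol intake from 24-h recalls,
with adequacy against Spanish dietary reference intakes (FESNAD) and SENC
food-group frequency recommendations.

Two energy denominators are reported for %E shares:

* ``*_pctE`` — Atwater-derived energy (4/9/4 kcal per g of protein/lipid/
  carbohydrate, alcohol 7 kcal/g when present). Protein + lipid + carb
  shares close to 100% by construction, which makes the shares testable.
* ``*_pctE_food`` — the composition table's energy field as denominator.
  Food-table energies normally also count fibre (2 kcal/g), so these
  shares match how published intake tables report macronutrient
  distribution and need not sum to 100.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .food_db import FoodTable
from .records import (ACTIVITY_FACTORS, Cohort, DayType, FFQResponse,
                      FreqUnit, IntakeEvent, Participant, SencGroup, Visit)

__all__ = [
    "ATWATER", "NutrientProfile", "RecommendationSet", "Flag",
    "nutrient_profile", "energy_expenditure", "schofield_rmr",
    "adequacy", "ffq_adequacy", "daily_mean",
]

#: Atwater energy-conversion factors, kcal per gram.
ATWATER = {"protein": 4.0, "lipid": 9.0, "carb": 4.0, "alcohol": 7.0}


class Flag(str, Enum):
    low = "low"
    adequate = "adequate"
    high = "high"


@dataclass
class NutrientProfile:
    """Per-participant-visit daily means over the 3 recall days."""

    participant_id: str
    visit_code: str
    energy_kcal_day: float              # composition-table energy
    energy_atwater_kcal_day: float      # 4/9/4 energy from the same grams
    protein_g_day: float
    lipid_g_day: float
    sfa_g_day: float
    carb_g_day: float
    sugars_g_day: float
    fibre_g_day: float
    cholesterol_mg_day: float
    protein_pctE: float
    lipid_pctE: float
    sfa_pctE: float
    carb_pctE: float
    sugars_pctE: float
    protein_pctE_food: float
    lipid_pctE_food: float
    sfa_pctE_food: float
    carb_pctE_food: float
    sugars_pctE_food: float
    energy_expenditure_kcal_day: Optional[float] = None
    incomplete: bool = False
    n_days: int = 0
    adequacy_flags: dict[str, Flag] = field(default_factory=dict)


# SENC food-group frequency bands: (low, high, unit); high=None means
# "at least", low=None means "less than" (upper bound exclusive).
_SENC_BANDS: dict[SencGroup, tuple[Optional[float], Optional[float], FreqUnit]] = {
    SencGroup.dairy: (2, 4, FreqUnit.per_day),
    SencGroup.cereals: (4, 6, FreqUnit.per_day),
    SencGroup.vegetables: (2, None, FreqUnit.per_day),
    SencGroup.fruits: (3, None, FreqUnit.per_day),
    SencGroup.oils: (3, 6, FreqUnit.per_day),
    SencGroup.meat: (3, 4, FreqUnit.per_week),
    SencGroup.fish: (3, 4, FreqUnit.per_week),
    SencGroup.eggs: (3, 4, FreqUnit.per_week),
    SencGroup.legumes: (2, 4, FreqUnit.per_week),
    SencGroup.nuts: (3, 7, FreqUnit.per_week),
    SencGroup.pastries: (None, 1, FreqUnit.per_week),
}


@dataclass
class RecommendationSet:
    """FESNAD/SENC reference values for a balanced diet."""

    protein_pctE: float = 12.5
    lipid_pctE: float = 32.5
    carb_pctE: float = 55.0
    sfa_pctE_max: float = 10.0
    sugars_pctE_max: float = 10.0
    fibre_g_low: float = 25.0
    fibre_g_high: float = 35.0
    fibre_g_per_1000kcal: float = 14.0
    cholesterol_mg_max: float = 300.0
    energy_ee_tolerance: float = 0.20      # adequate within EE +/- 20%
    point_tolerance_pctE: float = 2.5      # band around point %E targets
    senc_bands: dict = field(default_factory=lambda: dict(_SENC_BANDS))


def daily_mean(day_totals: dict[int, float], day_types: dict[int, DayType],
               weighted: bool = False) -> float:
    """Mean over recall days. Unweighted by default; with ``weighted=True``
    weekdays carry 5/7 and the weekend day 2/7 of the week."""
    if not day_totals:
        return 0.0
    if not weighted:
        return sum(day_totals.values()) / len(day_totals)
    w = {d: (5 / 7 / 2 if day_types[d] == DayType.weekday else 2 / 7)
         for d in day_totals}
    tot_w = sum(w.values())
    return sum(day_totals[d] * w[d] for d in day_totals) / tot_w


_GRAM_FIELDS = {
    "energy": "energy_kcal_100g", "protein": "protein_g_100g",
    "carb": "carb_g_100g", "sugars": "sugars_g_100g",
    "lipid": "lipid_g_100g", "sfa": "sfa_g_100g",
    "fibre": "fibre_g_100g", "cholesterol": "cholesterol_mg_100g",
}


def nutrient_profile(events: list[IntakeEvent], foods: FoodTable,
                     weighted_days: bool = False,
                     energy_expenditure_kcal: Optional[float] = None) -> NutrientProfile:
    """Compute the daily nutrient profile for one participant-visit.

    Each nutrient's daily total is sum(amount_g * per-100g / 100) over the
    day's events; daily means are taken over the 3 recall days. A visit
    with fewer than 3 recall days (or a day without events) is flagged
    ``incomplete`` and should be excluded from cohort means.
    """
    if not events:
        raise ValueError("no intake events supplied")
    pid = events[0].participant_id
    vc = events[0].visit_code
    if any(e.participant_id != pid or e.visit_code != vc for e in events):
        raise ValueError("events span multiple participant-visits")

    day_types: dict[int, DayType] = {}
    day_sums: dict[str, dict[int, float]] = {k: {} for k in _GRAM_FIELDS}
    for e in events:
        food = foods[e.food_id]
        day_types[e.day_index] = e.day_type
        for k, attr in _GRAM_FIELDS.items():
            day_sums[k][e.day_index] = (day_sums[k].get(e.day_index, 0.0)
                                        + e.amount_g * getattr(food, attr) / 100.0)

    n_days = len(day_types)
    means = {k: daily_mean(day_sums[k], day_types, weighted_days)
             for k in _GRAM_FIELDS}

    e_atw = (ATWATER["protein"] * means["protein"]
             + ATWATER["lipid"] * means["lipid"]
             + ATWATER["carb"] * means["carb"])
    e_food = means["energy"]

    def pct(kcal: float, denom: float) -> float:
        return 100.0 * kcal / denom if denom > 0 else 0.0

    return NutrientProfile(
        participant_id=pid, visit_code=vc.value,
        energy_kcal_day=e_food, energy_atwater_kcal_day=e_atw,
        protein_g_day=means["protein"], lipid_g_day=means["lipid"],
        sfa_g_day=means["sfa"], carb_g_day=means["carb"],
        sugars_g_day=means["sugars"], fibre_g_day=means["fibre"],
        cholesterol_mg_day=means["cholesterol"],
        protein_pctE=pct(4 * means["protein"], e_atw),
        lipid_pctE=pct(9 * means["lipid"], e_atw),
        sfa_pctE=pct(9 * means["sfa"], e_atw),
        carb_pctE=pct(4 * means["carb"], e_atw),
        sugars_pctE=pct(4 * means["sugars"], e_atw),
        protein_pctE_food=pct(4 * means["protein"], e_food),
        lipid_pctE_food=pct(9 * means["lipid"], e_food),
        sfa_pctE_food=pct(9 * means["sfa"], e_food),
        carb_pctE_food=pct(4 * means["carb"], e_food),
        sugars_pctE_food=pct(4 * means["sugars"], e_food),
        energy_expenditure_kcal_day=energy_expenditure_kcal,
        incomplete=(n_days < 3 or e_food <= 0),
        n_days=n_days,
    )


def schofield_rmr(sex, age_years: float, weight_kg: float) -> float:
    """Schofield weight-based resting metabolic rate, kcal/day.

    WHO age/sex bands; the standard predictive equation family covering
    children, adolescents and adults.
    """
    s = getattr(sex, "value", sex)
    w = weight_kg
    if age_years < 3:
        return 59.512 * w - 30.4 if s == "M" else 58.317 * w - 31.1
    if age_years < 10:
        return 22.706 * w + 504.3 if s == "M" else 20.315 * w + 485.9
    if age_years < 18:
        return 17.686 * w + 658.2 if s == "M" else 13.384 * w + 692.6
    if age_years < 30:
        return 15.057 * w + 692.2 if s == "M" else 14.818 * w + 486.6
    if age_years < 60:
        return 11.472 * w + 873.1 if s == "M" else 8.126 * w + 845.6
    return 11.711 * w + 587.7 if s == "M" else 9.082 * w + 658.5


def energy_expenditure(participant: Participant, visit: Visit) -> float:
    """Daily energy expenditure = RMR x activity-level factor.

    Uses the impedance-measured RMR when recorded on the visit, otherwise
    the Schofield predictive equation from sex, age and weight.
    """
    if visit.measured_rmr_kcal is not None:
        rmr = visit.measured_rmr_kcal
    else:
        if visit.weight_kg is None:
            raise ValueError("no measured RMR and no anthropometry")
        rmr = schofield_rmr(participant.sex, participant.age_years, visit.weight_kg)
    return rmr * ACTIVITY_FACTORS[participant.activity_level]


def adequacy(profile: NutrientProfile,
             rec: RecommendationSet | None = None) -> dict[str, Flag]:
    """Flag each profile component low / adequate / high.

    Point %E targets (protein, lipids, carbohydrates) use a +/-2.5 %E band
    around the reference; bounded targets (SFA and sugars <10 %E,
    cholesterol <300 mg) flag by their bound; fibre is adequate if within
    the 25-35 g band OR at >=14 g per 1000 kcal; energy is adequate within
    +/-20% of estimated expenditure (when expenditure is available).
    """
    rec = rec or RecommendationSet()
    if profile.incomplete:
        raise ValueError("profile incomplete; adequacy not defined")
    flags: dict[str, Flag] = {}

    def point(value: float, target: float) -> Flag:
        if value < target - rec.point_tolerance_pctE:
            return Flag.low
        if value > target + rec.point_tolerance_pctE:
            return Flag.high
        return Flag.adequate

    flags["protein"] = point(profile.protein_pctE, rec.protein_pctE)
    flags["lipid"] = point(profile.lipid_pctE, rec.lipid_pctE)
    flags["carb"] = point(profile.carb_pctE, rec.carb_pctE)
    flags["sfa"] = Flag.high if profile.sfa_pctE >= rec.sfa_pctE_max else Flag.adequate
    flags["sugars"] = (Flag.high if profile.sugars_pctE >= rec.sugars_pctE_max
                       else Flag.adequate)
    flags["cholesterol"] = (Flag.high
                            if profile.cholesterol_mg_day >= rec.cholesterol_mg_max
                            else Flag.adequate)

    f = profile.fibre_g_day
    density_ok = (profile.energy_kcal_day > 0
                  and f >= rec.fibre_g_per_1000kcal * profile.energy_kcal_day / 1000.0)
    if rec.fibre_g_low <= f <= rec.fibre_g_high or density_ok:
        flags["fibre"] = Flag.adequate
    elif f < rec.fibre_g_low:
        flags["fibre"] = Flag.low
    else:
        flags["fibre"] = Flag.high

    ee = profile.energy_expenditure_kcal_day
    if ee is not None and ee > 0:
        lo, hi = ee * (1 - rec.energy_ee_tolerance), ee * (1 + rec.energy_ee_tolerance)
        if profile.energy_kcal_day < lo:
            flags["energy"] = Flag.low
        elif profile.energy_kcal_day > hi:
            flags["energy"] = Flag.high
        else:
            flags["energy"] = Flag.adequate

    profile.adequacy_flags = flags
    return flags


def ffq_adequacy(ffq: FFQResponse,
                 rec: RecommendationSet | None = None) -> dict[SencGroup, Flag]:
    """Flag each food group's frequency below / within / above the SENC
    recommended portion band, honouring per-day vs per-week conventions."""
    rec = rec or RecommendationSet()
    flags: dict[SencGroup, Flag] = {}
    for group, value in ffq.frequencies.items():
        if group not in rec.senc_bands:
            continue
        low, high, unit = rec.senc_bands[group]
        if ffq.units[group] != unit:
            raise ValueError(
                f"{group.value}: frequency reported {ffq.units[group].value} but "
                f"the recommendation is {unit.value}")
        if low is not None and value < low:
            flags[group] = Flag.low
        elif high is not None and (value >= high if low is None else value > high):
            # bands with no lower bound are "< high" (e.g. pastries < 1/week)
            flags[group] = Flag.high
        else:
            flags[group] = Flag.adequate
    return flags
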