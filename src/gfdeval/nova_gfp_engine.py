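"""NOVA processing-group consumption and gluten-free-product (GFP) energy
contribution.

NOVA groups foods by degree of industrial processing (G1 unprocessed or
minimally processed, G2 processed culinary ingredients, G3 processed, G4
ultra-processed). GFP are manufactured gluten-free rendered foods (bread,
pasta, biscuits, ...) whose energy share of the total diet is a marker of
reliance on ultra-processed substitutes in a gluten-free diet.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .food_db import FoodTable, GFPCategory, NovaGroup
from .intake_engine import daily_mean
from .records import DayType, IntakeEvent, portions_from_grams

__all__ = ["NOVAProfile", "GFPProfile", "nova_profile", "gfp_energy_contribution"]


@dataclass
class NOVAProfile:
    participant_id: str
    visit_code: str
    portions_day: dict[NovaGroup, float]
    energy_kcal_day: dict[NovaGroup, float]

    @property
    def total_portions_day(self) -> float:
        return sum(self.portions_day.values())

    @property
    def total_energy_kcal_day(self) -> float:
        return sum(self.energy_kcal_day.values())


@dataclass
class GFPProfile:
    participant_id: str
    visit_code: str
    gfp_pctE: float                         # % of total energy from GFP
    category_pctE: dict[GFPCategory, float]  # per GFP category, same denominator
    top_g4_contributors: list[tuple[str, float]]  # (label, % of G4 energy)
    method: str = "pooled"


def nova_profile(events: list[IntakeEvent], foods: FoodTable,
                 weighted_days: bool = False) -> NOVAProfile:
    """Portions/day and kcal/day per NOVA group (daily means over the 3
    recall days). Order-invariant in the event list."""
    if not events:
        raise ValueError("no intake events supplied")
    pid, vc = events[0].participant_id, events[0].visit_code
    day_types: dict[int, DayType] = {}
    portions: dict[NovaGroup, dict[int, float]] = {g: {} for g in NovaGroup}
    energy: dict[NovaGroup, dict[int, float]] = {g: {} for g in NovaGroup}
    for e in events:
        food = foods[e.food_id]
        g = food.nova_group
        day_types.setdefault(e.day_index, e.day_type)
        portions[g][e.day_index] = (portions[g].get(e.day_index, 0.0)
                                    + portions_from_grams(e, food))
        energy[g][e.day_index] = (energy[g].get(e.day_index, 0.0)
                                  + e.amount_g * food.energy_kcal_100g / 100.0)
    all_days = dict.fromkeys(day_types, 0.0)
    return NOVAProfile(
        participant_id=pid, visit_code=vc.value,
        portions_day={g: daily_mean({**all_days, **portions[g]}, day_types,
                                    weighted_days) for g in NovaGroup},
        energy_kcal_day={g: daily_mean({**all_days, **energy[g]}, day_types,
                                       weighted_days) for g in NovaGroup},
    )


def gfp_energy_contribution(events: list[IntakeEvent], foods: FoodTable,
                            method: str = "pooled") -> GFPProfile:
    """GFP share of total energy intake for one participant-visit.

    ``pooled`` (default) is the ratio of summed energies over all 3 recall
    days (stable to low-energy days); ``mean_of_days`` averages the three
    daily percentages instead. The per-category split uses the same
    denominator, so category shares sum to the overall GFP share. Also
    ranks the composition of ultra-processed (G4) energy by label (GFP
    foods under "GFP", other G4 foods under their SENC group).
    """
    if not events:
        raise ValueError("no intake events supplied")
    if method not in ("pooled", "mean_of_days"):
        raise ValueError(f"unknown method {method!r}")
    pid, vc = events[0].participant_id, events[0].visit_code

    day_total: dict[int, float] = {}
    day_gfp: dict[int, float] = {}
    cat_kcal: dict[GFPCategory, float] = {}
    g4_label_kcal: dict[str, float] = {}
    for e in events:
        food = foods[e.food_id]
        kcal = e.amount_g * food.energy_kcal_100g / 100.0
        day_total[e.day_index] = day_total.get(e.day_index, 0.0) + kcal
        if food.is_gfp:
            day_gfp[e.day_index] = day_gfp.get(e.day_index, 0.0) + kcal
            cat_kcal[food.gfp_category] = cat_kcal.get(food.gfp_category, 0.0) + kcal
        if food.nova_group == NovaGroup.G4:
            label = "GFP" if food.is_gfp else food.senc_group.value
            g4_label_kcal[label] = g4_label_kcal.get(label, 0.0) + kcal

    total = sum(day_total.values())
    if total <= 0:
        raise ValueError("zero total energy")

    if method == "pooled":
        gfp_pct = 100.0 * sum(day_gfp.values()) / total
        cat_pct = {c: 100.0 * k / total for c, k in cat_kcal.items()}
    else:
        pcts = [100.0 * day_gfp.get(d, 0.0) / day_total[d]
                for d in day_total if day_total[d] > 0]
        gfp_pct = sum(pcts) / len(pcts)
        # per-category split kept on the pooled denominator, rescaled so the
        # categories still sum to the reported overall share
        pooled = 100.0 * sum(day_gfp.values()) / total
        scale = gfp_pct / pooled if pooled > 0 else 0.0
        cat_pct = {c: 100.0 * k / total * scale for c, k in cat_kcal.items()}

    g4_total = sum(g4_label_kcal.values())
    ranking = sorted(
        ((lbl, 100.0 * k / g4_total) for lbl, k in g4_label_kcal.items()),
        key=lambda t: (-t[1], t[0])) if g4_total > 0 else []

    return GFPProfile(participant_id=pid, visit_code=vc.value,
                      gfp_pctE=gfp_pct, category_pctE=cat_pct,
                      top_g4_contributors=ranking, method=method)
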