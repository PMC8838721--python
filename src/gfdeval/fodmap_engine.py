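"""Daily FODMAP intake per participant-visit.

Compounds quantified: fructose, glucose, excess fructose (fructose minus
glucose, floored at zero — the fraction absorbed poorly), lactose, total
fructans, inulin, the polyols sorbitol and mannitol and the
galacto-oligosaccharides raffinose and stachyose.

Composition coverage is uneven across data sources, so missing values are
skipped (never counted as zero) and each profile carries a
``coverage_fraction``: the share of consumed grams whose food has any
known FODMAP composition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .food_db import FODMAP_FIELDS, FoodTable, resolve_fructan
from .intake_engine import daily_mean
from .records import DayType, IntakeEvent

__all__ = ["FODMAPProfile", "fodmap_profile", "excess_fructose",
           "total_fodmap", "COMPOUNDS"]

COMPOUNDS = ("fructose", "glucose", "lactose", "sorbitol", "mannitol",
             "raffinose", "stachyose", "fructans", "inulin")

_FIELD_OF = {c: f"{c}_g_100g" for c in COMPOUNDS if c not in ("fructans",)}
_FIELD_OF["inulin"] = "inulin_g_100g"


@dataclass
class FODMAPProfile:
    participant_id: str
    visit_code: str
    g_day: dict[str, float]                 # per compound, daily mean
    excess_fructose_g_day: float
    total_fodmap_g_day: float               # default mode (see total_fodmap)
    total_fodmap_table_g_day: float         # "as_table5" row-sum mode
    coverage_fraction: float
    low_coverage: bool = False
    netting: str = "per_item"

    def __post_init__(self):
        assert self.excess_fructose_g_day <= self.g_day.get("fructose", 0.0) + 1e-9


def excess_fructose(fructose_g: float, glucose_g: float) -> float:
    """Fructose in excess of glucose, floored at zero."""
    if fructose_g < 0 or glucose_g < 0:
        raise ValueError("negative sugar content")
    return max(0.0, fructose_g - glucose_g)


def total_fodmap(g_day: dict[str, float], excess_fructose_g: float,
                 mode: str = "excess") -> float:
    """Total daily FODMAP load.

    ``excess`` (default): excess fructose + lactose + fructans + sorbitol +
    mannitol + raffinose + stachyose, where the fructan term is the
    per-food resolved value (inulin already stands in when it is the only
    fructan datum, so inulin is never double-counted).

    ``as_table5``: plain sum of the reported compound rows — fructose,
    glucose, raw total fructan, lactose, inulin, mannitol, raffinose,
    stachyose, sorbitol — mirroring published consumption tables that list
    fructose and glucose (and fructans and inulin) as separate rows.
    """
    if mode == "excess":
        return (excess_fructose_g + g_day["lactose"] + g_day["fructans"]
                + g_day["sorbitol"] + g_day["mannitol"]
                + g_day["raffinose"] + g_day["stachyose"])
    if mode == "as_table5":
        return (g_day["fructose"] + g_day["glucose"] + g_day["fructans_raw"]
                + g_day["lactose"] + g_day["inulin"] + g_day["mannitol"]
                + g_day["raffinose"] + g_day["stachyose"] + g_day["sorbitol"])
    raise ValueError(f"unknown total mode {mode!r}")


def fodmap_profile(events: list[IntakeEvent], foods: FoodTable,
                   netting: str = "per_item", coverage_floor: float = 0.5,
                   weighted_days: bool = False,
                   fructan_overrides: dict | None = None) -> FODMAPProfile:
    """Compute the daily FODMAP profile for one participant-visit.

    Per-compound g/day = sum(amount_g x per-100g / 100) per day, averaged
    over the 3 recall days, skipping foods whose value for that compound
    is missing. Fructans use the source-priority resolution (laboratory
    assay > literature > inulin floor). Excess fructose is netted per food
    item by default (a glucose-rich food cannot offset a fructose-rich
    one); ``netting="per_day"`` nets the daily totals instead.
    """
    if not events:
        raise ValueError("no intake events supplied")
    if netting not in ("per_item", "per_day"):
        raise ValueError(f"unknown netting {netting!r}")
    pid, vc = events[0].participant_id, events[0].visit_code

    day_types: dict[int, DayType] = {}
    day_sums: dict[str, dict[int, float]] = {
        **{c: {} for c in COMPOUNDS}, "fructans_raw": {}, "excess_fructose": {}}
    grams_total = 0.0
    grams_known = 0.0

    for e in events:
        fod = foods[e.food_id].fodmap
        day_types.setdefault(e.day_index, e.day_type)
        grams_total += e.amount_g
        if fod.has_any_data:
            grams_known += e.amount_g
        for c, fld in _FIELD_OF.items():
            v = getattr(fod, fld)
            if v is not None:
                day_sums[c][e.day_index] = (day_sums[c].get(e.day_index, 0.0)
                                            + e.amount_g * v / 100.0)
        res = resolve_fructan(fod, fructan_overrides)
        if res.value is not None:
            day_sums["fructans"][e.day_index] = (
                day_sums["fructans"].get(e.day_index, 0.0)
                + e.amount_g * res.value / 100.0)
        if fod.total_fructan_g_100g is not None:
            day_sums["fructans_raw"][e.day_index] = (
                day_sums["fructans_raw"].get(e.day_index, 0.0)
                + e.amount_g * fod.total_fructan_g_100g / 100.0)
        if fod.fructose_g_100g is not None and fod.glucose_g_100g is not None:
            ex = excess_fructose(fod.fructose_g_100g, fod.glucose_g_100g)
            day_sums["excess_fructose"][e.day_index] = (
                day_sums["excess_fructose"].get(e.day_index, 0.0)
                + e.amount_g * ex / 100.0)

    # make every compound's daily mean average over the full set of recall
    # days (a day with no known source of a compound contributes 0 to it)
    all_days = dict.fromkeys(day_types, 0.0)
    g_day = {}
    for c in (*COMPOUNDS, "fructans_raw", "excess_fructose"):
        totals = {**all_days, **day_sums[c]}
        g_day[c] = daily_mean(totals, day_types, weighted_days)

    if netting == "per_item":
        ex = g_day["excess_fructose"]
    else:
        per_day = {d: excess_fructose(day_sums["fructose"].get(d, 0.0),
                                      day_sums["glucose"].get(d, 0.0))
                   for d in day_types}
        ex = daily_mean(per_day, day_types, weighted_days)
    ex = min(ex, g_day["fructose"])  # guard against per-day/per-item edge rounding

    coverage = grams_known / grams_total if grams_total > 0 else 0.0
    compounds_only = {c: g_day[c] for c in COMPOUNDS}
    return FODMAPProfile(
        participant_id=pid, visit_code=vc.value,
        g_day={**compounds_only, "fructans_raw": g_day["fructans_raw"]},
        excess_fructose_g_day=ex,
        total_fodmap_g_day=total_fodmap({**compounds_only}, ex, mode="excess"),
        total_fodmap_table_g_day=total_fodmap(
            {**compounds_only, "fructans_raw": g_day["fructans_raw"]},
            ex, mode="as_table5"),
        coverage_fraction=coverage,
        low_coverage=coverage < coverage_floor,
        netting=netting,
    )
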