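"""Synthetic celiac cohorts with known ground truth.

The generator emulates the study design this package targets: an adult
and a pediatric arm, visits at diagnosis and after 3 and 12 months on a
gluten-free diet (vt0/vt3/vt12) with substantial dropout, 3-day 24-h
recalls per visit (two weekdays + one weekend day), an FFQ at vt0 and
vt12, and a 15-item GSRS questionnaire per visit.

Recall records are constructed backwards from planted targets: for each
participant-visit the generator jitters the arm-visit targets (energy,
%E macronutrient split, gluten-free-product energy share, NOVA portion
mix, total FODMAP load), samples a realistic food set from the fixture
composition table, and solves a non-negative least-squares system for
gram amounts so that every planted target holds on every recall day.
Fibre is the energy-closure slack: food energy follows the convention
4*protein + 9*lipid + 4*carb + 2*fibre kcal per 100 g, so a %E split
summing below 100 leaves the remainder to fibre.

The ground truth records, for every participant-visit, both the nominal
planted values and the achieved values recomputed by direct per-event
summation (a deliberately simple, engine-independent bookkeeping pass).
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import lsq_linear

from .food_db import FoodTable, NovaGroup, default_food_table
from .records import (ActivityLevel, Cohort, CohortBundle, DayType,
                      FFQResponse, FreqUnit, GSRSResponse, IntakeEvent,
                      Participant, SencGroup, Sex, Visit, VisitCode)
from .intake_engine import schofield_rmr

__all__ = ["VisitTargets", "CohortSpec", "GroundTruth", "generate", "perturb",
           "study_design_spec", "InfeasibleSpec"]

VISITS = (VisitCode.vt0, VisitCode.vt3, VisitCode.vt12)


class InfeasibleSpec(ValueError):
    """Planted targets are mutually inconsistent."""


class VisitTargets(BaseModel):
    """Planted targets for one arm at one visit.

    %E shares are of the food-table energy; protein + lipid + carb must
    stay below 100, the remainder being supplied by fibre at 2 kcal/g.
    ``fodmap_total_g`` is in the row-sum ("as_table5") accounting.
    """

    energy_kcal: float = Field(gt=0)
    energy_sd_kcal: float = Field(ge=0)
    protein_pctE: float = Field(gt=0)
    lipid_pctE: float = Field(gt=0)
    carb_pctE: float = Field(gt=0)
    gfp_energy_pct: float = Field(ge=0, le=100)
    nova_portions: tuple[float, float, float, float]  # G1..G4 portions/day
    fodmap_total_g: float = Field(ge=0)
    gsrs_category_props: tuple[float, float, float] = (0.25, 0.45, 0.30)
    ffq_freq: dict[SencGroup, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _feasible(self) -> "VisitTargets":
        s = self.protein_pctE + self.lipid_pctE + self.carb_pctE
        if not 90.0 <= s < 100.0:
            raise InfeasibleSpec(
                f"%E split sums to {s:.1f}; must lie in [90, 100) so that "
                "fibre can close the energy balance")
        if any(n < 0 for n in self.nova_portions):
            raise InfeasibleSpec("negative NOVA portion target")
        if abs(sum(self.gsrs_category_props) - 1.0) > 1e-6:
            raise InfeasibleSpec("GSRS category proportions must sum to 1")
        return self


# Arm-and-visit default targets: the cohort means reported for the study
# population (energy/macronutrient distribution, GFP energy share, NOVA
# portion mix, FODMAP row-sum totals, FFQ food-group frequencies).
_FFQ_ADULT = {SencGroup.dairy: 2.6, SencGroup.cereals: 2.6,
              SencGroup.vegetables: 1.3, SencGroup.fruits: 2.3,
              SencGroup.oils: 2.5, SencGroup.meat: 6.2, SencGroup.fish: 3.5,
              SencGroup.eggs: 2.9, SencGroup.legumes: 1.9,
              SencGroup.nuts: 2.6, SencGroup.pastries: 0.8}
_FFQ_ADULT_12 = {SencGroup.dairy: 3.2, SencGroup.cereals: 2.7,
                 SencGroup.vegetables: 2.0, SencGroup.fruits: 2.2,
                 SencGroup.oils: 2.7, SencGroup.meat: 4.5, SencGroup.fish: 4.3,
                 SencGroup.eggs: 3.0, SencGroup.legumes: 1.7,
                 SencGroup.nuts: 2.2, SencGroup.pastries: 0.3}
_FFQ_CHILD = {SencGroup.dairy: 2.7, SencGroup.cereals: 3.8,
              SencGroup.vegetables: 0.8, SencGroup.fruits: 1.7,
              SencGroup.oils: 2.1, SencGroup.meat: 7.2, SencGroup.fish: 3.1,
              SencGroup.eggs: 2.7, SencGroup.legumes: 2.6,
              SencGroup.nuts: 1.3, SencGroup.pastries: 1.3}
_FFQ_CHILD_12 = {SencGroup.dairy: 2.5, SencGroup.cereals: 2.7,
                 SencGroup.vegetables: 0.9, SencGroup.fruits: 2.0,
                 SencGroup.oils: 2.4, SencGroup.meat: 6.5, SencGroup.fish: 3.4,
                 SencGroup.eggs: 2.8, SencGroup.legumes: 2.5,
                 SencGroup.nuts: 1.1, SencGroup.pastries: 1.8}

_DEFAULT_TARGETS: dict[str, dict[str, dict]] = {
    "adult": {
        "vt0": dict(energy_kcal=1968.4, energy_sd_kcal=607.4,
                    protein_pctE=16.3, lipid_pctE=41.1, carb_pctE=40.5,
                    gfp_energy_pct=23.7, nova_portions=(6.3, 2.8, 1.4, 5.0),
                    fodmap_total_g=32.8,
                    gsrs_category_props=(0.25, 0.45, 0.30), ffq_freq=_FFQ_ADULT),
        "vt3": dict(energy_kcal=2079.7, energy_sd_kcal=474.0,
                    protein_pctE=19.6, lipid_pctE=36.6, carb_pctE=42.5,
                    gfp_energy_pct=18.9, nova_portions=(7.2, 3.2, 1.5, 4.3),
                    fodmap_total_g=45.1,
                    gsrs_category_props=(0.45, 0.40, 0.15)),
        "vt12": dict(energy_kcal=1944.0, energy_sd_kcal=97.7,
                     protein_pctE=19.8, lipid_pctE=40.6, carb_pctE=36.3,
                     gfp_energy_pct=21.4, nova_portions=(8.2, 3.8, 1.8, 3.7),
                     fodmap_total_g=42.3,
                     gsrs_category_props=(0.35, 0.40, 0.25),
                     ffq_freq=_FFQ_ADULT_12),
    },
    "pediatric": {
        "vt0": dict(energy_kcal=1867.5, energy_sd_kcal=517.4,
                    protein_pctE=16.3, lipid_pctE=41.3, carb_pctE=40.2,
                    gfp_energy_pct=17.4, nova_portions=(5.6, 3.4, 1.1, 6.1),
                    fodmap_total_g=39.4,
                    gsrs_category_props=(0.20, 0.45, 0.35), ffq_freq=_FFQ_CHILD),
        "vt3": dict(energy_kcal=2194.2, energy_sd_kcal=393.5,
                    protein_pctE=20.3, lipid_pctE=36.0, carb_pctE=42.7,
                    gfp_energy_pct=18.8, nova_portions=(6.8, 4.4, 1.1, 5.9),
                    fodmap_total_g=38.2,
                    gsrs_category_props=(0.50, 0.38, 0.12)),
        "vt12": dict(energy_kcal=1944.0, energy_sd_kcal=97.7,
                     protein_pctE=19.8, lipid_pctE=40.6, carb_pctE=36.3,
                     gfp_energy_pct=21.4, nova_portions=(7.1, 3.5, 1.1, 5.9),
                     fodmap_total_g=41.8,
                     gsrs_category_props=(0.40, 0.40, 0.20),
                     ffq_freq=_FFQ_CHILD_12),
    },
}


class CohortSpec(BaseModel):
    """Study-design description for the generator."""

    seed: int = 0
    adults_per_visit: tuple[int, int, int] = (27, 13, 4)
    children_per_visit: tuple[int, int, int] = (31, 22, 16)
    targets: dict[str, dict[str, VisitTargets]] = Field(
        default_factory=lambda: {
            arm: {vc: VisitTargets(**tv) for vc, tv in per.items()}
            for arm, per in _DEFAULT_TARGETS.items()})
    jitter_pctE_sd: float = 1.0
    jitter_gfp_sd: float = 2.0
    jitter_nova_rel_sd: float = 0.08
    jitter_fodmap_rel_sd: float = 0.12

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        for counts in (self.adults_per_visit, self.children_per_visit):
            if not counts[0] >= counts[1] >= counts[2] >= 0:
                raise InfeasibleSpec("per-visit counts must be non-increasing")
        for arm in ("adult", "pediatric"):
            if arm not in self.targets:
                raise InfeasibleSpec(f"missing targets for arm {arm}")
        return self


@dataclass
class PlantedValues:
    """Nominal per-participant-visit planted targets (after jitter) and the
    achieved values recomputed by plain per-event summation."""

    planted: dict[str, float]
    achieved: dict[str, float]


@dataclass
class GroundTruth:
    spec: CohortSpec
    values: dict[tuple[str, str], PlantedValues] = dc_field(default_factory=dict)
    gsrs_planted_category: dict[tuple[str, str], str] = dc_field(default_factory=dict)

    def planted_mean(self, arm_prefix: str, visit: str, key: str) -> float:
        vals = [pv.planted[key] for (pid, vc), pv in self.values.items()
                if vc == visit and pid.startswith(arm_prefix)]
        return float(np.mean(vals))

    def achieved_mean(self, arm_prefix: str, visit: str, key: str) -> float:
        vals = [pv.achieved[key] for (pid, vc), pv in self.values.items()
                if vc == visit and pid.startswith(arm_prefix)]
        return float(np.mean(vals))


def study_design_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default spec mirroring the emulated study: 27 adults and 31
    children at diagnosis, dropping to 13/22 at 3 months and 4/16 at 12
    months, with the published cohort means as planted targets."""
    return CohortSpec(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# food sampling and the per-day gram solver

def _food_pools(foods: FoodTable, allow_gfp: bool):
    by_nova = {g: [] for g in NovaGroup}
    for r in foods:
        if r.is_gfp and not allow_gfp:
            continue
        by_nova[r.nova_group].append(r)
    return by_nova


def _sample_day_foods(rng: np.random.Generator, foods: FoodTable,
                      allow_gfp: bool) -> list:
    """A realistic day's food set: staples guaranteeing solvability plus a
    random complement from every NOVA group."""
    pools = _food_pools(foods, allow_gfp)
    ids = set()
    chosen = []

    def take(fid):
        if fid in foods and fid not in ids:
            ids.add(fid)
            chosen.append(foods[fid])

    # staples: a dairy (lactose), a fruit (fructose), oil and sugar (pure
    # lipid / carb), a lean protein, a vegetable, a legume (fibre)
    take(rng.choice(["milk_whole", "milk_semi"]))
    take(rng.choice(["apple", "pear", "orange", "banana"]))
    take("olive_oil")
    take("sugar")
    take("honey")       # zero-fibre FODMAP lever
    take(rng.choice(["chicken_breast", "hake", "beef_lean", "egg"]))
    take(rng.choice(["tomato", "green_beans", "carrot", "lettuce"]))
    take(rng.choice(["lentils", "chickpeas", "white_beans"]))
    if allow_gfp:
        take("gf_bread")                       # anchor: bread as main GFP
        extra_gfp = [r.food_id for r in pools[NovaGroup.G4]
                     if r.is_gfp and r.food_id not in ids]
        for fid in rng.choice(extra_gfp, size=min(2, len(extra_gfp)),
                              replace=False):
            take(fid)
    # complement per NOVA group
    want = {NovaGroup.G1: 3, NovaGroup.G2: 1, NovaGroup.G3: 2, NovaGroup.G4: 2}
    for g, k in want.items():
        cands = [r.food_id for r in pools[g] if r.food_id not in ids]
        if cands:
            for fid in rng.choice(cands, size=min(k, len(cands)), replace=False):
                take(fid)
    return chosen


def _day_targets_vector(day: dict) -> tuple[list[str], np.ndarray]:
    names = ["protein_g", "lipid_g", "carb_g", "fibre_g", "gfp_kcal",
             "nova_G1", "nova_G2", "nova_G3", "nova_G4", "fodmap_g"]
    return names, np.array([day[n] for n in names])


def _build_system(day_foods: list, names: list[str]) -> np.ndarray:
    A = np.zeros((len(names), len(day_foods)))
    for j, f in enumerate(day_foods):
        fod = f.fodmap
        f5 = sum(v for v in (
            fod.fructose_g_100g, fod.glucose_g_100g, fod.total_fructan_g_100g,
            fod.lactose_g_100g, fod.inulin_g_100g, fod.mannitol_g_100g,
            fod.raffinose_g_100g, fod.stachyose_g_100g, fod.sorbitol_g_100g)
            if v is not None)
        col = {
            "protein_g": f.protein_g_100g / 100, "lipid_g": f.lipid_g_100g / 100,
            "carb_g": f.carb_g_100g / 100, "fibre_g": f.fibre_g_100g / 100,
            "gfp_kcal": (f.energy_kcal_100g / 100 if f.is_gfp else 0.0),
            "fodmap_g": f5 / 100,
        }
        col[f"nova_{f.nova_group.value}"] = 1.0 / f.standard_portion_g
        for i, n in enumerate(names):
            A[i, j] = col.get(n, 0.0)
    return A


def _solve_day(rng: np.random.Generator, foods: FoodTable, day: dict,
               allow_gfp: bool, n_tries: int = 12) -> tuple[list, np.ndarray]:
    """Pick foods and solve non-negative grams hitting the day's targets.

    The fibre row carries a lower weight: fibre is the energy-closure
    slack, not a planted headline target, and relaxing it slightly keeps
    the macronutrient/portion/FODMAP rows exactly attainable on food sets
    where the fibre that staple plant foods bring exceeds a small gap."""
    names, b = _day_targets_vector(day)
    keep = [i for i, n in enumerate(names)
            if not (n == "gfp_kcal" and not allow_gfp)]
    row_w = np.array([0.3 if names[i] == "fibre_g" else 1.0 for i in keep])
    scale = np.array([max(abs(b[i]), 1.0) for i in keep]) / row_w
    best = None
    for _ in range(n_tries):
        day_foods = _sample_day_foods(rng, foods, allow_gfp)
        A = _build_system(day_foods, names)
        Aw = A[keep] / scale[:, None]
        bw = b[keep] / scale
        res = lsq_linear(Aw, bw, bounds=(0.0, 800.0), tol=1e-12)
        err = float(np.max(np.abs(Aw @ res.x - bw)))
        if best is None or err < best[0]:
            best = (err, day_foods, res.x)
        if err < 1e-8:
            break
    _, day_foods, x = best
    return day_foods, x


# ---------------------------------------------------------------------------
# bookkeeping: plain per-event summation of the achieved targets (the
# oracle the engines are checked against; intentionally engine-independent)

def _bookkeep(events: list[IntakeEvent], foods: FoodTable) -> dict[str, float]:
    days = sorted({e.day_index for e in events})
    acc = {k: 0.0 for k in
           ("energy_kcal", "protein_g", "lipid_g", "carb_g", "fibre_g",
            "gfp_kcal", "fodmap_g", "nova_G1", "nova_G2", "nova_G3", "nova_G4")}
    for e in events:
        f = foods[e.food_id]
        a = e.amount_g
        acc["energy_kcal"] += a * f.energy_kcal_100g / 100
        acc["protein_g"] += a * f.protein_g_100g / 100
        acc["lipid_g"] += a * f.lipid_g_100g / 100
        acc["carb_g"] += a * f.carb_g_100g / 100
        acc["fibre_g"] += a * f.fibre_g_100g / 100
        if f.is_gfp:
            acc["gfp_kcal"] += a * f.energy_kcal_100g / 100
        acc[f"nova_{f.nova_group.value}"] += a / f.standard_portion_g
        fod = f.fodmap
        acc["fodmap_g"] += a / 100 * sum(v for v in (
            fod.fructose_g_100g, fod.glucose_g_100g, fod.total_fructan_g_100g,
            fod.lactose_g_100g, fod.inulin_g_100g, fod.mannitol_g_100g,
            fod.raffinose_g_100g, fod.stachyose_g_100g, fod.sorbitol_g_100g)
            if v is not None)
    nd = max(len(days), 1)
    out = {k: v / nd for k, v in acc.items()}
    e = out["energy_kcal"]
    out["protein_pctE"] = 400 * out["protein_g"] / e if e else 0.0
    out["lipid_pctE"] = 900 * out["lipid_g"] / e if e else 0.0
    out["carb_pctE"] = 400 * out["carb_g"] / e if e else 0.0
    out["gfp_energy_pct"] = 100 * out["gfp_kcal"] / e if e else 0.0
    return out


# ---------------------------------------------------------------------------

def _jitter_visit_targets(rng: np.random.Generator, t: VisitTargets,
                          spec: CohortSpec) -> dict:
    """Per-participant daily targets around the arm-visit nominals."""
    e = float(np.clip(rng.normal(t.energy_kcal, t.energy_sd_kcal),
                      max(900.0, 0.45 * t.energy_kcal), 2.2 * t.energy_kcal))
    p = t.protein_pctE + rng.normal(0, spec.jitter_pctE_sd)
    l = t.lipid_pctE + rng.normal(0, 1.5 * spec.jitter_pctE_sd)
    c = t.carb_pctE + rng.normal(0, 1.5 * spec.jitter_pctE_sd)
    total = p + l + c
    if not 96.0 <= total <= 98.8:         # keep the fibre gap in 1.2-4 %E
        tgt = min(max(total, 96.0), 98.8)
        p, l, c = (v * tgt / total for v in (p, l, c))
    if t.gfp_energy_pct <= 0:
        gfp = 0.0
    else:
        gfp = float(np.clip(rng.normal(t.gfp_energy_pct, spec.jitter_gfp_sd),
                            2.0, 65.0))
    # food volume scales with the participant's energy draw, so portion and
    # FODMAP targets scale with it too (E[r] = 1 keeps cohort means on target)
    r = e / t.energy_kcal
    nova = tuple(max(0.2, n * r * rng.normal(1.0, spec.jitter_nova_rel_sd))
                 for n in t.nova_portions)
    fod = max(2.0, t.fodmap_total_g * r
              * rng.normal(1.0, spec.jitter_fodmap_rel_sd))
    fib = (100.0 - p - l - c) / 100.0 * e / 2.0
    return dict(energy_kcal=e, protein_pctE=p, lipid_pctE=l, carb_pctE=c,
                gfp_energy_pct=gfp, fibre_g=fib,
                protein_g=p / 100 * e / 4, lipid_g=l / 100 * e / 9,
                carb_g=c / 100 * e / 4, gfp_kcal=gfp / 100 * e,
                nova_G1=nova[0], nova_G2=nova[1], nova_G3=nova[2],
                nova_G4=nova[3], fodmap_g=fod)


def _sample_gsrs_items(rng: np.random.Generator, props: tuple) -> tuple[list[int], str]:
    cat = rng.choice(3, p=np.asarray(props) / sum(props))
    scores = [1] * 15
    if cat == 0:
        return scores, "none"
    k = int(rng.integers(1, 6)) if cat == 1 else int(rng.integers(6, 16))
    idx = rng.choice(15, size=k, replace=False)
    for i in idx:
        scores[i] = int(rng.choice([2, 3, 4, 5, 6, 7],
                                   p=[0.40, 0.25, 0.15, 0.10, 0.07, 0.03]))
    return scores, ("one_to_five" if cat == 1 else "six_plus")


def generate(spec: CohortSpec,
             foods: Optional[FoodTable] = None) -> tuple[CohortBundle, GroundTruth]:
    """Generate a cohort bundle and its ground truth. Deterministic given
    ``spec.seed``; raises :class:`InfeasibleSpec` before sampling when the
    targets are inconsistent (via the spec model validators)."""
    foods = foods or default_food_table()
    rng = np.random.default_rng(spec.seed)
    gt = GroundTruth(spec=spec)

    participants: list[Participant] = []
    visits: list[Visit] = []
    events: list[IntakeEvent] = []
    ffqs: list[FFQResponse] = []
    gsrs: list[GSRSResponse] = []
    growth_h = lambda age: 0.84 + 0.058 * age       # crude height-for-age, m

    arm_defs = [
        (Cohort.adult, "A", spec.adults_per_visit, 0.81),
        (Cohort.pediatric, "C", spec.children_per_visit, 0.5),
    ]
    for cohort, prefix, counts, p_female, in arm_defs:
        arm_key = "adult" if cohort == Cohort.adult else "pediatric"
        n0 = counts[0]
        pids = [f"{prefix}{i:03d}" for i in range(1, n0 + 1)]
        # dropout is missing-at-random within arm: vt3 subset of vt0, vt12 of vt3
        at = {VisitCode.vt0: list(pids)}
        at[VisitCode.vt3] = sorted(rng.choice(pids, size=counts[1], replace=False))
        at[VisitCode.vt12] = sorted(rng.choice(at[VisitCode.vt3],
                                               size=counts[2], replace=False))
        heights, weights = {}, {}
        for pid in pids:
            if cohort == Cohort.adult:
                age = float(np.clip(rng.normal(37.1, 9.1), 19.0, 65.0))
                sex = Sex.F if rng.random() < p_female else Sex.M
                h = float(np.clip(rng.normal(1.62 if sex == Sex.F else 1.75, 0.06),
                                  1.45, 1.95))
                bmi = float(np.clip(rng.normal(23.3, 2.6), 17.5, 33.0))
            else:
                age = float(np.clip(rng.normal(7.1, 3.9), 2.0, 16.5))
                sex = Sex.F if rng.random() < p_female else Sex.M
                h = float(np.clip(growth_h(age) * rng.normal(1.0, 0.04), 0.8, 1.85))
                bmi = float(np.clip(rng.normal(16.8, 1.8), 13.0, 26.0))
            act = ActivityLevel(rng.choice(
                ["sedentary", "light", "moderate", "high"],
                p=[0.25, 0.45, 0.25, 0.05]))
            participants.append(Participant(
                participant_id=pid, cohort=cohort, sex=sex,
                age_years=round(age, 1), activity_level=act))
            heights[pid], weights[pid] = h, bmi * h * h

        for vc in VISITS:
            t = spec.targets[arm_key][vc.value]
            for pid in at[vc]:
                part = next(p for p in participants if p.participant_id == pid)
                w = weights[pid] * float(rng.normal(1.0, 0.015))
                rmr = (schofield_rmr(part.sex, part.age_years, w)
                       * float(rng.normal(1.0, 0.05)))
                ranges = dict(glucose=(75, 98), total_cholesterol=(140, 195),
                              hdl_cholesterol=(45, 75), ldl_cholesterol=(60, 125),
                              triglycerides=(50, 140), ferritin=(20, 180),
                              transferrin=(210, 340))
                bio = {k: round(float(rng.uniform(*rg)), 1)
                       for k, rg in ranges.items()}
                visits.append(Visit(
                    participant_id=pid, visit_code=vc,
                    weight_kg=round(w, 2), height_m=round(heights[pid], 3),
                    measured_rmr_kcal=(round(rmr, 0) if rng.random() < 0.6 else None),
                    **bio))

                day = _jitter_visit_targets(rng, t, spec)
                allow_gfp = day["gfp_energy_pct"] > 0
                pv_events: list[IntakeEvent] = []
                for d, dtype in ((1, DayType.weekday), (2, DayType.weekday),
                                 (3, DayType.weekend)):
                    day_foods, x = _solve_day(rng, foods, day, allow_gfp)
                    for f, grams in zip(day_foods, x):
                        if grams >= 0.05:
                            pv_events.append(IntakeEvent(
                                participant_id=pid, visit_code=vc,
                                day_index=d, day_type=dtype,
                                food_id=f.food_id, amount_g=float(grams)))
                events.extend(pv_events)
                gt.values[(pid, vc.value)] = PlantedValues(
                    planted=dict(day), achieved=_bookkeep(pv_events, foods))

                scores, cat = _sample_gsrs_items(rng, t.gsrs_category_props)
                gsrs.append(GSRSResponse(participant_id=pid, visit_code=vc,
                                         item_scores=scores))
                gt.gsrs_planted_category[(pid, vc.value)] = cat

                if vc in (VisitCode.vt0, VisitCode.vt12) and t.ffq_freq:
                    freqs, units = {}, {}
                    for g, mean in t.ffq_freq.items():
                        freqs[g] = round(max(0.0, float(
                            rng.normal(mean, 0.25 * mean + 0.1))), 1)
                        units[g] = (FreqUnit.per_day if g in
                                    (SencGroup.dairy, SencGroup.cereals,
                                     SencGroup.vegetables, SencGroup.fruits,
                                     SencGroup.oils) else FreqUnit.per_week)
                    ffqs.append(FFQResponse(participant_id=pid, visit_code=vc,
                                            frequencies=freqs, units=units))

    bundle = CohortBundle(participants, visits, events, ffqs, gsrs)
    return bundle, gt


# ---------------------------------------------------------------------------

_EFFECTS = ("reduce_g4_amounts", "shift_energy", "raise_gsrs")


def perturb(bundle: CohortBundle, foods: FoodTable, effect: str,
            delta: float, visit: VisitCode = VisitCode.vt3) -> CohortBundle:
    """Apply a named longitudinal effect to paired participants only
    (those with recall data at both vt0 and ``visit``); delta=0 is the
    identity. Unknown effect names raise ``ValueError``."""
    if effect not in _EFFECTS:
        raise ValueError(f"unknown effect {effect!r}; known: {_EFFECTS}")
    out = copy.deepcopy(bundle)
    with_v0 = {e.participant_id for e in out.events
               if e.visit_code == VisitCode.vt0}
    with_vx = {e.participant_id for e in out.events if e.visit_code == visit}
    paired = with_v0 & with_vx
    if effect == "reduce_g4_amounts":
        for e in out.events:
            if (e.visit_code == visit and e.participant_id in paired
                    and foods[e.food_id].nova_group == NovaGroup.G4):
                e.amount_g = max(e.amount_g * (1.0 - delta), 1e-9)
    elif effect == "shift_energy":
        for e in out.events:
            if e.visit_code == visit and e.participant_id in paired:
                e.amount_g = max(e.amount_g * (1.0 + delta), 1e-9)
    elif effect == "raise_gsrs":
        for r in out.gsrs:
            if r.visit_code == visit and r.participant_id in paired:
                r.item_scores = [min(7, s + int(round(delta)))
                                 for s in r.item_scores]
    return out
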