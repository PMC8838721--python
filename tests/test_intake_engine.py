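import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfdeval.food_db import FODMAPRecord, FoodRecord, FoodTable
from gfdeval.intake_engine import (Flag, NutrientProfile, RecommendationSet,
                                   adequacy, energy_expenditure, ffq_adequacy,
                                   nutrient_profile, schofield_rmr)
from gfdeval.records import (FFQResponse, FreqUnit, IntakeEvent, Participant,
                             SencGroup, Visit)


def _food(fid="t1", p=10.0, c=50.0, l=10.0, sug=0.0, sfa=0.0, fib=0.0,
          chol=0.0, energy=None, portion=100.0):
    if energy is None:
        energy = 4 * p + 4 * c + 9 * l + 2 * fib
    return FoodRecord(
        food_id=fid, name=fid, senc_group="other", nova_group="G1",
        energy_kcal_100g=energy, protein_g_100g=p, carb_g_100g=c,
        sugars_g_100g=sug, lipid_g_100g=l, sfa_g_100g=sfa, fibre_g_100g=fib,
        cholesterol_mg_100g=chol, standard_portion_g=portion,
        fodmap=FODMAPRecord(food_id=fid))


def _events(menu, pid="p", visit="vt0"):
    """menu: dict day -> list of (food_id, grams); days 1,2 weekday, 3 weekend."""
    evs = []
    for d, items in menu.items():
        for fid, g in items:
            evs.append(IntakeEvent(
                participant_id=pid, visit_code=visit, day_index=d,
                day_type="weekend" if d == 3 else "weekday",
                food_id=fid, amount_g=g))
    return evs


THREE_DAYS = {1: [("t1", 300.0)], 2: [("t1", 300.0)], 3: [("t1", 300.0)]}


class TestNutrientProfile:
    def test_atwater_arithmetic_single_food(self):
        # 300 g of 10/50/10 per 100 g: protein 30 g -> %E = 120/990
        foods = FoodTable([_food()])
        prof = nutrient_profile(_events(THREE_DAYS), foods)
        assert prof.protein_g_day == pytest.approx(30.0)
        assert prof.carb_g_day == pytest.approx(150.0)
        assert prof.lipid_g_day == pytest.approx(30.0)
        assert prof.protein_pctE == pytest.approx(100 * 120 / 990, abs=1e-9)
        assert prof.protein_pctE == pytest.approx(12.12, abs=0.005)

    def test_all_zero_composition_flagged(self):
        foods = FoodTable([_food(p=0, c=0, l=0)])
        prof = nutrient_profile(_events(THREE_DAYS), foods)
        assert prof.energy_kcal_day == 0
        assert prof.incomplete

    def test_missing_day_flagged_incomplete(self):
        foods = FoodTable([_food()])
        prof = nutrient_profile(_events({1: THREE_DAYS[1], 2: THREE_DAYS[2]}),
                                foods)
        assert prof.incomplete and prof.n_days == 2

    def test_pct_closure(self, foods, small_cohort):
        bundle, _ = small_cohort
        for pid, vc in bundle.participant_visits()[:20]:
            prof = nutrient_profile(bundle.events_for(pid, vc), foods)
            s = prof.protein_pctE + prof.lipid_pctE + prof.carb_pctE
            assert s == pytest.approx(100.0, abs=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.floats(0.1, 10), grams=st.lists(
        st.floats(10, 500), min_size=3, max_size=3))
    def test_scale_invariance(self, scale, grams):
        foods = FoodTable([_food(sug=5, sfa=2, fib=3, chol=20)])
        menu = {d: [("t1", g)] for d, g in zip((1, 2, 3), grams)}
        menu2 = {d: [(f, g * scale) for f, g in items]
                 for d, items in menu.items()}
        p1 = nutrient_profile(_events(menu), foods)
        p2 = nutrient_profile(_events(menu2), foods)
        assert p2.energy_kcal_day == pytest.approx(scale * p1.energy_kcal_day)
        assert p2.protein_g_day == pytest.approx(scale * p1.protein_g_day)
        assert p2.protein_pctE == pytest.approx(p1.protein_pctE, rel=1e-9)
        assert p2.sfa_pctE == pytest.approx(p1.sfa_pctE, rel=1e-9)

    def test_weighted_day_mean(self):
        # weekday days weight 5/14 each, weekend 2/7 of the week
        foods = FoodTable([_food()])
        menu = {1: [("t1", 100.0)], 2: [("t1", 100.0)], 3: [("t1", 450.0)]}
        prof_u = nutrient_profile(_events(menu), foods)
        prof_w = nutrient_profile(_events(menu), foods, weighted_days=True)
        assert prof_u.protein_g_day == pytest.approx((10 + 10 + 45) / 3)
        expect = (100 * 5 / 14 + 100 * 5 / 14 + 450 * 2 / 7) / 1.0 * 10 / 100
        assert prof_w.protein_g_day == pytest.approx(expect)


class TestEnergyExpenditure:
    def test_measured_rmr_times_factor(self):
        p = Participant(participant_id="a", cohort="adult", sex="F",
                        age_years=40, activity_level="light")
        v = Visit(participant_id="a", visit_code="vt0", weight_kg=60,
                  height_m=1.6, measured_rmr_kcal=1400)
        assert energy_expenditure(p, v) == pytest.approx(1960.0)

    def test_sedentary_factor_identity_scaling(self):
        p = Participant(participant_id="a", cohort="adult", sex="M",
                        age_years=40, activity_level="sedentary")
        v = Visit(participant_id="a", visit_code="vt0", weight_kg=80,
                  height_m=1.8, measured_rmr_kcal=1700)
        assert energy_expenditure(p, v) == pytest.approx(1700 * 1.2)

    def test_equation_rmr_matches_hand_calculation(self):
        # Schofield, woman 30-60 y: 8.126*W + 845.6
        p = Participant(participant_id="a", cohort="adult", sex="F",
                        age_years=37, activity_level="sedentary")
        v = Visit(participant_id="a", visit_code="vt0", weight_kg=60,
                  height_m=1.65)
        hand = (8.126 * 60 + 845.6) * 1.2
        assert energy_expenditure(p, v) == pytest.approx(hand)
        # boy 3-10 y: 22.706*W + 504.3
        assert schofield_rmr("M", 7, 25) == pytest.approx(22.706 * 25 + 504.3)


def _profile(**over):
    base = dict(participant_id="p", visit_code="vt0",
                energy_kcal_day=1968.4, energy_atwater_kcal_day=1950,
                protein_g_day=80, lipid_g_day=90, sfa_g_day=28,
                carb_g_day=200, sugars_g_day=21, fibre_g_day=21.6,
                cholesterol_mg_day=298.8, protein_pctE=16.3, lipid_pctE=41.1,
                sfa_pctE=12.8, carb_pctE=40.5, sugars_pctE=4.3,
                protein_pctE_food=16.3, lipid_pctE_food=41.1,
                sfa_pctE_food=12.8, carb_pctE_food=40.5,
                sugars_pctE_food=4.3, energy_expenditure_kcal_day=2000.0)
    base.update(over)
    return NutrientProfile(**base)


class TestAdequacy:
    def test_study_like_adult_profile_flags(self):
        # SFA 12.8 %E high, cholesterol 298.8 < 300 adequate, fibre 21.6 low
        flags = adequacy(_profile())
        assert flags["sfa"] == Flag.high
        assert flags["cholesterol"] == Flag.adequate
        assert flags["fibre"] == Flag.low
        assert flags["protein"] == Flag.high     # 16.3 > 12.5 + 2.5
        assert flags["lipid"] == Flag.high       # 41.1 > 32.5 + 2.5
        assert flags["carb"] == Flag.low         # 40.5 < 55 - 2.5
        assert flags["sugars"] == Flag.adequate  # 4.3 < 10
        assert flags["energy"] == Flag.adequate  # within 2000 +/- 20%

    def test_fibre_density_criterion_accepts_low_absolute(self):
        # 20 g at 1300 kcal: below 25 g band but >= 14 g / 1000 kcal
        flags = adequacy(_profile(fibre_g_day=20, energy_kcal_day=1300))
        assert flags["fibre"] == Flag.adequate

    def test_energy_outside_band(self):
        assert adequacy(_profile(energy_kcal_day=1500))["energy"] == Flag.low
        assert adequacy(_profile(energy_kcal_day=2500))["energy"] == Flag.high

    def test_incomplete_profile_rejected(self):
        p = _profile()
        p.incomplete = True
        with pytest.raises(ValueError, match="incomplete"):
            adequacy(p)


class TestFFQAdequacy:
    def _ffq(self, freqs_units):
        freqs = {g: v for g, (v, _) in freqs_units.items()}
        units = {g: u for g, (_, u) in freqs_units.items()}
        return FFQResponse(participant_id="p", visit_code="vt0",
                           frequencies=freqs, units=units)

    def test_study_like_flags(self):
        ffq = self._ffq({
            SencGroup.meat: (6.2, FreqUnit.per_week),       # 3-4 -> above
            SencGroup.vegetables: (2.0, FreqUnit.per_day),  # 2 -> within
            SencGroup.pastries: (0.0, FreqUnit.per_week),   # <1 -> within
            SencGroup.cereals: (2.6, FreqUnit.per_day),     # 4-6 -> below
            SencGroup.dairy: (3.0, FreqUnit.per_day),       # 2-4 -> within
        })
        flags = ffq_adequacy(ffq)
        assert flags[SencGroup.meat] == Flag.high
        assert flags[SencGroup.vegetables] == Flag.adequate
        assert flags[SencGroup.pastries] == Flag.adequate
        assert flags[SencGroup.cereals] == Flag.low
        assert flags[SencGroup.dairy] == Flag.adequate

    def test_pastries_at_one_per_week_is_above(self):
        ffq = self._ffq({SencGroup.pastries: (1.0, FreqUnit.per_week)})
        assert ffq_adequacy(ffq)[SencGroup.pastries] == Flag.high

    def test_unit_mismatch_error(self):
        ffq = self._ffq({SencGroup.meat: (0.5, FreqUnit.per_day)})
        with pytest.raises(ValueError, match="per_week"):
            ffq_adequacy(ffq)
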