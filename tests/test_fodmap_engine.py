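import pytest
from hypothesis import given, settings, strategies as st

from gfdeval.food_db import FODMAPRecord, FoodRecord, FoodTable
from gfdeval.fodmap_engine import (excess_fructose, fodmap_profile,
                                   total_fodmap)
from gfdeval.records import IntakeEvent


def _food(fid, **fodmap):
    return FoodRecord(
        food_id=fid, name=fid, senc_group="other", nova_group="G1",
        energy_kcal_100g=100, protein_g_100g=1, carb_g_100g=20,
        sugars_g_100g=5, lipid_g_100g=1, sfa_g_100g=0.2, fibre_g_100g=1,
        cholesterol_mg_100g=0, standard_portion_g=100,
        fodmap=FODMAPRecord(food_id=fid, **fodmap))


def _ev(fid, grams, day=1, pid="p"):
    return IntakeEvent(participant_id=pid, visit_code="vt0", day_index=day,
                       day_type="weekend" if day == 3 else "weekday",
                       food_id=fid, amount_g=grams)


def _three_days(fid, grams=(100, 100, 100)):
    return [_ev(fid, g, d) for d, g in zip((1, 2, 3), grams)]


class TestExcessFructose:
    @pytest.mark.parametrize("f,g,expected",
                             [(5, 3, 2), (3, 3, 0), (2, 5, 0), (0, 0, 0)])
    def test_examples(self, f, g, expected):
        assert excess_fructose(f, g) == expected

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(f=st.floats(0, 100), g=st.floats(0, 100))
    def test_contract(self, f, g):
        ex = excess_fructose(f, g)
        assert ex == max(0.0, f - g)
        assert 0 <= ex <= f

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            excess_fructose(-1, 0)


class TestProfile:
    def test_single_day_averaging(self):
        foods = FoodTable([_food("milkish", lactose_g_100g=5.0)])
        events = [_ev("milkish", 100, 1), _ev("milkish", 0.1, 2),
                  _ev("milkish", 0.1, 3)]
        prof = fodmap_profile(events, foods)
        assert prof.g_day["lactose"] == pytest.approx((5.0 + 0.005 + 0.005) / 3)

    def test_lactose_on_one_day_only_divided_by_three(self):
        foods = FoodTable([_food("milkish", lactose_g_100g=5.0),
                           _food("water")])
        events = [_ev("milkish", 100, 1), _ev("water", 100, 2),
                  _ev("water", 100, 3)]
        assert fodmap_profile(events, foods).g_day["lactose"] == \
            pytest.approx(5.0 / 3)

    def test_all_missing_zero_coverage_flagged(self):
        foods = FoodTable([_food("mystery")])  # no fodmap data at all
        prof = fodmap_profile(_three_days("mystery"), foods)
        assert prof.coverage_fraction == 0.0
        assert prof.low_coverage
        assert all(v == 0.0 for v in prof.g_day.values())
        assert prof.total_fodmap_g_day == 0.0

    def test_missing_values_skipped_not_zeroed(self):
        known = _food("known", fructose_g_100g=2.0, glucose_g_100g=1.0)
        unknown = _food("unknown")
        foods = FoodTable([known, unknown])
        events = ([_ev("known", 100, d) for d in (1, 2, 3)]
                  + [_ev("unknown", 100, d) for d in (1, 2, 3)])
        prof = fodmap_profile(events, foods)
        assert prof.g_day["fructose"] == pytest.approx(2.0)
        assert prof.coverage_fraction == pytest.approx(0.5)

    def test_netting_modes_differ_only_with_glucose_rich_item(self):
        fr_rich = _food("fr", fructose_g_100g=5.0, glucose_g_100g=1.0)
        gl_rich = _food("gl", fructose_g_100g=1.0, glucose_g_100g=5.0)
        neutral = _food("nt", fructose_g_100g=2.0, glucose_g_100g=2.0)
        foods = FoodTable([fr_rich, gl_rich, neutral])

        # no glucose-rich item: modes agree
        events = ([_ev("fr", 100, d) for d in (1, 2, 3)]
                  + [_ev("nt", 100, d) for d in (1, 2, 3)])
        a = fodmap_profile(events, foods, netting="per_item")
        b = fodmap_profile(events, foods, netting="per_day")
        assert a.excess_fructose_g_day == pytest.approx(b.excess_fructose_g_day)

        # glucose-rich item present: per-day netting offsets, per-item floors
        events += [_ev("gl", 100, d) for d in (1, 2, 3)]
        a = fodmap_profile(events, foods, netting="per_item")
        b = fodmap_profile(events, foods, netting="per_day")
        assert a.excess_fructose_g_day == pytest.approx(4.0)
        assert b.excess_fructose_g_day == pytest.approx(0.0)
        assert a.excess_fructose_g_day > b.excess_fructose_g_day

    def test_excess_never_exceeds_fructose(self, foods, small_cohort):
        bundle, _ = small_cohort
        for pid, vc in bundle.participant_visits()[:15]:
            prof = fodmap_profile(bundle.events_for(pid, vc), foods)
            assert prof.excess_fructose_g_day <= prof.g_day["fructose"] + 1e-9

    def test_monotone_in_events(self, foods, small_cohort):
        bundle, _ = small_cohort
        pid, vc = bundle.participant_visits()[0]
        events = bundle.events_for(pid, vc)
        before = fodmap_profile(events, foods)
        extra = IntakeEvent(participant_id=pid, visit_code=vc, day_index=1,
                            day_type="weekday", food_id="apple", amount_g=150)
        after = fodmap_profile(events + [extra], foods)
        for c in before.g_day:
            assert after.g_day[c] >= before.g_day[c] - 1e-12
        assert after.total_fodmap_g_day >= before.total_fodmap_g_day

    def test_additivity_over_days(self):
        f = _food("x", fructose_g_100g=3.0, glucose_g_100g=1.0,
                  sorbitol_g_100g=0.5)
        foods = FoodTable([f])
        per_day_events = {d: [_ev("x", 100.0 * d, d)] for d in (1, 2, 3)}
        combined = [e for evs in per_day_events.values() for e in evs]
        prof = fodmap_profile(combined, foods)
        # element-wise mean of per-day sums
        assert prof.g_day["fructose"] == pytest.approx(
            (3.0 + 6.0 + 9.0) / 3)
        assert prof.g_day["sorbitol"] == pytest.approx((0.5 + 1.0 + 1.5) / 3)


class TestTotals:
    def test_zero_and_single_compound(self):
        g = {c: 0.0 for c in ("fructose", "glucose", "lactose", "sorbitol",
                              "mannitol", "raffinose", "stachyose",
                              "fructans", "inulin", "fructans_raw")}
        assert total_fodmap(g, 0.0) == 0.0
        g2 = dict(g, lactose=4.0)
        assert total_fodmap(g2, 0.0) == 4.0

    def test_as_table5_equals_hand_row_sum(self):
        rows = dict(fructose=11.3, glucose=9.5, fructans_raw=0.8, lactose=10.4,
                    inulin=0.1, mannitol=0.1, raffinose=0.0, stachyose=0.02,
                    sorbitol=0.4, fructans=0.9)
        hand = 11.3 + 9.5 + 0.8 + 10.4 + 0.1 + 0.1 + 0.0 + 0.02 + 0.4
        assert total_fodmap(rows, 1.8, mode="as_table5") == pytest.approx(hand)

    def test_default_mode_uses_excess_and_resolved_fructans(self):
        rows = dict(fructose=11.3, glucose=9.5, lactose=10.4, sorbitol=0.4,
                    mannitol=0.1, raffinose=0.0, stachyose=0.02, fructans=0.9,
                    inulin=0.1)
        hand = 1.8 + 10.4 + 0.9 + 0.4 + 0.1 + 0.0 + 0.02
        assert total_fodmap(rows, 1.8, mode="excess") == pytest.approx(hand)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            total_fodmap({}, 0.0, mode="bogus")
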