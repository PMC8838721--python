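"""Quantify daily FODMAP intake, with per-item excess-fructose netting.

Shows how missing composition values are skipped (never counted as
zero) and surfaced through the coverage fraction.
"""
from gfdeval import default_food_table, fodmap_profile
from gfdeval.records import IntakeEvent

foods = default_food_table()
menu = [
    (1, "weekday", "milk_whole", 400), (1, "weekday", "apple", 180),
    (1, "weekday", "onion", 80), (1, "weekday", "chickpeas", 70),
    (2, "weekday", "pear", 160), (2, "weekday", "milk_whole", 300),
    (2, "weekday", "gf_bread", 120), (2, "weekday", "mushroom", 100),
    (3, "weekend", "honey", 25), (3, "weekend", "milk_whole", 300),
    (3, "weekend", "gf_cereal_bar", 25),  # FODMAP composition unknown
]
events = [IntakeEvent(participant_id="demo", visit_code="vt0", day_index=d,
                      day_type=t, food_id=f, amount_g=g)
          for d, t, f, g in menu]

prof = fodmap_profile(events, foods)
for compound in ("fructose", "glucose", "lactose", "fructans", "inulin",
                 "sorbitol", "mannitol", "raffinose", "stachyose"):
    print(f"{compound:10s} {prof.g_day[compound]:6.2f} g/day")
print(f"excess fructose  {prof.excess_fructose_g_day:6.2f} g/day "
      "(fructose minus glucose, floored at 0 per food)")
print(f"TOTAL (excess accounting)   {prof.total_fodmap_g_day:6.2f} g/day")
print(f"TOTAL (row-sum accounting)  {prof.total_fodmap_table_g_day:6.2f} g/day")
print(f"coverage: {prof.coverage_fraction:.0%} of consumed grams have known "
      "FODMAP composition")
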