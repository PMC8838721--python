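# gfdeval

Dietary evaluation of celiac cohorts on a gluten-free diet (GFD).

People with celiac disease must follow a strict GFD for life, and the diet
that results is frequently imbalanced: protein and lipids (especially
saturated fat) in excess, carbohydrates and fibre in defect, heavy reliance
on manufactured gluten-free products (GFP) whose composition differs from
their gluten-containing homologues, and — for the roughly 20–30% whose
symptoms persist — a possible role of FODMAPs (fermentable oligo-, di-,
monosaccharides and polyols). `gfdeval` implements, as a tested Python
library, the computations a dietitian's evaluation platform performs on
such cohorts:

- **24-h recall nutrient computation** — from visit-tagged 3-day recalls
  (2 weekdays + 1 weekend day) and a per-100 g food-composition table:
  daily energy, %E macronutrient distribution with Atwater factors
  (4/9/4 kcal/g), fibre and cholesterol, with adequacy flags against the
  Spanish reference intakes (protein 12.5 %E, lipids 32.5 %E, carbohydrates
  55 %E, SFA and sugars < 10 %E, fibre 25–35 g or ≥ 14 g/1000 kcal,
  cholesterol < 300 mg, energy within ±20% of expenditure);
- **FFQ adequacy** against the SENC food-group frequency bands
  (e.g. cereals 4–6/day, meat 3–4/week, pastries < 1/week);
- **FODMAP quantification** — fructose, glucose, excess fructose
  (max(0, fructose − glucose), netted per food item), lactose, fructans
  with a source-priority resolution (laboratory cereal assay > literature >
  inulin as lower bound), inulin, polyols and GOS, with explicit handling
  of missing composition values and a coverage fraction;
- **NOVA and GFP profiling** — portions/day and energy/day per NOVA
  processing group (G1 unprocessed … G4 ultra-processed) and the GFP share
  of total energy, overall and per product category (bread, pasta, …);
- **Clinical scoring** — WHO adult BMI bands and pediatric BMI-for-age
  percentile bands (3/85/95), biochemical reference-range checks, and GSRS
  symptom scoring (15 items, 1–7 Likert, five sub-dimensions) with the
  none / 1–5 / 6+ marked-symptom categorisation;
- **Longitudinal statistics** — Kolmogorov–Smirnov (Lilliefors) normality
  screening, Levene homogeneity, paired Wilcoxon signed-rank for visit
  contrasts (diagnosis vs 3 and 12 months), one-way ANOVA for the
  adults-vs-children contrast (two groups: F = t²), Pearson correlation,
  log transform for skewed variables;
- **A synthetic-cohort generator** that emulates the underlying study
  design (adult and pediatric arms, visits vt0/vt3/vt12 with dropout,
  3-day recalls) and *plants* known targets — energy, %E split, GFP energy
  share, NOVA portion mix, FODMAP totals, symptom-category proportions —
  by solving non-negative least-squares gram amounts over sampled foods,
  so every engine is testable offline against known ground truth;
- **Reports** — the per-participant written evaluation with exactly one
  advice line per flagged imbalance, plus a thin `gfdeval` CLI.

## Worked example

```python
from gfdeval import default_food_table, nutrient_profile, adequacy
from gfdeval.records import IntakeEvent

foods = default_food_table()
events = [IntakeEvent(participant_id="demo", visit_code="vt0", day_index=d,
                      day_type="weekend" if d == 3 else "weekday",
                      food_id=f, amount_g=g)
          for d, f, g in [(1, "gf_bread", 120), (1, "milk_whole", 250),
                          (1, "chicken_breast", 150), (1, "olive_oil", 30),
                          (2, "gf_pasta", 90), (2, "hake", 150),
                          (2, "apple", 180), (2, "olive_oil", 25),
                          (3, "gf_pizza", 250), (3, "orange", 180)]]
p = nutrient_profile(events, foods)
print(f"{p.energy_kcal_day:.0f} kcal/day, protein {p.protein_pctE:.1f} %E, "
      f"lipids {p.lipid_pctE:.1f} %E, carbs {p.carb_pctE:.1f} %E")
```

prints

```
856 kcal/day, protein 15.8 %E, lipids 36.7 %E, carbs 47.6 %E
```

i.e. a (deliberately sparse) menu averaging 856 kcal/day with 15.8% of
Atwater energy from protein — protein above the 12.5 %E reference, lipids
above 32.5 %E, carbohydrates below the 55 %E reference: the typical GFD
pattern. The `examples/` directory holds
one short script per capability (nutrients, FODMAP, NOVA/GFP, clinical
scoring, longitudinal statistics, full pipeline); each prints its results
with a line on how to read them.

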