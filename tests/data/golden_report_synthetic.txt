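DIETARY EVALUATION REPORT
=========================
Participant: A001   Visit: vt0   Cohort: adult

1. NUTRITIONAL STATUS
BMI 25.0 kg/m2: normal
glucose: 88 [70-100] within
total_cholesterol: 182.1 [120-200] within
hdl_cholesterol: 64 [40-90] within
ldl_cholesterol: 96 [50-130] within
triglycerides: 100.3 [40-150] within
ferritin: 68.6 [15-250] within
transferrin: 214 [200-360] within

2. DIET QUALITY
Energy 2490 kcal/day (expenditure 2075 kcal/day)
Protein 17.1 %E, lipids 41.6 %E (SFA 13.3 %E), carbohydrates 41.2 %E (sugars 10.8 %E)
Fibre 49.8 g/day, cholesterol 353 mg/day
NOVA portions/day: G1 8.3, G2 3.6, G3 1.9, G4 6.1
Gluten-free products: 21.9% of energy
Total FODMAP 20.8 g/day (coverage 87%)
GSRS total 2.20, 7 marked symptom(s) (six_plus)

3. FLAGGED IMBALANCES AND ADVICE
Protein supplies an excessive share of energy; reduce portion sizes of meat and other protein-rich foods.
Fat supplies an excessive share of energy; reduce added fats and fatty processed foods.
Carbohydrates supply too small a share of energy; increase gluten-free whole grains, legumes, fruit and vegetables.
Saturated fat exceeds 10% of energy; replace fatty meats, butter and pastries with vegetable fats and fish.
Simple sugars exceed 10% of energy; limit sweets, sugary drinks and sweetened dairy.
Dietary cholesterol exceeds 300 mg/day; moderate egg yolk, offal and fatty animal foods.
Cereal consumption is below 4 portions/day; include gluten-free bread, rice, maize or pasta at each meal.
Vegetable consumption is below 2 portions/day; include vegetables at lunch and dinner.
Fruit consumption is below 3 portions/day; add fruit as dessert or snack.
Added-oil use is below 3 portions/day; use olive oil for cooking and dressing.
Meat consumption exceeds 4 portions/week; replace some meat meals with fish, eggs or legumes.
Fish consumption is below 3 portions/week; aim for 3-4 portions including oily fish.
Egg consumption is below 3 portions/week.
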