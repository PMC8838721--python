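# Advice line per adequacy flag key. Keys are "<component>:<flag>".
# Exactly one line is emitted per non-adequate flag in a report.
energy:low: "Energy intake is below 80% of estimated expenditure; increase overall intake with energy-dense, nutrient-rich foods."
energy:high: "Energy intake exceeds estimated expenditure by more than 20%; moderate portion sizes."
protein:low: "Protein supplies too small a share of energy; include lean protein sources at main meals."
protein:high: "Protein supplies an excessive share of energy; reduce portion sizes of meat and other protein-rich foods."
lipid:low: "Fat intake is below the recommended share of energy; favour olive oil and oily fish."
lipid:high: "Fat supplies an excessive share of energy; reduce added fats and fatty processed foods."
sfa:high: "Saturated fat exceeds 10% of energy; replace fatty meats, butter and pastries with vegetable fats and fish."
carb:low: "Carbohydrates supply too small a share of energy; increase gluten-free whole grains, legumes, fruit and vegetables."
carb:high: "Carbohydrates supply an excessive share of energy; check added sugars and refined products."
sugars:high: "Simple sugars exceed 10% of energy; limit sweets, sugary drinks and sweetened dairy."
fibre:low: "Fibre intake is below recommendations (25-35 g/day); increase vegetables, fruit, legumes and wholegrain gluten-free cereals."
fibre:high: "Fibre intake is unusually high; ensure adequate fluid intake."
cholesterol:high: "Dietary cholesterol exceeds 300 mg/day; moderate egg yolk, offal and fatty animal foods."
ffq.dairy:below: "Dairy consumption is below 2 portions/day; add milk, yogurt or cheese."
ffq.dairy:above: "Dairy consumption exceeds 4 portions/day; moderate intake."
ffq.cereals:below: "Cereal consumption is below 4 portions/day; include gluten-free bread, rice, maize or pasta at each meal."
ffq.cereals:above: "Cereal consumption exceeds 6 portions/day; moderate portions."
ffq.vegetables:below: "Vegetable consumption is below 2 portions/day; include vegetables at lunch and dinner."
ffq.fruits:below: "Fruit consumption is below 3 portions/day; add fruit as dessert or snack."
ffq.oils:below: "Added-oil use is below 3 portions/day; use olive oil for cooking and dressing."
ffq.oils:above: "Added-oil use exceeds 6 portions/day; moderate quantities."
ffq.meat:below: "Meat consumption is below 3 portions/week."
ffq.meat:above: "Meat consumption exceeds 4 portions/week; replace some meat meals with fish, eggs or legumes."
ffq.fish:below: "Fish consumption is below 3 portions/week; aim for 3-4 portions including oily fish."
ffq.fish:above: "Fish consumption exceeds 4 portions/week."
ffq.eggs:below: "Egg consumption is below 3 portions/week."
ffq.eggs:above: "Egg consumption exceeds 4 portions/week."
ffq.legumes:below: "Legume consumption is below 2 portions/week; add lentil or chickpea dishes."
ffq.legumes:above: "Legume consumption exceeds 4 portions/week."
ffq.nuts:below: "Nut consumption is below 3 portions/week; a daily handful of unsalted nuts is recommended."
ffq.nuts:above: "Nut consumption exceeds 7 portions/week; moderate quantities."
ffq.pastries:above: "Pastry and sweet consumption exceeds the occasional (<1 portion/week) recommendation; reserve for special occasions."
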