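"""BMI classification, biochemical range checks and GSRS symptom scoring."""
from gfdeval import (check_ranges, classify_bmi, default_growth_reference,
                     score_gsrs)
from gfdeval.records import GSRSResponse, Visit

# adult BMI, WHO bands
adult = classify_bmi(82, 1.70, "adult")
print(f"adult   BMI {adult.bmi_kg_m2:.1f} -> {adult.bmi_class.value}")

# child BMI-for-age percentile (packaged synthetic growth reference)
growth = default_growth_reference()
child = classify_bmi(38, 1.34, "pediatric", age_years=9.0, sex="M",
                     growth_reference=growth)
print(f"child   BMI {child.bmi_kg_m2:.1f} -> percentile "
      f"{child.percentile:.1f} -> {child.bmi_class.value}")

# biochemical panel against package default reference ranges
visit = Visit(participant_id="demo", visit_code="vt0", weight_kg=82,
              height_m=1.70, glucose=104, ferritin=12, triglycerides=120)
for chk in check_ranges(visit):
    print(f"{chk.analyte:14s} {chk.value:6.1f} "
          f"[{chk.low:g}-{chk.high:g}] {chk.status.value}")

# GSRS: 15 items, 1 (none) .. 7 (most severe); sub-scores are item means
resp = GSRSResponse(participant_id="demo", visit_code="vt0",
                    item_scores=[1, 2, 1, 3, 1, 4, 2, 1, 1, 1, 5, 2, 1, 1, 1])
res = score_gsrs(resp)
print(f"GSRS total {res.total_score:.2f}; sub-scores:",
      {k: round(v, 2) for k, v in res.subscores.items()})
print(f"{res.marked_count} marked symptoms -> category "
      f"{res.symptom_category.value}")
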