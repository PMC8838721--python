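"""Paired visit comparisons and arm contrasts on a synthetic cohort.

Plants a 40% reduction of ultra-processed (G4) intake at the 3-month
visit and shows the paired Wilcoxon detecting it, next to the null
contrast on unperturbed energy intake.
"""
from gfdeval import (default_food_table, generate, nova_profile,
                     nutrient_profile, perturb, study_design_spec)
from gfdeval.records import VisitCode
from gfdeval.stats_longitudinal import group_test, paired_visit_test

foods = default_food_table()
spec = study_design_spec(seed=21, adults_per_visit=(20, 16, 10),
                         children_per_visit=(20, 16, 10))
bundle, _ = generate(spec, foods)
bundle = perturb(bundle, foods, "reduce_g4_amounts", delta=0.4,
                 visit=VisitCode.vt3)


def collect(metric):
    out = {vc: {} for vc in VisitCode}
    for pid, vc in bundle.participant_visits():
        out[vc][pid] = metric(bundle.events_for(pid, vc))
    return out


g4 = collect(lambda ev: sum(v for g, v in
                            nova_profile(ev, foods).portions_day.items()
                            if g.value == "G4"))
energy = collect(lambda ev: nutrient_profile(ev, foods).energy_kcal_day)

for name, data in (("G4 portions/day", g4), ("energy kcal/day", energy)):
    a, b = data[VisitCode.vt0], data[VisitCode.vt3]
    res = paired_visit_test(list(a.values()), list(b.values()),
                            list(a), list(b), variable=name)
    print(f"{name:16s} vt0 vs vt3: n={res.n} pairs, "
          f"W={res.statistic:+.1f}, p={res.p_value:.4f}")
# the planted G4 reduction yields a strongly significant negative shift;
# energy only reflects the generator's own between-visit drift in targets.

adults = [v for pid, v in energy[VisitCode.vt0].items() if pid.startswith("A")]
children = [v for pid, v in energy[VisitCode.vt0].items() if pid.startswith("C")]
res = group_test(adults, children, variable="energy")
print(f"adults vs children energy at vt0: F={res.statistic:.2f}, "
      f"p={res.p_value:.3f} (two groups: F = t^2)")
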