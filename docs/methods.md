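# Methods

This note documents the models, conventions and design choices behind
`gfdeval`, in the order the data flow through the package.

## Food composition and the energy convention

Composition is stored per 100 g edible portion. The fixture table ships
with the package (54 foods, every SENC food group, every NOVA group,
eight GFP categories) so all computation runs offline. Fixture energies
follow the convention

    energy_kcal_100g = 4·protein + 4·carbohydrate + 9·lipid + 2·fibre

— the Atwater general factors plus fibre at 2 kcal/g, which is how
modern composition databases account for energy. This has a consequence
used throughout the package: the macronutrient %E shares computed
against the food-table energy do **not** sum to 100 (fibre supplies the
remainder), while shares computed against pure Atwater energy
(4/9/4 on the same grams) close to 100 by construction. `NutrientProfile`
reports both: the Atwater-based `*_pctE` fields (testable closure) and
the food-energy-based `*_pctE_food` fields (comparable to published
intake tables). User-supplied tables need not follow the convention; only
the Atwater closure invariant depends on the grams themselves.

FODMAP values mix sources of unequal coverage — a national composition
database (which reports inulin but not total fructan), literature values
for plant foods and pulses, and a laboratory assay for cereal foods. A
missing value is `None`, never zero; profile sums skip missing values
and report a **coverage fraction** (share of consumed grams whose food
has any known FODMAP datum; profiles below a configurable floor, default
0.5, are flagged low-coverage). Fructan resolution is by source
priority: own cereal assay > literature (plant or pulse) > inulin as an
explicit lower bound; an optional literature override table competes at
the literature tier and loses ties to the record's own value. This makes
resolution deterministic and order-independent.

## Intake engine

Daily nutrient totals are Σ(amount_g × per-100 g value / 100) per recall
day, averaged over the 3 days (2 weekdays + 1 weekend day). The average
is unweighted by default; a switch enables 5/14–5/14–2/7 weekday/weekend
weighting, off because the emulated protocol specifies the day mix but
no weighting. Visits with fewer than 3 recall days are flagged
incomplete and excluded from cohort means.

Adequacy flags: point %E targets (protein 12.5, lipids 32.5,
carbohydrates 55) carry a ±2.5 %E band — a band is needed to turn a
point recommendation into a deterministic low/adequate/high flag, and
2.5 %E is half the gap between the protein reference and the nearest
reported cohort mean. Bounded targets flag by their bound (SFA and
sugars < 10 %E, cholesterol < 300 mg/day). Fibre is adequate if within
25–35 g/day **or** at ≥ 14 g per 1000 kcal (both printed criteria are
accepted). Energy is adequate within ±20% of estimated expenditure.

Energy expenditure = RMR × activity factor. The measured (bioimpedance)
RMR is used when recorded; otherwise the Schofield weight-based
equations (WHO age/sex bands) — one documented equation family covering
children, adolescents and adults. Activity factors: sedentary 1.2,
light 1.4, moderate 1.6, high 1.8.

FFQ adequacy uses the SENC daily bands (dairy 2–4, cereals 4–6,
vegetables ≥ 2, fruits ≥ 3, oils 3–6) and weekly bands (meat/fish/eggs
3–4, legumes 2–4, nuts 3–7, pastries < 1). Frequencies must be reported
in each group's conventional unit; a mismatch is an error rather than a
silent conversion.

## FODMAP engine

Excess fructose = max(0, fructose − glucose), computed **per food item**
before summation (a glucose-rich food cannot offset a fructose-rich one;
this is standard FODMAP accounting); per-day netting is available as a
switch. Two total definitions are reported side by side:

- `total_fodmap_g_day` ("excess" accounting): excess fructose + lactose
  + resolved fructans + sorbitol + mannitol + raffinose + stachyose.
  The fructan term comes from the per-food source resolution, so inulin
  is never double-counted — it stands in only when it is the sole
  fructan datum.
- `total_fodmap_table_g_day` ("row-sum" accounting): fructose + glucose
  + raw total fructan + lactose + inulin + mannitol + raffinose +
  stachyose + sorbitol, mirroring consumption tables that list fructose,
  glucose, fructans and inulin as separate rows and total them.

## NOVA and GFP

Portions are amount_g / standard_portion_g (unrounded); the standard
portion is a fixture per food. NOVA group energies and portions
partition the totals exactly. The GFP energy share pools all 3 recall
days (ratio of sums — stable when one day is low-energy); mean-of-daily-
ratios is a switch. A food's NOVA group comes from the table, not from
its GFP flag (most but not all GFP are ultra-processed). The G4 energy
composition is also ranked by label (GFP foods under "GFP", other
ultra-processed foods under their SENC group).

## Clinical scoring

Adult BMI uses the WHO bands with cut-points inclusive to the heavier
class and obesity strictly above 30 (underweight < 18.5 ≤ normal < 25 ≤
overweight ≤ 30 < obese). Pediatric classification converts BMI to a
BMI-for-age percentile through an LMS growth reference
(z = ((BMI/M)^L − 1)/(L·S)) and applies the 3/85/95 cut-offs with the
same convention (percentile 3 → normal, 85 and 95 → overweight, > 95 →
obese). The packaged reference table is **synthetic** — smooth, plausible
curves whose only role is to make the pediatric pathway runnable and
testable offline; its CSV schema (sex, age_years, L, M, S) is the
interface for supplying a published national reference.

GSRS: sub-dimension scores are means of their items, the total the mean
of all 15. The instrument's standard item→sub-dimension mapping is used
(abdominal pain 1/4/5, reflux 2/3, indigestion 6–9, diarrhea 11–13,
constipation 10/14/15). An item is "marked" at score ≥ 2 — any
discomfort above the scale floor; the threshold is configurable because
the categorisation ("0 marked / 1–5 / 6+") presupposes a definition the
instrument itself does not fix. Biochemical reference intervals are
closed (a value at either bound is within) and live in a YAML config
with package defaults; supply your laboratory's ranges for real use.

## Longitudinal statistics

Normality screening uses the KS statistic with the Lilliefors correction
(the normal parameters are estimated from the sample); the fully
specified KS test is a switch. |sample skewness| > 1 flags a variable
for natural-log transform; when zeros are present the offset is half the
smallest positive value. Paired visit contrasts use the Wilcoxon
signed-rank on pairwise-complete participants (all available data are
used; no imputation), dropping zero differences, with the exact null for
≤ 25 non-zero pairs and the tie-corrected normal approximation above;
fewer than 5 complete pairs yields an "underpowered" result without a
p-value. The two-arm contrast is a one-way ANOVA (two groups, so
F = t²), log-transforming skewed variables first. Correlation is
Pearson's r with a two-sided p. No multiple-testing correction is
applied by default, matching the single-comparison reporting convention
of small dietary studies; Benjamini–Hochberg is available as a helper.
p-values are always reported numerically; 0.05 is a reading convention,
not a rounding rule.

## Synthetic cohort generator

The generator emulates the study design end to end: 27 adults (mean age
37.1 ± 9.1, ~80% women) and 31 children (7.1 ± 3.9) at diagnosis,
retention 13/22 at 3 months and 4/16 at 12 months (dropout is
missing-at-random within arm — the emulated study reports no dropout
mechanism), three recall days per visit, FFQ at vt0/vt12, GSRS at every
visit. Default planted targets are the emulated study's reported cohort
means per arm and visit: energy (mean and SD), %E split, GFP energy
share, NOVA portion mix, total FODMAP (row-sum accounting), FFQ
frequencies, and symptom-category proportions following the described
trend (improvement at 3 months, partial recurrence at 12; the source
reports no numeric percentages, so the proportions are package choices).

Per participant-visit the targets are jittered (energy from its stated
SD; %E split with ~1–1.5 %E noise, the three shares clamped to sum in
[96, 98.8] so fibre — the energy-closure slack — stays in a realistic
1.2–4 %E band; GFP share ±2 points; NOVA portions and FODMAP total
scaled by the participant's energy draw, since food volume tracks
energy, times ~10% noise). Each recall day then samples a realistic food
set (staples guaranteeing solvability — dairy, fruit, oil, sugar, honey,
a lean protein, a vegetable, a legume, gluten-free bread when GFP are
allowed — plus a random complement from every NOVA group) and solves a
10-row non-negative least-squares system (protein, lipid, carbohydrate
and fibre grams; GFP kcal; four NOVA portion rows; FODMAP grams) for
gram amounts, retrying with fresh food sets until the weighted residual
is negligible. The fibre row carries a reduced weight: it is closure
slack, not a planted headline target. Ground truth records both the
per-participant planted values and the achieved values recomputed by a
deliberately simple per-event bookkeeping pass, independent of the
engines.

What the generator does *not* emulate: food-preference structure, meal
timing, seasonal menus, correlated day-to-day variation, reporting
error, and any nutrient not planted (sugars, SFA and cholesterol fall
out of the food mix rather than being controlled). Passing recovery
tests therefore demonstrate computational correctness of the engines on
design-faithful inputs, not behavioural realism of the menus.

`perturb` applies named longitudinal effects (scaling ultra-processed
amounts, shifting energy, raising GSRS scores) to paired participants
only, enabling power and type-I-error studies of the paired tests.

## Numerical choices and degenerate inputs

- Engines are exact summations; no rounding anywhere before output.
- Solver: `scipy.optimize.lsq_linear`, bounds [0, 800] g per food per
  day, rows scaled by target magnitude; foods with solved amounts
  < 0.05 g are dropped (ground truth is recomputed from the kept
  events, so bookkeeping stays exact).
- Percentile boundaries guard the printed cut-offs with a 1e-9 epsilon
  against floating round-trip noise.
- Zero-variance inputs: screening flags them degenerate; the group test
  and correlation raise.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical
  cohorts and pipeline outputs.

## Problem sizes used in the shipped checks

Unit and acceptance tests run a reduced cohort (10+10 participants with
the study's dropout structure) for engine equivalence and invariants, a
200-adult single-visit cohort for parameter recovery (cohort means
within 2% of planted values), 2000 simulated pair sets for the Wilcoxon
type-I error (accepted in [0.03, 0.07] at α = 0.05) and 400 for power
(> 0.9 at a 1-SD shift), and exhaustive 2^n enumeration up to n = 10 as
the exact-p oracle. These sizes keep the whole suite in the minutes
range on one CPU while leaving the statistical assertions comfortable
margins.
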