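"""Per-participant written reports and the end-to-end pipeline.

After each visit the evaluated participant receives a written summary:
nutritional-status diagnosis (BMI class, biochemical range checks), diet
quality (macronutrient and food-group adequacy, NOVA/GFP and FODMAP
summaries) and one templated advice line per flagged imbalance. Advice
wording lives in an editable YAML template, not in code; reports are a
pure function of the engine outputs, so identical inputs render
identical text.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from . import clinical_engine as ce
from . import fodmap_engine as fe
from . import intake_engine as ie
from . import nova_gfp_engine as ne
from .food_db import FoodTable, default_food_table, load_composition_table
from .records import (Cohort, CohortBundle, VisitCode, load_cohort)
from .intake_engine import Flag

log = logging.getLogger("gfdeval")

__all__ = ["ParticipantReport", "render_report", "PipelineConfig",
           "PipelineResult", "run_pipeline", "evaluate_participant_visit"]


def _load_advice() -> dict[str, str]:
    ref = resources.files("gfdeval.data").joinpath("templates/advice.yaml")
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


def _load_template() -> str:
    ref = resources.files("gfdeval.data").joinpath("templates/report_en.txt")
    return ref.read_text(encoding="utf-8")


@dataclass
class ParticipantReport:
    participant_id: str
    visit_code: str
    text: str
    data: dict                     # machine-readable companion content
    advice_lines: list[str] = field(default_factory=list)


_FFQ_WORD = {Flag.low: "below", Flag.adequate: "within", Flag.high: "above"}


def evaluate_participant_visit(bundle: CohortBundle, foods: FoodTable,
                               pid: str, vc: VisitCode,
                               growth_reference=None,
                               biochem_ranges=None) -> dict:
    """Run every engine for one participant-visit; missing inputs yield
    ``None`` sections rather than errors."""
    part = bundle.participant(pid)
    visit = bundle.visit(pid, vc)
    events = bundle.events_for(pid, vc)
    out: dict = {"participant": part, "visit": visit}

    if visit is not None:
        out["bmi"] = ce.classify_bmi(
            visit.weight_kg, visit.height_m, part.cohort,
            age_years=part.age_years, sex=part.sex,
            growth_reference=(growth_reference or ce.default_growth_reference()
                              if part.cohort == Cohort.pediatric else None))
        out["ranges"] = ce.check_ranges(visit, biochem_ranges)
        out["ee"] = ie.energy_expenditure(part, visit)
    if events:
        out["nutrients"] = ie.nutrient_profile(
            events, foods, energy_expenditure_kcal=out.get("ee"))
        if not out["nutrients"].incomplete:
            out["adequacy"] = ie.adequacy(out["nutrients"])
        out["fodmap"] = fe.fodmap_profile(events, foods)
        out["nova"] = ne.nova_profile(events, foods)
        out["gfp"] = ne.gfp_energy_contribution(events, foods)
    for f in bundle.ffq:
        if f.participant_id == pid and f.visit_code == vc:
            out["ffq"] = f
            out["ffq_adequacy"] = ie.ffq_adequacy(f)
    for r in bundle.gsrs:
        if r.participant_id == pid and r.visit_code == vc:
            out["gsrs"] = ce.score_gsrs(r)
    return out


def render_report(evaluation: dict, template: Optional[str] = None,
                  advice_map: Optional[dict[str, str]] = None) -> ParticipantReport:
    """Render the written per-participant report from one visit's engine
    outputs. Every low/high/above adequacy flag produces exactly one
    advice line; sections with missing inputs read "not assessed"."""
    template = template or _load_template()
    advice_map = advice_map or _load_advice()
    part = evaluation["participant"]

    status_lines = []
    bmi = evaluation.get("bmi")
    if bmi is not None:
        pc = f" (percentile {bmi.percentile:.1f})" if bmi.percentile is not None else ""
        status_lines.append(f"BMI {bmi.bmi_kg_m2:.1f} kg/m2: {bmi.bmi_class.value}{pc}")
    else:
        status_lines.append("BMI: not assessed")
    ranges = evaluation.get("ranges")
    if ranges:
        for r in ranges:
            status_lines.append(
                f"{r.analyte}: {r.value:g} [{r.low:g}-{r.high:g}] {r.status.value}")
    else:
        status_lines.append("Biochemistry: not assessed")

    quality_lines = []
    prof = evaluation.get("nutrients")
    if prof is not None:
        quality_lines.append(
            f"Energy {prof.energy_kcal_day:.0f} kcal/day"
            + (f" (expenditure {prof.energy_expenditure_kcal_day:.0f} kcal/day)"
               if prof.energy_expenditure_kcal_day else ""))
        quality_lines.append(
            f"Protein {prof.protein_pctE:.1f} %E, lipids {prof.lipid_pctE:.1f} %E "
            f"(SFA {prof.sfa_pctE:.1f} %E), carbohydrates {prof.carb_pctE:.1f} %E "
            f"(sugars {prof.sugars_pctE:.1f} %E)")
        quality_lines.append(
            f"Fibre {prof.fibre_g_day:.1f} g/day, cholesterol "
            f"{prof.cholesterol_mg_day:.0f} mg/day")
    else:
        quality_lines.append("24-h recall profile: not assessed")
    nova = evaluation.get("nova")
    if nova is not None:
        quality_lines.append("NOVA portions/day: " + ", ".join(
            f"{g.value} {nova.portions_day[g]:.1f}" for g in nova.portions_day))
    gfp = evaluation.get("gfp")
    if gfp is not None:
        quality_lines.append(f"Gluten-free products: {gfp.gfp_pctE:.1f}% of energy")
    fod = evaluation.get("fodmap")
    if fod is not None:
        quality_lines.append(
            f"Total FODMAP {fod.total_fodmap_g_day:.1f} g/day "
            f"(coverage {fod.coverage_fraction:.0%})")
    gsrs = evaluation.get("gsrs")
    if gsrs is not None:
        quality_lines.append(
            f"GSRS total {gsrs.total_score:.2f}, {gsrs.marked_count} marked "
            f"symptom(s) ({gsrs.symptom_category.value})")
    else:
        quality_lines.append("Symptoms: not assessed")

    advice: list[str] = []
    flags_data: dict[str, str] = {}
    for comp, flag in (evaluation.get("adequacy") or {}).items():
        flags_data[comp] = flag.value
        if flag != Flag.adequate:
            key = f"{comp}:{flag.value}"
            advice.append(advice_map.get(key, f"{comp}: {flag.value}"))
    for group, flag in (evaluation.get("ffq_adequacy") or {}).items():
        word = _FFQ_WORD[flag]
        flags_data[f"ffq.{group.value}"] = word
        if flag != Flag.adequate:
            key = f"ffq.{group.value}:{word}"
            advice.append(advice_map.get(key, f"{group.value}: {word}"))

    vc = (evaluation["visit"].visit_code.value if evaluation.get("visit")
          else (prof.visit_code if prof else "?"))
    text = template.format(
        participant_id=part.participant_id, visit_code=vc,
        cohort=part.cohort.value,
        nutritional_status="\n".join(status_lines),
        diet_quality="\n".join(quality_lines),
        advice="\n".join(advice) if advice else "No imbalances flagged.")

    data = {
        "participant_id": part.participant_id, "visit_code": vc,
        "flags": flags_data, "advice": advice,
        "nutrients": (None if prof is None else {
            "energy_kcal_day": prof.energy_kcal_day,
            "protein_pctE": prof.protein_pctE, "lipid_pctE": prof.lipid_pctE,
            "carb_pctE": prof.carb_pctE, "sfa_pctE": prof.sfa_pctE,
            "sugars_pctE": prof.sugars_pctE, "fibre_g_day": prof.fibre_g_day,
            "cholesterol_mg_day": prof.cholesterol_mg_day}),
        "gfp_pctE": None if gfp is None else gfp.gfp_pctE,
        "total_fodmap_g_day": None if fod is None else fod.total_fodmap_g_day,
        "gsrs": None if gsrs is None else {
            "total": gsrs.total_score, "marked": gsrs.marked_count,
            "category": gsrs.symptom_category.value},
    }
    return ParticipantReport(part.participant_id, vc, text, data, advice)


@dataclass
class PipelineConfig:
    data_dir: Optional[str] = None      # load an existing cohort ...
    synth_seed: Optional[int] = None    # ... or generate one
    out_dir: str = "gfdeval_out"
    food_table_path: Optional[str] = None
    weighted_days: bool = False
    write_reports: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(cfg) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


@dataclass
class PipelineResult:
    bundle: CohortBundle
    profiles: dict                     # (pid, visit) -> evaluation dict
    reports: list[ParticipantReport]
    counts: dict[str, int]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load (or synthesise) a cohort, run every engine per participant-
    visit, render reports and write tabular outputs under ``out_dir``.

    Raises on validation errors; deterministic for a fixed config/seed.
    """
    foods = (load_composition_table(config.food_table_path)
             if config.food_table_path else default_food_table())
    if config.data_dir is not None:
        bundle, report = load_cohort(config.data_dir, foods)
        if not report.ok:
            raise ValueError(
                f"cohort failed validation: {len(report.rejected)} rejected rows; "
                f"first: {report.rejected[:3]}")
        log.info("loaded cohort: %s", report.n_accepted)
    elif config.synth_seed is not None:
        from .synth_cohort import generate, study_design_spec
        bundle, _ = generate(study_design_spec(seed=config.synth_seed))
        log.info("generated synthetic cohort with seed %d", config.synth_seed)
    else:
        raise ValueError("config needs data_dir or synth_seed")

    growth = ce.default_growth_reference()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    profiles = {}
    reports = []
    rows = []
    for pid, vc in sorted(bundle.participant_visits()):
        ev = evaluate_participant_visit(bundle, foods, pid, vc,
                                        growth_reference=growth)
        profiles[(pid, vc.value)] = ev
        prof = ev.get("nutrients")
        if prof is not None:
            fod, gfp, nova = ev.get("fodmap"), ev.get("gfp"), ev.get("nova")
            rows.append({
                "participant_id": pid, "visit_code": vc.value,
                "cohort": ev["participant"].cohort.value,
                "energy_kcal_day": prof.energy_kcal_day,
                "protein_pctE": prof.protein_pctE,
                "lipid_pctE": prof.lipid_pctE, "sfa_pctE": prof.sfa_pctE,
                "carb_pctE": prof.carb_pctE, "sugars_pctE": prof.sugars_pctE,
                "fibre_g_day": prof.fibre_g_day,
                "cholesterol_mg_day": prof.cholesterol_mg_day,
                "gfp_pctE": gfp.gfp_pctE if gfp else None,
                "total_fodmap_g_day": fod.total_fodmap_g_day if fod else None,
                **{f"nova_{g.value}_portions": nova.portions_day[g]
                   for g in nova.portions_day},
            })
        if config.write_reports:
            rep = render_report(ev)
            reports.append(rep)
            (out_dir / f"report_{pid}_{vc.value}.txt").write_text(
                rep.text, encoding="utf-8")
            (out_dir / f"report_{pid}_{vc.value}.json").write_text(
                json.dumps(rep.data, indent=1, sort_keys=True), encoding="utf-8")

    import pandas as pd
    pd.DataFrame(rows).to_csv(out_dir / "profiles.csv", index=False)

    counts = {"participants": len(bundle.participants),
              "participant_visits": len(profiles),
              "intake_events": len(bundle.events),
              "reports": len(reports)}
    log.info("pipeline complete: %s", counts)
    return PipelineResult(bundle, profiles, reports, counts)
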