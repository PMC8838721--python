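import filecmp
from pathlib import Path

import numpy as np
import pytest
from pydantic import ValidationError

from gfdeval.records import VisitCode, load_cohort, save_cohort
from gfdeval.synth_cohort import (CohortSpec, InfeasibleSpec, VisitTargets,
                                  generate, perturb, study_design_spec)

from conftest import small_spec


def _zero_gfp_spec(seed=5):
    spec = small_spec(seed)
    targets = {arm: {vc: t.model_copy(update={"gfp_energy_pct": 0.0})
                     for vc, t in per.items()}
               for arm, per in spec.targets.items()}
    return spec.model_copy(update={"targets": targets})


class TestSpecValidation:
    def test_pct_split_must_leave_fibre_gap(self):
        with pytest.raises(ValidationError, match="fibre"):
            VisitTargets(energy_kcal=2000, energy_sd_kcal=100,
                         protein_pctE=20, lipid_pctE=40, carb_pctE=45,
                         gfp_energy_pct=20, nova_portions=(5, 2, 1, 4),
                         fodmap_total_g=30)

    def test_gsrs_props_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            VisitTargets(energy_kcal=2000, energy_sd_kcal=100,
                         protein_pctE=16, lipid_pctE=41, carb_pctE=40,
                         gfp_energy_pct=20, nova_portions=(5, 2, 1, 4),
                         fodmap_total_g=30,
                         gsrs_category_props=(0.5, 0.5, 0.5))

    def test_dropout_counts_must_be_monotone(self):
        with pytest.raises(ValidationError, match="non-increasing"):
            CohortSpec(adults_per_visit=(10, 12, 3))


class TestGenerate:
    def test_same_seed_byte_identical(self, tmp_path, foods):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            bundle, _ = generate(small_spec(7), foods)
            save_cohort(bundle, d)
        for name in ("participants.csv", "visits.csv", "recalls.csv",
                     "ffq.csv", "gsrs.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seed_differs(self, foods):
        b1, _ = generate(small_spec(1), foods)
        b2, _ = generate(small_spec(2), foods)
        assert [e.amount_g for e in b1.events] != [e.amount_g for e in b2.events]

    def test_bundle_passes_records_validation(self, tmp_path, foods,
                                              small_cohort):
        bundle, _ = small_cohort
        save_cohort(bundle, tmp_path)
        _, report = load_cohort(tmp_path, foods)
        assert report.ok

    def test_dropout_structure(self, small_cohort):
        bundle, _ = small_cohort
        by_visit = {vc: {pid for pid, c in bundle.participant_visits()
                         if c == vc} for vc in VisitCode}
        assert by_visit[VisitCode.vt3] <= by_visit[VisitCode.vt0]
        assert by_visit[VisitCode.vt12] <= by_visit[VisitCode.vt3]
        adults = {p.participant_id for p in bundle.participants
                  if p.participant_id.startswith("A")}
        assert len(by_visit[VisitCode.vt0] & adults) == 10
        assert len(by_visit[VisitCode.vt3] & adults) == 6
        assert len(by_visit[VisitCode.vt12] & adults) == 3

    def test_zero_gfp_share_means_no_gfp_events(self, foods):
        bundle, _ = generate(_zero_gfp_spec(), foods)
        assert not any(foods[e.food_id].is_gfp for e in bundle.events)

    def test_recall_day_structure(self, small_cohort):
        bundle, _ = small_cohort
        for pid, vc in bundle.participant_visits():
            days = {}
            for e in bundle.events_for(pid, vc):
                days[e.day_index] = e.day_type.value
            assert sorted(days) == [1, 2, 3]
            assert sum(1 for t in days.values() if t == "weekend") == 1

    def test_planted_values_recovered_by_bookkeeping(self, small_cohort):
        bundle, gt = small_cohort
        rels = []
        for (pid, vc), pv in gt.values.items():
            for k in ("energy_kcal", "protein_pctE", "lipid_pctE",
                      "carb_pctE", "gfp_energy_pct", "fodmap_g"):
                rels.append(abs(pv.achieved[k] - pv.planted[k])
                            / max(abs(pv.planted[k]), 1e-9))
        assert float(np.median(rels)) < 1e-4   # typical solve is near-exact
        assert float(np.mean(rels)) < 0.01     # rare tight cases stay close

    def test_gsrs_planted_categories_match_scored(self, small_cohort):
        from gfdeval.clinical_engine import score_gsrs
        bundle, gt = small_cohort
        for r in bundle.gsrs:
            planted = gt.gsrs_planted_category[(r.participant_id,
                                                r.visit_code.value)]
            assert score_gsrs(r).symptom_category.value == planted


class TestPerturb:
    def test_zero_delta_identity(self, foods, small_cohort):
        bundle, _ = small_cohort
        out = perturb(bundle, foods, "reduce_g4_amounts", delta=0.0)
        assert [e.model_dump() for e in out.events] == \
               [e.model_dump() for e in bundle.events]

    def test_effect_leaves_vt0_untouched(self, foods, small_cohort):
        bundle, _ = small_cohort
        out = perturb(bundle, foods, "reduce_g4_amounts", delta=0.5,
                      visit=VisitCode.vt3)
        before = [e.amount_g for e in bundle.events
                  if e.visit_code == VisitCode.vt0]
        after = [e.amount_g for e in out.events
                 if e.visit_code == VisitCode.vt0]
        assert before == after
        g4_before = sum(e.amount_g for e in bundle.events
                        if e.visit_code == VisitCode.vt3
                        and foods[e.food_id].nova_group.value == "G4")
        g4_after = sum(e.amount_g for e in out.events
                       if e.visit_code == VisitCode.vt3
                       and foods[e.food_id].nova_group.value == "G4")
        assert g4_after < g4_before

    def test_unknown_effect(self, foods, small_cohort):
        bundle, _ = small_cohort
        with pytest.raises(ValueError, match="unknown effect"):
            perturb(bundle, foods, "teleport", delta=1.0)

    def test_wilcoxon_detects_large_g4_reduction(self, foods, small_cohort):
        from gfdeval.nova_gfp_engine import nova_profile
        from gfdeval.stats_longitudinal import paired_visit_test
        bundle, _ = small_cohort
        out = perturb(bundle, foods, "reduce_g4_amounts", delta=0.6,
                      visit=VisitCode.vt3)
        vals, ids = {}, {}
        for vc in (VisitCode.vt0, VisitCode.vt3):
            vals[vc], ids[vc] = [], []
            for pid, code in out.participant_visits():
                if code == vc:
                    prof = nova_profile(out.events_for(pid, code), foods)
                    vals[vc].append(sum(
                        v for g, v in prof.portions_day.items()
                        if g.value == "G4"))
                    ids[vc].append(pid)
        res = paired_visit_test(vals[VisitCode.vt0], vals[VisitCode.vt3],
                                ids[VisitCode.vt0], ids[VisitCode.vt3])
        assert res.p_value < 0.01
        assert res.statistic < 0
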