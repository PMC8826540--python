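import copy
import json

import numpy as np
import pytest

from pulsesv import (ScalingFactors, SubjectRecord, ValidationError,
                     adjust_anatomy, apply_age_distensibility, apply_scalings,
                     build_generic_tree)
from pulsesv.tree import _default_config


def subject(**kw):
    base = dict(id="s", gender="F", age=40, height_cm=170, weight_kg=70,
                brsbp_mmhg=120, brdbp_mmhg=70, hr_bpm=66, cfpwv_mps=7.0)
    base.update(kw)
    return SubjectRecord(**base)


class TestGenericTree:
    def test_structure_and_sites(self, generic_tree):
        assert generic_tree.root == "ascending_aorta"
        assert len(generic_tree.segments) >= 20
        for site in ("carotid", "brachial", "femoral"):
            assert generic_tree.path_length_to_site(site) > 0
        # femoral path exceeds the carotid path (cfPWV needs the asymmetry)
        assert (generic_tree.path_length_to_site("femoral")
                > generic_tree.path_length_to_site("carotid"))

    def test_total_resistance_matches_cohort_arithmetic(self, generic_tree):
        # MAP/(SV*HR/60) at cohort means: 88 mmHg at 92 mL/s -> ~0.95 mmHg s/mL
        assert generic_tree.total_peripheral_resistance() == pytest.approx(0.95, rel=0.05)

    def test_parallel_resistance_bookkeeping(self, generic_tree):
        declared = generic_tree.meta["reference_r_total_mmhg_s_ml"]
        assert generic_tree.total_peripheral_resistance() == pytest.approx(
            declared, rel=1e-9)

    def test_declared_compliance_matches_table(self, generic_tree):
        declared = generic_tree.meta["reference_c_total_ml_mmhg"]
        assert generic_tree.total_compliance() == pytest.approx(declared, rel=1e-6)

    @pytest.mark.parametrize("mutation,match", [
        (lambda c: c["segments"][3].__setitem__("parent", c["segments"][3]["name"]),
         "parent"),
        (lambda c: c["terminals"].pop(), "Windkessel terminal"),
        (lambda c: c["sites"]["femoral"].__setitem__("segment", "nonexistent"),
         "unresolvable"),
    ])
    def test_invalid_configs_rejected(self, mutation, match):
        cfg = copy.deepcopy(_default_config())
        mutation(cfg)
        with pytest.raises(ValidationError, match=match):
            build_generic_tree(cfg)

    def test_cycle_detected(self):
        cfg = copy.deepcopy(_default_config())
        # l_iliac -> abdominal_aorta_c -> ... replaced by a 2-cycle
        cfg["segments"][15]["parent"] = "l_iliac"   # abdominal_aorta_c
        with pytest.raises(ValidationError):
            build_generic_tree(cfg)


class TestAnatomy:
    def test_reference_demographics_identity(self, generic_tree):
        adj = adjust_anatomy(generic_tree, subject(height_cm=170, weight_kg=70))
        for a, b in zip(adj.segments, generic_tree.segments):
            assert a.length_cm == pytest.approx(b.length_cm, abs=1e-12)
            assert a.area_prox_cm2 == pytest.approx(b.area_prox_cm2, abs=1e-12)
            assert a.distensibility_per_mmhg == b.distensibility_per_mmhg

    def test_height_scales_lengths_and_paths(self, generic_tree):
        adj = adjust_anatomy(generic_tree, subject(height_cm=187, weight_kg=70))
        for a, b in zip(adj.segments, generic_tree.segments):
            assert a.length_cm == pytest.approx(1.1 * b.length_cm, rel=1e-12)
        d0 = (generic_tree.path_length_to_site("femoral")
              - generic_tree.path_length_to_site("carotid"))
        d1 = (adj.path_length_to_site("femoral")
              - adj.path_length_to_site("carotid"))
        assert d1 == pytest.approx(1.1 * d0, rel=1e-12)

    def test_gender_neutral_by_default(self, generic_tree):
        m = adjust_anatomy(generic_tree, subject(gender="M"))
        f = adjust_anatomy(generic_tree, subject(gender="F"))
        for a, b in zip(m.segments, f.segments):
            assert a.area_prox_cm2 == b.area_prox_cm2
            assert a.length_cm == b.length_cm

    def test_non_physiological_height_rejected(self, generic_tree):
        with pytest.raises(ValidationError):
            subject(height_cm=90)


class TestAging:
    def test_reference_age_is_identity(self, generic_tree):
        aged = apply_age_distensibility(generic_tree, 25)
        for a, b in zip(aged.segments, generic_tree.segments):
            assert a.distensibility_per_mmhg == pytest.approx(
                b.distensibility_per_mmhg, rel=1e-12)

    def test_factor_non_increasing_over_adulthood(self, generic_tree):
        ages = np.linspace(18, 90, 37)
        aorta = "thoracic_aorta"
        prox = "ascending_aorta"
        d_prox = [apply_age_distensibility(generic_tree, a).segment(prox)
                  .distensibility_per_mmhg for a in ages]
        d_dist = [apply_age_distensibility(generic_tree, a).segment(aorta)
                  .distensibility_per_mmhg for a in ages]
        assert all(x >= y - 1e-15 for x, y in zip(d_prox, d_prox[1:]))
        assert all(x >= y - 1e-15 for x, y in zip(d_dist, d_dist[1:]))

    def test_proximal_stiffening_stronger_than_distal(self, generic_tree):
        aged = apply_age_distensibility(generic_tree, 75)
        ratio = {s.name: aged.segment(s.name).distensibility_per_mmhg
                 / s.distensibility_per_mmhg for s in generic_tree.segments}
        assert ratio["ascending_aorta"] < ratio["thoracic_aorta"] < 1.0
        assert ratio["l_femoral"] == 1.0  # non-aortic segments untouched

    def test_below_adult_age_rejected(self, generic_tree):
        with pytest.raises(ValidationError):
            apply_age_distensibility(generic_tree, 12)


class TestScalings:
    def test_identity_scaling(self, generic_tree):
        out = apply_scalings(generic_tree, ScalingFactors(1, 1, 1))
        assert out.total_peripheral_resistance() == pytest.approx(
            generic_tree.total_peripheral_resistance(), rel=1e-12)
        assert out.total_compliance() == pytest.approx(
            generic_tree.total_compliance(), rel=1e-12)

    @pytest.mark.parametrize("s_r", [0.5, 2.0, 4.9])
    def test_resistance_scales_exactly(self, generic_tree, s_r):
        out = apply_scalings(generic_tree, ScalingFactors(1.0, s_r, 1.0))
        assert out.total_peripheral_resistance() == pytest.approx(
            s_r * generic_tree.total_peripheral_resistance(), rel=1e-9)

    def test_compliance_scales_all_distensibilities(self, generic_tree):
        out = apply_scalings(generic_tree, ScalingFactors(3.0, 1.0, 1.0))
        for a, b in zip(out.segments, generic_tree.segments):
            assert a.distensibility_per_mmhg == pytest.approx(
                3.0 * b.distensibility_per_mmhg, rel=1e-12)
        assert out.total_compliance() == pytest.approx(
            3.0 * generic_tree.total_compliance(), rel=1e-9)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            ScalingFactors(0.1, 1.0, 1.0)
        with pytest.raises(ValidationError):
            ScalingFactors(1.0, 5.5, 1.0)


class TestSubjectRecord:
    @pytest.mark.parametrize("kw", [
        dict(brsbp_mmhg=70, brdbp_mmhg=80),
        dict(hr_bpm=10),
        dict(cfpwv_mps=1.0),
        dict(age=15),
        dict(gender="X"),
    ])
    def test_invariants_enforced(self, kw):
        with pytest.raises(ValidationError):
            subject(**kw)

    def test_map_convention(self):
        s = subject(brsbp_mmhg=120, brdbp_mmhg=60)
        assert s.map_mmhg == pytest.approx(80.0)
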