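"""Maternal and fetal physiology curves: baselines, monotonicity, landmarks."""

import math

import numpy as np
import pytest

from pregpk import (SubjectSpec, fetal_state, maternal_physiology,
                    scale_transporter_expression, weight_gain)
from pregpk.physiology import amniotic_fluid_volume


class TestSubjectSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(age=30, prepregnancy_weight=60, height=160, gestational_age=45),
        dict(age=30, prepregnancy_weight=-1, height=160),
        dict(age=30, prepregnancy_weight=60, height=160, gestational_age=20,
             sex="male"),
        dict(age=16, prepregnancy_weight=60, height=160, gestational_age=20),
        dict(age=30, prepregnancy_weight=60, height=160, sex="other"),
    ])
    def test_invalid_subjects_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SubjectSpec(**kwargs)


class TestWeightGain:
    def test_zero_before_pregnancy(self, female_617):
        assert weight_gain(female_617(0)) == 0.0

    def test_cz_subject_gains_about_six_kg_at_25_weeks(self):
        # 62 kg subject with ~6 kg gain at 25 wk GA
        spec = SubjectSpec(age=25, prepregnancy_weight=62, height=160,
                           gestational_age=25)
        assert weight_gain(spec) == pytest.approx(6.0, abs=2.0)

    def test_monotone_and_nonnegative(self, female_617):
        gains = [weight_gain(female_617(ga)) for ga in np.linspace(0, 41, 83)]
        assert all(g >= 0 for g in gains)
        assert all(b > a for a, b in zip(gains, gains[1:]))
        assert weight_gain(female_617(41)) > weight_gain(female_617(20))


class TestMaternalPhysiology:
    def test_nonpregnant_reduction_at_ga_zero(self, female_617):
        p = maternal_physiology(female_617(0))
        assert p.weight_gain == 0.0
        assert p.total_body_weight == 61.7
        assert p.albumin_ratio == 1.0 and p.agp_ratio == 1.0
        assert "placenta_maternal" not in p.volumes
        assert "placenta_maternal" not in p.flows

    def test_gfr_increases_in_pregnancy(self, female_617):
        assert (maternal_physiology(female_617(25)).gfr
                > maternal_physiology(female_617(0)).gfr)

    def test_gfr_monotone_through_mid_gestation(self, female_617):
        gfrs = [maternal_physiology(female_617(ga)).gfr
                for ga in np.linspace(0, 25, 26)]
        assert all(b > a for a, b in zip(gfrs, gfrs[1:]))

    def test_hemodilution_regression_values(self, female_617):
        """Frozen oracle: hematocrit falls and plasma volume expands at 38 wk."""
        p0 = maternal_physiology(female_617(0))
        p38 = maternal_physiology(female_617(38))
        assert p38.hematocrit < p0.hematocrit
        assert p38.plasma_volume > p0.plasma_volume
        assert p38.hematocrit == pytest.approx(0.34162311081198105, rel=1e-9)
        assert p38.plasma_volume == pytest.approx(3.5965809397089084, rel=1e-9)
        assert p0.gfr == pytest.approx(112.32931755866684, rel=1e-9)
        assert maternal_physiology(female_617(25)).gfr == pytest.approx(
            165.00185308221307, rel=1e-9)

    def test_continuity_in_ga(self, female_617):
        gas = np.linspace(0, 42, 211)
        gfr = np.array([maternal_physiology(female_617(g)).gfr for g in gas])
        pv = np.array([maternal_physiology(female_617(g)).plasma_volume for g in gas])
        assert np.abs(np.diff(gfr)).max() < 2.0      # mL/min per 0.2 wk
        assert np.abs(np.diff(pv)).max() < 0.05      # L per 0.2 wk

    def test_flow_balance(self, female_617, male70):
        for spec in (female_617(0), female_617(30), male70):
            p = maternal_physiology(spec)
            assert sum(p.flows.values()) <= p.cardiac_output_plasma * (1 + 1e-12)
            assert all(v > 0 for v in p.volumes.values())
            assert all(q > 0 for q in p.flows.values())

    @pytest.mark.parametrize("ga", [20.0, 30.0, 40.0])
    def test_mass_consistency(self, female_617, ga):
        """Pregnancy tissue increments must be covered by the weight gain."""
        p0 = maternal_physiology(female_617(0))
        p = maternal_physiology(female_617(ga))
        fs = fetal_state(ga)
        increments = (
            (p.volumes["kidney"] - p0.volumes["kidney"])
            + (p.volumes["uterus"] - p0.volumes["uterus"])
            + p.volumes["placenta_maternal"] + fs.fetal_placenta_volume
            + fs.fetal_weight + fs.amniotic_fluid_volume
            + (p.plasma_volume - p0.plasma_volume)
            + (p.volumes["skin"] - p0.volumes["skin"])
            + (p.volumes["adipose"] - p0.volumes["adipose"])
        )
        assert increments <= 1.15 * p.weight_gain

    def test_fup_adjustment_identity_at_baseline(self, female_617):
        p0 = maternal_physiology(female_617(0))
        assert p0.fup_at_ga(0.67) == 0.67
        p38 = maternal_physiology(female_617(38))
        assert p38.fup_at_ga(0.67) > 0.67  # albumin dilution frees drug

    def test_snapshot_export(self, female_617):
        df = maternal_physiology(female_617(30)).to_frame()
        assert set(df.columns) == {"parameter", "value", "units"}
        assert (df.parameter == "GFR").any()


class TestFetalState:
    def test_term_weight_is_reference_birth_weight(self):
        assert fetal_state(40).fetal_weight == pytest.approx(3.32, rel=0.10)

    def test_zero_state_before_pregnancy(self):
        fs = fetal_state(0)
        assert fs.fetal_weight == 0.0
        assert fs.amniotic_fluid_volume == 0.0
        assert fs.fetal_gfr == 0.0

    def test_no_urine_before_onset(self):
        assert fetal_state(8).fetal_gfr == 0.0

    def test_monotone_growth(self):
        gas = np.linspace(9, 40, 63)
        states = [fetal_state(g) for g in gas]
        for attr in ("fetal_weight", "fetal_height", "fetal_blood_volume",
                     "fetal_tissue_volume", "fetal_placenta_volume",
                     "fetal_hematocrit", "fetal_gfr", "protein_ratio"):
            vals = [getattr(s, attr) for s in states]
            assert all(b >= a for a, b in zip(vals, vals[1:])), attr

    def test_amniotic_fluid_volume_curve(self):
        # peaks around 34 wk, declines toward term, zero at GA 0
        assert amniotic_fluid_volume(0.0) == 0.0
        assert amniotic_fluid_volume(34.0) == pytest.approx(0.8500461874958376,
                                                            rel=1e-9)
        assert amniotic_fluid_volume(40.0) < amniotic_fluid_volume(34.0)
        assert amniotic_fluid_volume(20.0) < amniotic_fluid_volume(34.0)

    def test_range_errors(self):
        with pytest.raises(ValueError):
            fetal_state(-1)
        with pytest.raises(ValueError):
            fetal_state(43)


class TestTransporterScaling:
    def test_identity_and_proportionality(self):
        assert scale_transporter_expression(100.0, 1.0) == 100.0
        assert scale_transporter_expression(100.0, 1.3) == pytest.approx(130.0)

    def test_kidney_volume_ratio_drives_pregnant_vmax(self, female_617):
        p0 = maternal_physiology(female_617(0))
        p30 = maternal_physiology(female_617(30))
        ratio = p30.volumes["kidney"] / p0.volumes["kidney"]
        assert scale_transporter_expression(100.0, ratio) == pytest.approx(
            100.0 * ratio)
        assert ratio > 1

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            scale_transporter_expression(-1.0, 1.0)
        with pytest.raises(ValueError):
            scale_transporter_expression(100.0, 0.0)
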