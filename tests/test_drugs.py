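"""Partition coefficients, clearance primitives, fixture provenance."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pregpk import (DrugParameters, kp_lukacova, kp_poulin_theil_extracellular,
                    load_drug, mm_rate, renal_filtration_clearance)
from pregpk.drugs import (EXTRACELLULAR_ALBUMIN_RATIO, TissueComposition,
                          load_tissue_composition)


def neutral_probe(logp=0.0, fup=1.0):
    return DrugParameters(
        name="probe", molecular_weight=300.0, logp=logp, pka_list=[],
        fup=fup, blood_plasma_ratio=1.0, fup_fetal=fup,
    )


class TestKpLukacova:
    def test_neutral_unbound_compound_partitions_like_water(self):
        """logP=0, fup=1: Kp approaches the tissue/plasma water ratio.

        Hand oracle for muscle: f_ew + f_iw + f_nl + (0.3+0.7)*f_np
        vs water ratio (f_ew + f_iw) / 0.945.
        """
        comp = load_tissue_composition()["muscle"]
        kp = kp_lukacova(neutral_probe(), "muscle")
        water_ratio = (comp.f_ew + comp.f_iw) / 0.945
        assert kp == pytest.approx(water_ratio, rel=0.20)
        oracle = comp.f_ew + comp.f_iw + comp.f_nl + comp.f_np
        assert kp == pytest.approx(oracle, rel=1e-6)

    def test_kp_increases_with_logp_for_neutral_compound(self):
        kps = [kp_lukacova(neutral_probe(logp=p), "adipose")
               for p in (-1.0, 0.0, 1.0, 2.0)]
        assert all(b > a for a, b in zip(kps, kps[1:]))

    def test_plasma_like_composition_gives_unit_kp(self, cfx):
        plasma_like = TissueComposition(f_ew=0.945, f_iw=0.0, f_nl=0.0023,
                                        f_np=0.0013, alb_ratio=1.0)
        assert kp_lukacova(cfx, plasma_like) == pytest.approx(1.0, rel=0.10)

    def test_positive_continuous_in_fup(self, cfx):
        kps = [kp_lukacova(cfx, "kidney", fup=f) for f in (0.05, 0.2, 0.5, 1.0)]
        assert all(k > 0 and math.isfinite(k) for k in kps)

    @pytest.mark.parametrize("drug_fixture", ["cfx", "cz"])
    def test_fixture_kps_physiologically_plausible(self, drug_fixture, request):
        """Perfusion-tissue Kps for these polar acids fall in 0.05-5."""
        drug = request.getfixturevalue(drug_fixture)
        for tissue in ("adipose", "brain", "heart", "liver", "lung", "muscle",
                       "skin", "spleen", "kidney", "placenta", "rest"):
            assert 0.05 <= kp_lukacova(drug, tissue) <= 5.0

    def test_unknown_tissue_is_config_error(self, cfx):
        with pytest.raises(KeyError):
            kp_lukacova(cfx, "bone")


class TestKpExtracellular:
    def test_unbound_low_logp_limit_is_extracellular_water(self):
        comp = load_tissue_composition()["kidney"]
        kp = kp_poulin_theil_extracellular(neutral_probe(logp=-3.0), "kidney")
        assert kp == pytest.approx(comp.f_ew, rel=1e-9)

    def test_explicit_fup_dependence(self, cfx):
        """Hand oracle: Kp_ec = fup*f_ew + r_alb*(1 - fup)."""
        comp = load_tissue_composition()["kidney"]
        for fup in (0.09, 0.335, 0.67):
            expected = fup * comp.f_ew + EXTRACELLULAR_ALBUMIN_RATIO * (1 - fup)
            assert kp_poulin_theil_extracellular(cfx, "kidney", fup=fup) == \
                pytest.approx(expected, rel=1e-12)

    def test_cfx_kidney_kp_finite_positive(self, cfx):
        kp = kp_poulin_theil_extracellular(cfx, "kidney")
        assert kp > 0 and math.isfinite(kp)


class TestClearancePrimitives:
    def test_filtration_is_product(self):
        assert renal_filtration_clearance(0.09, 120.0) == pytest.approx(10.8)
        assert renal_filtration_clearance(1.0, 88.0) == 88.0
        assert renal_filtration_clearance(0.0, 88.0) == 0.0

    def test_mm_rate_half_saturation_and_limits(self):
        assert mm_rate(50.0, 50.0, 200.0) == pytest.approx(100.0)
        assert mm_rate(1e9, 50.0, 200.0) == pytest.approx(200.0, rel=1e-6)
        c = 0.5  # km/100
        assert mm_rate(c, 50.0, 200.0) == pytest.approx(200.0 / 50.0 * c,
                                                        rel=0.01)

    def test_mm_rate_domain_errors(self):
        with pytest.raises(ValueError):
            mm_rate(1.0, 0.0, 100.0)
        with pytest.raises(ValueError):
            mm_rate(-1.0, 10.0, 100.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(a=st.floats(0, 1e4), b=st.floats(0, 1e4))
    def test_mm_rate_globally_lipschitz(self, a, b):
        km, vmax = 27.6, 5e5
        lip = vmax / km
        assert abs(mm_rate(a, km, vmax) - mm_rate(b, km, vmax)) <= \
            lip * abs(a - b) + 1e-6


class TestFixtureLoading:
    def test_printed_cz_constants(self, cz):
        assert cz.transporter("OAT3").km_um == 117.0
        assert cz.transporter("MRP4").km_um == 80.9
        assert cz.fup == 0.09

    def test_cfx_mrp4_km_equals_oat3(self, cfx):
        assert cfx.transporter("MRP4").km_um == cfx.transporter("OAT3").km_um
        assert cfx.provenance["transporters.MRP4.km_um"] == "assumed"

    def test_every_numeric_carries_provenance(self, cfx, cz):
        tags = {"printed", "supplementary", "literature", "fitted", "assumed",
                "calibrated"}
        for drug in (cfx, cz):
            assert drug.provenance, "empty provenance map"
            assert set(drug.provenance.values()) <= tags
            assert drug.provenance["fup"] in tags

    def test_untagged_numeric_rejected(self):
        with pytest.raises(ValueError, match="provenance tag"):
            load_drug({
                "name": "bad", "molecular_weight": 300.0,
                "logp": {"value": 0.0, "tag": "literature"},
                "fup": {"value": 0.5, "tag": "literature"},
                "blood_plasma_ratio": {"value": 1.0, "tag": "assumed"},
                "fup_fetal": {"value": 0.5, "tag": "assumed"},
            })

    def test_invalid_fup_rejected(self):
        with pytest.raises(ValueError):
            neutral_probe(fup=0.0)
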