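"""Assembly of the maternal-fetal PBPK compartment graph.

Maternal side: whole-body PBPK with lung in series and the systemic tissues
in parallel between arterial and venous plasma; the kidney is permeability-
limited with vascular / extracellular / intracellular sub-spaces, a small
tubular-filtrate space draining to urine, passive permeability-surface area
(PStc) barriers, OAT3 basolateral influx (vascular -> cell) and MRP4 apical
efflux (cell -> filtrate); renal filtration is fup x GFR from kidney plasma
into the filtrate.

Fetal side (GA > 0): venous + arterial plasma, a lumped perfusion-limited
fetal tissue, the fetal-facing placenta, and the amniotic fluid.  The
placenta is split into maternal-facing and fetal-facing sub-tissues, each
perfused from its own circulation and coupled through their PStc values in
series.  Fetal renal clearance (fetal fup x fetal GFR) moves drug from
fetal blood into the amniotic fluid; the swallowing / secretion /
intramembranous / transmembranous pathways connect amniotic fluid with
fetal tissue, fetal blood, and the uterine wall.

GA = 0 produces a standard non-pregnant model with no fetal compartments.
"""

from __future__ import annotations

import numpy as np

from . import units
from .amniotic import AmnioticRates, amniotic_rates
from .compartments import CompartmentGraph, DoseRegimen, SimulationResult, simulate
from .drugs import DrugParameters, kp_lukacova, kp_poulin_theil_extracellular
from .units import km_um_to_ug_ml
from .physiology import (FetalState, MaternalPhysiology, SubjectSpec,
                         fetal_state, maternal_physiology,
                         scale_transporter_expression, _placenta_total_volume)

__all__ = ["build_model", "build_subject_model", "systemic_clearance"]

# Kidney sub-space volume fractions (vascular / extracellular /
# intracellular / tubular filtrate); documented modeling choice, locked by
# regression tests.
KIDNEY_FRACTIONS = {"vasc": 0.15, "ec": 0.25, "ic": 0.59, "filtrate": 0.01}

#: Kidney volume (L) of the reference subject at which fixture Vmax values
#: are defined; transporter expression scales with kidney volume.
REFERENCE_KIDNEY_L = 0.308

# map compartment names to composition-table rows
_COMPOSITION_KEY = {
    "placenta_maternal": "placenta",
    "placenta_fetal": "placenta",
    "rest": "rest",
}

# Fetal cardiac output: blood L/h = coefficient * weight^0.75; ~40% of it
# perfuses the fetal placenta (umbilical flow), the rest the lumped tissue.
FETAL_CO_COEF = 20.0
UMBILICAL_FLOW_FRACTION = 0.40

_MIN_AF_VOLUME_L = 5e-3  # floor to keep early-GA amniotic fluid integrable


def _pstc_l_h(entry: dict, sub_volume_l: float, volume_scale: float = 1.0) -> float:
    """Resolve a PStc map entry to L/h.

    Specific values (mL/s/mL tissue) multiply the sub-tissue volume;
    absolute values (mL/s) are rescaled by ``volume_scale`` (sub-tissue
    volume relative to the calibration GA).
    """
    if entry["units"] == "mL/s/mL":
        ml_s = entry["value"] * sub_volume_l * 1000.0
    elif entry["units"] == "mL/s":
        ml_s = entry["value"] * volume_scale
    else:
        raise ValueError(f"unknown PStc units {entry['units']!r}")
    return ml_s * units.ML_S_TO_L_H


def build_model(
    physio: MaternalPhysiology,
    fstate: FetalState | None,
    rates: AmnioticRates | None,
    drug: DrugParameters,
    postpartum: bool = False,
    vmax_multipliers: dict[str, float] | None = None,
) -> CompartmentGraph:
    """Assemble the full compartment graph for one subject/GA/drug.

    ``postpartum`` applies the postpartum MRP4 Vmax reduction.
    ``vmax_multipliers`` (population sampling) scales individual
    transporter Vmax values by name.
    """
    ga = physio.spec.gestational_age
    if ga > 0 and (fstate is None or rates is None):
        raise ValueError("pregnant build requires a FetalState and AmnioticRates")
    if drug.transporters and drug.tissue_model_map.get("kidney") != "permeability":
        raise ValueError(
            "kidney transporters require the permeability-limited kidney model")

    fup_m = physio.fup_at_ga(drug.fup)
    g = CompartmentGraph()
    g.dose_target = "venous"
    g.meta["drug"] = drug.name
    g.meta["ga_weeks"] = ga
    g.meta["fup_maternal"] = fup_m

    pv = physio.plasma_volume
    g.add_compartment("venous", 2.0 / 3.0 * pv, free_factor=fup_m)
    g.add_compartment("arterial", 1.0 / 3.0 * pv, free_factor=fup_m)

    # ---- lung in series ---------------------------------------------------
    kp_lung = kp_lukacova(drug, "lung", fup=fup_m)
    g.add_compartment("lung", physio.volumes["lung"], free_factor=fup_m / kp_lung)
    q_total = sum(physio.flows.values())
    g.add_flow("venous", "lung", q_total)
    g.add_flow("lung", "arterial", q_total, partition=kp_lung)

    # ---- parallel perfusion-limited tissues -------------------------------
    perfusion = ["heart", "spleen", "liver", "skin", "adipose", "muscle",
                 "brain", "uterus", "rest"]
    perfusion = [t for t in perfusion if t in physio.volumes]
    for tissue in perfusion:
        kp = kp_lukacova(drug, _COMPOSITION_KEY.get(tissue, tissue), fup=fup_m)
        g.add_compartment(tissue, physio.volumes[tissue], free_factor=fup_m / kp)
        q = physio.flows[tissue]
        g.add_flow("arterial", tissue, q)
        g.add_flow(tissue, "venous", q, partition=kp)

    # ---- permeability-limited kidney --------------------------------------
    vk = physio.volumes["kidney"]
    kp_kid_ec = kp_poulin_theil_extracellular(drug, "kidney", fup=fup_m)
    kp_kid_ic = kp_lukacova(drug, "kidney", fup=fup_m)
    g.add_compartment("kidney_vasc", KIDNEY_FRACTIONS["vasc"] * vk, free_factor=fup_m)
    g.add_compartment("kidney_ec", KIDNEY_FRACTIONS["ec"] * vk,
                      free_factor=fup_m / kp_kid_ec)
    g.add_compartment("kidney_ic", KIDNEY_FRACTIONS["ic"] * vk,
                      free_factor=fup_m / kp_kid_ic)
    g.add_compartment("filtrate", KIDNEY_FRACTIONS["filtrate"] * vk, free_factor=1.0)
    g.add_compartment("urine_maternal", None)

    q_kid = physio.flows["kidney"]
    g.add_flow("arterial", "kidney_vasc", q_kid)
    g.add_flow("kidney_vasc", "venous", q_kid)

    ps_cap = _pstc_l_h(drug.pstc_map["kidney_capillary"], vk)
    ps_cell = _pstc_l_h(drug.pstc_map["kidney_cell"], vk)
    g.add_permeability("kidney_vasc", "kidney_ec", ps_cap)
    g.add_permeability("kidney_ec", "kidney_ic", ps_cell)

    gfr_l_h = physio.gfr_l_h
    g.add_unbound_clearance("kidney_vasc", "filtrate", gfr_l_h)
    # filtrate drains to urine at the filtration flow rate
    g.add_flow("filtrate", "urine_maternal", gfr_l_h)

    mult = vmax_multipliers or {}
    kidney_scale = vk / REFERENCE_KIDNEY_L
    for t in drug.transporters:
        vmax = (scale_transporter_expression(t.vmax_ug_h, kidney_scale)
                if t.vmax_ug_h > 0 else 0.0)
        vmax *= mult.get(t.name, 1.0)
        if postpartum and t.name == "MRP4":
            vmax *= drug.postpartum_mrp4_factor
        km = km_um_to_ug_ml(t.km_um, drug.molecular_weight)
        if t.name == "OAT3":
            g.add_transporter("kidney_vasc", "kidney_ic", vmax, km)
        elif t.name == "MRP4":
            g.add_transporter("kidney_ic", "filtrate", vmax, km)
        else:
            raise ValueError(f"no membrane defined for transporter {t.name!r}")
        g.meta[f"vmax_{t.name}_ug_h"] = vmax

    g.meta["filtration_clearance_l_h"] = fup_m * gfr_l_h

    if ga == 0:
        return g

    # ---- placenta ---------------------------------------------------------
    assert fstate is not None and rates is not None
    fup_f = drug.fup_fetal
    kp_pm = kp_lukacova(drug, "placenta", fup=fup_m)
    kp_pf = kp_lukacova(drug, "placenta", fup=fup_f)
    v_pm = physio.volumes["placenta_maternal"]
    v_pf = fstate.fetal_placenta_volume
    g.add_compartment("placenta_maternal", v_pm, free_factor=fup_m / kp_pm)
    q_pm = physio.flows["placenta_maternal"]
    g.add_flow("arterial", "placenta_maternal", q_pm)
    g.add_flow("placenta_maternal", "venous", q_pm, partition=kp_pm)

    # PStc volume rescaling for absolute (mL/s) entries fitted at a
    # reference GA
    if drug.pstc_reference_ga is not None:
        v_ref = 0.5 * _placenta_total_volume(drug.pstc_reference_ga)
        scale_m = v_pm / v_ref
        scale_f = v_pf / v_ref
    else:
        scale_m = scale_f = 1.0
    if drug.tissue_model_map.get("placenta") == "permeability":
        ps_m = _pstc_l_h(drug.pstc_map["placenta_maternal"], v_pm, scale_m)
        ps_f = _pstc_l_h(drug.pstc_map["placenta_fetal"], v_pf, scale_f)
    else:
        # perfusion-limited placenta: transplacental barrier non-limiting
        ps_m = ps_f = 3600.0
    g.meta["pstc_placenta_maternal_ml_s"] = ps_m / units.ML_S_TO_L_H
    g.meta["pstc_placenta_fetal_ml_s"] = ps_f / units.ML_S_TO_L_H
    ps_series = 1.0 / (1.0 / ps_m + 1.0 / ps_f)

    # ---- fetus ------------------------------------------------------------
    pv_f = fstate.fetal_plasma_volume
    kp_ft = kp_lukacova(drug, "fetal_tissue", fup=fup_f)
    g.add_compartment("fetal_venous", 2.0 / 3.0 * pv_f, free_factor=fup_f)
    g.add_compartment("fetal_arterial", 1.0 / 3.0 * pv_f, free_factor=fup_f)
    g.add_compartment("fetal_tissue", fstate.fetal_tissue_volume,
                      free_factor=fup_f / kp_ft)
    g.add_compartment("placenta_fetal", v_pf, free_factor=fup_f / kp_pf)
    v_af = max(fstate.amniotic_fluid_volume, _MIN_AF_VOLUME_L)
    g.add_compartment("amniotic_fluid", v_af, free_factor=1.0)

    g.add_permeability("placenta_maternal", "placenta_fetal", ps_series)

    co_f_plasma = (FETAL_CO_COEF * fstate.fetal_weight ** 0.75
                   * (1.0 - fstate.fetal_hematocrit))
    q_umb = UMBILICAL_FLOW_FRACTION * co_f_plasma
    q_ft = co_f_plasma - q_umb
    g.add_flow("fetal_venous", "fetal_arterial", co_f_plasma)
    g.add_flow("fetal_arterial", "fetal_tissue", q_ft)
    g.add_flow("fetal_tissue", "fetal_venous", q_ft, partition=kp_ft)
    g.add_flow("fetal_arterial", "placenta_fetal", q_umb)
    g.add_flow("placenta_fetal", "fetal_venous", q_umb, partition=kp_pf)

    # fetal renal clearance: fetal fup x fetal GFR, fetal blood -> amniotic
    if fstate.fetal_gfr_l_h > 0:
        g.add_unbound_clearance("fetal_venous", "amniotic_fluid",
                                fstate.fetal_gfr_l_h)
    g.meta["fetal_renal_clearance_l_h"] = fup_f * fstate.fetal_gfr_l_h

    # amniotic solute pathways (rates L/day -> L/h); bulk-fluid pathways
    # carry the total concentration of their source compartment
    g.add_flow("amniotic_fluid", "fetal_tissue", rates.k_sw * units.L_DAY_TO_L_H)
    g.add_flow("fetal_tissue", "amniotic_fluid",
               rates.k_sec * units.L_DAY_TO_L_H, partition=1.0)
    g.add_flow("amniotic_fluid", "fetal_venous", rates.k_intram * units.L_DAY_TO_L_H)
    g.add_permeability("uterus", "amniotic_fluid", rates.k_trans * units.L_DAY_TO_L_H)

    g.meta["fup_fetal"] = fup_f
    return g


def build_subject_model(
    spec: SubjectSpec,
    drug: DrugParameters,
    postpartum: bool = False,
    rate_overrides: dict[str, float] | None = None,
    vmax_multipliers: dict[str, float] | None = None,
    physio: MaternalPhysiology | None = None,
) -> CompartmentGraph:
    """Convenience: physiology + fetal state + rates + graph in one call."""
    physio = physio if physio is not None else maternal_physiology(spec)
    ga = spec.gestational_age
    if ga > 0:
        fstate = fetal_state(ga, fup_fetal=drug.fup_fetal)
        rates = amniotic_rates(ga, fstate.fetal_weight, reference=rate_overrides)
    else:
        fstate, rates = None, None
    return build_model(physio, fstate, rates, drug, postpartum=postpartum,
                       vmax_multipliers=vmax_multipliers)


def systemic_clearance(
    graph: CompartmentGraph,
    dose_mg: float = 100.0,
    t_end: float = 72.0,
) -> float:
    """Plasma clearance (L/h) as dose / AUC from a single IV bolus.

    The AUC is the trapezoidal area of the venous plasma concentration to
    ``t_end`` plus a log-linear tail extrapolation.
    """
    res = simulate(graph, DoseRegimen(dose_mg=dose_mg), t_end=t_end)
    c = res.concentration("venous")
    t = res.times
    auc = float(np.trapezoid(c, t))
    # terminal extrapolation from the last decade of the curve
    tail = c > 0
    if tail[-1] and c[-1] < c[0]:
        n = len(t)
        i0 = int(0.8 * n)
        lam = np.polyfit(t[i0:], np.log(np.maximum(c[i0:], 1e-300)), 1)[0]
        if lam < 0:
            auc += float(c[-1] / -lam)
    return dose_mg / auc  # mg / (mg/L * h) = L/h
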