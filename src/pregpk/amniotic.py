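"""Fluid and solute exchange between fetus, amniotic fluid, and uterus.

Four active pathways plus one passive pathway move fluid (and with it,
drug) among fetal blood, fetal tissue, the amniotic fluid, and the uterine
wall:

* fetal urine:            fetal blood  -> amniotic fluid
* secretion (lung/oral):  fetal tissue -> amniotic fluid
* swallowing:             amniotic fluid -> fetal tissue
* intramembranous:        amniotic fluid -> fetal blood (placenta/membranes)
* transmembranous:        amniotic fluid <-> uterine wall (passive, driven
  by the free-concentration difference)

Amniotic fluid homeostasis requires the active inflow and outflow to
balance::

    urinary_rate + k_sec == k_sw + k_intram

The term reference rates sum to 1.46 L/day at the reference birth weight
(3.32 kg); every active rate scales linearly with fetal weight and all
active rates are zero before 9 weeks GA, when fetal urine production and
swallowing have not yet developed.  Before that, the passive
transmembranous pathway is the only operating exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

from .physiology import FETAL_REFERENCE_WEIGHT_KG, GA_MAX, PATHWAY_ONSET_WEEKS

__all__ = [
    "AmnioticRates",
    "REFERENCE_RATES_L_DAY",
    "amniotic_rates",
    "transmembranous_flux",
    "solute_pathway_fluxes",
]

#: Default pathway rate constants (L/day) at the 3.32 kg reference weight.
#: The total active turnover (urinary + secretion = swallowing +
#: intramembranous = 1.46 L/day) is the authoritative constraint; the
#: split between pathways is a documented default taken from the averaged
#: ovine literature values, rebalanced to close the fluid budget exactly.
#: k_trans is a calibrated permeability-type constant (no printed source
#: value exists) and may be overridden in scenario config.
REFERENCE_RATES_L_DAY = {
    "urinary_rate": 1.00,
    "k_sec": 0.46,
    "k_sw": 0.80,
    "k_intram": 0.66,
    "k_trans": 0.24,
}


@dataclass(frozen=True)
class AmnioticRates:
    """Pathway rate constants, all in L/day."""

    urinary_rate: float
    k_sec: float
    k_sw: float
    k_intram: float
    k_trans: float

    def __post_init__(self) -> None:
        for name in ("urinary_rate", "k_sec", "k_sw", "k_intram", "k_trans"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def active_inflow(self) -> float:
        return self.urinary_rate + self.k_sec

    @property
    def active_outflow(self) -> float:
        return self.k_sw + self.k_intram


def amniotic_rates(
    ga: float,
    fetal_weight: float,
    reference: dict[str, float] | None = None,
) -> AmnioticRates:
    """Pathway rate constants at a GA and fetal weight.

    Rates are the term reference values normalized by the 3.32 kg reference
    birth weight and multiplied by the actual fetal weight; the four active
    rates are identically zero before 9 weeks GA.

    Parameters
    ----------
    ga : float
        Gestational age, weeks (0..42).
    fetal_weight : float
        Fetal body weight, kg (must be >= 0).
    reference : dict, optional
        Override of :data:`REFERENCE_RATES_L_DAY` (same keys).
    """
    if not (0.0 <= ga <= GA_MAX):
        raise ValueError(f"GA must be in [0, {GA_MAX}] weeks, got {ga}")
    if fetal_weight < 0:
        raise ValueError("fetal_weight must be >= 0")
    ref = dict(REFERENCE_RATES_L_DAY)
    if reference:
        ref.update(reference)
    scale = fetal_weight / FETAL_REFERENCE_WEIGHT_KG
    active = ga >= PATHWAY_ONSET_WEEKS
    return AmnioticRates(
        urinary_rate=ref["urinary_rate"] * scale if active else 0.0,
        k_sec=ref["k_sec"] * scale if active else 0.0,
        k_sw=ref["k_sw"] * scale if active else 0.0,
        k_intram=ref["k_intram"] * scale if active else 0.0,
        k_trans=ref["k_trans"] * scale,
    )


def transmembranous_flux(
    c_free_amniotic: float, c_free_uterus: float, k_trans: float
) -> float:
    """Passive drug flux (amount/time) across the transmembranous pathway.

    Positive flux means net movement *into* the amniotic fluid.  With
    concentrations in ug/mL and k_trans in L/h the flux is in mg/h; the
    caller owns the time-unit of k_trans.
    """
    if k_trans < 0:
        raise ValueError("k_trans must be >= 0")
    if c_free_amniotic < 0 or c_free_uterus < 0:
        raise ValueError("concentrations must be >= 0")
    return k_trans * (c_free_uterus - c_free_amniotic)


def solute_pathway_fluxes(
    c_fetal_blood: float,
    c_fetal_tissue: float,
    c_amniotic: float,
    rates: AmnioticRates,
    fetal_renal_clearance: float,
) -> dict[str, float]:
    """Per-pathway drug fluxes (amount/time) given compartment concentrations.

    Bulk-fluid pathways entrain drug at the *total* concentration of their
    source compartment; urine carries drug at the fetal renal clearance
    (fetal fup x fetal GFR, i.e. filtration of free drug).  Rate constants
    in ``rates`` are interpreted in the same time-unit as
    ``fetal_renal_clearance`` (the engine uses L/h).

    Returns a dict with signed fluxes keyed ``urine`` (fetal blood -> AF),
    ``swallowing`` (AF -> fetal tissue), ``secretion`` (fetal tissue -> AF),
    ``intramembranous`` (AF -> fetal blood).
    """
    if min(c_fetal_blood, c_fetal_tissue, c_amniotic) < 0:
        raise ValueError("concentrations must be >= 0")
    return {
        "urine": fetal_renal_clearance * c_fetal_blood,
        "swallowing": rates.k_sw * c_amniotic,
        "secretion": rates.k_sec * c_fetal_tissue,
        "intramembranous": rates.k_intram * c_amniotic,
    }
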