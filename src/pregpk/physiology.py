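"""Maternal and fetal physiology as deterministic functions of gestational age.

Every anatomical/physiological quantity needed by the PBPK engine is computed
from four subject descriptors: age, pre-pregnancy body weight, height, and
gestational age (GA, weeks).  GA = 0 reduces *exactly* (bitwise) to the
non-pregnant baseline for the same body size: all pregnancy increments are
written so that they evaluate to 0.0 at GA = 0.

The GA-dependent curves are smooth anchored fits through standard landmark
values of human pregnancy physiology (plasma-volume expansion ~+47% at term,
GFR ~+50% by mid-gestation, hematocrit dilution ~-15% at term, uterus
0.08 -> 1.1 kg, placenta ~0.65 kg at term, amniotic fluid peaking ~0.85 L
around week 33-34, fetal weight 3.32 kg at 40 weeks).  Each curve is locked
by regression tests; the anchor values are listed next to each function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SubjectSpec",
    "MaternalPhysiology",
    "FetalState",
    "weight_gain",
    "maternal_physiology",
    "fetal_state",
    "scale_transporter_expression",
    "FETAL_REFERENCE_WEIGHT_KG",
]

#: Reference fetal birth weight (kg) used to normalize amniotic pathway rates.
FETAL_REFERENCE_WEIGHT_KG = 3.32

#: GA (weeks) at which fetal urine production and the active amniotic
#: pathways switch on.
PATHWAY_ONSET_WEEKS = 9.0

GA_MAX = 42.0


# --------------------------------------------------------------------------
# Subject descriptor
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectSpec:
    """Descriptors from which the whole physiology is generated.

    Parameters
    ----------
    age : float
        Age in years.  Maternal (pregnant) subjects must be >= 18.
    prepregnancy_weight : float
        Body weight in kg before pregnancy (or simply body weight for a
        non-pregnant subject).
    height : float
        Height in cm.
    gestational_age : float
        GA in weeks; 0 means non-pregnant / postpartum baseline.
    sex : str
        'female' or 'male'.  Male is only allowed for the non-pregnant
        baseline (healthy-volunteer models).
    """

    age: float
    prepregnancy_weight: float
    height: float
    gestational_age: float = 0.0
    sex: str = "female"

    def __post_init__(self) -> None:
        if not (0.0 <= self.gestational_age <= GA_MAX):
            raise ValueError(
                f"gestational_age must be in [0, {GA_MAX}] weeks, "
                f"got {self.gestational_age}"
            )
        if self.prepregnancy_weight <= 0:
            raise ValueError("prepregnancy_weight must be > 0")
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.gestational_age > 0:
            if self.sex != "female":
                raise ValueError("pregnant subjects must be female")
            if self.age < 18:
                raise ValueError("maternal subjects must be >= 18 years old")


# --------------------------------------------------------------------------
# Non-pregnant baseline ("reference human" generator)
# --------------------------------------------------------------------------

# Organ weights as fractions of total body weight (reference adult human;
# standard reference-man/woman compositions, density ~1 kg/L assumed).
# Brain and uterus are fixed masses, not fractions.
_ORGAN_FRAC = {
    "female": {
        "heart": 0.0047,
        "spleen": 0.0026,
        "liver": 0.0240,
        "lung": 0.0076,
        "kidney": 0.0044,
        "skin": 0.0470,
        "muscle": 0.2900,
        "adipose": 0.3250,
    },
    "male": {
        "heart": 0.0047,
        "spleen": 0.0026,
        "liver": 0.0240,
        "lung": 0.0076,
        "kidney": 0.0044,
        "skin": 0.0470,
        "muscle": 0.4000,
        "adipose": 0.2100,
    },
}
_BRAIN_KG = {"female": 1.30, "male": 1.45}
_UTERUS_KG = {"female": 0.08, "male": 0.0}

# Plasma volume (mL per kg body weight) and hematocrit.
_PLASMA_ML_KG = {"female": 40.0, "male": 45.0}
_HCT0 = {"female": 0.40, "male": 0.44}

# Baseline GFR (mL/min) at the reference weight, allometric exponent 0.75.
_GFR_REF = {"female": 110.0, "male": 125.0}
_GFR_REF_WEIGHT = {"female": 60.0, "male": 70.0}

# Cardiac output (blood, L/h) = 15 * BW^0.75  (~6 L/min at 70 kg).
_CO_COEF = 15.0

# Regional blood flows as fractions of cardiac output (parallel systemic
# circulation; lung is in series and carries the full cardiac output).
_FLOW_FRAC = {
    "heart": 0.040,
    "brain": 0.120,
    "muscle": 0.170,
    "skin": 0.050,
    "adipose": 0.050,
    "kidney": 0.190,
    "liver": 0.065,
    "spleen": 0.030,
    "uterus": 0.010,
}


@dataclass
class MaternalPhysiology:
    """Snapshot of all maternal quantities at one GA.

    volumes are L (1 kg tissue ~ 1 L), flows are *plasma* flows in L/h for
    the parallel systemic tissues (lung, in series, carries the full plasma
    cardiac output), cardiac_output is whole-blood L/h, GFR is mL/min.
    albumin_ratio / agp_ratio are multipliers on the non-pregnant plasma
    protein concentration (1.0 at GA = 0).
    """

    spec: SubjectSpec
    total_body_weight: float
    weight_gain: float
    volumes: dict[str, float] = field(default_factory=dict)
    flows: dict[str, float] = field(default_factory=dict)
    cardiac_output: float = 0.0
    plasma_volume: float = 0.0
    hematocrit: float = 0.0
    gfr: float = 0.0
    albumin_ratio: float = 1.0
    agp_ratio: float = 1.0

    @property
    def cardiac_output_plasma(self) -> float:
        """Plasma fraction of cardiac output, L/h."""
        return self.cardiac_output * (1.0 - self.hematocrit)

    @property
    def gfr_l_h(self) -> float:
        return self.gfr * 0.06

    def fup_at_ga(self, fup_baseline: float) -> float:
        """Adjust a plasma free fraction for the pregnancy albumin dilution.

        fup' = fup / (fup + (1 - fup) * albumin_ratio); equals fup exactly
        at GA = 0 where albumin_ratio == 1.
        """
        return fup_baseline / (fup_baseline + (1.0 - fup_baseline) * self.albumin_ratio)

    def to_frame(self) -> pd.DataFrame:
        """Flat (parameter, value, units) table for auditability."""
        rows = [
            ("total_body_weight", self.total_body_weight, "kg"),
            ("weight_gain", self.weight_gain, "kg"),
            ("cardiac_output", self.cardiac_output, "L/h blood"),
            ("plasma_volume", self.plasma_volume, "L"),
            ("hematocrit", self.hematocrit, "fraction"),
            ("GFR", self.gfr, "mL/min"),
            ("albumin_ratio", self.albumin_ratio, "-"),
            ("agp_ratio", self.agp_ratio, "-"),
        ]
        rows += [(f"V_{k}", v, "L") for k, v in sorted(self.volumes.items())]
        rows += [(f"Q_{k}", v, "L/h plasma") for k, v in sorted(self.flows.items())]
        return pd.DataFrame(rows, columns=["parameter", "value", "units"])


@dataclass
class FetalState:
    """Fetal anatomy/physiology at one GA (all-zero for GA = 0)."""

    gestational_age: float
    fetal_weight: float = 0.0          # kg
    fetal_height: float = 0.0          # cm
    fetal_blood_volume: float = 0.0    # L
    fetal_tissue_volume: float = 0.0   # L
    fetal_placenta_volume: float = 0.0  # L
    fetal_hematocrit: float = 0.0      # fraction
    fetal_gfr: float = 0.0             # mL/min
    fetal_fup: float | None = None     # drug-specific, set when a drug is given
    amniotic_fluid_volume: float = 0.0  # L
    protein_ratio: float = 0.0         # fetal/maternal plasma protein ratio

    @property
    def fetal_plasma_volume(self) -> float:
        return self.fetal_blood_volume * (1.0 - self.fetal_hematocrit)

    @property
    def fetal_gfr_l_h(self) -> float:
        return self.fetal_gfr * 0.06


# --------------------------------------------------------------------------
# GA-dependent maternal curves
# --------------------------------------------------------------------------

def weight_gain(spec: SubjectSpec) -> float:
    """Pregnancy weight gain (kg) at the subject's GA.

    Smooth monotone quadratic through the averaged underweight/normal/
    overweight gestational weight-gain percentiles: anchors ~1.8 kg at
    13 wk, 6.0 kg at 25 wk (the cefazolin development subject), ~14.7 kg
    at 40 wk.  Exactly 0 at GA = 0.
    """
    ga = spec.gestational_age
    return 0.0285 * ga + 0.0084615 * ga * ga


def _sat(ga: float, tau: float) -> float:
    """Smooth saturating ramp, exactly 0 at ga=0, -> 1 for ga >> tau."""
    return 1.0 - math.exp(-((ga / tau) ** 2))


def _placenta_total_volume(ga: float) -> float:
    """Whole placenta volume (L); ~0.65 L at 40 wk, quadratic growth."""
    return 0.65 * (ga / 40.0) ** 2


def maternal_physiology(spec: SubjectSpec) -> MaternalPhysiology:
    """Evaluate the full maternal physiology snapshot at the subject's GA.

    GA-invariant organs (heart, spleen, liver, lung, muscle, brain except
    for a small late decrease) keep their pre-pregnancy values; skin,
    adipose and cardiac output are recomputed from the *current* body
    weight with the baseline allometric rules; kidney, uterus, placenta,
    plasma volume, hematocrit, GFR and plasma protein ratios follow the
    pregnancy curves.
    """
    sex = spec.sex
    ga = spec.gestational_age
    w0 = spec.prepregnancy_weight
    wg = weight_gain(spec)
    tbw = w0 + wg

    frac = _ORGAN_FRAC[sex]
    volumes: dict[str, float] = {}
    # unchanged organs, from pre-pregnancy weight
    for organ in ("heart", "spleen", "liver", "lung", "muscle"):
        volumes[organ] = frac[organ] * w0
    # brain: small late-gestation decrease (~3% at term)
    volumes["brain"] = _BRAIN_KG[sex] * (1.0 - 0.03 * _sat(ga, 25.0))
    # recomputed from current body weight (baseline allometric rules)
    volumes["skin"] = frac["skin"] * tbw
    volumes["adipose"] = frac["adipose"] * tbw
    # pregnancy-enlarged organs
    volumes["kidney"] = frac["kidney"] * w0 * (1.0 + 0.30 * (ga / 40.0))
    if sex == "female":
        volumes["uterus"] = _UTERUS_KG[sex] + 0.0006375 * ga * ga  # -> 1.1 kg at 40
    if ga > 0:
        volumes["placenta_maternal"] = 0.5 * _placenta_total_volume(ga)

    plasma_volume = _PLASMA_ML_KG[sex] * 1e-3 * w0 * (1.0 + 0.47 * _sat(ga, 20.0))
    hct = _HCT0[sex] * (1.0 - 0.15 * _sat(ga, 20.0))
    gfr0 = _GFR_REF[sex] * (w0 / _GFR_REF_WEIGHT[sex]) ** 0.75
    gfr = gfr0 * (1.0 + 0.50 * _sat(ga, 15.0))

    co = _CO_COEF * tbw ** 0.75           # blood L/h
    co_plasma = co * (1.0 - hct)

    blood_volume = plasma_volume / (1.0 - hct)
    explicit = sum(volumes.values())
    volumes["rest"] = max(tbw - explicit - blood_volume, 0.5)

    # parallel plasma flows; placenta and extra uterine flow grow with GA
    flows: dict[str, float] = {}
    used = 0.0
    for organ, f in _FLOW_FRAC.items():
        if organ == "uterus":
            if sex != "female":
                continue  # uterine share falls through to rest-of-body
            f = f + 0.04 * (ga / 40.0) ** 2
        flows[organ] = f * co_plasma
        used += f
    f_pl = 0.07 * (ga / 40.0) ** 2
    if ga > 0:
        flows["placenta_maternal"] = f_pl * co_plasma
    used += f_pl
    flows["rest"] = (1.0 - used) * co_plasma

    alb_ratio = 1.0 - 0.22 * _sat(ga, 25.0)
    agp_ratio = 1.0 - 0.15 * _sat(ga, 25.0)

    return MaternalPhysiology(
        spec=spec,
        total_body_weight=tbw,
        weight_gain=wg,
        volumes=volumes,
        flows=flows,
        cardiac_output=co,
        plasma_volume=plasma_volume,
        hematocrit=hct,
        gfr=gfr,
        albumin_ratio=alb_ratio,
        agp_ratio=agp_ratio,
    )


# --------------------------------------------------------------------------
# Fetal curves
# --------------------------------------------------------------------------

def _fetal_weight_kg(ga: float) -> float:
    # Hadlock-type exponential growth curve, rescaled so the curve passes
    # exactly through 0 at GA=0 and 3.32 kg at 40 wk.
    def h(g: float) -> float:
        return math.exp(0.578 + 0.332 * g - 0.00354 * g * g)

    w = FETAL_REFERENCE_WEIGHT_KG * (h(ga) - h(0.0)) / (h(40.0) - h(0.0))
    return max(w, 0.0)


def _onset_ramp(ga: float) -> float:
    """0 before pathway onset (9 wk), linear to 1 at 40 wk."""
    return min(max((ga - PATHWAY_ONSET_WEEKS) / (40.0 - PATHWAY_ONSET_WEEKS), 0.0), 1.0)


def amniotic_fluid_volume(ga: float) -> float:
    """Amniotic fluid volume (L): gamma-shaped curve, peak ~0.85 L at ~34 wk,
    declining to ~0.80 L at 40 wk, exactly 0 at GA = 0."""
    if not (0.0 <= ga <= GA_MAX):
        raise ValueError(f"GA must be in [0, {GA_MAX}] weeks, got {ga}")
    return 3.473e-5 * ga ** 4 * math.exp(-ga / 8.5)


def fetal_state(ga: float, fup_fetal: float | None = None) -> FetalState:
    """Fetal anatomy/physiology at GA (weeks).

    Weight follows a rescaled Hadlock growth curve (3.32 kg at 40 wk);
    blood volume is 80 mL/kg; hematocrit rises 0.30 -> 0.47 between
    pathway onset and term; fetal GFR is 0 before urine-production onset
    (9 wk) and ~1.2 mL/min/kg at term.  ``fup_fetal`` is drug-specific
    and simply carried through when provided.
    """
    if not (0.0 <= ga <= GA_MAX):
        raise ValueError(f"GA must be in [0, {GA_MAX}] weeks, got {ga}")
    if ga == 0.0:
        return FetalState(gestational_age=0.0)

    w = _fetal_weight_kg(ga)
    ramp = _onset_ramp(ga)
    blood = 0.080 * w
    hct = 0.30 + 0.17 * ramp
    gfr = 1.2 * w * ramp  # mL/min; 0 before 9 wk
    return FetalState(
        gestational_age=ga,
        fetal_weight=w,
        fetal_height=50.0 * (ga / 40.0) ** 0.85,
        fetal_blood_volume=blood,
        fetal_tissue_volume=max(w - blood, 0.0),
        fetal_placenta_volume=0.5 * _placenta_total_volume(ga),
        fetal_hematocrit=hct,
        fetal_gfr=gfr,
        fetal_fup=fup_fetal,
        amniotic_fluid_volume=amniotic_fluid_volume(ga),
        protein_ratio=0.25 + 0.55 * ramp,
    )


def scale_transporter_expression(baseline_vmax: float, organ_volume_ratio: float) -> float:
    """Scale a transporter Vmax with organ size (constant expression per
    gram of tissue): returns baseline_vmax * organ_volume_ratio."""
    if baseline_vmax <= 0 or organ_volume_ratio <= 0:
        raise ValueError("baseline_vmax and organ_volume_ratio must be > 0")
    return baseline_vmax * organ_volume_ratio
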