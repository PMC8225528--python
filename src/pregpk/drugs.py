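"""Compound parameters, tissue partitioning, and clearance primitives.

Tissue:plasma partition coefficients (Kp) are computed mechanistically from
tissue composition:

* :func:`kp_lukacova` - Rodgers-Rowland-family equation for acids, neutrals
  and very weak bases, with the tissue macromolecule binding term derived
  from the plasma free fraction (fup) rather than a measured tissue-binding
  input.  Used for perfusion-limited tissues.
* :func:`kp_poulin_theil_extracellular` - extracellular-space partitioning
  for permeability-limited tissues: free drug distributes into extracellular
  water, bound drug binds interstitial albumin at a fixed fraction of the
  plasma level.

Clearance primitives: renal filtration (fup x GFR) and saturable
Michaelis-Menten transport.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "TissueComposition",
    "load_tissue_composition",
    "TransporterKinetics",
    "DrugParameters",
    "load_drug",
    "builtin_drug_path",
    "kp_lukacova",
    "kp_poulin_theil_extracellular",
    "renal_filtration_clearance",
    "mm_rate",
]

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0

PROVENANCE_TAGS = {"printed", "supplementary", "literature", "fitted", "assumed", "calibrated"}


# --------------------------------------------------------------------------
# Tissue composition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueComposition:
    """Fractional composition of one tissue (or plasma)."""

    f_ew: float       # extracellular water
    f_iw: float       # intracellular water
    f_nl: float       # neutral lipid
    f_np: float       # neutral phospholipid
    alb_ratio: float  # interstitial albumin / plasma albumin


_COMPOSITION_CACHE: dict[str, TissueComposition] | None = None


def load_tissue_composition() -> dict[str, TissueComposition]:
    """Load the packaged tissue composition table (cached)."""
    global _COMPOSITION_CACHE
    if _COMPOSITION_CACHE is None:
        with resources.files("pregpk.data").joinpath("tissue_composition.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        _COMPOSITION_CACHE = {
            row.tissue: TissueComposition(
                f_ew=row.f_ew, f_iw=row.f_iw, f_nl=row.f_nl,
                f_np=row.f_np, alb_ratio=row.alb_ratio,
            )
            for row in df.itertuples()
        }
    return _COMPOSITION_CACHE


# --------------------------------------------------------------------------
# Drug parameter containers
# --------------------------------------------------------------------------

@dataclass
class TransporterKinetics:
    """Michaelis-Menten kinetics of one membrane transporter.

    Vmax is the maximal transport rate (ug/h) at the reference organ size;
    the engine rescales it with organ volume.  Km is in uM and is applied
    to the unbound concentration at the source face of the membrane.
    """

    name: str                      # e.g. OAT3, MRP4
    location: str                  # 'kidney basolateral' | 'kidney apical'
    direction: str                 # 'influx' | 'efflux'
    km_um: float
    vmax_ug_h: float
    vmax_cv: float = 1.0           # lognormal CV for population sampling

    def __post_init__(self) -> None:
        if self.km_um <= 0:
            raise ValueError("Km must be > 0")
        if self.vmax_ug_h < 0:
            raise ValueError("Vmax must be >= 0")
        if self.direction not in ("influx", "efflux"):
            raise ValueError("direction must be 'influx' or 'efflux'")


@dataclass
class DrugParameters:
    """Compound-specific model inputs.

    pKa entries are ``(value, 'acid'|'base')`` pairs.  ``tissue_model_map``
    assigns 'perfusion' or 'permeability' per tissue; ``pstc_map`` holds
    permeability-surface area products for the permeability-limited
    barriers, each entry ``{'value': x, 'units': 'mL/s' | 'mL/s/mL'}``
    (specific values are multiplied by the sub-tissue volume at build
    time).  ``provenance`` maps dotted field paths to their source tag.
    """

    name: str
    molecular_weight: float
    logp: float
    pka_list: list[tuple[float, str]]
    fup: float
    blood_plasma_ratio: float
    fup_fetal: float
    transporters: list[TransporterKinetics] = field(default_factory=list)
    tissue_model_map: dict[str, str] = field(default_factory=dict)
    pstc_map: dict[str, dict] = field(default_factory=dict)
    postpartum_mrp4_factor: float = 1.0
    pstc_reference_ga: float | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        for nm, f in (("fup", self.fup), ("fup_fetal", self.fup_fetal)):
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{nm} must be in (0, 1]")
        for key, entry in self.pstc_map.items():
            if entry["value"] <= 0:
                raise ValueError(f"pstc_map[{key}] must be > 0")

    def transporter(self, name: str) -> TransporterKinetics:
        for t in self.transporters:
            if t.name == name:
                return t
        raise KeyError(name)


def _tagged(node, path: str, provenance: dict[str, str]):
    """Unwrap a {value, tag} leaf, recording its provenance tag."""
    if isinstance(node, dict) and "value" in node:
        tag = node.get("tag", "assumed")
        if tag not in PROVENANCE_TAGS:
            raise ValueError(f"unknown provenance tag {tag!r} at {path}")
        provenance[path] = tag
        return node["value"]
    raise ValueError(f"numeric field {path} must carry a provenance tag")


def load_drug(source) -> DrugParameters:
    """Load a drug parameter file (YAML path or pre-parsed dict).

    Every numeric leaf in the file must be written as
    ``{value: <x>, tag: printed|supplementary|literature|fitted|assumed|calibrated}``;
    tags are collected into :attr:`DrugParameters.provenance` so fixture
    provenance stays machine-checkable.
    """
    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)

    prov: dict[str, str] = {}
    transporters = []
    for t in raw.get("transporters", []):
        transporters.append(
            TransporterKinetics(
                name=t["name"],
                location=t["location"],
                direction=t["direction"],
                km_um=_tagged(t["km_um"], f"transporters.{t['name']}.km_um", prov),
                vmax_ug_h=_tagged(t["vmax_ug_h"], f"transporters.{t['name']}.vmax_ug_h", prov),
                vmax_cv=_tagged(t["vmax_cv"], f"transporters.{t['name']}.vmax_cv", prov),
            )
        )
    pstc_map = {}
    for key, entry in raw.get("pstc_map", {}).items():
        pstc_map[key] = {
            "value": _tagged(entry, f"pstc_map.{key}", prov),
            "units": entry["units"],
        }
    ref_ga = raw.get("pstc_reference_ga")
    return DrugParameters(
        name=raw["name"],
        molecular_weight=_tagged(raw["molecular_weight"], "molecular_weight", prov),
        logp=_tagged(raw["logp"], "logp", prov),
        pka_list=[
            (_tagged(p, f"pka.{i}", prov), p["type"])
            for i, p in enumerate(raw.get("pka_list", []))
        ],
        fup=_tagged(raw["fup"], "fup", prov),
        blood_plasma_ratio=_tagged(raw["blood_plasma_ratio"], "blood_plasma_ratio", prov),
        fup_fetal=_tagged(raw["fup_fetal"], "fup_fetal", prov),
        transporters=transporters,
        tissue_model_map=raw.get("tissue_model_map", {}),
        pstc_map=pstc_map,
        postpartum_mrp4_factor=_tagged(
            raw["postpartum_mrp4_factor"], "postpartum_mrp4_factor", prov)
        if "postpartum_mrp4_factor" in raw else 1.0,
        pstc_reference_ga=ref_ga,
        provenance=prov,
    )


def builtin_drug_path(name: str) -> str:
    """Filesystem path of a packaged drug fixture ('cefuroxime'/'cefazolin')."""
    return str(resources.files("pregpk.data").joinpath(f"{name}.yaml"))


# --------------------------------------------------------------------------
# Ionization helpers
# --------------------------------------------------------------------------

def _ionization_factor(pka_list: list[tuple[float, str]], ph: float) -> float:
    """1 + sum of ionized/neutral ratios at the given pH (monoprotic terms)."""
    x = 1.0
    for pka, kind in pka_list:
        if kind == "acid":
            x += 10.0 ** (ph - pka)
        elif kind == "base":
            x += 10.0 ** (pka - ph)
        else:
            raise ValueError(f"pKa type must be 'acid' or 'base', got {kind!r}")
    return x


# --------------------------------------------------------------------------
# Partition coefficients
# --------------------------------------------------------------------------

def kp_lukacova(drug: DrugParameters, tissue: str | TissueComposition,
                fup: float | None = None) -> float:
    """Tissue:plasma partition coefficient for a perfusion-limited tissue.

    Rodgers-Rowland-family mechanistic equation for acids/neutrals/very
    weak bases: neutral species partitions into neutral lipid and
    phospholipid, total species distributes in tissue water with
    ionization at intracellular pH 7.0 vs plasma pH 7.4, and the residual
    plasma-protein binding implied by fup (minus the plasma lipid
    contribution) is projected into the tissue interstitium via the
    tissue-to-plasma albumin ratio.
    """
    fup = drug.fup if fup is None else fup
    comp = _resolve(tissue)
    plasma = load_tissue_composition()["plasma"]
    p = 10.0 ** drug.logp
    x_iw = _ionization_factor(drug.pka_list, PH_INTRACELLULAR)
    y = _ionization_factor(drug.pka_list, PH_PLASMA)
    lipid = lambda c: (p * c.f_nl + (0.3 * p + 0.7) * c.f_np) / y
    # albumin association implied by fup, net of plasma lipid partitioning
    ka_alb = max(1.0 / fup - 1.0 - lipid(plasma), 0.0)
    kpu = comp.f_ew + comp.f_iw * (x_iw / y) + lipid(comp) + ka_alb * comp.alb_ratio
    kp = kpu * fup
    if not (kp > 0 and math.isfinite(kp)):
        raise ValueError(f"non-physical Kp computed for {drug.name}/{tissue}")
    return kp


#: Interstitial-fluid albumin concentration relative to plasma used by the
#: extracellular method (lymph/interstitium carries roughly half the
#: plasma albumin level).
EXTRACELLULAR_ALBUMIN_RATIO = 0.5


def kp_poulin_theil_extracellular(drug: DrugParameters, tissue: str | TissueComposition,
                                  fup: float | None = None) -> float:
    """Extracellular tissue:plasma partition coefficient for
    permeability-limited tissues.

    Drug is restricted to the extracellular space: the free fraction
    distributes into extracellular water and the bound fraction binds
    interstitial albumin at :data:`EXTRACELLULAR_ALBUMIN_RATIO` times the
    plasma level::

        Kp_ec = fup * f_ew + r_alb * (1 - fup)

    Limits: fup = 1 gives the extracellular water fraction; the explicit
    fup dependence is linear.
    """
    fup = drug.fup if fup is None else fup
    comp = _resolve(tissue)
    kp = fup * comp.f_ew + EXTRACELLULAR_ALBUMIN_RATIO * (1.0 - fup)
    if not (kp > 0 and math.isfinite(kp)):
        raise ValueError(f"non-physical extracellular Kp for {drug.name}/{tissue}")
    return kp


def _resolve(tissue: str | TissueComposition) -> TissueComposition:
    if isinstance(tissue, TissueComposition):
        return tissue
    table = load_tissue_composition()
    try:
        return table[tissue]
    except KeyError:
        raise KeyError(
            f"no composition entry for tissue {tissue!r}; known: {sorted(table)}"
        ) from None


# --------------------------------------------------------------------------
# Clearance primitives
# --------------------------------------------------------------------------

def renal_filtration_clearance(fup: float, gfr: float) -> float:
    """Renal filtration clearance = fup x GFR (same flow units as gfr)."""
    if fup < 0 or gfr < 0:
        raise ValueError("fup and gfr must be >= 0")
    return fup * gfr


def mm_rate(c_unbound: float, km: float, vmax: float) -> float:
    """Michaelis-Menten transport rate vmax * c / (km + c).

    Saturating and monotone in c; globally Lipschitz on c >= 0 with
    constant vmax/km (solver-stability contract).
    """
    if km <= 0:
        raise ValueError("km must be > 0")
    if c_unbound < 0 or vmax < 0:
        raise ValueError("c_unbound and vmax must be >= 0")
    return vmax * c_unbound / (km + c_unbound)
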