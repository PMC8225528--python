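"""Virtual pregnant populations and Monte-Carlo prediction intervals.

Virtual subjects are generated from a bivariate lognormal height/weight
distribution (documented correlation 0.5 on the log scale) for the chosen
age, GA drawn uniformly over the study's GA range, and lognormal
multipliers (mean 1) applied to selected physiological parameters and to
the transporter Vmax values (CV 100% by default, reflecting kidney protein
abundance variability).  CVs are interpreted on the natural scale:
sigma^2 = ln(1 + CV^2).  A fixed seed reproduces the cohort exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compartments import DoseRegimen, SimulationResult, simulate
from .drugs import DrugParameters
from .model import build_subject_model
from .physiology import MaternalPhysiology, SubjectSpec, maternal_physiology

__all__ = ["PopulationSpec", "PopulationResult", "sample_subjects", "run_population",
           "delivery_samples"]

#: Default intersubject CVs for physiological parameters where no
#: literature value is available (editable; the 10-20% assumption band).
DEFAULT_CV_MAP = {
    "gfr": 0.15,
    "plasma_volume": 0.15,
    "cardiac_output": 0.15,
}

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass
class PopulationSpec:
    n_subjects: int
    age_range: tuple[float, float] = (25.0, 35.0)
    ga_range: tuple[float, float] = (39.0, 41.0)
    weight_mean: float = 62.0           # pre-pregnancy kg
    weight_cv: float = 0.15
    height_mean: float = 163.0          # cm
    height_cv: float = 0.04
    height_weight_corr: float = 0.5
    cv_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CV_MAP))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for lo, hi in (self.age_range, self.ga_range):
            if hi < lo:
                raise ValueError("ranges must be non-empty (lo <= hi)")
        if any(cv < 0 for cv in self.cv_map.values()):
            raise ValueError("all CVs must be >= 0")


def _lognormal_multiplier(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 lognormal multipliers; exactly 1.0 when cv == 0."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def sample_subjects(
    spec: PopulationSpec,
    drug: DrugParameters | None = None,
) -> list[tuple[SubjectSpec, dict[str, float]]]:
    """Draw n virtual subjects and their parameter multipliers.

    Returns (SubjectSpec, multipliers) pairs; multiplier keys are the
    physiological entries of ``cv_map`` plus ``vmax:<transporter>`` for
    each transporter of ``drug`` (sampled at that transporter's own CV).
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    # bivariate lognormal height/weight
    sh = np.sqrt(np.log1p(spec.height_cv ** 2))
    sw = np.sqrt(np.log1p(spec.weight_cv ** 2))
    if sh == 0 and sw == 0:
        heights = np.full(n, spec.height_mean)
        weights = np.full(n, spec.weight_mean)
    else:
        cov = np.array([
            [sh * sh, spec.height_weight_corr * sh * sw],
            [spec.height_weight_corr * sh * sw, sw * sw],
        ])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        heights = spec.height_mean * np.exp(z[:, 0] - 0.5 * sh * sh)
        weights = spec.weight_mean * np.exp(z[:, 1] - 0.5 * sw * sw)

    ages = rng.uniform(*spec.age_range, size=n) if spec.age_range[1] > spec.age_range[0] \
        else np.full(n, spec.age_range[0])
    gas = rng.uniform(*spec.ga_range, size=n) if spec.ga_range[1] > spec.ga_range[0] \
        else np.full(n, spec.ga_range[0])

    mults: dict[str, np.ndarray] = {
        key: _lognormal_multiplier(rng, cv, n) for key, cv in spec.cv_map.items()
    }
    if drug is not None:
        for t in drug.transporters:
            mults[f"vmax:{t.name}"] = _lognormal_multiplier(rng, t.vmax_cv, n)

    out = []
    for i in range(n):
        subj = SubjectSpec(
            age=float(ages[i]), prepregnancy_weight=float(weights[i]),
            height=float(heights[i]), gestational_age=float(gas[i]), sex="female",
        )
        out.append((subj, {k: float(v[i]) for k, v in mults.items()}))
    return out


def perturb_physiology(physio: MaternalPhysiology,
                       multipliers: dict[str, float]) -> MaternalPhysiology:
    """Apply sampled physiological multipliers to a physiology snapshot."""
    m_gfr = multipliers.get("gfr", 1.0)
    m_pv = multipliers.get("plasma_volume", 1.0)
    m_co = multipliers.get("cardiac_output", 1.0)
    return replace(
        physio,
        gfr=physio.gfr * m_gfr,
        plasma_volume=physio.plasma_volume * m_pv,
        cardiac_output=physio.cardiac_output * m_co,
        flows={k: q * m_co for k, q in physio.flows.items()},
    )


@dataclass
class PopulationResult:
    times: np.ndarray
    bands: dict[str, np.ndarray]        # observable -> (len(PERCENTILES), nt)
    subjects: list[SubjectSpec]
    results: list[SimulationResult] | None
    summary: pd.DataFrame
    failures: list[tuple[int, str]]

    def band(self, observable: str, percentile: int) -> np.ndarray:
        return self.bands[observable][PERCENTILES.index(percentile)]


def run_population(
    spec: PopulationSpec,
    drug: DrugParameters,
    regimen: DoseRegimen,
    t_end: float,
    observables: tuple[str, ...] = ("venous",),
    rate_overrides: dict[str, float] | None = None,
    keep_results: bool = False,
    n_points: int = 241,
) -> PopulationResult:
    """Simulate every virtual subject and compute pointwise percentile bands.

    Subjects whose simulation fails are recorded, excluded and warned
    about; bands are pointwise percentiles on the common time grid and are
    monotone by construction.
    """
    cohort = sample_subjects(spec, drug)
    t_eval = np.linspace(0.0, t_end, n_points)
    trajs: dict[str, list[np.ndarray]] = {o: [] for o in observables}
    results: list[SimulationResult] = []
    failures: list[tuple[int, str]] = []
    rows = []
    for i, (subj, mult) in enumerate(cohort):
        try:
            physio = perturb_physiology(maternal_physiology(subj), mult)
            vmax_mult = {k.split(":", 1)[1]: v for k, v in mult.items()
                         if k.startswith("vmax:")}
            graph = build_subject_model(subj, drug, rate_overrides=rate_overrides,
                                        vmax_multipliers=vmax_mult, physio=physio)
            res = simulate(graph, regimen, t_end, t_eval=t_eval)
        except Exception as exc:  # noqa: BLE001 - robustness boundary
            failures.append((i, str(exc)))
            warnings.warn(f"subject {i} failed and was excluded: {exc}",
                          stacklevel=2)
            continue
        for o in observables:
            trajs[o].append(res.concentration(o))
        cp = res.concentration("venous")
        rows.append({
            "subject": i,
            "ga_weeks": subj.gestational_age,
            "weight_kg": subj.prepregnancy_weight,
            "cmax_ug_ml": float(cp.max()),
            "auc_ug_h_ml": float(np.trapezoid(cp, res.times)),
            "urinary_pct": float(res.amount("urine_maternal")[-1]
                                 / regimen.administered(res.times)[-1] * 100.0),
        })
        if keep_results:
            results.append(res)

    if not rows:
        raise RuntimeError("every subject simulation failed")
    bands = {
        o: np.percentile(np.vstack(v), PERCENTILES, axis=0)
        for o, v in trajs.items() if v
    }
    return PopulationResult(
        times=t_eval, bands=bands, subjects=[s for s, _ in cohort],
        results=results if keep_results else None,
        summary=pd.DataFrame(rows), failures=failures,
    )


def delivery_samples(
    result: PopulationResult,
    observable: str,
    rng: np.random.Generator,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """One observation time per subject (delivery-style sampling).

    Mimics cord-blood / amniotic-fluid studies where each subject
    contributes a single sample; requires ``keep_results=True`` runs.
    """
    if result.results is None:
        raise ValueError("run_population(..., keep_results=True) is required")
    t = result.times
    lo, hi = window if window else (t[0], t[-1])
    rows = []
    for i, res in enumerate(result.results):
        ts = float(rng.uniform(lo, hi))
        c = float(np.interp(ts, res.times, res.concentration(observable)))
        rows.append({"subject": i, "time_h": ts, "observable": observable,
                     "value": c, "unit": "ug/mL"})
    return pd.DataFrame(rows)
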