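"""Scenario runner, study fixtures, synthetic observed data, fit metrics.

A *scenario* is a YAML/JSON file binding a subject, a drug file, a dosing
regimen and simulation options; the packaged scenarios encode the printed
study designs used to develop and validate the cefuroxime and cefazolin
models (dose, route, GA, body weight).  Observed clinical profiles exist
only as figures in the source studies, so the repo ships no digitized
ground truth: validation rests on printed numbers, invariants, and
synthetic-data recovery, with an optional slot for user-digitized CSVs
(columns time_h, observable, value, unit) to overlay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compartments import DoseRegimen, SimulationResult, simulate, urinary_excretion_pct
from .drugs import DrugParameters, builtin_drug_path, load_drug
from .model import build_subject_model
from .physiology import SubjectSpec, maternal_physiology

__all__ = ["Scenario", "load_scenario", "builtin_scenario_path", "list_builtin_scenarios",
           "run_scenario", "synthesize_observed", "compute_fit_metrics", "FitMetrics",
           "validate_fixtures"]


@dataclass
class Scenario:
    """One study fixture: subject + drug + regimen + simulation options."""

    name: str
    subject: SubjectSpec
    drug: DrugParameters
    regimen: DoseRegimen
    t_end: float
    postpartum: bool = False
    n_points: int = 481
    rate_overrides: dict[str, float] | None = None
    observed_csv: str | None = None
    provenance: str = ""
    raw: dict = field(default_factory=dict)


def load_scenario(source) -> Scenario:
    """Load a scenario from a YAML path or a pre-parsed dict."""
    if isinstance(source, dict):
        raw = dict(source)
        base = Path(".")
    else:
        path = Path(source)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"scenario file {path} did not parse to a mapping")
        base = path.parent

    try:
        s = raw["subject"]
        subject = SubjectSpec(
            age=s["age"], prepregnancy_weight=s["weight"], height=s["height"],
            gestational_age=s.get("gestational_age_weeks", 0.0),
            sex=s.get("sex", "female"),
        )
        r = raw["regimen"]
        regimen = DoseRegimen(
            dose_mg=r["dose_mg"], times=tuple(r.get("times_h", [0.0])),
            duration=r.get("infusion_duration_h", 0.0),
        )
        drug_ref = raw["drug"]
    except KeyError as exc:
        raise ValueError(f"scenario is missing required key: {exc}") from exc

    drug_path = Path(drug_ref)
    if not drug_path.suffix:
        drug_path = Path(builtin_drug_path(drug_ref))
    elif not drug_path.is_absolute():
        drug_path = base / drug_path
    drug = load_drug(str(drug_path))

    observed = raw.get("observed")
    if observed is not None and not Path(observed).is_absolute():
        observed = str(base / observed)

    return Scenario(
        name=raw.get("name", "scenario"),
        subject=subject, drug=drug, regimen=regimen,
        t_end=raw.get("t_end_h", 24.0),
        postpartum=raw.get("postpartum", False),
        n_points=raw.get("n_points", 481),
        rate_overrides=raw.get("rate_overrides"),
        observed_csv=observed,
        provenance=raw.get("provenance", ""),
        raw=raw,
    )


def builtin_scenario_path(name: str) -> str:
    return str(resources.files("pregpk.data").joinpath(f"scenarios/{name}.yaml"))


def list_builtin_scenarios() -> list[str]:
    root = resources.files("pregpk.data").joinpath("scenarios")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def run_scenario(scenario: Scenario | str, outdir: str | None = None,
                 plot: bool = False) -> SimulationResult:
    """Simulate a scenario; optionally write CSV + summary JSON (+ PNG).

    Output files: ``<name>_timeseries.csv`` (tidy time/compartment/amount/
    concentration), ``<name>_summary.json`` (Cmax, Tmax, AUC, urinary
    excretion %, mass-balance residual, physiology snapshot reference) and
    optionally ``<name>_overlay.png``.
    """
    if not isinstance(scenario, Scenario):
        scenario = load_scenario(scenario)
    graph = build_subject_model(
        scenario.subject, scenario.drug, postpartum=scenario.postpartum,
        rate_overrides=scenario.rate_overrides,
    )
    t_eval = np.linspace(0.0, scenario.t_end, scenario.n_points)
    result = simulate(graph, scenario.regimen, scenario.t_end, t_eval=t_eval)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_frame().to_csv(out / f"{scenario.name}_timeseries.csv", index=False)
        cp = result.concentration("venous")
        summary = {
            "scenario": scenario.name,
            "drug": scenario.drug.name,
            "ga_weeks": scenario.subject.gestational_age,
            "cmax_ug_ml": float(cp.max()),
            "tmax_h": float(result.times[int(np.argmax(cp))]),
            "auc_ug_h_ml": float(np.trapezoid(cp, result.times)),
            "urinary_excretion_pct": urinary_excretion_pct(result),
            "max_mass_balance_residual": float(result.mass_balance_residual.max()),
            "parameter_provenance": scenario.drug.provenance,
        }
        with open(out / f"{scenario.name}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        physio = maternal_physiology(scenario.subject)
        physio.to_frame().to_csv(out / f"{scenario.name}_physiology.csv", index=False)
        if plot:
            _overlay_plot(scenario, result, out / f"{scenario.name}_overlay.png")
    return result


def _overlay_plot(scenario: Scenario, result: SimulationResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.semilogy(result.times, result.concentration("venous"), label="maternal plasma")
    for name, label in (("fetal_venous", "fetal plasma"),
                        ("amniotic_fluid", "amniotic fluid")):
        if name in result.names:
            ax.semilogy(result.times, result.concentration(name), label=label)
    if scenario.observed_csv:
        obs = pd.read_csv(scenario.observed_csv)
        for o, grp in obs.groupby("observable"):
            ax.semilogy(grp.time_h, grp.value, "o", label=f"observed {o}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ug/mL)")
    ax.set_title(scenario.name)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# Synthetic observed data
# --------------------------------------------------------------------------

def synthesize_observed(
    scenario: Scenario,
    cv: float,
    schedule: np.ndarray,
    seed: int,
    observables: tuple[str, ...] = ("venous",),
) -> pd.DataFrame:
    """Simulated-truth concentrations with multiplicative lognormal noise.

    Stands in for the clinical datasets (which exist only as figures).
    CV = 0 returns the truth exactly.  Columns: time_h, observable, value,
    unit.
    """
    result = run_scenario(scenario)
    rng = np.random.default_rng(seed)
    schedule = np.asarray(schedule, dtype=float)
    rows = []
    sigma = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0
    for obs in observables:
        truth = np.interp(schedule, result.times, result.concentration(obs))
        noise = (rng.lognormal(-0.5 * sigma * sigma, sigma, size=schedule.size)
                 if cv > 0 else np.ones_like(schedule))
        for t, v in zip(schedule, truth * noise):
            rows.append({"time_h": float(t), "observable": obs,
                         "value": float(v), "unit": "ug/mL"})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Fit metrics
# --------------------------------------------------------------------------

@dataclass
class FitMetrics:
    """Standard PBPK acceptance metrics."""

    aafe: float                      # absolute average fold error (>= 1)
    fraction_within_2fold: float     # boundary (exactly 2-fold) counts as within
    fold_errors: np.ndarray
    n_excluded: int = 0


def compute_fit_metrics(
    predicted_times: np.ndarray,
    predicted_values: np.ndarray,
    observed: pd.DataFrame,
) -> FitMetrics:
    """AAFE and 2-fold fraction of predictions vs one observed series.

    Predictions are interpolated to the observed times linearly in
    log-concentration.  Non-positive observed values are excluded (with a
    count in the result).  AAFE = 10 ** mean(|log10(pred / obs)|).
    """
    obs = observed.copy()
    mask = obs["value"] > 0
    n_excluded = int((~mask).sum())
    if n_excluded:
        import warnings
        warnings.warn(f"excluded {n_excluded} non-positive observed values",
                      stacklevel=2)
    obs = obs[mask]
    if obs.empty:
        raise ValueError("no positive observed values to compare against")
    logp = np.interp(obs["time_h"].to_numpy(), predicted_times,
                     np.log(np.maximum(predicted_values, 1e-300)))
    pred = np.exp(logp)
    ratio = pred / obs["value"].to_numpy()
    fold = np.maximum(ratio, 1.0 / ratio)
    aafe = float(10.0 ** np.mean(np.abs(np.log10(ratio))))
    return FitMetrics(
        aafe=aafe,
        fraction_within_2fold=float(np.mean(fold <= 2.0 * (1.0 + 1e-9))),
        fold_errors=fold,
        n_excluded=n_excluded,
    )


# --------------------------------------------------------------------------
# Fixture validation
# --------------------------------------------------------------------------

def validate_fixtures(smoke_t_end: float = 2.0) -> dict[str, dict]:
    """Round-trip every packaged scenario: load, run briefly, schema-check.

    Returns a report per scenario; raises on the first hard failure.
    Provenance tags of every drug file are validated by the loader.
    """
    report: dict[str, dict] = {}
    for name in list_builtin_scenarios():
        scenario = load_scenario(builtin_scenario_path(name))
        scenario = Scenario(**{**scenario.__dict__,
                               "t_end": min(scenario.t_end, smoke_t_end),
                               "n_points": 25})
        result = run_scenario(scenario)
        report[name] = {
            "drug": scenario.drug.name,
            "ga_weeks": scenario.subject.gestational_age,
            "compartments": len(result.names),
            "max_mass_balance_residual": float(result.mass_balance_residual.max()),
            "provenance_tags": len(scenario.drug.provenance),
        }
    return report
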