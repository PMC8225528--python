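"""Weighted least-squares parameter estimation against concentration data.

The paper-style workflow fits transporter Vmax values (and, for the
placenta, PStc) against observed plasma/urine/fetal profiles.  The
estimator here is generic: the caller supplies observed series and a
predictor mapping a parameter vector to model outputs; residuals are taken
in log-concentration space (multiplicative error model, the PK standard)
and minimized with a bounded trust-region solver.  Fitting is done on
log-transformed parameters, which keeps them positive and makes the
optimum scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

__all__ = ["ObservedSeries", "FitResult", "fit_parameters"]


@dataclass
class ObservedSeries:
    """One observed concentration (or amount) time series."""

    observable: str
    times: np.ndarray
    values: np.ndarray
    log_scale: bool = True
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if self.log_scale and np.any(self.values <= 0):
            raise ValueError(
                f"series {self.observable!r} has non-positive values; "
                "log-scale residuals need positive observations")


@dataclass
class FitResult:
    params: dict[str, float]
    objective: float
    cv_estimates: dict[str, float]
    n_obs: int
    success: bool
    message: str
    diagnostics: dict = field(default_factory=dict)


def fit_parameters(
    observed: list[ObservedSeries],
    predict: Callable[[dict[str, float]], dict[str, np.ndarray]],
    x0: dict[str, float],
    bounds: dict[str, tuple[float, float]] | None = None,
    xtol: float = 1e-10,
) -> FitResult:
    """Fit the parameters named in ``x0`` to the observed series.

    ``predict(params)`` must return, for every observed series, the model
    values at that series' times, keyed by observable name.  Residuals are
    log-scale by default.  Deterministic given a fixed starting point.

    Raises ValueError when no observations are given; warns (and reports a
    flat-objective diagnostic) when some parameter leaves the residuals
    essentially unchanged, i.e. is not identifiable from the data.
    """
    if not observed:
        raise ValueError("at least one observed series is required")
    names = list(x0)
    lo = np.array([np.log(bounds[n][0]) if bounds and n in bounds else -np.inf
                   for n in names])
    hi = np.array([np.log(bounds[n][1]) if bounds and n in bounds else np.inf
                   for n in names])

    def residuals(z: np.ndarray) -> np.ndarray:
        params = {n: float(np.exp(v)) for n, v in zip(names, z)}
        pred = predict(params)
        res = []
        for s in observed:
            p = np.asarray(pred[s.observable], dtype=float)
            if s.log_scale:
                r = np.log(np.maximum(p, 1e-12)) - np.log(s.values)
            else:
                r = p - s.values
            res.append(s.weight * r)
        return np.concatenate(res)

    z0 = np.log(np.array([x0[n] for n in names]))
    sol = least_squares(residuals, z0, bounds=(lo, hi), xtol=xtol)
    params = {n: float(np.exp(v)) for n, v in zip(names, sol.x)}

    n_obs = sum(s.times.size for s in observed)
    dof = max(n_obs - len(names), 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    cvs: dict[str, float] = {}
    flat: list[str] = []
    col_norm = np.linalg.norm(sol.jac, axis=0)
    for i, n in enumerate(names):
        if col_norm[i] < 1e-8:
            flat.append(n)
            cvs[n] = np.inf
            continue
        try:
            var = s2 * np.linalg.inv(jtj)[i, i]
            # parameter is log-transformed: sd of log ~ CV on natural scale
            cvs[n] = float(np.sqrt(max(var, 0.0)))
        except np.linalg.LinAlgError:
            cvs[n] = np.inf
    if flat:
        warnings.warn(
            f"flat objective: parameters {flat} are not identifiable from "
            "the supplied observations", stacklevel=2)
    return FitResult(
        params=params,
        objective=float(sol.cost),
        cv_estimates=cvs,
        n_obs=n_obs,
        success=bool(sol.success),
        message=str(sol.message),
        diagnostics={"flat_parameters": flat, "nfev": sol.nfev},
    )
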