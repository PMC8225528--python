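"""Generic compartmental ODE machinery.

A :class:`CompartmentGraph` is a list of well-stirred compartments joined by
linear transfer terms (perfusion flows, permeability products, clearances,
bulk-fluid pathways -- anything of the form flux = k * amount_source) plus
saturable Michaelis-Menten transporter connections.  Elimination sinks are
ordinary compartments without a volume, so total drug amount summed over
*all* compartments equals the administered amount at every time: mass
balance is checked, not assumed.

The state vector is amounts in ug.  ``simulate`` integrates piecewise
between dose events with a stiff BDF solver and an analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["Compartment", "CompartmentGraph", "DoseRegimen", "SimulationResult",
           "simulate", "urinary_excretion_pct", "SolverFailure"]


class SolverFailure(RuntimeError):
    """Raised when the ODE solver fails; carries a state dump for diagnosis."""

    def __init__(self, message: str, t: float, state: dict[str, float]):
        super().__init__(f"{message} at t={t:.4g} h; state={state}")
        self.t = t
        self.state = state


@dataclass
class Compartment:
    """One well-stirred space.

    volume is in L; ``volume=None`` marks an amount-only sink (urine).
    ``free_factor`` phi maps total concentration to unbound concentration
    (C_u = phi * A / V): fup for plasma spaces, fup/Kp for tissues, 1 for
    protein-free fluids such as amniotic fluid or tubular filtrate.
    """

    name: str
    volume: float | None
    free_factor: float = 1.0


@dataclass
class DoseRegimen:
    """IV dosing description: bolus when duration == 0, else constant-rate
    infusion of ``duration`` hours starting at each entry of ``times``."""

    dose_mg: float
    times: tuple[float, ...] = (0.0,)
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose must be > 0")
        if self.duration < 0:
            raise ValueError("infusion duration must be >= 0")
        object.__setattr__(self, "times", tuple(sorted(self.times)))

    @property
    def dose_ug(self) -> float:
        return self.dose_mg * 1000.0

    def administered(self, t: np.ndarray) -> np.ndarray:
        """Cumulative administered amount (ug) at times t."""
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        for t0 in self.times:
            if self.duration == 0:
                total += np.where(t >= t0, self.dose_ug, 0.0)
            else:
                frac = np.clip((t - t0) / self.duration, 0.0, 1.0)
                total += frac * self.dose_ug
        return total


@dataclass
class _MMConnection:
    src: int
    dst: int
    vmax: float      # ug/h
    km: float        # ug/mL, applied to unbound concentration at source


class CompartmentGraph:
    """Compartments plus linear and Michaelis-Menten connections."""

    def __init__(self) -> None:
        self.compartments: list[Compartment] = []
        self._index: dict[str, int] = {}
        self._linear: list[tuple[int, int, float]] = []   # (src, dst, coef /h)
        self._mm: list[_MMConnection] = []
        self.dose_target = "venous"
        self.meta: dict = {}

    # -- construction ------------------------------------------------------

    def add_compartment(self, name: str, volume: float | None,
                        free_factor: float = 1.0) -> None:
        if name in self._index:
            raise ValueError(f"duplicate compartment {name!r}")
        if volume is not None and volume <= 0:
            raise ValueError(f"compartment {name!r} volume must be > 0")
        self._index[name] = len(self.compartments)
        self.compartments.append(Compartment(name, volume, free_factor))

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown compartment {name!r}") from None

    def volume(self, name: str) -> float:
        v = self.compartments[self.index(name)].volume
        if v is None:
            raise ValueError(f"compartment {name!r} is a sink (no volume)")
        return v

    def add_linear(self, src: str, dst: str, coef: float) -> None:
        """Raw linear transfer: flux (ug/h) = coef * A_src."""
        if coef < 0:
            raise ValueError("linear transfer coefficient must be >= 0")
        self._linear.append((self.index(src), self.index(dst), coef))

    def add_flow(self, src: str, dst: str, q: float, partition: float = 1.0) -> None:
        """Convective flow q (L/h) leaving ``src`` at concentration
        A/(V*partition); partition is the tissue:plasma Kp for venous-
        equilibrium outflow from a perfusion-limited tissue, 1 for fluids."""
        self.add_linear(src, dst, q / (self.volume(src) * partition))

    def add_unbound_clearance(self, src: str, dst: str, cl: float) -> None:
        """One-way clearance cl (L/h) acting on the unbound concentration."""
        c = self.compartments[self.index(src)]
        self.add_linear(src, dst, cl * c.free_factor / c.volume)

    def add_permeability(self, a: str, b: str, ps: float) -> None:
        """Bidirectional passive exchange ps (L/h) on unbound concentrations."""
        ca = self.compartments[self.index(a)]
        cb = self.compartments[self.index(b)]
        self.add_linear(a, b, ps * ca.free_factor / ca.volume)
        self.add_linear(b, a, ps * cb.free_factor / cb.volume)

    def add_transporter(self, src: str, dst: str, vmax_ug_h: float, km_ug_ml: float) -> None:
        """Saturable MM transport on the unbound source concentration."""
        if km_ug_ml <= 0:
            raise ValueError("Km must be > 0")
        self._mm.append(_MMConnection(self.index(src), self.index(dst),
                                      vmax_ug_h, km_ug_ml))

    # -- assembly ----------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    def matrix(self) -> np.ndarray:
        n = len(self.compartments)
        k = np.zeros((n, n))
        for src, dst, coef in self._linear:
            k[src, src] -= coef
            k[dst, src] += coef
        return k

    def _phi_over_v(self) -> np.ndarray:
        """Per-compartment factor mapping amount (ug) to unbound
        concentration in ug/mL (volume L -> 1000 mL)."""
        out = np.zeros(len(self.compartments))
        for i, c in enumerate(self.compartments):
            out[i] = c.free_factor / (c.volume * 1000.0) if c.volume else 0.0
        return out


@dataclass
class SimulationResult:
    """Solved time courses.

    amounts is (n_times, n_compartments) in ug; concentrations are ug/mL
    (== mg/L) for volumetric compartments.  ``mass_balance_residual`` is
    |sum(amounts) - administered| / total dose at each output time.
    """

    times: np.ndarray
    amounts: np.ndarray
    names: list[str]
    volumes: list[float | None]
    regimen: DoseRegimen
    administered: np.ndarray
    meta: dict = field(default_factory=dict)

    def amount(self, name: str) -> np.ndarray:
        return self.amounts[:, self.names.index(name)]

    def concentration(self, name: str) -> np.ndarray:
        i = self.names.index(name)
        v = self.volumes[i]
        if v is None:
            raise ValueError(f"{name!r} is a sink; it has no concentration")
        return self.amounts[:, i] / (v * 1000.0)  # ug/mL == mg/L

    @property
    def mass_balance_residual(self) -> np.ndarray:
        total = self.amounts.sum(axis=1)
        denom = max(float(self.administered[-1]), self.regimen.dose_ug)
        return np.abs(total - self.administered) / denom

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for i, name in enumerate(self.names):
            v = self.volumes[i]
            conc = self.amounts[:, i] / v * 1e-3 if v else np.full_like(self.times, np.nan)
            rows.append(pd.DataFrame({
                "time_h": self.times, "compartment": name,
                "amount_ug": self.amounts[:, i], "conc_ug_ml": conc,
            }))
        return pd.concat(rows, ignore_index=True)


def _segments(regimen: DoseRegimen, t_end: float) -> list[float]:
    pts = {0.0, t_end}
    for t0 in regimen.times:
        if t0 < t_end:
            pts.add(t0)
            if regimen.duration > 0 and t0 + regimen.duration < t_end:
                pts.add(t0 + regimen.duration)
    return sorted(pts)


def simulate(
    graph: CompartmentGraph,
    regimen: DoseRegimen,
    t_end: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """Integrate the graph under the dosing regimen.

    Piecewise stiff BDF integration with breakpoints at every dose /
    infusion boundary; bolus doses are instantaneous additions to the dose
    target compartment; infusions enter as a constant source term.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 481)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] != 0.0 or t_eval[-1] > t_end or np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must start at 0, be increasing, end <= t_end")

    k = graph.matrix()
    n = len(graph.compartments)
    phi_v = graph._phi_over_v()
    mm = graph._mm
    target = graph.index(graph.dose_target)

    def rhs_factory(u: np.ndarray):
        def rhs(t: float, a: np.ndarray) -> np.ndarray:
            da = k @ a + u
            for c in mm:
                cu = max(phi_v[c.src] * a[c.src], 0.0)
                rate = c.vmax * cu / (c.km + cu)
                da[c.src] -= rate
                da[c.dst] += rate
            return da

        def jac(t: float, a: np.ndarray) -> np.ndarray:
            j = k.copy()
            for c in mm:
                cu = max(phi_v[c.src] * a[c.src], 0.0)
                d = c.vmax * c.km / (c.km + cu) ** 2 * phi_v[c.src]
                j[c.src, c.src] -= d
                j[c.dst, c.src] += d
            return j

        return rhs, jac

    a = np.zeros(n)
    out_t: list[np.ndarray] = []
    out_a: list[np.ndarray] = []
    bounds = _segments(regimen, t_end)
    infusing_rate = regimen.dose_ug / regimen.duration if regimen.duration > 0 else 0.0

    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if regimen.duration == 0 and t0 in regimen.times:
            a[target] += regimen.dose_ug
        u = np.zeros(n)
        if regimen.duration > 0 and any(
            s <= t0 < s + regimen.duration for s in regimen.times
        ):
            u[target] = infusing_rate
        rhs, jac = rhs_factory(u)
        seg_eval = t_eval[(t_eval >= t0) & (t_eval <= t1)]
        seg_eval = np.unique(np.concatenate([[t0], seg_eval, [t1]]))
        sol = solve_ivp(rhs, (t0, t1), a, method="BDF", jac=jac,
                        t_eval=seg_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverFailure(sol.message, t0, dict(zip(graph.names, a)))
        keep = np.isin(sol.t, t_eval)
        if t1 in t_eval and t1 != bounds[-1]:
            # segment boundaries are emitted by the *following* segment so
            # that samples at a dose time are post-bolus, consistent with
            # the administered-amount convention
            keep &= sol.t != t1
        out_t.append(sol.t[keep])
        out_a.append(sol.y[:, keep].T)
        a = sol.y[:, -1].copy()

    times = np.concatenate(out_t)
    amounts = np.concatenate(out_a, axis=0)
    # tolerate solver-scale negative undershoot only
    if amounts.min() < -1e-6:
        raise SolverFailure("negative amounts beyond solver tolerance",
                            float(times[np.argmin(amounts.min(axis=1))]),
                            dict(zip(graph.names, amounts[np.argmin(amounts.min(axis=1))])))
    amounts = np.clip(amounts, 0.0, None)
    administered = regimen.administered(times)
    return SimulationResult(
        times=times, amounts=amounts, names=graph.names,
        volumes=[c.volume for c in graph.compartments],
        regimen=regimen, administered=administered, meta=dict(graph.meta),
    )


def urinary_excretion_pct(
    result: SimulationResult,
    window: tuple[float, float] | None = None,
    sink: str = "urine_maternal",
    dose_reference: float | None = None,
) -> float:
    """Cumulative urinary excretion over a window as percent of dose.

    The default dose reference is the amount administered with start time
    inside the window (per-interval accounting for multi-dose regimens),
    falling back to the total administered dose when no dose starts in the
    window.
    """
    t = result.times
    if window is None:
        window = (float(t[0]), float(t[-1]))
    t0, t1 = window
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(f"window {window} outside simulated range [{t[0]}, {t[-1]}]")
    if t1 < t0:
        raise ValueError("window must be increasing")
    urine = result.amount(sink)
    a0 = float(np.interp(t0, t, urine))
    a1 = float(np.interp(t1, t, urine))
    if dose_reference is None:
        reg = result.regimen
        in_window = [s for s in reg.times if t0 <= s <= t1]
        dose_reference = reg.dose_ug * len(in_window) if in_window else float(
            reg.administered(np.array([t1]))[0])
    if dose_reference <= 0:
        return 0.0
    return (a1 - a0) / dose_reference * 100.0
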