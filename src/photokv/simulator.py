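"""Hodgkin--Huxley-type photoreceptor model: integration and experiments.

The membrane equation for the isopotential soma is

    C dV/dt = -(I_light + I_KDR + I_KA + I_leak) + I_inj

with ohmic currents ``I_x = g_x (V - E_x)`` and first-order gating kinetics

    dx/dt = (x_inf(V) - x) / tau_x(V)

for each activation/inactivation gate.  Two modes are provided:

* **current clamp** -- the full ODE system driven by a light-conductance
  waveform ``g_light(t)`` (and optionally injected current), used for
  simulated light responses;
* **voltage clamp** -- the command voltage is imposed (ideal clamp, dV/dt
  removed), only the gating ODEs are integrated, and the net clamp current
  is read out algebraically, mirroring how the model is validated against
  voltage-clamp recordings.

The voltage-clamp subtraction experiment (inactivation-removing vs
inactivating prepulse) and the conductance-scaling light-response
experiments are layered on top of these two primitives.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import kinetics
from .kinetics import (
    CellParameters,
    ConductanceSpec,
    GatingParameters,
    boltzmann_steady_state,
    gate_steady_state,
    conductance_value,
    equilibrium_gating,
    leak_conductance_for_rest,
    time_constant,
)

__all__ = [
    "VoltageProtocol",
    "StimulusWaveform",
    "SimulationResult",
    "SubtractionResult",
    "SensitivityResult",
    "calibrate_leak",
    "calibrated_cell",
    "instantaneous_input_resistance",
    "membrane_time_constant",
    "closed_form_gating_relaxation",
    "simulate_voltage_clamp",
    "simulate_current_clamp",
    "simulate_subtraction_protocol",
    "ka_sensitivity_experiment",
    "steady_state_voltage",
]

#: Default solver tolerances: gating time constants span ~1.5-50 ms against
#: stimuli lasting seconds, so a stiff-capable adaptive method is used.
RTOL = 1e-6
ATOL = 1e-9
_GATE_RTOL = 1e-9
_GATE_ATOL = 1e-12


# ---------------------------------------------------------------------------
# protocol / stimulus containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoltageProtocol:
    """A piecewise-constant command-voltage protocol.

    ``epochs`` is an ordered sequence of ``(level, duration)`` pairs in
    volts/seconds; ``holding`` is the pre-protocol holding potential the
    gates are equilibrated at.  Epochs are half-open ``[start, end)`` and
    command transitions are instantaneous (ideal clamp).
    """

    epochs: tuple[tuple[float, float], ...]
    holding: float
    sample_interval: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple((float(v), float(d)) for v, d in self.epochs))
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        if any(d <= 0 for _, d in self.epochs):
            raise ValueError("epoch durations must be > 0")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be > 0")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.epochs)

    def times(self) -> np.ndarray:
        n = int(round(self.total_duration / self.sample_interval))
        return np.arange(n + 1) * self.sample_interval

    def command(self, t) -> np.ndarray:
        """Command voltage at times ``t`` (half-open epochs)."""
        t = np.asarray(t, dtype=float)
        edges = np.cumsum([d for _, d in self.epochs])
        levels = np.array([v for v, _ in self.epochs])
        idx = np.minimum(np.searchsorted(edges, t, side="right"), len(levels) - 1)
        return levels[idx]


@dataclass(frozen=True)
class StimulusWaveform:
    """A light-conductance waveform (plus optional injected current).

    ``time`` must be a uniform, strictly increasing grid; ``g_light`` is
    the light-gated conductance in siemens (non-negative everywhere).
    """

    time: np.ndarray
    g_light: np.ndarray
    i_inj: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        g = np.asarray(self.g_light, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "g_light", g)
        if time.ndim != 1 or time.size < 2:
            raise ValueError("time base must be a 1-D array with >= 2 samples")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise ValueError("time base must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time base must be uniform")
        if g.shape != time.shape:
            raise ValueError("g_light must match the time base")
        if np.any(g < 0):
            raise ValueError("g_light must be non-negative")
        if self.i_inj is not None:
            i = np.asarray(self.i_inj, dtype=float)
            if i.shape != time.shape:
                raise ValueError("i_inj must match the time base")
            object.__setattr__(self, "i_inj", i)

    @property
    def sample_interval(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class SimulationResult:
    """Time series output of a simulation run.

    ``gating`` maps conductance name -> {"act": array, "inact": array};
    ``currents`` holds per-species currents in amperes under the keys
    "light", "leak" and each conductance name (outward positive).
    """

    time: np.ndarray
    v: np.ndarray
    gating: dict[str, dict[str, np.ndarray]]
    currents: dict[str, np.ndarray]
    mode: str = "current_clamp"

    @property
    def i_light(self) -> np.ndarray:
        return self.currents["light"]

    @property
    def i_leak(self) -> np.ndarray:
        return self.currents["leak"]

    @property
    def i_kdr(self) -> np.ndarray:
        return self.currents["KDR"]

    @property
    def i_ka(self) -> np.ndarray:
        return self.currents["KA"]

    def total_membrane_current(self) -> np.ndarray:
        return sum(self.currents.values())

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one column per state/current (SI units)."""
        cols: dict[str, np.ndarray] = {"time_s": self.time, "v_V": self.v}
        for name, gates in self.gating.items():
            for gate, series in gates.items():
                cols[f"{name}_{gate}"] = series
        for name, series in self.currents.items():
            cols[f"i_{name}_A"] = series
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------

def calibrate_leak(cell: CellParameters, v_rest: Optional[float] = None) -> float:
    """Leak conductance giving zero net current at the resting potential.

    With gates at equilibrium for ``v_rest`` (default: the cell's own), the
    outward Kv currents must be balanced by the inward leak; raises if the
    balance would require a negative leak.
    """
    vr = cell.v_rest if v_rest is None else v_rest
    return leak_conductance_for_rest(cell.conductances, vr, cell.e_leak)


def calibrated_cell(cell: CellParameters, v_rest: Optional[float] = None) -> CellParameters:
    """Copy of ``cell`` with its leak re-calibrated (and v_rest updated if given)."""
    vr = cell.v_rest if v_rest is None else v_rest
    g = leak_conductance_for_rest(cell.conductances, vr, cell.e_leak)
    return replace(cell, g_leak=g, v_rest=vr)


def instantaneous_input_resistance(cell: CellParameters, v: float) -> float:
    """Reciprocal of the total instantaneous conductance at voltage ``v``.

    Gates are frozen at their equilibrium values for ``v`` (chord
    conductance; no dV-derivative terms):
    ``R = 1 / (g_leak + sum_k g_max,k * a**P * h)``.
    """
    g_total = cell.g_leak + sum(
        conductance_value(spec, equilibrium_gating(spec, v)) for spec in cell.conductances
    )
    if g_total <= 0:
        raise ValueError("total instantaneous conductance is zero; resistance undefined")
    return 1.0 / g_total


def membrane_time_constant(capacitance: float, resistance: float) -> tuple[float, float]:
    """RC membrane time constant and the matching low-pass cut-off.

    Returns ``(tau, f_c)`` with ``tau = R*C`` seconds and
    ``f_c = 1/(2*pi*tau)`` Hz.
    """
    if not (capacitance > 0 and resistance > 0):
        raise ValueError("capacitance and resistance must be > 0")
    tau = resistance * capacitance
    return tau, 1.0 / (2.0 * math.pi * tau)


# ---------------------------------------------------------------------------
# gating helpers
# ---------------------------------------------------------------------------

def closed_form_gating_relaxation(gp: GatingParameters, v: float, a0: float, t):
    """Exact gate relaxation at fixed voltage.

    ``a(t) = a_inf(v) - (a_inf(v) - a0) * exp(-t / tau(v))`` -- the test
    oracle for any fixed-voltage epoch.
    """
    if not 0.0 <= a0 <= 1.0:
        raise ValueError("initial level a0 must lie in [0, 1]")
    t = np.asarray(t, dtype=float)
    a_inf = gate_steady_state(gp, v)
    tau = time_constant(gp, v)
    out = a_inf - (a_inf - a0) * np.exp(-t / tau)
    return float(out) if out.ndim == 0 else out


def _gates(cell: CellParameters) -> list[tuple[str, str, GatingParameters]]:
    """Flattened (conductance name, gate kind, parameters) state layout."""
    layout = []
    for spec in cell.conductances:
        layout.append((spec.name, "act", spec.activation))
        if spec.inactivation is not None:
            layout.append((spec.name, "inact", spec.inactivation))
    return layout


def _equilibrium_vector(cell: CellParameters, v: float) -> np.ndarray:
    return np.array([gate_steady_state(gp, v) for _, _, gp in _gates(cell)])


def _gate_series(cell: CellParameters, states: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    for i, (name, kind, _) in enumerate(_gates(cell)):
        out.setdefault(name, {})[kind] = states[i]
    return out


def _kv_currents(cell: CellParameters, v: np.ndarray,
                 gating: dict[str, dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    currents = {}
    for spec in cell.conductances:
        g = spec.g_max * gating[spec.name]["act"] ** spec.activation.order
        if spec.inactivation is not None:
            g = g * gating[spec.name]["inact"]
        currents[spec.name] = g * (v - spec.e_rev)
    return currents


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

def simulate_voltage_clamp(cell: CellParameters, protocol: VoltageProtocol) -> SimulationResult:
    """Integrate the gating ODEs under an ideal voltage clamp.

    The membrane voltage follows the command exactly (dV/dt is removed from
    the system); within each fixed-voltage epoch the gating ODEs are
    integrated numerically and per-species currents are evaluated
    algebraically at every sample (no light term).
    """
    layout = _gates(cell)
    t_grid = protocol.times()
    states = np.empty((len(layout), t_grid.size))

    def rhs_factory(v):
        a_inf = np.array([gate_steady_state(gp, v) for _, _, gp in layout])
        tau = np.array([time_constant(gp, v) for _, _, gp in layout])

        def rhs(t, y):
            return (a_inf - y) / tau

        return rhs

    y = _equilibrium_vector(cell, protocol.holding)
    t0 = 0.0
    for level, duration in protocol.epochs:
        t1 = t0 + duration
        mask = (t_grid >= t0 - 1e-12) & (t_grid < t1 - 1e-12)
        t_eval = t_grid[mask]
        # integrate across the whole epoch; request the in-epoch samples
        sol = solve_ivp(
            rhs_factory(level), (t0, t1), y,
            t_eval=np.concatenate([t_eval, [t1]]) if (t_eval.size == 0 or t_eval[-1] < t1) else t_eval,
            method="LSODA", rtol=_GATE_RTOL, atol=_GATE_ATOL,
        )
        if not sol.success:  # pragma: no cover - LSODA on linear ODEs
            raise RuntimeError(f"gating integration failed in epoch at {level} V: {sol.message}")
        states[:, mask] = sol.y[:, : t_eval.size]
        y = sol.y[:, -1]
        t0 = t1
    # final sample (t = total duration) belongs to the last epoch's end state
    if t_grid[-1] >= t0 - 1e-12:
        states[:, -1] = y

    v = protocol.command(t_grid)
    gating = _gate_series(cell, states)
    currents = _kv_currents(cell, v, gating)
    currents["leak"] = cell.g_leak * (v - cell.e_leak)
    currents["light"] = np.zeros_like(v)
    return SimulationResult(time=t_grid, v=v, gating=gating, currents=currents,
                            mode="voltage_clamp")


# ---------------------------------------------------------------------------
# current clamp
# ---------------------------------------------------------------------------

def simulate_current_clamp(cell: CellParameters, stim: StimulusWaveform,
                           v0: Optional[float] = None,
                           rtol: float = RTOL, atol: float = ATOL,
                           max_step: Optional[float] = None) -> SimulationResult:
    """Integrate the full membrane ODE driven by a light-conductance waveform.

    The state is ``[V, gates...]`` initialized at equilibrium for ``v0``
    (default: the cell's resting potential); output is sampled on the
    stimulus grid.  A stiff-capable adaptive solver (LSODA) is used with a
    maximum step bounded by the stimulus sampling so fluctuations are not
    skipped.
    """
    layout = _gates(cell)
    v_init = cell.v_rest if v0 is None else v0
    y0 = np.concatenate([[v_init], _equilibrium_vector(cell, v_init)])
    t = stim.time
    g_light_t = stim.g_light
    i_inj_t = stim.i_inj

    # per-conductance (g_max, order, e_rev, act index, inact index or None)
    cond_info = []
    k = 1
    for spec in cell.conductances:
        ih = k + 1 if spec.inactivation is not None else None
        cond_info.append((spec.g_max, spec.activation.order, spec.e_rev, k, ih))
        k += 2 if spec.inactivation is not None else 1

    gps = [gp for _, _, gp in layout]

    def rhs(tt, y):
        v = y[0]
        g_light = np.interp(tt, t, g_light_t)
        i_total = g_light * (v - cell.e_light) + cell.g_leak * (v - cell.e_leak)
        for g_max, order, e_rev, ia, ih in cond_info:
            g = g_max * y[ia] ** order
            if ih is not None:
                g *= y[ih]
            i_total += g * (v - e_rev)
        if i_inj_t is not None:
            i_total -= np.interp(tt, t, i_inj_t)
        dv = -i_total / cell.capacitance
        dy = np.empty_like(y)
        dy[0] = dv
        for j, gp in enumerate(gps, start=1):
            a_inf = gate_steady_state(gp, v)
            tau = time_constant(gp, v)
            dy[j] = (a_inf - y[j]) / tau
        return dy

    if max_step is None:
        max_step = 2.0 * stim.sample_interval
    sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise RuntimeError(
            f"current-clamp integration failed: {sol.message} (rtol={rtol}, atol={atol})"
        )
    v = sol.y[0]
    states = np.clip(sol.y[1:], 0.0, 1.0)
    gating = _gate_series(cell, states)
    currents = _kv_currents(cell, v, gating)
    currents["leak"] = cell.g_leak * (v - cell.e_leak)
    currents["light"] = g_light_t * (v - cell.e_light)
    return SimulationResult(time=t, v=v, gating=gating, currents=currents,
                            mode="current_clamp")


def steady_state_voltage(cell: CellParameters, g_light: float,
                         bracket: tuple[float, float] = (-0.1, 0.02)) -> float:
    """Voltage zeroing the algebraic current balance at constant ``g_light``.

    Independent scalar root-finding on
    ``g_light (V - E_light) + sum g_k(V) (V - E_k) + g_leak (V - E_leak) = 0``
    with gates at equilibrium -- the fixed point a current-clamp run
    converges to under a constant light conductance.
    """
    from scipy.optimize import brentq

    def net_current(v):
        i = g_light * (v - cell.e_light) + cell.g_leak * (v - cell.e_leak)
        for spec in cell.conductances:
            i += conductance_value(spec, equilibrium_gating(spec, v)) * (v - spec.e_rev)
        return i

    return brentq(net_current, *bracket, xtol=1e-12)


# ---------------------------------------------------------------------------
# subtraction protocol
# ---------------------------------------------------------------------------

@dataclass
class SubtractionResult:
    """Current families from the paired-prepulse subtraction experiment.

    ``total`` holds currents after the inactivation-removing prepulse,
    ``sustained`` after the inactivating prepulse, and
    ``transient = total - sustained`` pointwise on the shared grid
    (one row per test level).  ``step_onset`` is the time of the test-step
    transition on the shared ``time`` axis.
    """

    time: np.ndarray
    step_onset: float
    test_levels: np.ndarray
    total: np.ndarray
    sustained: np.ndarray
    transient: np.ndarray
    runs_total: list[SimulationResult]
    runs_sustained: list[SimulationResult]

    def true_transient_current(self, level_index: int) -> np.ndarray:
        """The model's actual KA current in the total-protocol run."""
        return self.runs_total[level_index].currents["KA"]


def simulate_subtraction_protocol(cell: CellParameters,
                                  test_levels: Sequence[float],
                                  prepulse_removing: float = -117e-3,
                                  prepulse_inactivating: float = -57e-3,
                                  prepulse_duration: float = 0.2,
                                  step_duration: float = 0.05,
                                  holding: float = -74e-3,
                                  sample_interval: float = 5e-5) -> SubtractionResult:
    """Simulate the paired-prepulse protocol that isolates the transient current.

    For each test level two voltage-clamp runs are performed: one after a
    hyperpolarizing prepulse that removes KA inactivation, one after a
    depolarized prepulse that inactivates KA.  Their pointwise difference
    is the conventional estimate of the transient (KA) current.

    Note that the difference is only an estimate: the two prepulses also
    leave KDR at different activation levels, so early in the test step the
    subtraction contains a decaying KDR relaxation term in addition to the
    KA current (see the methods documentation for the magnitude of this
    systematic error under canonical parameters).
    """
    levels = np.asarray(list(test_levels), dtype=float)
    if levels.size == 0:
        raise ValueError("need at least one test level")
    runs_total, runs_sustained = [], []
    for v_test in levels:
        for prepulse, store in ((prepulse_removing, runs_total),
                                (prepulse_inactivating, runs_sustained)):
            protocol = VoltageProtocol(
                epochs=((prepulse, prepulse_duration), (v_test, step_duration)),
                holding=holding, sample_interval=sample_interval,
            )
            store.append(simulate_voltage_clamp(cell, protocol))
    time = runs_total[0].time
    total = np.vstack([r.total_membrane_current() for r in runs_total])
    sustained = np.vstack([r.total_membrane_current() for r in runs_sustained])
    if total.shape != sustained.shape:
        raise ValueError("total/sustained grids do not match")
    return SubtractionResult(
        time=time, step_onset=prepulse_duration, test_levels=levels,
        total=total, sustained=sustained, transient=total - sustained,
        runs_total=runs_total, runs_sustained=runs_sustained,
    )


# ---------------------------------------------------------------------------
# conductance-scaling light-response experiments
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Voltage traces from re-running a light response with scaled g_max."""

    conductance: str
    scales: np.ndarray
    time: np.ndarray
    v: np.ndarray  # shape (n_scales, n_samples)
    max_pairwise_deviation: float
    runs: list[SimulationResult]

    def depolarization_levels(self, window: float = 0.0) -> np.ndarray:
        """Mean membrane voltage per scale (optionally skipping ``window`` s)."""
        mask = self.time >= window
        return self.v[:, mask].mean(axis=1)


def ka_sensitivity_experiment(cell: CellParameters, stim: StimulusWaveform,
                              scale_factors: Sequence[float],
                              conductance: str = "KA",
                              recalibrate_leak: bool = True) -> SensitivityResult:
    """Re-run a light response with one conductance's g_max scaled.

    Each scaled variant's leak is re-calibrated (by default) so all
    variants rest at the same potential before the stimulus; reported is
    the maximum absolute voltage deviation across all pairs of scales.
    """
    scales = np.asarray(list(scale_factors), dtype=float)
    if np.any(scales < 0):
        raise ValueError("scale factors must be >= 0")
    runs = []
    for s in scales:
        variant = cell.with_scaled_conductance(conductance, float(s))
        if recalibrate_leak:
            variant = calibrated_cell(variant)
        runs.append(simulate_current_clamp(variant, stim))
    v = np.vstack([r.v for r in runs])
    max_dev = 0.0
    for i, j in itertools.combinations(range(len(runs)), 2):
        max_dev = max(max_dev, float(np.max(np.abs(v[i] - v[j]))))
    return SensitivityResult(conductance=conductance, scales=scales,
                             time=stim.time, v=v,
                             max_pairwise_deviation=max_dev, runs=runs)
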