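"""Closed-form gating mathematics for voltage-gated conductances.

This module holds the algebra of Hodgkin--Huxley style gating: Boltzmann
steady-state activation/inactivation curves, bell-shaped voltage dependence
of gating time constants, conductance evaluation, Nernst electrochemistry,
and the canonical parameter set for a dark-adapted insect photoreceptor
model with its two Kv conductances:

* **KDR** -- a delayed-rectifier type, slow, non-inactivating sustained
  current modelled with a single first-order activation gate.
* **KA** -- an A-type, fast transient current with second-order activation
  and first-order voltage-dependent inactivation.

All quantities are SI internally (volts, siemens, farads, seconds, kelvin);
millivolts/nanosiemens/picofarads appear only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import constants as _const

__all__ = [
    "GatingParameters",
    "ConductanceSpec",
    "GatingState",
    "CellParameters",
    "boltzmann_steady_state",
    "gate_steady_state",
    "bell_time_constant",
    "time_constant",
    "bell_peak_voltage",
    "equilibrium_gating",
    "conductance_value",
    "nernst_potential",
    "nernst_slope_per_decade",
    "leak_conductance_for_rest",
    "kdr_conductance",
    "ka_conductance",
    "default_parameter_registry",
    "validation_cell",
]

FARADAY = _const.physical_constants["Faraday constant"][0]  # C/mol
GAS_CONSTANT = _const.R  # J/(mol K)

#: Standard recording temperature, kelvin (room temperature).
ROOM_TEMPERATURE = 293.15


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingParameters:
    """One gate's Boltzmann steady state and time-constant law.

    Parameters
    ----------
    v_half :
        Half-activation voltage V50 of the Boltzmann term, volts.  For an
        order-P gate the steady-state value at ``v_half`` is ``2**-P``, so
        for P > 1 this is *not* the voltage of half-maximal conductance.
    slope :
        Boltzmann slope factor, volts.  A negative slope encodes an
        inactivation gate (level decreasing with depolarization).
    order :
        Gate exponent P (>= 1); the conductance carries ``a**order``.
    tau_alpha, tau_beta :
        Rate amplitudes (1/s) of the bell-shaped time-constant law
        ``tau(v) = 1 / (alpha*exp(-s*v) + beta*exp(s*v)) + tau_offset``.
    tau_slope :
        Voltage sensitivity s of the bell law, 1/V.
    tau_offset :
        Additive floor tau0 of the bell law, seconds.
    tau_constant :
        If set, overrides the bell law with a voltage-independent time
        constant (used for KA activation, which is too fast to resolve
        against the capacitive transient and is taken as 1.5 ms).
    """

    v_half: float
    slope: float
    order: int = 1
    tau_alpha: float = 0.0
    tau_beta: float = 0.0
    tau_slope: float = 0.0
    tau_offset: float = 0.0
    tau_constant: Optional[float] = None

    def __post_init__(self) -> None:
        if not (isinstance(self.order, (int, np.integer)) and self.order >= 1):
            raise ValueError(f"gate order must be a positive integer, got {self.order!r}")
        if self.slope == 0 or not math.isfinite(self.slope):
            raise ValueError("Boltzmann slope must be finite and non-zero")
        if self.tau_alpha < 0 or self.tau_beta < 0:
            raise ValueError("rate amplitudes tau_alpha/tau_beta must be >= 0")
        if self.tau_offset < 0:
            raise ValueError("tau_offset must be >= 0")
        if self.tau_constant is not None and not self.tau_constant > 0:
            raise ValueError("tau_constant, when set, must be > 0")


@dataclass(frozen=True)
class GatingState:
    """Instantaneous gating levels of one conductance, each in [0, 1]."""

    activation: float
    inactivation: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.activation <= 1.0:
            raise ValueError(f"activation level {self.activation} outside [0, 1]")
        if self.inactivation is not None and not 0.0 <= self.inactivation <= 1.0:
            raise ValueError(f"inactivation level {self.inactivation} outside [0, 1]")


@dataclass(frozen=True)
class ConductanceSpec:
    """A named voltage-gated conductance.

    ``g_max`` is the maximal (fully open) conductance in siemens, ``e_rev``
    its reversal potential in volts.  ``inactivation`` is ``None`` for
    non-inactivating conductances such as KDR.
    """

    name: str
    g_max: float
    e_rev: float
    activation: GatingParameters
    inactivation: Optional[GatingParameters] = None

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")


@dataclass(frozen=True)
class CellParameters:
    """Whole-cell model of an isopotential photoreceptor soma.

    The leak conductance is ohmic with reversal ``e_leak``; the
    light-gated conductance reverses at ``e_light``.  ``v_rest`` is the
    dark resting potential the leak is calibrated against.
    """

    capacitance: float
    g_leak: float
    e_leak: float
    e_light: float
    conductances: tuple[ConductanceSpec, ...]
    v_rest: float
    temperature: float = ROOM_TEMPERATURE

    def __post_init__(self) -> None:
        if not self.capacitance > 0:
            raise ValueError("capacitance must be > 0")
        if self.g_leak < 0:
            raise ValueError("g_leak must be >= 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 K")
        object.__setattr__(self, "conductances", tuple(self.conductances))

    def conductance(self, name: str) -> ConductanceSpec:
        for spec in self.conductances:
            if spec.name == name:
                return spec
        raise KeyError(f"no conductance named {name!r}")

    def with_scaled_conductance(self, name: str, factor: float) -> "CellParameters":
        """Return a copy with one conductance's g_max scaled by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        scaled = tuple(
            replace(c, g_max=c.g_max * factor) if c.name == name else c
            for c in self.conductances
        )
        if all(c is o for c, o in zip(scaled, self.conductances)):
            raise KeyError(f"no conductance named {name!r}")
        return replace(self, conductances=scaled)


# ---------------------------------------------------------------------------
# gating algebra
# ---------------------------------------------------------------------------

def _check_voltage(v):
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    if np.any(np.abs(v) > 1.0):
        raise ValueError(
            "voltage magnitude exceeds 1 V; arguments are in volts "
            "(a -60 mV potential is -0.060, not -60)")
    return v


def boltzmann_steady_state(gp: GatingParameters, v):
    """Steady-state gating level ``(1 + exp((v_half - v)/slope))**-order``.

    Monotone increasing in ``v`` for positive slope (activation), monotone
    decreasing for negative slope (inactivation); equals ``2**-order`` at
    ``v = v_half``.  Accepts scalars or arrays.
    """
    v = _check_voltage(v)
    out = (1.0 + np.exp((gp.v_half - v) / gp.slope)) ** (-gp.order)
    return float(out) if out.ndim == 0 else out


def gate_steady_state(gp: GatingParameters, v):
    """Steady-state level of the *dynamic* gate variable (first-order Boltzmann).

    The gating ODE ``dx/dt = (x_inf - x)/tau`` relaxes the per-gate variable
    ``x`` toward ``x_inf(v) = (1 + exp((v_half - v)/slope))**-1``; the
    conductance then carries ``x**order``, so at equilibrium the conductance
    fraction equals :func:`boltzmann_steady_state` (the fitted order-P curve).
    For first-order gates the two functions coincide.
    """
    v = _check_voltage(v)
    out = 1.0 / (1.0 + np.exp((gp.v_half - v) / gp.slope))
    return float(out) if out.ndim == 0 else out


def bell_time_constant(gp: GatingParameters, v):
    """Voltage-dependent gating time constant, seconds.

    ``tau(v) = 1/(alpha*exp(-s*v) + beta*exp(s*v)) + tau0`` -- a bell-shaped
    function of voltage peaking at ``v* = ln(alpha/beta)/(2 s)``.  If the
    gate carries a constant time constant it is returned unchanged.
    """
    v = _check_voltage(v)
    if gp.tau_constant is not None:
        out = np.full_like(v, gp.tau_constant)
        return float(out) if out.ndim == 0 else out
    if gp.tau_alpha == 0 and gp.tau_beta == 0:
        raise ValueError("bell time constant undefined: tau_alpha = tau_beta = 0")
    s = gp.tau_slope
    out = 1.0 / (gp.tau_alpha * np.exp(-s * v) + gp.tau_beta * np.exp(s * v)) + gp.tau_offset
    return float(out) if out.ndim == 0 else out


#: Alias: the generic accessor used by the simulator.
time_constant = bell_time_constant


def bell_peak_voltage(gp: GatingParameters) -> float:
    """Voltage maximizing the bell time-constant law, ``ln(alpha/beta)/(2 s)``."""
    if gp.tau_constant is not None:
        raise ValueError("constant time constant has no bell peak")
    if gp.tau_alpha <= 0 or gp.tau_beta <= 0 or gp.tau_slope == 0:
        raise ValueError("bell peak requires alpha, beta > 0 and non-zero tau_slope")
    return math.log(gp.tau_alpha / gp.tau_beta) / (2.0 * gp.tau_slope)


def equilibrium_gating(spec: ConductanceSpec, v: float) -> GatingState:
    """All gates of ``spec`` at their Boltzmann steady state for voltage ``v``.

    Gate *variables* equilibrate to the first-order Boltzmann level; the
    conductance fraction ``a**P * h`` then equals the fitted order-P
    steady-state curve times the inactivation curve.
    """
    a = float(gate_steady_state(spec.activation, v))
    h = None
    if spec.inactivation is not None:
        h = float(gate_steady_state(spec.inactivation, v))
    return GatingState(activation=a, inactivation=h)


def conductance_value(spec: ConductanceSpec, state: GatingState) -> float:
    """Instantaneous conductance ``g_max * a**P * h`` (h = 1 if no inactivation)."""
    g = spec.g_max * state.activation ** spec.activation.order
    if spec.inactivation is not None:
        if state.inactivation is None:
            raise ValueError(f"{spec.name}: inactivating conductance needs an inactivation level")
        g *= state.inactivation
    return g


# ---------------------------------------------------------------------------
# electrochemistry
# ---------------------------------------------------------------------------

def nernst_potential(c_in: float, c_out: float, z: int = 1,
                     temperature: float = ROOM_TEMPERATURE) -> float:
    """Nernst equilibrium potential ``(R*T/(z*F)) * ln(c_out/c_in)``, volts.

    ``c_in``/``c_out`` are intra-/extracellular concentrations of the
    permeant ion (any common unit; only their ratio matters), ``z`` its
    valence.  For K+ at 140 mM inside / 5 mM outside and 293.15 K this
    gives -84 mV.
    """
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be > 0")
    if z == 0:
        raise ValueError("ion valence must be non-zero")
    if not temperature > 0:
        raise ValueError("temperature must be > 0 K")
    return GAS_CONSTANT * temperature / (z * FARADAY) * math.log(c_out / c_in)


def nernst_slope_per_decade(temperature: float = ROOM_TEMPERATURE, z: int = 1) -> float:
    """Nernst slope per tenfold concentration change, ``R*T*ln(10)/(z*F)`` volts.

    58.2 mV per decade for a monovalent ion at 293.15 K.  (Experimental
    reports sometimes label this "mV/mM"; it is mV per decade of
    concentration.)
    """
    if z == 0:
        raise ValueError("ion valence must be non-zero")
    return GAS_CONSTANT * temperature * math.log(10.0) / (z * FARADAY)


# ---------------------------------------------------------------------------
# leak balance
# ---------------------------------------------------------------------------

def leak_conductance_for_rest(conductances: Sequence[ConductanceSpec],
                              v_rest: float, e_leak: float) -> float:
    """Leak conductance that zeroes the net membrane current at ``v_rest``.

    With every gate at equilibrium for ``v_rest`` the balance is
    ``sum_k g_k(v_rest) * (v_rest - E_k) + g_leak * (v_rest - e_leak) = 0``.
    Raises if the balance would require a negative leak (i.e. the gated
    currents and the leak driving force have the same sign).
    """
    if v_rest == e_leak:
        raise ValueError("v_rest equals e_leak: leak carries no current, balance is degenerate")
    i_gated = sum(
        conductance_value(spec, equilibrium_gating(spec, v_rest)) * (v_rest - spec.e_rev)
        for spec in conductances
    )
    g_leak = -i_gated / (v_rest - e_leak)
    if g_leak < 0:
        raise ValueError(
            f"current balance at v_rest={v_rest} would need g_leak={g_leak:.3e} S < 0"
        )
    return g_leak


# ---------------------------------------------------------------------------
# canonical parameter registry
# ---------------------------------------------------------------------------

#: Reversal potential used for both Kv conductances (tail-current estimate
#: under standard 140/5 mM K+; the transient current's reversal could not be
#: measured independently and is taken equal to the sustained current's).
E_K = -68e-3

_KDR_GATE = GatingParameters(
    v_half=-31e-3, slope=12e-3, order=1,
    tau_alpha=4.0, tau_beta=156.0, tau_slope=43.0, tau_offset=0.0,
)
_KA_ACT_GATE = GatingParameters(
    v_half=-43e-3, slope=8.4e-3, order=2,
    tau_constant=1.5e-3,
)
_KA_INACT_GATE = GatingParameters(
    v_half=-85e-3, slope=-11.3e-3, order=1,
    tau_alpha=341.0, tau_beta=0.211, tau_slope=-44.0, tau_offset=0.0,
)


def kdr_conductance(g_max: float = 78e-9) -> ConductanceSpec:
    """Delayed-rectifier (KDR) conductance with the mean fitted parameters."""
    return ConductanceSpec(name="KDR", g_max=g_max, e_rev=E_K, activation=_KDR_GATE)


def ka_conductance(g_max: float = 60e-9) -> ConductanceSpec:
    """A-type (KA) conductance: 2nd-order activation, voltage-dependent inactivation."""
    return ConductanceSpec(name="KA", g_max=g_max, e_rev=E_K,
                           activation=_KA_ACT_GATE, inactivation=_KA_INACT_GATE)


def _make_cell(g_kdr: float, g_ka: float) -> CellParameters:
    conductances = (kdr_conductance(g_kdr), ka_conductance(g_ka))
    v_rest = -60e-3
    e_leak = 0.0
    g_leak = leak_conductance_for_rest(conductances, v_rest, e_leak)
    return CellParameters(
        capacitance=380e-12,
        g_leak=g_leak,
        e_leak=e_leak,
        e_light=10e-3,
        conductances=conductances,
        v_rest=v_rest,
        temperature=ROOM_TEMPERATURE,
    )


def default_parameter_registry() -> CellParameters:
    """The canonical model cell.

    380 pF capacitance, 78 nS KDR, 60 nS KA, E_K = -68 mV, ohmic leak
    reversing at 0 mV calibrated to rest the cell at -60 mV, light
    conductance reversing at +10 mV.
    """
    return _make_cell(g_kdr=78e-9, g_ka=60e-9)


def validation_cell() -> CellParameters:
    """The representative cell used for voltage-clamp validation.

    Identical to the canonical cell except KDR g_max = 52 nS, matching the
    example cell whose subtraction-protocol recordings the simulations are
    validated against.
    """
    return _make_cell(g_kdr=52e-9, g_ka=60e-9)
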