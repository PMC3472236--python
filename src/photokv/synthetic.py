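"""Seeded generators emulating the study's raw inputs.

Every analysis stage in :mod:`photokv.clamp_analysis` and every model
experiment in :mod:`photokv.simulator` can be exercised without recorded
data: these generators forward-simulate noisy voltage-clamp families (with
capacitive transients and residual series-resistance error), steady-state
activation/inactivation point sets, tail-current families under varying
external K+, fractional-block dose-response points, a naturalistic-like
fluctuating light conductance, and dim-flash quantum-bump trains.

All generators are pure functions of their parameters and a seed, and embed
their ground-truth parameters in the output metadata so parameter-recovery
tests can close the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .clamp_analysis import Trace, TraceSet, TailMeasurement, DoseResponseModel
from .kinetics import (
    CellParameters,
    GatingParameters,
    boltzmann_steady_state,
    nernst_slope_per_decade,
)
from .simulator import (
    StimulusWaveform,
    VoltageProtocol,
    simulate_voltage_clamp,
)

__all__ = [
    "NoiseSpec",
    "BumpSpec",
    "make_voltage_clamp_dataset",
    "make_activation_dataset",
    "make_tail_family",
    "make_tail_trace",
    "make_dose_response_dataset",
    "make_naturalistic_conductance",
    "make_quantum_bump_train",
]

#: Default additive noise, plausible for a compensated whole-cell rig.
DEFAULT_CURRENT_SD = 5e-12   # A
DEFAULT_VOLTAGE_SD = 0.5e-3  # V


@dataclass(frozen=True)
class NoiseSpec:
    """Recording-artifact model for synthetic clamp traces.

    ``capacitive`` injects an uncompensated charging transient at every
    command step, decaying with ``tau = residual_rs * capacitance`` and
    carrying total charge ``C * dV`` (charge conservation).  ``residual_rs``
    is the uncompensated access resistance remaining after amplifier
    compensation.
    """

    current_sd: float = DEFAULT_CURRENT_SD
    voltage_sd: float = DEFAULT_VOLTAGE_SD
    capacitive: bool = True
    residual_rs: float = 2e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.current_sd < 0 or self.voltage_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.residual_rs < 0:
            raise ValueError("residual_rs must be >= 0")


@dataclass(frozen=True)
class BumpSpec:
    """Phenomenological quantum-bump model (gamma-shaped inward events).

    The bump waveform is ``amplitude * (t/t_peak)**shape * exp(shape*(1 -
    t/t_peak))`` -- a gamma-like pulse normalized to peak at ``amplitude``
    (inward, so amplitude <= 0) after ``t_peak`` seconds.  Event onsets are
    Poisson with the given photon ``rate``; each event's latency is jittered
    around ``latency_mean``.
    """

    rate: float = 5.0
    amplitude: float = -15e-12
    shape: float = 3.0
    t_peak: float = 0.03
    latency_mean: float = 0.04
    latency_jitter: float = 0.01

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("photon rate must be >= 0")
        if self.amplitude > 0:
            raise ValueError("bump amplitude must be <= 0 (inward current)")
        if self.shape <= 0 or self.t_peak <= 0:
            raise ValueError("bump shape parameters must be > 0")


# ---------------------------------------------------------------------------
# voltage-clamp current families
# ---------------------------------------------------------------------------

def _capacitive_transient(t_grid: np.ndarray, protocol: VoltageProtocol,
                          capacitance: float, rs: float) -> np.ndarray:
    """Uncompensated charging current: a decaying exponential at each step."""
    if rs <= 0:
        return np.zeros_like(t_grid)
    tau = rs * capacitance
    out = np.zeros_like(t_grid)
    prev = protocol.holding
    t0 = 0.0
    for level, duration in protocol.epochs:
        dv = level - prev
        if dv != 0.0:
            mask = t_grid >= t0 - 1e-12
            out[mask] += (dv / rs) * np.exp(-(t_grid[mask] - t0) / tau)
        prev = level
        t0 += duration
    return out


def make_voltage_clamp_dataset(cell: CellParameters,
                               protocols: Sequence[VoltageProtocol] | VoltageProtocol,
                               noise: NoiseSpec = NoiseSpec()) -> TraceSet:
    """Forward-simulate a voltage-clamp current family and inject artifacts.

    One trace per protocol: the model's total clamp current plus (optionally)
    a capacitive transient at every command transition and additive Gaussian
    current noise.  Ground truth (the cell parameters and the noise spec)
    is embedded in the trace-set metadata; output is deterministic per seed.
    """
    if isinstance(protocols, VoltageProtocol):
        protocols = [protocols]
    rng = np.random.default_rng(noise.seed)
    traces = []
    for protocol in protocols:
        result = simulate_voltage_clamp(cell, protocol)
        i = result.total_membrane_current().copy()
        if noise.capacitive:
            i += _capacitive_transient(result.time, protocol,
                                       cell.capacitance, noise.residual_rs)
        if noise.current_sd > 0:
            i += rng.normal(0.0, noise.current_sd, size=i.shape)
        meta = {
            "holding": protocol.holding,
            "epochs": list(protocol.epochs),
            "step_level": protocol.epochs[-1][0],
            "rs": noise.residual_rs if noise.capacitive else 0.0,
            "seed": noise.seed,
        }
        traces.append(Trace(time=result.time, values=i, kind="current", meta=meta))
    truth = {
        "g_leak": cell.g_leak,
        "capacitance": cell.capacitance,
        "conductances": {
            spec.name: {"g_max": spec.g_max, "e_rev": spec.e_rev}
            for spec in cell.conductances
        },
        "noise": {"current_sd": noise.current_sd, "capacitive": noise.capacitive,
                  "residual_rs": noise.residual_rs, "seed": noise.seed},
    }
    return TraceSet(traces=traces, meta={"truth": truth})


# ---------------------------------------------------------------------------
# steady-state activation / inactivation point sets
# ---------------------------------------------------------------------------

@dataclass
class SteadyStateDataset:
    """Per-cell (voltage, level) replicates with embedded ground truth."""

    voltages: np.ndarray
    cells: list[np.ndarray]
    truth: dict

    def __iter__(self):
        return iter(self.cells)


def make_activation_dataset(gating: GatingParameters,
                            voltages: Sequence[float],
                            g_max: float = 1.0,
                            noise_sd_frac: float = 0.05,
                            n_cells: int = 6,
                            g_max_jitter_frac: float = 0.0,
                            seed: int = 0) -> SteadyStateDataset:
    """Steady-state conductance (or normalized availability) points per cell.

    Each synthetic cell's points lie on ``g_max * boltzmann(v)`` for the
    supplied gating truth (order-P curve; a negative slope gives an
    inactivation data set), with optional per-cell g_max jitter and additive
    Gaussian noise of ``noise_sd_frac * g_max``.
    """
    v = np.asarray(list(voltages), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two voltages")
    rng = np.random.default_rng(seed)
    curve = boltzmann_steady_state(gating, v)
    cells = []
    gmax_per_cell = []
    for _ in range(n_cells):
        g_cell = g_max * (1.0 + g_max_jitter_frac * rng.standard_normal()) \
            if g_max_jitter_frac > 0 else g_max
        g_cell = abs(g_cell)
        points = g_cell * curve + rng.normal(0.0, noise_sd_frac * g_max, size=v.shape)
        cells.append(points)
        gmax_per_cell.append(g_cell)
    truth = {
        "v_half": gating.v_half, "slope": gating.slope, "order": gating.order,
        "g_max": g_max, "g_max_per_cell": gmax_per_cell,
        "noise_sd_frac": noise_sd_frac, "seed": seed,
    }
    return SteadyStateDataset(voltages=v, cells=cells, truth=truth)


# ---------------------------------------------------------------------------
# tail-current families
# ---------------------------------------------------------------------------

def make_tail_family(concentrations: Sequence[float],
                     test_voltages: Sequence[float],
                     slope_per_decade: float = 52e-3,
                     anchor: tuple[float, float] = (5.0, -68e-3),
                     tail_conductance: float = 10e-9,
                     noise_sd: float = DEFAULT_CURRENT_SD,
                     seed: int = 0) -> dict[float, list[TailMeasurement]]:
    """Tail-current amplitude sets at varying external K+ concentration.

    The reversal potential follows the configured log-linear relation
    ``E_rev(c) = E_anchor + slope_per_decade * log10(c / c_anchor)``
    (default: the fitted 52 mV/decade anchored at -68 mV @ 5 mM; pass the
    ideal ``nernst_slope_per_decade()`` and a -84 mV anchor for a perfectly
    K+-selective channel).  Tail amplitudes are linear in the driving force,
    ``g_tail * (V - E_rev)``, plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    c_anchor, e_anchor = anchor
    out: dict[float, list[TailMeasurement]] = {}
    for c in concentrations:
        if c <= 0:
            raise ValueError("concentrations must be > 0")
        e_rev = e_anchor + slope_per_decade * math.log10(c / c_anchor)
        tails = []
        for v in test_voltages:
            amp = tail_conductance * (v - e_rev)
            if noise_sd > 0:
                amp += rng.normal(0.0, noise_sd)
            tails.append(TailMeasurement(test_voltage=float(v), amplitude=float(amp),
                                         k_out=float(c), true_e_rev=e_rev))
        out[float(c)] = tails
    return out


def make_tail_trace(amplitude: float, tau: float = 8e-3,
                    tail_start: float = 0.02, duration: float = 0.08,
                    baseline: float = 0.0, sample_interval: float = 1e-4,
                    noise_sd: float = 0.0, seed: int = 0) -> Trace:
    """A single deactivating tail segment with known instantaneous amplitude.

    Before ``tail_start`` the trace sits at ``baseline + amplitude`` (the
    step current); from ``tail_start`` on it decays exponentially to
    ``baseline`` with time constant ``tau``.  Ground truth in metadata.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, sample_interval)
    i = np.where(t < tail_start, baseline + amplitude,
                 baseline + amplitude * np.exp(-(t - tail_start) / tau))
    if noise_sd > 0:
        i = i + rng.normal(0.0, noise_sd, size=i.shape)
    meta = {"tail_start": tail_start, "true_amplitude": amplitude,
            "true_tau": tau, "baseline": baseline, "seed": seed}
    return Trace(time=t, values=i, kind="current", meta=meta)


# ---------------------------------------------------------------------------
# dose-response points
# ---------------------------------------------------------------------------

def make_dose_response_dataset(model: DoseResponseModel,
                               doses: Sequence[float],
                               n_reps: int = 4,
                               noise_sd: float = 0.05,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Fractional-block points ``1/(1 + (dose/IC50)**p)`` plus Gaussian noise.

    Returns ``(concentrations, responses)`` with ``n_reps`` replicates per
    dose, clipped to be non-negative (a blocked fraction cannot be < 0).
    """
    doses = np.asarray(list(doses), dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(seed)
    conc = np.repeat(doses, n_reps)
    mean = 1.0 / (1.0 + (conc / model.ic50) ** model.hill)
    resp = mean + rng.normal(0.0, noise_sd, size=conc.shape) if noise_sd > 0 else mean
    return conc, np.clip(resp, 0.0, None)


# ---------------------------------------------------------------------------
# light stimuli
# ---------------------------------------------------------------------------

def make_naturalistic_conductance(duration: float = 10.0,
                                  mean_level: float = 5e-9,
                                  contrast: float = 0.5,
                                  correlation_time: float = 0.05,
                                  sample_interval: float = 1e-3,
                                  seed: int = 0) -> StimulusWaveform:
    """A naturalistic-like fluctuating light conductance.

    A log-normal marginal with low-pass temporal correlation: an
    Ornstein--Uhlenbeck process (time constant ``correlation_time``) drives
    the log-conductance, giving a non-negative, positively skewed waveform
    whose mean is ``mean_level`` and whose coefficient of variation is
    ``contrast``.  This is a statistical stand-in exercising the simulator
    with fluctuating input; it does not reproduce any particular recorded
    light-intensity series.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not 0 <= contrast:
        raise ValueError("contrast must be >= 0")
    n = int(round(duration / sample_interval)) + 1
    t = np.arange(n) * sample_interval
    if contrast == 0:
        return StimulusWaveform(time=t, g_light=np.full(n, mean_level))
    rng = np.random.default_rng(seed)
    # unit-variance stationary OU, exact discretization
    rho = math.exp(-sample_interval / correlation_time)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * math.sqrt(1.0 - rho * rho)
    for k in range(1, n):
        x[k] = rho * x[k - 1] + innov[k - 1]
    sigma = math.sqrt(math.log(1.0 + contrast ** 2))
    g = mean_level * np.exp(sigma * x - 0.5 * sigma * sigma)
    return StimulusWaveform(time=t, g_light=g)


def make_quantum_bump_train(spec: BumpSpec, duration: float,
                            sample_interval: float = 1e-3,
                            noise_sd: float = 0.0,
                            seed: int = 0) -> Trace:
    """Poisson-timed quantum bumps: discrete inward single-photon currents.

    Photon absorptions arrive as a Poisson process at ``spec.rate``; each
    elicits a gamma-shaped inward current after a jittered latency.  Event
    (absorption) times are recorded in the trace metadata.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration / sample_interval)) + 1
    t = np.arange(n) * sample_interval
    i = np.zeros(n)
    n_events = rng.poisson(spec.rate * duration)
    event_times = np.sort(rng.uniform(0.0, duration, size=n_events))
    for t_event in event_times:
        latency = max(0.0, t_event + rng.normal(spec.latency_mean, spec.latency_jitter))
        rel = (t - latency) / spec.t_peak
        mask = rel > 0
        i[mask] += spec.amplitude * rel[mask] ** spec.shape * np.exp(spec.shape * (1.0 - rel[mask]))
    if noise_sd > 0:
        i += rng.normal(0.0, noise_sd, size=i.shape)
    meta = {"event_times": event_times.tolist(), "rate": spec.rate,
            "amplitude": spec.amplitude, "seed": seed}
    return Trace(time=t, values=i, kind="current", meta=meta)
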