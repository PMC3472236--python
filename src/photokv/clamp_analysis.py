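"""Conductance characterization from voltage-clamp traces.

The pipeline the package applies to recorded (or synthetic) data:

1. offline series-resistance correction of command voltages;
2. isolation of the transient current by protocol subtraction;
3. conductance extraction ``g = I / (V - E_rev)``;
4. curve fits: Boltzmann steady states (order 1 or 2), single-exponential
   relaxations, the m^2 h "pulse function" for transients, bell-shaped
   time-constant laws, tail-current reversal potentials, the Nernst
   relation across external K+ concentrations, logistic dose-response
   (IC50 / Hill), and passive properties from a hyperpolarizing test pulse.

Nonlinear fits use damped least squares (lmfit / Levenberg-Marquardt) with
positivity bounds on scale parameters and data-driven initial guesses;
linear relations use ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lmfit import Model
from scipy import stats

__all__ = [
    "Trace",
    "TraceSet",
    "FitResult",
    "DoseResponseModel",
    "TailMeasurement",
    "PassiveProperties",
    "correct_series_resistance",
    "conductance_from_current",
    "fit_boltzmann",
    "fit_exponential_relaxation",
    "fit_pulse_function",
    "fit_bell_time_constant",
    "isolate_transient_current",
    "measure_tail_amplitude",
    "estimate_reversal_potential",
    "fit_nernst_relation",
    "fit_dose_response",
    "passive_properties_from_test_pulse",
]

#: Series-resistance correction threshold: commands are only corrected for
#: currents exceeding this magnitude.
RS_CORRECTION_THRESHOLD = 200e-12  # A


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """A sampled recording on a uniform time grid.

    ``kind`` is "current" (values in amperes) or "voltage" (volts).
    ``meta`` carries protocol and provenance fields (holding level, step
    level, access resistance, LJP offset, ion concentrations, seed, ...).
    """

    time: np.ndarray
    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape or self.time.ndim != 1:
            raise ValueError("time and values must be matching 1-D arrays")
        if self.time.size >= 3:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
                raise ValueError("trace requires a uniform, increasing time grid")
        if self.kind not in ("current", "voltage"):
            raise ValueError(f"kind must be 'current' or 'voltage', got {self.kind!r}")

    @property
    def sample_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def segment(self, t_start: float, t_stop: Optional[float] = None) -> "Trace":
        """Sub-trace on ``[t_start, t_stop)`` keeping metadata."""
        mask = self.time >= t_start - 1e-12
        if t_stop is not None:
            mask &= self.time < t_stop - 1e-12
        return Trace(time=self.time[mask], values=self.values[mask],
                     kind=self.kind, meta=dict(self.meta))


@dataclass
class TraceSet:
    """A family of traces sharing protocol context (plus set-level metadata)."""

    traces: list[Trace]
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.traces)

    def __len__(self):
        return len(self.traces)


@dataclass(frozen=True)
class DoseResponseModel:
    """Logistic block model ``f(c) = 1 / (1 + (c/ic50)**hill)``."""

    ic50: float
    hill: float

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError("ic50 must be > 0")
        if not self.hill > 0:
            raise ValueError("Hill coefficient must be > 0")

    def __call__(self, c):
        return 1.0 / (1.0 + (np.asarray(c, dtype=float) / self.ic50) ** self.hill)


@dataclass(frozen=True)
class TailMeasurement:
    """One tail-current amplitude at a test voltage and external K+ level."""

    test_voltage: float
    amplitude: float
    k_out: float
    true_e_rev: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.k_out > 0:
            raise ValueError("external K+ concentration must be > 0")


@dataclass
class FitResult:
    """Parameter estimates with standard errors from one least-squares fit."""

    model: str
    params: dict[str, float]
    stderr: dict[str, Optional[float]]
    rss: float
    converged: bool
    covar: Optional[np.ndarray] = None
    flags: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def se(self, name: str) -> Optional[float]:
        return self.stderr.get(name)


def _from_lmfit(model_name: str, out, flags: Sequence[str] = ()) -> FitResult:
    params = {k: float(p.value) for k, p in out.params.items() if p.vary or p.expr is None}
    stderr = {k: (float(p.stderr) if p.stderr is not None else None)
              for k, p in out.params.items()}
    return FitResult(
        model=model_name,
        params=params,
        stderr=stderr,
        rss=float(np.sum(np.square(out.residual))),
        converged=bool(out.success),
        covar=out.covar,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def correct_series_resistance(trace: Trace, rs: float,
                              threshold: float = RS_CORRECTION_THRESHOLD) -> Trace:
    """Offline series-resistance correction of the command voltage.

    For samples whose current magnitude exceeds ``threshold`` the effective
    membrane voltage ``V_m = V_cmd - I * rs`` is recorded alongside the
    (unchanged) current samples as ``meta['v_effective']``; smaller currents
    keep the nominal command.  ``rs = 0`` is the identity correction.
    """
    if trace.kind != "current":
        raise ValueError("series-resistance correction applies to current traces")
    if rs < 0:
        raise ValueError("rs must be >= 0")
    command = trace.meta.get("step_level")
    if command is None:
        raise KeyError("trace metadata must provide 'step_level' (command voltage)")
    i = trace.values
    v_eff = np.where(np.abs(i) > threshold, command - i * rs, command)
    meta = dict(trace.meta)
    meta["v_effective"] = v_eff
    meta["rs_corrected"] = rs
    return Trace(time=trace.time, values=i, kind="current", meta=meta)


def conductance_from_current(i, v, e_rev: float):
    """Chord conductance ``g = I / (V - E_rev)``; rejects zero driving force."""
    v = np.asarray(v, dtype=float)
    if np.any(v == e_rev):
        raise ValueError("zero driving force: v equals e_rev")
    out = np.asarray(i, dtype=float) / (v - e_rev)
    return float(out) if out.ndim == 0 else out


def isolate_transient_current(total: Trace, sustained: Trace) -> Trace:
    """Pointwise subtraction isolating the inactivating (transient) current."""
    if total.time.shape != sustained.time.shape or \
            not np.allclose(total.time, sustained.time, rtol=0, atol=1e-12):
        raise ValueError("total and sustained traces must share one time grid")
    lv_t, lv_s = total.meta.get("step_level"), sustained.meta.get("step_level")
    if lv_t is not None and lv_s is not None and not math.isclose(lv_t, lv_s,
                                                                  abs_tol=1e-9):
        raise ValueError("total and sustained traces must share the test level")
    meta = dict(total.meta)
    meta["isolated"] = "transient (total - sustained)"
    return Trace(time=total.time, values=total.values - sustained.values,
                 kind="current", meta=meta)


# ---------------------------------------------------------------------------
# steady-state fits
# ---------------------------------------------------------------------------

def _boltzmann_curve(v, g_max, v_half, slope, order):
    return g_max * (1.0 + np.exp((v_half - v) / slope)) ** (-order)


def fit_boltzmann(voltages, values, order: int = 1) -> FitResult:
    """Least-squares Boltzmann fit ``g_max / (1 + exp((V50 - V)/slope))**P``.

    ``order`` (P) is held fixed.  For P = 2 the fitted V50 is *not* the
    half-maximum voltage of the curve.  The slope's sign is initialized
    from the data trend (rising: activation; falling: inactivation) and a
    sign flip of the fitted slope is flagged.
    """
    v = np.asarray(voltages, dtype=float)
    g = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("Boltzmann fit needs at least 4 points spanning the rise")
    rising = float(np.polyfit(v, g, 1)[0]) >= 0
    g_max0 = float(np.max(g))
    half = g_max0 / 2.0
    # crossing of the half level, in the direction of the trend
    order_idx = np.argsort(v)
    vs, gs = v[order_idx], g[order_idx]
    crossings = np.nonzero(np.diff(np.sign(gs - half)))[0]
    v50_0 = float(vs[crossings[0]]) if crossings.size else float(np.median(vs))
    slope0 = (vs[-1] - vs[0]) / 4.0
    if not rising:
        slope0 = -slope0

    model = Model(_boltzmann_curve)
    pars = model.make_params(g_max=max(g_max0, 1e-30), v_half=v50_0,
                             slope=slope0, order=order)
    pars["g_max"].min = 0.0
    pars["order"].vary = False
    out = model.fit(g, pars, v=v)
    flags = []
    if not out.success:
        flags.append("not_converged")
    if np.sign(out.params["slope"].value) != np.sign(slope0):
        flags.append("slope_sign_flip")
    return _from_lmfit(f"boltzmann_p{order}", out, flags)


# ---------------------------------------------------------------------------
# kinetics fits
# ---------------------------------------------------------------------------

def _as_xy(segment) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(segment, Trace):
        t = segment.time - segment.time[0]
        return t, segment.values
    t, y = segment
    t = np.asarray(t, dtype=float)
    return t - t[0], np.asarray(y, dtype=float)


def _exp_curve(t, amplitude, tau, offset):
    return offset + amplitude * np.exp(-t / tau)


def fit_exponential_relaxation(segment) -> FitResult:
    """Single-exponential fit ``offset + amplitude * exp(-t/tau)``.

    ``segment`` is a :class:`Trace` (or ``(t, y)`` pair) starting at the
    epoch transition.  A flat segment (amplitude indistinguishable from
    zero) leaves tau unidentifiable and is flagged; strong non-monotonicity
    beyond noise is flagged as well.
    """
    t, y = _as_xy(segment)
    span = float(np.max(y) - np.min(y))
    scale = max(abs(float(np.max(np.abs(y)))), 1e-300)
    if span < 1e-9 * scale:
        return FitResult(model="exponential", params={"amplitude": 0.0,
                                                      "tau": float("nan"),
                                                      "offset": float(np.mean(y))},
                         stderr={}, rss=float(np.sum((y - np.mean(y)) ** 2)),
                         converged=False, flags=("tau_unidentifiable",))
    offset0 = float(y[-1])
    amp0 = float(y[0] - offset0)
    # time at which the deviation from the asymptote falls to 1/e
    dev = np.abs(y - offset0)
    below = np.nonzero(dev <= abs(amp0) / math.e)[0]
    tau0 = float(t[below[0]]) if below.size and t[below[0]] > 0 else float(t[-1] / 3)
    model = Model(_exp_curve)
    pars = model.make_params(amplitude=amp0, tau=max(tau0, 1e-9), offset=offset0)
    pars["tau"].min = 1e-12
    out = model.fit(y, pars, t=t)
    flags = []
    if not out.success:
        flags.append("not_converged")
    # non-monotone beyond noise: residual variation of a smoothed derivative
    if t.size >= 10:
        k = max(t.size // 10, 2)
        smooth = np.convolve(y, np.ones(k) / k, mode="valid")
        d = np.diff(smooth)
        pos, neg = d[d > 0].sum(), -d[d < 0].sum()
        if min(pos, neg) > 0.2 * (pos + neg) and min(pos, neg) > 0.05 * span:
            flags.append("non_monotone")
    return _from_lmfit("exponential", out, flags)


def _pulse_curve(t, i_max, tau_act, tau_inact):
    return i_max * (1.0 - np.exp(-t / tau_act)) ** 2 * np.exp(-t / tau_inact)


def pulse_peak_time(tau_act: float, tau_inact: float) -> float:
    """Closed-form peak time of ``(1 - exp(-t/ta))**2 * exp(-t/ti)``.

    Setting the derivative to zero gives ``exp(-t/ta) = ta / (ta + 2 ti)``.
    """
    return tau_act * math.log((tau_act + 2.0 * tau_inact) / tau_act)


def fit_pulse_function(segment) -> FitResult:
    """Fit the m^2 h transient ``I_max (1 - exp(-t/tau_act))**2 exp(-t/tau_inact)``.

    Models a second-order-activating, first-order-inactivating current
    following a voltage step at t = 0.  A sustained-only segment (no decay
    after the rise) is flagged.
    """
    t, y = _as_xy(segment)
    if t.size < 6:
        raise ValueError("pulse fit needs at least 6 samples")
    ipk = int(np.argmax(np.abs(y)))
    y_pk = float(y[ipk])
    t_pk = float(t[ipk]) if t[ipk] > 0 else float(t[-1] / 10)
    flags = []
    tail = np.abs(y[max(ipk, 1):])
    if tail.size and tail[-1] > 0.8 * abs(y_pk):
        flags.append("sustained_only")
    tau_act0 = t_pk / 2.0
    # decay time to 1/e of the peak
    dec = np.nonzero(np.abs(y[ipk:]) <= abs(y_pk) / math.e)[0]
    tau_inact0 = float(t[ipk + dec[0]] - t_pk) if dec.size else float(t[-1] - t_pk) or t_pk
    shape = (1.0 - math.exp(-t_pk / tau_act0)) ** 2 * math.exp(-t_pk / max(tau_inact0, 1e-9))
    i_max0 = y_pk / max(shape, 1e-6)
    model = Model(_pulse_curve)
    pars = model.make_params(i_max=i_max0, tau_act=tau_act0,
                             tau_inact=max(tau_inact0, 1e-9))
    pars["tau_act"].min = 1e-12
    pars["tau_inact"].min = 1e-12
    out = model.fit(y, pars, t=t)
    if not out.success:
        flags.append("not_converged")
    return _from_lmfit("pulse_m2h", out, flags)


def _bell_curve(v, alpha, beta, tau_slope, tau_offset):
    return 1.0 / (alpha * np.exp(-tau_slope * v) + beta * np.exp(tau_slope * v)) + tau_offset


def fit_bell_time_constant(voltages, taus, fix_tau_offset: bool = False,
                           tau_slope_init: float = 40.0) -> FitResult:
    """Fit the bell law ``1/(alpha e^(-s v) + beta e^(s v)) + tau0`` to tau(V) data.

    ``fix_tau_offset=True`` pins tau0 = 0.  Initial alpha/beta are solved
    from the apparent peak (location and height); if the data are monotone
    the fitted bell peak lies outside the sampled range and the result is
    flagged (but still returned).
    """
    v = np.asarray(voltages, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if v.size < 5:
        raise ValueError("bell fit needs at least 5 (voltage, tau) points")
    if np.any(tau <= 0):
        raise ValueError("time constants must be > 0")
    s0 = tau_slope_init
    i_pk = int(np.argmax(tau))
    v_pk, tau_pk = float(v[i_pk]), float(tau[i_pk])
    alpha0 = math.exp(s0 * v_pk) / (2.0 * tau_pk)
    beta0 = 1.0 / (2.0 * tau_pk * math.exp(s0 * v_pk))
    model = Model(_bell_curve)
    pars = model.make_params(alpha=alpha0, beta=beta0, tau_slope=s0, tau_offset=0.0)
    pars["alpha"].min = 0.0
    pars["beta"].min = 0.0
    pars["tau_offset"].min = 0.0
    if fix_tau_offset:
        pars["tau_offset"].vary = False
    out = model.fit(tau, pars, v=v)
    flags = [] if out.success else ["not_converged"]
    a, b, s = (out.params[k].value for k in ("alpha", "beta", "tau_slope"))
    if a > 0 and b > 0 and s != 0:
        v_star = math.log(a / b) / (2.0 * s)
        if not (v.min() <= v_star <= v.max()):
            flags.append("peak_outside_range")
    return _from_lmfit("bell_tau", out, flags)


def bell_fit_peak_voltage(fit: FitResult) -> float:
    """Peak location ``ln(alpha/beta) / (2 tau_slope)`` of a bell-law fit."""
    return math.log(fit["alpha"] / fit["beta"]) / (2.0 * fit["tau_slope"])


# ---------------------------------------------------------------------------
# tail currents, reversal potentials, Nernst relation
# ---------------------------------------------------------------------------

def measure_tail_amplitude(trace: Trace, method: str = "extrapolate",
                           fixed_latency: float = 0.5e-3,
                           fit_skip: float = 0.0) -> float:
    """Instantaneous tail-current amplitude at the repolarization step.

    ``extrapolate`` (default) fits a single exponential to the deactivating
    tail and extrapolates it back to the repolarization instant -- unbiased
    by deactivation during the measurement latency.  ``fixed_latency``
    instead reads the (baseline-subtracted) sample a configured delay after
    repolarization, which underestimates decaying tails.  The tail epoch
    onset must be present as ``meta['tail_start']``.
    """
    tail_start = trace.meta.get("tail_start")
    if tail_start is None:
        raise KeyError("trace metadata must provide 'tail_start' (repolarization time)")
    tail = trace.segment(tail_start + fit_skip)
    if tail.time.size < 4:
        raise ValueError("tail epoch too short to measure")
    if method == "extrapolate":
        fit = fit_exponential_relaxation(tail)
        if "tau_unidentifiable" in fit.flags:
            return 0.0
        # value at the repolarization instant, relative to the fitted baseline
        dt = (tail_start - (tail_start + fit_skip))
        return float(fit["amplitude"] * math.exp(-dt / fit["tau"]))
    if method == "fixed_latency":
        baseline = float(np.mean(trace.values[trace.time >=
                                              trace.time[-1] - 0.1 * (trace.time[-1] - tail_start)]))
        idx = int(np.argmin(np.abs(trace.time - (tail_start + fixed_latency))))
        return float(trace.values[idx] - baseline)
    raise ValueError(f"unknown method {method!r}")


def estimate_reversal_potential(tails: Sequence[TailMeasurement]) -> FitResult:
    """Reversal potential from the zero crossing of amplitude vs test voltage.

    Fits a line to (V, amplitude) and solves for the voltage of zero
    amplitude; the standard error follows from the coefficient covariance
    by the delta method.  If the amplitudes do not bracket zero the
    estimate is an extrapolation and is flagged.
    """
    v = np.array([m.test_voltage for m in tails], dtype=float)
    a = np.array([m.amplitude for m in tails], dtype=float)
    if v.size < 2:
        raise ValueError("need at least two tail measurements")
    flags = []
    if a.min() > 0 or a.max() < 0:
        flags.append("extrapolated")
    if v.size >= 4:
        coef, cov = np.polyfit(v, a, 1, cov=True)
    else:
        coef, cov = np.polyfit(v, a, 1), None
    m, b = float(coef[0]), float(coef[1])
    if m == 0:
        raise ValueError("tail amplitudes independent of voltage; no reversal")
    e_rev = -b / m
    se = None
    if cov is not None:
        grad = np.array([b / m ** 2, -1.0 / m])
        var = float(grad @ cov @ grad)
        se = math.sqrt(var) if var >= 0 else None
    resid = a - (m * v + b)
    return FitResult(model="linear_reversal",
                     params={"e_rev": e_rev, "slope": m, "intercept": b},
                     stderr={"e_rev": se}, rss=float(np.sum(resid ** 2)),
                     converged=True, flags=tuple(flags))


def fit_nernst_relation(points: Sequence[tuple[float, float]]) -> FitResult:
    """Linear regression of reversal potential on log10 of external K+.

    ``points`` are ``(concentration, E_rev)`` pairs; the fitted slope is in
    volts per tenfold concentration change.  At least two distinct
    concentrations are required.
    """
    c = np.array([p[0] for p in points], dtype=float)
    e = np.array([p[1] for p in points], dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.unique(c).size < 2:
        raise ValueError("Nernst fit needs more than one concentration")
    res = stats.linregress(np.log10(c), e)
    pred = res.intercept + res.slope * np.log10(c)
    return FitResult(model="nernst_line",
                     params={"slope_per_decade": float(res.slope),
                             "intercept": float(res.intercept)},
                     stderr={"slope_per_decade": float(res.stderr),
                             "intercept": float(res.intercept_stderr)},
                     rss=float(np.sum((e - pred) ** 2)), converged=True)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def _logistic_block(c, ic50, hill):
    return 1.0 / (1.0 + (c / ic50) ** hill)


def fit_dose_response(concentrations, responses) -> FitResult:
    """Least-squares logistic fit ``1 / (1 + (c/IC50)**p)`` to fractional currents.

    ``responses`` are drug/control current ratios in [0, ~1].  An
    all-saturated data set (every response near 0 or near 1) cannot
    constrain IC50 and is flagged.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    flags = []
    if np.all(r > 0.9) or np.all(r < 0.1):
        flags.append("all_saturated")
    ic50_0 = float(c[np.argmin(np.abs(r - 0.5))])
    model = Model(_logistic_block)
    pars = model.make_params(ic50=ic50_0, hill=1.0)
    pars["ic50"].min = 1e-300
    pars["hill"].min = 1e-6
    out = model.fit(r, pars, c=c)
    if not out.success:
        flags.append("not_converged")
    return _from_lmfit("logistic_block", out, flags)


# ---------------------------------------------------------------------------
# passive properties (test-pulse method)
# ---------------------------------------------------------------------------

@dataclass
class PassiveProperties:
    """Whole-cell passive parameters from a hyperpolarizing test pulse."""

    r_in: float
    capacitance: Optional[float]
    r_access: float
    tau: Optional[float] = None
    flags: tuple[str, ...] = ()


def passive_properties_from_test_pulse(trace: Trace, step: float) -> PassiveProperties:
    """Input resistance, capacitance and access resistance from a test pulse.

    The current response to a small voltage step ``step`` (relative to
    holding; trace t = 0 at step onset, baseline-subtracted) through the
    access resistance into the RC membrane decays exponentially from
    ``I_peak = dV/R_a`` to ``I_ss = dV/(R_a + R_in)``; a single-exponential
    fit gives ``tau = C * R_a R_in / (R_a + R_in)``, hence
    ``C = tau (R_a + R_in) / (R_a R_in)``.  Without a resolvable transient
    (I_peak ~ I_ss) the capacitance is unreported and the response is
    dominated by R_in.
    """
    if trace.kind != "current":
        raise ValueError("test-pulse analysis needs a current trace")
    if step == 0:
        raise ValueError("test-pulse step must be non-zero")
    fit = fit_exponential_relaxation(trace)
    if "tau_unidentifiable" in fit.flags:
        i_ss = float(np.mean(trace.values))
        return PassiveProperties(r_in=step / i_ss, capacitance=None, r_access=0.0,
                                 flags=("no_transient",))
    i_peak = fit["offset"] + fit["amplitude"]
    i_ss = fit["offset"]
    if i_peak == 0 or i_ss == 0:
        raise ValueError("degenerate test-pulse response")
    r_access = step / i_peak
    r_total = step / i_ss
    r_in = r_total - r_access
    flags = []
    capacitance: Optional[float] = None
    if abs(fit["amplitude"]) < 0.01 * abs(i_ss) or r_in <= 0 or r_access <= 0:
        flags.append("no_transient")
        r_in = max(r_total, r_in)
    else:
        capacitance = fit["tau"] * (r_access + r_in) / (r_access * r_in)
    return PassiveProperties(r_in=r_in, capacitance=capacitance,
                             r_access=r_access, tau=fit["tau"], flags=tuple(flags))
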