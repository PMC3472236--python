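"""Fit pipeline: each estimator exercised on exactly-known synthetic inputs."""

import math

import numpy as np
import pytest

from photokv import clamp_analysis as ca
from photokv import kinetics, synthetic
from photokv.clamp_analysis import (
    DoseResponseModel,
    TailMeasurement,
    Trace,
    conductance_from_current,
    correct_series_resistance,
    estimate_reversal_potential,
    fit_bell_time_constant,
    fit_boltzmann,
    fit_dose_response,
    fit_exponential_relaxation,
    fit_nernst_relation,
    fit_pulse_function,
    isolate_transient_current,
    measure_tail_amplitude,
    passive_properties_from_test_pulse,
    pulse_peak_time,
)


def _make_current_trace(values, dt=1e-4, step_level=-0.027, **meta):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * dt
    return Trace(time=t, values=values, kind="current",
                 meta={"step_level": step_level, **meta})


class TestSeriesResistance:
    def test_effective_voltage(self):
        i = np.array([0.0, 1e-9, 2e-9])
        trace = _make_current_trace(i, step_level=-0.027)
        out = correct_series_resistance(trace, 5e6)
        v_eff = out.meta["v_effective"]
        # 1 nA across 5 MOhm drops 5 mV
        assert v_eff[1] == pytest.approx(-0.027 - 5e-3, rel=1e-12)
        assert v_eff[2] == pytest.approx(-0.027 - 10e-3, rel=1e-12)

    def test_small_currents_uncorrected(self):
        trace = _make_current_trace(np.array([50e-12, -100e-12]))
        out = correct_series_resistance(trace, 5e6)
        assert np.allclose(out.meta["v_effective"], -0.027)

    def test_missing_step_level_raises(self):
        t = np.arange(3) * 1e-4
        trace = Trace(time=t, values=np.zeros(3), kind="current", meta={})
        with pytest.raises(KeyError):
            correct_series_resistance(trace, 5e6)


class TestConductanceExtraction:
    def test_ohmic_definition(self):
        assert conductance_from_current(1e-9, -0.02, -0.068) == pytest.approx(
            1e-9 / 0.048, rel=1e-12)

    def test_at_reversal_raises(self):
        with pytest.raises(ValueError):
            conductance_from_current(1e-9, -0.068, -0.068)

    def test_isolation_requires_matching_grids(self):
        a = _make_current_trace(np.zeros(10))
        b = _make_current_trace(np.zeros(11))
        with pytest.raises(ValueError):
            isolate_transient_current(a, b)

    def test_isolation_subtracts_pointwise(self):
        a = _make_current_trace(np.full(10, 3e-9))
        b = _make_current_trace(np.full(10, 1e-9))
        diff = isolate_transient_current(a, b)
        assert np.allclose(diff.values, 2e-9)


class TestBoltzmannFit:
    def test_exact_recovery_order1(self):
        gp = kinetics.GatingParameters(v_half=-31e-3, slope=12e-3, order=1)
        v = np.arange(-0.09, 0.04, 0.01)
        g = 78e-9 * kinetics.boltzmann_steady_state(gp, v)
        fit = fit_boltzmann(v, g, order=1)
        assert fit.converged
        assert fit["v_half"] == pytest.approx(-31e-3, abs=1e-8)
        assert fit["slope"] == pytest.approx(12e-3, abs=1e-8)
        assert fit["g_max"] == pytest.approx(78e-9, rel=1e-6)

    def test_exact_recovery_order2(self):
        gp = kinetics.GatingParameters(v_half=-43e-3, slope=8.4e-3, order=2)
        v = np.arange(-0.08, 0.02, 0.01)
        g = 60e-9 * kinetics.boltzmann_steady_state(gp, v)
        fit = fit_boltzmann(v, g, order=2)
        assert fit["v_half"] == pytest.approx(-43e-3, abs=1e-8)
        assert fit["slope"] == pytest.approx(8.4e-3, abs=1e-8)

    def test_negative_slope_inactivation(self):
        gp = kinetics.GatingParameters(v_half=-85e-3, slope=-11.3e-3, order=1)
        v = np.arange(-0.13, -0.03, 0.01)
        h = kinetics.boltzmann_steady_state(gp, v)
        fit = fit_boltzmann(v, h, order=1)
        assert fit["v_half"] == pytest.approx(-85e-3, abs=1e-7)
        assert fit["slope"] == pytest.approx(-11.3e-3, abs=1e-7)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann(np.array([-0.05, 0.0]), np.array([1e-9, 2e-9]))


class TestExponentialFit:
    def test_exact_recovery(self):
        t = np.arange(0, 0.05, 1e-4)
        y = 2e-9 * np.exp(-t / 5e-3) + 1e-10
        fit = fit_exponential_relaxation(Trace(time=t, values=y, kind="current"))
        assert fit["amplitude"] == pytest.approx(2e-9, rel=1e-6)
        assert fit["tau"] == pytest.approx(5e-3, rel=1e-6)
        assert fit["offset"] == pytest.approx(1e-10, rel=1e-4)

    def test_flat_segment_flagged(self):
        t = np.arange(0, 0.05, 1e-4)
        fit = fit_exponential_relaxation(
            Trace(time=t, values=np.full(t.size, 1e-9), kind="current"))
        assert "tau_unidentifiable" in fit.flags


class TestPulseFunctionFit:
    def test_exact_recovery_and_peak_time(self):
        tau_a, tau_i, i_max = 1.5e-3, 8e-3, 1e-9
        t = np.arange(0, 0.05, 5e-5)
        y = i_max * (1 - np.exp(-t / tau_a)) ** 2 * np.exp(-t / tau_i)
        fit = fit_pulse_function(Trace(time=t, values=y, kind="current"))
        assert fit["tau_act"] == pytest.approx(tau_a, rel=1e-5)
        assert fit["tau_inact"] == pytest.approx(tau_i, rel=1e-5)
        assert fit["i_max"] == pytest.approx(i_max, rel=1e-5)
        # closed-form peak time vs grid argmax
        t_pk = pulse_peak_time(tau_a, tau_i)
        assert t_pk == pytest.approx(
            tau_a * math.log((tau_a + 2 * tau_i) / tau_a), rel=1e-12)
        assert abs(t[np.argmax(y)] - t_pk) < 1e-4


class TestBellFit:
    def test_exact_recovery(self):
        gp = kinetics.GatingParameters(v_half=-31e-3, slope=12e-3, order=1,
                                       tau_alpha=4.0, tau_beta=156.0,
                                       tau_slope=43.0)
        v = np.arange(-0.08, 0.02, 0.005)
        tau = kinetics.bell_time_constant(gp, v)
        fit = fit_bell_time_constant(v, tau, fix_tau_offset=True)
        assert fit["alpha"] == pytest.approx(4.0, rel=1e-4)
        assert fit["beta"] == pytest.approx(156.0, rel=1e-4)
        assert fit["tau_slope"] == pytest.approx(43.0, rel=1e-4)
        assert ca.bell_fit_peak_voltage(fit) == pytest.approx(
            kinetics.bell_peak_voltage(gp), rel=1e-3)


class TestTailsAndReversal:
    def test_extrapolated_amplitude_unbiased(self):
        trace = synthetic.make_tail_trace(amplitude=-0.4e-9, tau=8e-3)
        amp = measure_tail_amplitude(trace)
        assert amp == pytest.approx(-0.4e-9, rel=0.01)

    def test_fixed_latency_underestimates(self):
        trace = synthetic.make_tail_trace(amplitude=-0.4e-9, tau=2e-3)
        amp = measure_tail_amplitude(trace, method="fixed_latency",
                                     fixed_latency=1e-3)
        assert abs(amp) < 0.4e-9
        assert amp < 0  # sign preserved

    def test_reversal_from_noiseless_family(self):
        fam = synthetic.make_tail_family([5.0], np.arange(-0.1, -0.02, 0.01),
                                         noise_sd=0.0)
        fit = estimate_reversal_potential(fam[5.0])
        assert fit["e_rev"] == pytest.approx(-68e-3, abs=1e-9)
        assert "extrapolated" not in fit.flags

    def test_extrapolation_flagged(self):
        tails = [TailMeasurement(test_voltage=v, amplitude=10e-9 * (v + 0.068),
                                 k_out=5.0)
                 for v in (-0.05, -0.045, -0.04, -0.035)]
        fit = estimate_reversal_potential(tails)
        assert "extrapolated" in fit.flags
        assert fit["e_rev"] == pytest.approx(-68e-3, abs=1e-9)

    def test_nernst_relation_on_ideal_points(self):
        concs = [0.5, 5.0, 50.0]
        pts = [(c, kinetics.nernst_potential(140e-3, c * 1e-3)) for c in concs]
        fit = fit_nernst_relation(pts)
        assert fit["slope_per_decade"] * 1e3 == pytest.approx(58.17, abs=0.01)


class TestDoseResponse:
    def test_exact_recovery(self):
        model = DoseResponseModel(ic50=32e-6, hill=0.97)
        doses = np.array([1, 3, 10, 30, 100, 300, 1000]) * 1e-6
        conc, resp = synthetic.make_dose_response_dataset(
            model, doses, noise_sd=0.0)
        fit = fit_dose_response(conc, resp)
        assert fit["ic50"] == pytest.approx(32e-6, rel=1e-6)
        assert fit["hill"] == pytest.approx(0.97, rel=1e-6)

    def test_saturated_data_flagged(self):
        conc = np.array([1e-4, 3e-4, 1e-3, 3e-3])
        resp = np.full(4, 0.01)
        fit = fit_dose_response(conc, resp)
        assert "all_saturated" in fit.flags


class TestPassiveProperties:
    def test_round_trip_from_forward_model(self):
        # forward RC response: I(t) = dV/Ra at onset decaying to dV/(Ra+Rin)
        r_a, r_in, c, dv = 5e6, 150e6, 380e-12, -5e-3
        tau = c * r_a * r_in / (r_a + r_in)
        t = np.arange(0, 0.05, 2e-5)
        i_ss = dv / (r_a + r_in)
        i = i_ss + (dv / r_a - i_ss) * np.exp(-t / tau)
        props = passive_properties_from_test_pulse(
            Trace(time=t, values=i, kind="current"), step=dv)
        assert props.r_access == pytest.approx(r_a, rel=0.02)
        assert props.r_in == pytest.approx(r_in, rel=0.02)
        assert props.capacitance == pytest.approx(c, rel=0.02)

    def test_no_transient_reports_rin_only(self):
        t = np.arange(0, 0.05, 2e-5)
        i = np.full(t.size, -5e-3 / 155e6)
        props = passive_properties_from_test_pulse(
            Trace(time=t, values=i, kind="current"), step=-5e-3)
        assert "no_transient" in props.flags
        assert props.capacitance is None
        assert props.r_in == pytest.approx(155e6, rel=0.01)


class TestTraceValidation:
    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            Trace(time=np.array([0.0, 1e-4, 5e-4]), values=np.zeros(3),
                  kind="current")

    def test_unknown_kind_rejected(self):
        t = np.arange(3) * 1e-4
        with pytest.raises(ValueError):
            Trace(time=t, values=np.zeros(3), kind="charge")

    def test_segment_bounds(self):
        t = np.arange(100) * 1e-4
        tr = Trace(time=t, values=np.sin(t), kind="current")
        seg = tr.segment(2e-3, 5e-3)
        assert seg.time[0] >= 2e-3 - 1e-12
        assert seg.time[-1] <= 5e-3 + 1e-12
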