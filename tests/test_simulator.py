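"""Whole-cell model: clamp simulations against independent closed-form oracles."""

import numpy as np
import pytest

from photokv import kinetics, simulator
from photokv.kinetics import gate_steady_state
from photokv.simulator import (
    StimulusWaveform,
    VoltageProtocol,
    closed_form_gating_relaxation,
    instantaneous_input_resistance,
    ka_sensitivity_experiment,
    membrane_time_constant,
    simulate_current_clamp,
    simulate_subtraction_protocol,
    simulate_voltage_clamp,
    steady_state_voltage,
)


class TestPassiveCalibration:
    def test_input_resistance_at_rest(self, canonical_cell):
        r = instantaneous_input_resistance(canonical_cell, -60e-3)
        assert r / 1e6 == pytest.approx(136.4, abs=0.1)

    def test_kdr_dominates_resting_conductance(self, canonical_cell):
        g_total = 1.0 / instantaneous_input_resistance(canonical_cell, -60e-3)
        kdr = canonical_cell.conductance("KDR")
        g_kdr = kinetics.conductance_value(
            kdr, kinetics.equilibrium_gating(kdr, -60e-3))
        assert 0.85 <= g_kdr / g_total <= 0.90

    def test_membrane_time_constant_and_cutoff(self):
        tau, f_c = membrane_time_constant(400e-12, 150e6)
        assert tau * 1e3 == pytest.approx(60.0, rel=1e-12)
        assert f_c == pytest.approx(2.65, abs=0.05)

    def test_calibration_idempotent(self, canonical_cell):
        again = simulator.calibrated_cell(canonical_cell)
        assert again.g_leak == pytest.approx(canonical_cell.g_leak, rel=1e-12)


class TestVoltageClampGating:
    def test_gating_matches_closed_form_oracle(self, canonical_cell):
        protocol = VoltageProtocol(epochs=((-57e-3, 0.1), (3e-3, 0.05)),
                                   holding=-74e-3, sample_interval=1e-4)
        result = simulate_voltage_clamp(canonical_cell, protocol)
        t = result.time
        for name, which, gp in simulator._gates(canonical_cell):
            sim = result.gating[name][which]
            a0 = gate_steady_state(gp, -74e-3)
            oracle = np.empty_like(t)
            t0 = 0.0
            for v, dur in protocol.epochs:
                mask = (t >= t0 - 1e-12) & (t <= t0 + dur + 1e-12)
                oracle[mask] = closed_form_gating_relaxation(
                    gp, v, a0, t[mask] - t0)
                a0 = closed_form_gating_relaxation(gp, v, a0, dur)
                t0 += dur
            assert np.max(np.abs(sim - oracle)) < 1e-6

    def test_validation_cell_steady_current(self, validation_cell_calibrated):
        # prepulse to -117 mV then step to +3 mV: the sustained current is
        # dominated by KDR at its +3 mV equilibrium; closed-form cross-check
        protocol = VoltageProtocol(epochs=((-117e-3, 0.2), (3e-3, 0.1)),
                                   holding=-74e-3, sample_interval=5e-5)
        result = simulate_voltage_clamp(validation_cell_calibrated, protocol)
        i_ss = result.total_membrane_current()[-1]
        assert i_ss * 1e9 == pytest.approx(3.49, abs=0.02)
        cell = validation_cell_calibrated
        kdr = cell.conductance("KDR")
        expect = (kdr.g_max * gate_steady_state(kdr.activation, 3e-3)
                  * (3e-3 - kdr.e_rev)) + cell.g_leak * (3e-3 - cell.e_leak)
        assert i_ss == pytest.approx(expect, rel=0.01)

    def test_holding_equilibrium_is_stationary(self, canonical_cell):
        protocol = VoltageProtocol(epochs=((-74e-3, 0.05),),
                                   holding=-74e-3, sample_interval=1e-4)
        result = simulate_voltage_clamp(canonical_cell, protocol)
        for name, which, gp in simulator._gates(canonical_cell):
            g = result.gating[name][which]
            assert np.max(np.abs(g - g[0])) < 1e-9


class TestCurrentClamp:
    def test_dark_resting_potential_is_fixed_point(self, canonical_cell):
        t = np.arange(0, 0.5, 1e-3)
        stim = StimulusWaveform(time=t, g_light=np.zeros(t.size))
        result = simulate_current_clamp(canonical_cell, stim)
        assert np.max(np.abs(result.v - canonical_cell.v_rest)) < 1e-6

    def test_constant_light_converges_to_algebraic_root(self, canonical_cell,
                                                        smooth_light_run):
        _, result = smooth_light_run
        v_root = steady_state_voltage(canonical_cell, 5e-9)
        assert abs(result.v[-1] - v_root) < 1e-4  # within 0.1 mV

    def test_charge_conservation_residual(self, canonical_cell,
                                          smooth_light_run):
        # C dV/dt + sum(I) must vanish; dV/dt from central differences
        _, result = smooth_light_run
        dvdt = np.gradient(result.v, result.time)
        resid = canonical_cell.capacitance * dvdt \
            + result.total_membrane_current()
        assert np.max(np.abs(resid)) < 1e-12  # < 1 pA at every sample

    def test_voltage_bounded_by_reversal_potentials(self, canonical_cell):
        from photokv import synthetic
        stim = synthetic.make_naturalistic_conductance(duration=1.0, seed=6)
        result = simulate_current_clamp(canonical_cell, stim)
        e_k = canonical_cell.conductance("KDR").e_rev
        lo = min(e_k, canonical_cell.e_leak, canonical_cell.e_light,
                 canonical_cell.v_rest)
        hi = max(e_k, canonical_cell.e_leak, canonical_cell.e_light,
                 canonical_cell.v_rest)
        assert np.all(result.v >= lo - 1e-9)
        assert np.all(result.v <= hi + 1e-9)

    def test_current_injection_depolarizes(self, canonical_cell):
        t = np.arange(0, 0.5, 1e-3)
        stim = StimulusWaveform(time=t, g_light=np.zeros(t.size),
                                i_inj=np.full(t.size, 50e-12))
        result = simulate_current_clamp(canonical_cell, stim)
        assert result.v[-1] > canonical_cell.v_rest + 1e-3

    def test_dark_steady_state_voltage_is_rest(self, canonical_cell):
        assert steady_state_voltage(canonical_cell, 0.0) == pytest.approx(
            canonical_cell.v_rest, abs=1e-9)


@pytest.fixture(scope="module")
def run(canonical_cell):
    return simulate_subtraction_protocol(canonical_cell, [3e-3])


class TestSubtractionProtocol:
    def test_true_transient_peak(self, run):
        mask = run.time >= run.step_onset
        true_ka = run.true_transient_current(0)[mask]
        t_rel = run.time[mask] - run.step_onset
        k = np.argmax(true_ka)
        assert true_ka[k] * 1e9 == pytest.approx(1.00, abs=0.01)
        assert t_rel[k] * 1e3 == pytest.approx(2.25, abs=0.3)

    def test_subtraction_contains_kdr_artifact(self, run):
        # the conventional estimate differs from the model's true KA current
        # early in the step because the prepulses leave KDR at different
        # activation levels (documented systematic error)
        mask = run.time >= run.step_onset
        err = np.abs(run.transient[0][mask]
                     - run.true_transient_current(0)[mask])
        peak = np.max(run.true_transient_current(0)[mask])
        assert np.max(err) / peak > 0.1

    def test_artifact_decays_with_kdr_kinetics(self, run):
        # late in the step (>6 tau_KDR) the difference shrinks to the
        # residual-KA term only
        late = run.time >= run.step_onset + 0.04
        err = np.abs(run.transient[0][late]
                     - run.true_transient_current(0)[late])
        peak = np.max(run.true_transient_current(0))
        assert np.max(err) / peak < 0.02

    def test_no_ka_means_transient_only_artifact(self, canonical_cell):
        # with KA removed the subtraction shows the pure KDR-history artifact
        no_ka = simulator.calibrated_cell(
            canonical_cell.with_scaled_conductance("KA", 0.0))
        run = simulate_subtraction_protocol(no_ka, [3e-3])
        assert np.max(np.abs(run.true_transient_current(0))) == 0.0
        mask = run.time >= run.step_onset
        assert np.max(np.abs(run.transient[0][mask])) * 1e9 > 0.1


class TestSensitivityExperiments:
    def test_identical_scales_give_zero_deviation(self, canonical_cell):
        from photokv import synthetic
        stim = synthetic.make_naturalistic_conductance(duration=0.3, seed=2)
        res = ka_sensitivity_experiment(canonical_cell, stim, (1.0, 1.0))
        assert res.max_pairwise_deviation == 0.0

    def test_ka_removal_and_doubling_invisible(self, canonical_cell):
        from photokv import synthetic
        stim = synthetic.make_naturalistic_conductance(duration=2.0, seed=11)
        res = ka_sensitivity_experiment(canonical_cell, stim, (0.0, 1.0, 2.0))
        assert res.max_pairwise_deviation < 1e-3

    def test_kdr_scaling_decreases_depolarization(self, canonical_cell):
        from photokv import synthetic
        stim = synthetic.make_naturalistic_conductance(duration=2.0, seed=11)
        res = ka_sensitivity_experiment(canonical_cell, stim, (0.1, 1.0, 10.0),
                                        conductance="KDR")
        levels = res.depolarization_levels(window=0.1)
        assert levels[0] > levels[1] > levels[2]

    def test_negative_scale_rejected(self, canonical_cell):
        from photokv import synthetic
        stim = synthetic.make_naturalistic_conductance(duration=0.1, seed=2)
        with pytest.raises(ValueError):
            ka_sensitivity_experiment(canonical_cell, stim, (-1.0, 1.0))


class TestProtocolValidation:
    def test_nonuniform_stimulus_rejected(self):
        with pytest.raises(ValueError):
            StimulusWaveform(time=np.array([0.0, 1e-3, 3e-3]),
                             g_light=np.zeros(3))

    def test_negative_light_conductance_rejected(self):
        t = np.arange(0, 0.01, 1e-3)
        with pytest.raises(ValueError):
            StimulusWaveform(time=t, g_light=np.full(t.size, -1e-9))

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            VoltageProtocol(epochs=(), holding=-74e-3, sample_interval=1e-4)
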