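import numpy as np
import pytest

from photokv import kinetics, simulator


@pytest.fixture(scope="session")
def canonical_cell():
    """Canonical model cell with the leak calibrated for a -60 mV rest."""
    return simulator.calibrated_cell(kinetics.default_parameter_registry())


@pytest.fixture(scope="session")
def validation_cell_calibrated():
    """The 52 nS-KDR validation cell, leak calibrated."""
    return simulator.calibrated_cell(kinetics.validation_cell())


@pytest.fixture(scope="session")
def smooth_light_run(canonical_cell):
    """Current-clamp response to a constant 5 nS light conductance."""
    t = np.arange(0, 0.5 + 1e-12, 1e-4)
    stim = simulator.StimulusWaveform(time=t, g_light=np.full(t.size, 5e-9))
    return stim, simulator.simulate_current_clamp(canonical_cell, stim)
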