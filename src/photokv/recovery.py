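"""Closed-loop parameter-recovery experiments.

Each experiment generates many seeded synthetic data sets at study-like
noise from a known ground truth, runs the corresponding fit from
:mod:`photokv.clamp_analysis`, and summarizes the recovered parameter
distribution.  These are the experiments behind the reproducibility
script and the ``photokv recover`` subcommand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import clamp_analysis as ca
from . import synthetic
from .kinetics import GatingParameters

__all__ = [
    "RecoverySummary",
    "child_seeds",
    "recover_boltzmann_v50",
    "recover_kdr_v50",
    "recover_ka_activation_v50",
    "recover_ka_inactivation_v50",
    "recover_ic50",
    "EXPERIMENTS",
]

#: Per-cell maximal-conductance spread used when emulating multi-cell
#: activation data sets (coefficient of variation; the measured cell-to-cell
#: spread of g_max is of this order).
GMAX_JITTER_FRAC = 0.25


@dataclass
class RecoverySummary:
    """Distribution of a recovered parameter across seeded replicates."""

    name: str
    truth: float
    estimates: np.ndarray
    n_per_experiment: int

    @property
    def median(self) -> float:
        return float(np.median(self.estimates))

    @property
    def bias(self) -> float:
        return self.median - self.truth

    @property
    def sd(self) -> float:
        return float(np.std(self.estimates, ddof=1))

    @property
    def se(self) -> float:
        """Standard error of one experiment's mean (sd / sqrt(cells per experiment))."""
        return self.sd / np.sqrt(self.n_per_experiment)


def child_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic independent child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


# ---------------------------------------------------------------------------
# Boltzmann half-activation / half-inactivation recovery
# ---------------------------------------------------------------------------

def recover_boltzmann_v50(gating: GatingParameters, voltages, *,
                          g_max: float = 1.0, noise_sd_frac: float,
                          n_cells: int, n_seeds: int = 100,
                          g_max_jitter_frac: float = 0.0,
                          base_seed: int = 0,
                          name: str = "v50") -> RecoverySummary:
    """Fit order-P Boltzmanns to seeded synthetic steady-state data sets.

    Every synthetic cell is fit independently; the summary pools the
    per-cell V50 estimates over all seeds.
    """
    estimates = []
    for seed in child_seeds(base_seed, n_seeds):
        ds = synthetic.make_activation_dataset(
            gating, voltages, g_max=g_max, noise_sd_frac=noise_sd_frac,
            n_cells=n_cells, g_max_jitter_frac=g_max_jitter_frac, seed=int(seed),
        )
        for points in ds.cells:
            fit = ca.fit_boltzmann(ds.voltages, points, order=gating.order)
            if fit.converged:
                estimates.append(fit["v_half"])
    return RecoverySummary(name=name, truth=gating.v_half,
                           estimates=np.asarray(estimates),
                           n_per_experiment=n_cells)


def recover_kdr_v50(n_seeds: int = 100, base_seed: int = 0) -> RecoverySummary:
    """KDR half-activation: order-1 Boltzmann, -47..+23 mV, 6 cells, 5% noise."""
    gating = GatingParameters(v_half=-31e-3, slope=12e-3, order=1)
    voltages = np.arange(-47e-3, 23e-3 + 1e-6, 10e-3)
    return recover_boltzmann_v50(
        gating, voltages, g_max=78e-9, noise_sd_frac=0.05, n_cells=6,
        n_seeds=n_seeds, g_max_jitter_frac=GMAX_JITTER_FRAC,
        base_seed=base_seed, name="kdr_v50",
    )


def recover_ka_activation_v50(n_seeds: int = 100, base_seed: int = 0) -> RecoverySummary:
    """KA half-activation: order-2 Boltzmann, -57..+3 mV, 5 cells, 5% noise."""
    gating = GatingParameters(v_half=-43e-3, slope=8.4e-3, order=2)
    voltages = np.arange(-57e-3, 3e-3 + 1e-6, 10e-3)
    return recover_boltzmann_v50(
        gating, voltages, g_max=60e-9, noise_sd_frac=0.05, n_cells=5,
        n_seeds=n_seeds, g_max_jitter_frac=GMAX_JITTER_FRAC,
        base_seed=base_seed, name="ka_act_v50",
    )


def recover_ka_inactivation_v50(n_seeds: int = 100, base_seed: int = 0) -> RecoverySummary:
    """KA half-inactivation: order-1 negative-slope Boltzmann on normalized
    peak currents after prepulses -130..-40 mV, 4 cells, 3% noise."""
    gating = GatingParameters(v_half=-85e-3, slope=-11.3e-3, order=1)
    voltages = np.arange(-130e-3, -40e-3 + 1e-6, 10e-3)
    return recover_boltzmann_v50(
        gating, voltages, g_max=1.0, noise_sd_frac=0.03, n_cells=4,
        n_seeds=n_seeds, base_seed=base_seed, name="ka_inact_v50",
    )


# ---------------------------------------------------------------------------
# dose-response recovery
# ---------------------------------------------------------------------------

def recover_ic50(n_seeds: int = 100, base_seed: int = 0,
                 ic50: float = 32e-6, hill: float = 0.97) -> RecoverySummary:
    """Quinidine-block IC50: logistic fits to 7 doses x 4 replicates, 5% noise."""
    model = ca.DoseResponseModel(ic50=ic50, hill=hill)
    doses = np.array([1, 3, 10, 30, 100, 300, 1000]) * 1e-6
    estimates = []
    for seed in child_seeds(base_seed, n_seeds):
        conc, resp = synthetic.make_dose_response_dataset(
            model, doses, n_reps=4, noise_sd=0.05, seed=int(seed))
        fit = ca.fit_dose_response(conc, resp)
        if fit.converged:
            estimates.append(fit["ic50"])
    return RecoverySummary(name="ic50", truth=ic50,
                           estimates=np.asarray(estimates), n_per_experiment=1)


#: Name -> experiment registry used by the CLI.
EXPERIMENTS = {
    "kdr-v50": recover_kdr_v50,
    "ka-act-v50": recover_ka_activation_v50,
    "ka-inact-v50": recover_ka_inactivation_v50,
    "ic50": recover_ic50,
}
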