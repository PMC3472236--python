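# photokv

A conductance-based model and analysis toolkit for the voltage-dependent
K⁺ conductances of a dark-adapted insect photoreceptor.

Nocturnal insect photoreceptors encode light with graded (non-spiking)
membrane potentials. Two voltage-gated K⁺ (Kv) conductances shape those
signals: a sustained delayed rectifier (**KDR**, ~78 nS, half-activation
−31 mV) that dominates the membrane conductance once the cell depolarizes,
and a transient A-type conductance (**KA**, ~60 nS maximal) that activates
fast but inactivates almost completely at physiological voltages
(half-inactivation −85 mV), leaving only ~0.08 nS available at the −60 mV
dark resting potential. `photokv` packages:

- **`photokv.kinetics`** — Boltzmann steady-state curves, bell-shaped
  voltage-dependent time constants, Nernst electrochemistry, conductance
  evaluation, and a canonical whole-cell parameter registry;
- **`photokv.simulator`** — a Hodgkin–Huxley-type whole-cell model
  (`C dV/dt = −(I_light + I_KDR + I_KA + I_leak) + I_inj`) with ideal
  voltage clamp, current-clamp light responses, leak calibration, the
  paired-prepulse subtraction protocol, and conductance-scaling
  experiments;
- **`photokv.clamp_analysis`** — the fitting pipeline: series-resistance
  correction, conductance extraction `g = I/(V − E_rev)`, Boltzmann /
  exponential / pulse-function / bell / Nernst / dose–response fits,
  tail-current amplitudes and reversal potentials, test-pulse passive
  properties;
- **`photokv.synthetic`** — seeded generators for noisy voltage-clamp
  families (with capacitive transients), steady-state point sets,
  tail-current families, dose–response points, naturalistic-like light
  conductances and quantum-bump trains;
- **`photokv.recovery`** — closed-loop generate-and-refit parameter
  recovery experiments;
- **`photokv.cli`** — the `photokv` command-line workbench.

See [docs/methods.md](docs/methods.md) for model equations, parameter
provenance inside the package, numerical choices, and known limitations.

## Worked example

```python
import numpy as np
from photokv import (
    default_parameter_registry, calibrated_cell, instantaneous_input_resistance,
    ka_conductance, equilibrium_gating, conductance_value,
    nernst_potential, nernst_slope_per_decade, bell_time_constant,
    simulate_current_clamp, make_naturalistic_conductance,
)

cell = calibrated_cell(default_parameter_registry())

# Passive calibration: leak that balances the gated currents at rest
print(f"g_leak = {cell.g_leak * 1e9:.1f} nS")               # g_leak = 0.9 nS
r_in = instantaneous_input_resistance(cell, -60e-3)
print(f"R_in   = {r_in / 1e6:.1f} MOhm")                    # R_in   = 136.4 MOhm

# KA is almost fully inactivated at the dark resting potential
ka = ka_conductance()
g_ka = conductance_value(ka, equilibrium_gating(ka, -60e-3))
print(f"g_KA(-60 mV) = {g_ka * 1e9:.2f} nS")                # 0.08 nS

# K+ electrochemistry (140 mM in / 5 mM out, 293.15 K)
print(f"E_K = {nernst_potential(140e-3, 5e-3) * 1e3:.1f} mV")   # -84.2 mV
print(f"slope = {nernst_slope_per_decade() * 1e3:.1f} mV/decade")  # 58.2

# Gating kinetics: KDR activation tau peaks near -43 mV at ~20 ms
kdr_act = cell.conductance("KDR").activation
v = np.linspace(-70e-3, -10e-3, 6001)
print(f"max tau_KDR = {np.max(bell_time_constant(kdr_act, v)) * 1e3:.1f} ms")  # 20.0

# Light response to a fluctuating conductance input
stim = make_naturalistic_conductance(duration=2.0, seed=11)
resp = simulate_current_clamp(cell, stim)
print(f"V range: {resp.v.min() * 1e3:.1f} to {resp.v.max() * 1e3:.1f} mV")
# V range: -60.0 to -38.4 mV
```

## Command line

```sh
photokv simulate --duration 2.0 --seed 7 --out runs/sim
#   summary: g_leak 0.9 nS, R_in 136.4 MOhm
photokv synth --what vc-family --seed 5 --out runs/family
photokv characterize --traces runs/family --out runs/report
#   fit: V50 -30.4 mV, slope 11.5 mV, g_max 77.9 nS
photokv recover --experiment kdr-v50 --n-seeds 100 --seed 1 --out runs/recovery
```

Every run writes a provenance block (config hash, seed, package version);
identical configurations reproduce identical outputs.

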