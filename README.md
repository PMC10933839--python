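# actonem

Multiscale modelling and flow analysis for motor-driven active nematics.

Active nematics built from cytoskeletal filaments (e.g. short actin
filaments crowded to an oil–water interface) and synthetic molecular-motor
clusters flow spontaneously: motors hydrolyse ATP, slide filament pairs,
and inject extensile stress.  Their steady state is governed by two
hydrodynamic parameters — the active stress scale α and the nematic elastic
constant K — through a single length ℓ = √(K/α) and a flow speed
v = ℓα/η = √(Kα)/η.  The scientific question this package addresses is how
α and K descend from *microscopic* motor properties: catalytic rates,
processivity, cluster valency, and filament crosslinking.

The core model chain, for researchers in cytoskeletal active matter:

1. **Motor kinetics** (`actonem.motor_kinetics`) — each head of an n-valent
   cluster cycles irreversibly through three states (unbound/ATP →
   bound/ADP → bound/apo → unbound) with k31 ∝ [ATP]; exact Gillespie
   simulation on one or two filaments yields single-filament velocity and
   run length, the pair strain rate ε([ATP]), and the crosslink probability
   P_cl([ATP]), with closed-form renewal and inclusion–exclusion oracles
   (P_cl = 1 − 2(1 − p/2)ⁿ + (1 − p)ⁿ for independent heads).
2. **Scaling model** (`actonem.scaling`) — α = α₀ε^β and the
   crosslink-augmented elasticity K = K₀ + κ(c_m·P_cl + c_p).  Because
   P_cl falls while ε rises with [ATP], v = √(Kα)/η can peak at
   intermediate [ATP]; at the peak K′α + Kα′ = 0.  Motors therefore set
   both the activity *and* the elasticity.
3. **Flow statistics** (`actonem.flow`) — mean/RMS speed, 1/e velocity
   direction-correlation length, vorticity, and the vortex radius ℓ_vort by
   correlated displacement velocimetry (azimuthally averaged, spectrally
   whitened vorticity–velocity cross-correlation).
4. **Continuum simulator** (`actonem.lattice_boltzmann`) — hybrid D2Q9
   lattice-Boltzmann / Beris–Edwards Q-tensor solver for 2-D active nematic
   hydrodynamics (Landau–de Gennes bulk free energy, flow alignment, Guo
   forcing by elastic + active stress −αQ).
5. **Synthetic data** (`actonem.synthetic`) — vortex-field series with
   known core radius and Michaelis–Menten-structured ε/P_cl curves, so
   every estimator is validated against known ground truth without any
   microscopy data.

See `docs/methods.md` for model details, parameter defaults and
limitations.

## Worked example

Calibrated tetramer rate constants (from `calibrate_rates` against
single-filament measurements: 0.5 µm/s with 4 µm runs at 10 µM ATP,
10 µm/s with 0.5 µm runs at 500 µM) are k12 ≈ 1000 s⁻¹, k23 ≈ 433 s⁻¹,
k31_per_atp ≈ 2.85 µM⁻¹s⁻¹:

```python
import numpy as np
from actonem.motor_kinetics import ClusterConfig, RateConstants, sweep_atp
from actonem.scaling import ScalingParams, predict_curves, find_speed_peak

rates = RateConstants(k12=1000.0, k23=433.0, k31_per_atp=2.85)
cluster = ClusterConfig(n_heads=4, n_filaments=2)
curves = sweep_atp(cluster, rates, np.logspace(0, 3, 16),
                   reps=24, seed=23, t_max=20.0)
print(curves.p_cl[0], curves.p_cl[-1])      # 0.865 -> 0.679
print(curves.epsilon[0], curves.epsilon[-1])  # 0.098 -> 8.87 um/s

hydro = predict_curves(curves, ScalingParams())   # K0=0.001, kappa=10*K0, beta=0.1
peak = find_speed_peak(hydro)
print(peak.atp_peak, peak.boundary_flag)     # 63.1 uM, False
```

Over 1–1000 µM ATP the crosslink probability falls from 0.865 to 0.679
while the strain rate rises from 0.098 to 8.87 µm/s; composed through the
scaling model this yields an interior nematic-speed maximum at ≈ 63 µM ATP
— speed is non-monotonic in fuel concentration because faster motors
crosslink less.

Flow statistics on a synthetic vortex lattice (9 vortices of radius 10 px,
5% noise, 25 frames):

```python
from actonem.synthetic import VortexFieldParams, synth_vortex_field
from actonem.flow import compute_flow_stats

series = synth_vortex_field(VortexFieldParams(
    shape=(128, 128), core_radius=10, n_vortices=9,
    noise_sigma=0.05, n_frames=25, seed=7))
print(compute_flow_stats(series))
# v_mean=0.720, v_rms=0.789, ell_corr=19.4, ell_vort=9.82 (true radius 10)
```

And the continuum solver's statics/transport checks:

```python
from actonem.lattice_boltzmann import equilibrium_order, measure_viscosity
equilibrium_order(3.5)   # 0.61596  (ordered nematic minimum, ~0.62)
measure_viscosity()      # (0.33252 measured, 1/3 analytic)
```

A CLI wraps the same functions: `actonem motor`, `actonem scaling`,
`actonem flow`, `actonem lb`, `actonem synth vortex|curves` (see
`actonem --help`).

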