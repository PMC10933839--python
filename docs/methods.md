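# Methods

`actonem` models how the microscopic properties of molecular-motor clusters
set the hydrodynamic behaviour of a cytoskeletal active nematic, and provides
the flow-field statistics and the continuum simulator needed to close the
loop between the two scales.  This note records the models, the parameter
choices, the numerical conventions, and the known limitations.

## Motor-cluster stepping model

Each cluster carries `n` enzymatic heads (valency 3, 4 or 8 in practice)
that cycle independently and irreversibly through three chemical states:

1. unbound, ATP in the pocket;
2. bound to the filament, post-powerstroke, with ADP (entered at rate
   `k12`, which lumps hydrolysis and binding);
3. bound, nucleotide-free (entered at rate `k23`, ADP release).

The return 3 → 1 is ATP exchange and detachment, at rate
`k31 = k31_per_atp · [ATP]`.  At `[ATP] = 0` state 3 is absorbing: the
cluster enters rigor, as in experiments.  Because heads are independent and
transitions irreversible, exactly `n` transitions are possible at any
instant and the Gillespie algorithm reduces to one exponential waiting time
at the summed rate plus a proportional choice of head.  The simulation is
exact; per-state sojourn times are exponential with the configured rates
(tested by Kolmogorov–Smirnov at 10⁴ samples).

Mechanics enter through the anchor `x(t)` of the multimerisation domain.
On each filament with at least one bound head, `x` sits a distance `s/2`
ahead of the rearmost bound head, where `s = 0.036 µm` by default (the
actin pseudo-helical repeat; `s` is the model's only length scale, so the
rate calibration absorbs the choice).  A binding head draws its position
from `N(x + s/2, sd = s/2)` — we read the distribution's second parameter
as a standard deviation; the variance reading produces sub-step run lengths
incompatible with the published single-filament values.  After every
transition `x` is re-evaluated, so motion is generated by bindings ahead of
the rear and by rear-head release; displacements are signed and backward
excursions are allowed.  When both filaments of a pair are available, the
binding target is chosen uniformly at random.  When a filament empties its
anchor retains its last value.

**Observables.**  Velocity is total anchor displacement divided by total
simulated time.  A run is a maximal interval with at least one bound head;
its length is the anchor displacement between its first and last bound
instants, and runs truncated by the end of the simulation are counted.  For
filament pairs, treated as antiparallel and unbounded, the strain rate
`ε` is the summed anchor motion of both filaments accrued only while the
cluster bridges them, divided by total time; the crosslink probability
`P_cl` is the time fraction with both filaments bound.  Two analytic
oracles validate the machinery: the stationary bound fraction
`p = (1/k23 + 1/k31) / (1/k12 + 1/k23 + 1/k31)` and the independent-head
closed form `P_cl = 1 − 2(1 − p/2)ⁿ + (1 − p)ⁿ`, which long simulations
must reproduce within Monte-Carlo error.

**Calibration and the observation window.**  The three rates are scanned
(12-point logarithmic grids, `k12`, `k23` over 0.1–10³ s⁻¹ and
`k31_per_atp` over 10⁻³–10 µM⁻¹s⁻¹, then two local log-grid refinements
around the running best) to minimise the summed squared log-error against
tetramer single-filament measurements: 0.5 µm/s and 4 µm at 10 µM ATP,
10 µm/s and 0.5 µm at 500 µM.  Calibration simulations use a finite
observation window of 8 s per engagement, and this choice matters: at
10 µM the tetramer's duty ratio approaches 0.97, engagements essentially
never terminate, and — as in any finite-duration motility measurement —
the reported run length is bounded by speed × window.  With the 8 s window
the scan reproduces all four endpoint values to within ~12%; with windows
of 50–100 s the low-[ATP] run length is instead set by the window itself
(tens of µm) and no rate constants can match all four numbers at once.
The window is an explicit parameter of `calibrate_rates`.

The calibrated tetramer (`k12 ≈ 10³ s⁻¹`, `k23 ≈ 4·10² s⁻¹`,
`k31_per_atp ≈ 3 µM⁻¹s⁻¹`) yields `ε` rising and `P_cl` falling with
[ATP] (rank correlation beyond ±0.97 on ensemble means), higher `P_cl` at
every [ATP] for higher valency, and slower but more processive clusters as
valency grows — provided the run-length comparison is made where runs
actually terminate inside the window.

## Scaling model

The hydrodynamic map uses the standard active-nematic balance: elastic
stress `K/ℓ²` against active stress `α` selects `ℓ = √(K/α)`, and force
balance gives the flow speed `v = ℓα/η = √(Kα)/η`.  Activity follows the
strain rate through `α = α₀ ε^β` with `β = 0.1` by default (`ε` is first
normalised to its grid maximum; the scale is absorbed by `α₀ = 1`).
Crosslinking feeds the elasticity:

    K = K₀ + κ c_e,   c_e = c_m P_cl + c_p,

with `K₀ = 0.001`, `κ = 10 K₀`, motor concentration `c_m = 1` and an
optional passive-crosslinker concentration `c_p`.  `P_cl` enters as a
physical concentration and is not rescaled.  All outputs are reported
normalised to maximum 1; `η = 1` unless configured.

Because `P_cl` falls while `ε` rises with [ATP], `v` can peak at
intermediate [ATP]; at an interior peak `K′α + Kα′ = 0` (primes are [ATP]
derivatives).  `find_speed_peak` reports the grid argmax, this stationarity
residual (central differences, normalised by the largest competing term;
≤ 10⁻³ on refined closed-form grids), a boundary flag, and optionally a
refined peak from a quadratic vertex fit in log[ATP] over ±`refine` grid
points.  The broad vertex fit exists because for small `β` the speed curve
is extremely flat near its maximum (variations under 1% across two grid
steps), so a raw argmax on noisy curves jitters by several grid points.
Measured sensitivity on synthetic Michaelis–Menten curves with 5%
multiplicative noise: the refined peak lands within two grid steps of the
noiseless peak in ≥ 95% of replicates, but within one grid step only
~70–90% of the time; one-step localisation would require noise below ~2%.

A Michaelis–Menten alternative parameterisation is included for robustness
checks: `v_m(A) = v_max·A/(km_v + A)` rising, `P_cl(A)` falling from
`p_max` to `p_floor` with scale `km_p`, and `ε = v_m·P_cl`.  Defaults
(`v_max = 1`, `km_v = km_p = 50 µM`, `p_max = 1`, `p_floor = 0.05`) place
the speed peak inside the 1–1000 µM window.  Note that this `ε` has an
interior maximum by construction, so behaviours that rely on a monotone
strain rate (monotone `v` at `κ = 0` or at `β = 1`) apply to the simulated
motor curves, not to the Michaelis–Menten form.

## Flow-field statistics

Inputs are time series of 2-D velocity fields with pixel size and frame
interval; frames are treated as independent samples.  The mean speed is
`Σ|uᵢ|/N` (the root-mean-square speed is also reported; RMS ≥ mean with
equality only for uniform magnitude).  The direction autocorrelation
`C_uu(r) = ⟨ûᵢ·ûⱼ(r)⟩` is accumulated spectrally with periodic wrap,
radially binned at 1 px, and the correlation length is the linear
interpolation of the first crossing below `1/e` (flagged if no crossing
occurs).  Vorticity is `∂u_y/∂x − ∂u_x/∂y` by central differences
(one-sided at non-periodic boundaries).

The vortex radius `ℓ_vort` comes from correlated displacement velocimetry:
the response of the flow to a vortical perturbation at the origin,
estimated as the cross-spectrum of mean-subtracted vorticity with velocity,
whitened by the amplitude of the vorticity spectrum with a Tikhonov floor
(3% of its maximum), transformed to real space, projected on the azimuthal
direction `ẑ × r̂`, and azimuthally averaged in 1-px bins; the radius of
the single maximum (parabolic sub-bin refinement) is `ℓ_vort`.  The
whitening matters: the raw cross-correlation is the vortex velocity
pattern smeared by the vorticity core and peaks ~30% outside a solid-body
core, while full power-spectrum deconvolution returns the point-vortex
response peaked at the origin.  The amplitude normalisation, the 3% floor
and a 1-px Gaussian pre-filter (standard velocimetry denoising) were fixed
by the radius-recovery oracle on synthetic fields: worst-case error 5.6%
over core radii 5–20 px and additive noise up to 10% of peak speed.
Frame-set variability reproduces the experimental error convention: the
standard deviation of an estimator over five consecutive non-overlapping
sets of five frames.

## Synthetic data

The vortex generator superposes azimuthal profiles on a periodic grid:
Rankine (solid-body core, `1/r` tail; maximum speed exactly at the core
radius, which makes it a sharp oracle) or Lamb–Oseen (maximum-speed radius
computed numerically, never assumed), placed on an alternating-sign lattice
or at random with ≥ 3R separation, with i.i.d. Gaussian noise per component
and frame.  It writes the same TIFF + JSON-sidecar format the flow module
reads.  The curve generator evaluates the Michaelis–Menten forms with
optional multiplicative noise.  What these fixtures do not emulate: spatial
noise correlations, optical-flow artefacts, finite filament texture, or
defect cores — so passing the recovery suites validates the estimators'
statistical contracts, not their behaviour on raw microscopy.

## Lattice-Boltzmann simulator

The hybrid scheme couples a D2Q9 BGK momentum solver (collision time
`τ = 1.5`, hence lattice viscosity `η = (τ − ½)/3 = 1/3`, verified by
shear-wave decay within 5%) to finite-difference Beris–Edwards dynamics
for the nematic tensor, on a periodic lattice.  The tensor convention is
three-dimensionally embedded with the director confined to the plane: the
evolved fields are `Qxx`, `Qyy`, `Qxy` with `Qzz = −(Qxx + Qyy)`, which the
2-D flow preserves; `Q` is traceless by construction.  The bulk free energy
is `f = (A₀/2)(1 − U/3)Tr Q² − (A₀U/3)Tr Q³ + (A₀U/4)(Tr Q²)²` with
`A₀ = 0.1`, `U = 3.5`, plus one-constant elasticity `(K/2)|∇Q|²`.  In this
convention the ordered uniaxial minimum is
`q = ¼ + ¾√(1 − 8/(3U)) = 0.616` at `U = 3.5` (the strictly 2-D traceless
convention was rejected: its cubic invariant vanishes identically and the
same coefficients would give `q ≈ 0.154`).  Flow alignment uses `ξ = 0.7`,
rotational mobility `Γ = 0.13`; advection and all gradients are central
differences, the Q update is forward Euler at unit time step.

The momentum equation is forced through Guo forcing by the divergence of
the elastic stress (flow-alignment, antisymmetric and Ericksen distortion
terms) and the active stress `−αQ`, `α > 0` extensile.  Because the force
is a discrete divergence on a periodic lattice, total momentum is conserved
to round-off and mass is conserved to relative 10⁻¹³ per thousand steps.
A uniform ordered passive state is an exact fixed point; a perturbed
passive state relaxes back to `q = 0.616` with monotonically decaying
kinetic energy.

Production conditions are reduced for desk-scale validation: 64×64 lattice
(director-angle perturbation 0.1 rad), 2500–5000-step burn-in and
2000–5000 sampled steps at one sample per 50 steps, 3 seeds per condition;
full-size runs are a configuration choice away (`LBConfig`).  At
`α = 0.01` the time-averaged kinetic energy increases with `K` across
`K ∈ {0.002, …, 0.05}` (one-sided Spearman test on the pooled K–energy
pairs), and the vortex scale measured by the flow module on simulated
fields decreases with `α` at fixed `K`, consistent with `ℓ ~ √(K/α)`.

## Known limitations

- Head independence: no inter-head mechanochemical coupling, correlated
  binding, or load-dependent rates; both would lower `P_cl` at high [ATP].
- Filaments are rigid, unbounded and antiparallel; ends, bending and
  explicit forces are not modelled.
- The scaling map is a proportionality chain: `α₀`, `η` and the units of
  `K` and `α` are not calibrated to physical stresses; outputs are
  normalised curves.
- The turbulent scaling relations are assumed to hold across the whole
  [ATP] range, including below the onset of developed active turbulence.
- At the smallest elastic constants the active length `√(K/α)` approaches
  one lattice unit, so those simulations are grid-limited; the reported
  trend is robust to this but individual energies are not quantitative.
- Optical flow from raw images is out of scope; analysis starts from
  velocity fields.
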