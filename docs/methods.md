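# Methods

## Physical model

The simulator treats the clothed body segment as a 1D stack: outer shell,
moisture barrier, thermal liner, air-gap microenvironment, epidermis,
dermis, subcutaneous tissue.  Assumptions: heat transfer is 1D; no mass
(moisture) transfer; convection acts only on the exposed shell face;
radiation penetrates the shell in depth but the inner fabric layers are
opaque; the gap air is not advected or cooled by the wearer's motion; the
shell's conductivity is temperature dependent (fibre/air volume blend, 80 %
air / 20 % fibre, two linear branches splitting at 700 K, the boundary
assigned to the lower branch) while its density and specific heat are
constant.

### Radiative input

Source and body are coaxial parallel discs.  The closed-form disc-disc view
factor F(d) sets the incident flux; reciprocity gives the source-side
factor and closure the ambient factor.  The net flux at the shell face is
the source-exchange term minus re-radiation to the surroundings, the latter
screened by the hot-gas emissivity factor (1 − ε_g).  Inside the shell the
flux decays as exp(−γ_f x) with γ_f = −ln τ / L_shell; the control-volume
scheme deposits the absorbed share in each shell cell and the transmitted
remainder at the shell / moisture-barrier interface node, so exactly the
net incident flux enters the stack.  The front-face *conductive* boundary
condition therefore carries only natural convection; reading the printed
surface condition as also injecting the full radiant flux would count the
same energy twice, and the in-depth (Torvi-lineage) treatment is used
instead.

Across the gap, the liner back face and the skin exchange radiation as a
grey two-surface enclosure, q = σ(T_liner⁴ − T_skin⁴) /
[(1−ε_liner)/ε_liner + 1/F + (1−ε_skin)/ε_skin].  The gap air absorbs with
κ_air = 5 m⁻¹ (Beer's law over the instantaneous thickness); the attenuated
remainder is deposited at the skin surface node and the full flux is
withdrawn from the liner node, so the exchange conserves energy to round-off.

Front-face natural convection uses the Churchill–Chu vertical-plate
correlation with characteristic length 0.1 m, the laminar branch below
Ra = 10⁹ and the squared turbulent form above.  Air-film properties (β,
ν, a) are evaluated at the film temperature (T_shell + T_amb)/2 via
β = 1/T_film and a (T/300)^1.7 viscosity fit — the underlying publications
are silent on this point, and the choice only moves the small convective
loss term.

### Moving wearer and gap flutter

The source-body distance follows a piecewise-linear trajectory: `static`,
`enter` (approach at speed v, then stay at the closest point), or
`enter_exit_hold` (approach, immediate retreat at the same speed, hold at
the start distance).  Gap thickness follows x(t) = x0 + Δx sin(2πft),
clamped below at a configurable floor (default 0.1 mm) so a conduction path
always remains near contact.  The gap keeps a fixed node count; node
spacing rescales uniformly with thickness, and temperatures are carried in
the relative gap coordinate (material-frame carry — exact on the uniform
gap grid, and it makes a zero-amplitude "moving" run bit-identical to a
static run).  The advective work done by the moving boundary on the gap air
is neglected, consistent with neglecting gap cooling.

## Numerics

Finite-volume discretization with interfaces owned by a single shared node;
every interval lies in one material, so face conductances are k(T̄)/h from
that material's own law (conservative across dissimilar layers without
harmonic averaging).  Time stepping is Crank–Nicolson with the Thomas
algorithm (default dt = 0.1 s, dx = 5 µm, about 3.8 k nodes for the
default stack).  Nonlinearities are handled by lagging: properties and all
radiative/convective fluxes are evaluated at the previous step, keeping
each step one linear tridiagonal solve.

Two deviations from the plain lagged scheme proved necessary:

* **Rannacher startup.**  The stated initial condition is discontinuous
  (gap air at 300 K against skin at 305.65 K at a shared-node interface).
  Crank–Nicolson does not damp the resulting node-scale oscillation —
  with air-cell capacities of order 3 mJ/(m² K) the local mesh ratio is
  ~10⁵ and the CN amplification factor is within 10⁻⁵ of −1 — so the first
  4 steps of every run use backward Euler.

* **Semi-implicit radiation.**  Fully explicit T⁴ exchange terms are
  unstable whenever dt·(dq/dT)/C exceeds ~2 at a node; at flash-fire
  intensity this ratio reaches ~30 at the liner face and the run diverges
  (Picard iteration would diverge too, for the same ratio).  Each radiative
  flux is therefore linearized about T^n: the Jacobian 4σT³-type
  conductance of the emitting node enters the matrix diagonal
  (`stabilizers` in `build_cn_system`), which is the standard Newton-type
  radiative-conductance treatment and also improves accuracy over pure
  lagging.

The damage integral uses the trapezoidal rule on the solver grid with
linear interpolation of threshold crossings; accumulation starts at 44 °C
and the kinetic band boundary at exactly 50 °C belongs to the lower band.
Burn-time resolution is therefore well below one time step for the smooth
Ω trajectories that occur here.

Verification oracles in the test suite: the disc-disc view factor against a
brute-force triple-quadrature of the double-area integral (< 0.5 %); the CN
core against the semi-infinite-slab error-function solution (< 0.5 % of the
step size); Thomas against dense LAPACK (< 10⁻¹² relative); exact energy
conservation on an insulated slab (< 10⁻⁸ per 1000 steps); second-order
self-convergence in dt; grid self-convergence of the deep-interface trace
(< 0.1 K under dt, dx halving).

## Parameters and provenance

Everything a run needs lives in `src/tppsim/data/defaults.yaml` and can be
overridden per scenario.  Key defaults, with the reasoning where the choice
was open:

| parameter | default | note |
|---|---|---|
| dt, dx | 0.1 s, 5 µm | grid-independence plateau |
| gap mean x0 | 3 mm | stated microenvironment thickness |
| flutter amplitude / frequency | 0–2.5 mm; 0.25/0.5/1 Hz by speed level | stated study ranges |
| speed levels | arrival in 300/100/60 s from 0.3 m | low enters and stays; medium/high enter-exit-hold |
| gap floor | 0.1 mm | keeps a conduction path at near-contact |
| κ_air | 5 m⁻¹ | stated gap absorption coefficient |
| skin stack | Torvi-style 80 µm / 2 mm / 10 mm | classical bioheat values |
| garment stacks | `three_layer_nomex`, `flash_fire_ensemble` | literature-typical stand-ins, see below |
| ε_g | 0.02 (low-level), 0.9 (flash) | optically thin surroundings vs flame immersion |
| source/body radii | 1.5 m (0.1 m for flash bench) | backed out, see below |
| burn kinetics | band-split (P, ΔE/R) per interface | printed kinetic table |
| Ω thresholds | 0.53 / 1.0 / 1.0 | 1st degree threshold is an assumed convention and labelled as such |

Two parameter groups deserve emphasis because the source publication does
not print them:

* **Garment properties.**  Layer thicknesses, densities, specific heats,
  shell transmissivity and the constant conductivities of the inner layers
  are assembled from typical published figures for Nomex-type ensembles;
  they are stand-ins, not measurements.  The low-level validation scenario
  lands within ~6 % of the published 149.7 s second-degree burn time with
  these values; the flash-fire scenarios remain a factor ~2 slow on
  second-degree times, which is the expected sensitivity of a 4–5 s burn
  time to an unknown thin-ensemble property set.

* **Exposure geometry.**  Only the nominal flux (8.5 / 83 kW/m²) is
  stated.  The source temperature is calibrated by root finding so the
  cold-garment flux at the start distance matches the nominal level
  (0.1 %); the disc radii are backed out qualitatively: small radii make
  the close-approach flux spike dominate every speed level, while radii of
  about 1.5 m put the enter/exit scenarios in the regime where the
  second-degree burn time is minimized at medium movement speed.  The flash
  bench scenarios instead use burner-scale 0.1 m discs (calibrating to a
  ~2050 K source), since a bench exposure is a close, small, very hot
  source.

## What a green test does and does not establish

The packaged scenarios are a stated world, not measured data: green
validation tests establish that the discretized model reproduces its own
continuum limit, conserves energy, and yields the documented burn times
under the documented parameter stand-ins.  They do not establish that the
stand-ins match any particular garment.  Behavioural claims that depend on
the unprinted exposure geometry (the 33 % medium-speed reduction, the
amplitude-reversal at 2.5 mm, the ≥ 6 s flutter on/off shift) do not
emerge quantitatively in this stated world and their checks are left
failing by design rather than loosened.

## Limitations

No moisture or mass transfer; no forced convection in the gap during
motion; no fabric degradation, shrinkage or pyrolysis; no perfusion or
metabolic terms in the tissue equation (pure conduction with a pinned deep
boundary); 1D only — no folds, heterogeneous gaps or body mapping; radiation
inside the fabric is Beer attenuation of a collimated flux, not a
participating-medium solution.
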