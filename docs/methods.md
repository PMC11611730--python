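# Methods

## Bond model

A bond is a continuous-time Markov chain.  A slip bond has one bound state
and one dissociation pathway; a catch bond has a mechanically weak state 1,
a mechanically strong state 2, reversible interconversion between them, and
dissociation from each.  Every transition rate follows the Kramers–Bell law

    k(F) = k0 · exp(F · x‡ / kBT)

with `k0` the zero-force rate (1/s), `x‡` the distance to the transition
state (nm, signed), `F` the tensile force (pN) and `kBT = 4.047 pN·nm` at
20 °C.  Compression never reaches the rate law: tethers are tension-only, so
slack bonds see `F = 0`.

Mean lifetimes are mean first-passage times to the absorbing unbound state,
obtained from the linear solve `−Q_t·τ = 1` on the transient block of the
generator matrix.  The same chain can be sampled stochastically
(`sample_bond_lifetimes`), which the tests use as an independent route to the
same quantity.

Barrier energies and rates are linked by `E = −kBT·ln(k0/ν)` with attempt
frequency `ν = 10⁶ s⁻¹`; only rate ratios affect the dynamics, so `ν` is a
reporting convention, not a physical claim.  Under force each barrier tilts
linearly, `E(F) = E(0) − F·x‡/kBT` (in kBT units), with its own tilt
distance.  The four design requirements of a functional catch bond are
checked on this tilted landscape: (I) `E² > E¹`, (II) `E^IC > E¹` at low
tension, (III) `E^IC < E¹` at high tension, (IV) `ΔE₀ > 0`.  A slip bond has
no strong state; its landscape embedding sets `E² = E¹` and `ΔE₀ = 0`, so it
fails I and IV by construction.

### Default parameter registry

Published descriptions of the DNA constructs give the mechanism and an
activation-force estimate (≈ 12–18 pN) but not per-transition `k0`/`x‡`
values, so the registry declares a reference set chosen to (a) satisfy the
four requirements by a wide margin, (b) produce lifetimes of order 0.1–10 s
over 0–20 pN, and (c) place the lifetime maximum inside the activation
window:

| transition            | k0 (1/s) | x‡ (nm) | role |
|-----------------------|----------|---------|------|
| weak → unbound        | 2.0      | +1.0    | crosslink rupture (shear-loaded) |
| weak → strong         | 0.02     | +3.0    | hairpin unzipping (zipper-loaded, strongly force-susceptible) |
| strong → weak         | 2.0      | −1.0    | latch release, suppressed by tension |
| strong → unbound      | 0.012–0.40 | +0.3  | activated-crosslink rupture, per latch length |

The `catch_latch_k` presets (k = 2, 3, 4, 5, 7) encode the latch-length
trend phenomenologically — a longer latch means more base pairs in the
activated crosslink, hence a slower strong-state off-rate — not from
sequence thermodynamics.  `catch` is an alias of `catch_latch_5` (peak
lifetime 6.2 s at ~14 pN, 12× the zero-force lifetime).  The slip control is
`k0 = 1 s⁻¹, x‡ = 1 nm`; the ideal preset uses `x‡ = 0.005 nm`, giving
< 3 % lifetime variation over 0–20 pN.  The reverse interconversion is
force-suppressed (negative `x‡`), consistent with the observed spontaneous
return of activated bonds to the weak state once tension is released.
Mechanotype classification uses a 5 % relative-lifetime tolerance: an
interior maximum more than 5 % above τ(0) is catch, variation below 5 % is
ideal; curves that merely decrease are slip.

## Particle mechanics

The particle (radius 0.68 µm) sits at a fixed 0.02 µm clearance above the
wall; there is no vertical degree of freedom, no Brownian motion and no
lubrication correction.  A linear shear flow loads it with

    F_shear = 1.7009 · 6πηR²γ̇        M = 0.9440 · 4πηR³γ̇

— the standard wall-correction coefficients for a stationary sphere at a
plane wall in shear.  At γ̇ = 560 s⁻¹ this gives 8.3 pN and 2.1 pN·µm.

Tethers are Hookean and tension-only: `T = κ·max(0, L − L0)` with default
stiffness κ = 200 pN/µm.  The two generalized coordinates are downstream
translation and rolling rotation about the transverse axis; equilibrium
(net force along flow and net torque both zero, residual ≤ 10⁻⁶ pN /
pN·µm) is found by damped Newton iteration with an analytic 2×2 Jacobian,
Levenberg damping when the tension-only kink stalls a step, and a
BFGS energy-minimisation fallback.  Torque balance (rather than imposed
rolling-without-slipping kinematics) is the chosen closure.  A
numba-compiled twin of the solver drives the simulation hot loop; the test
suite verifies it against the reference solver on randomized configurations.

## Rolling-adhesion simulation

Event-driven Gillespie KMC.  Possible events and propensities:

- **formation**, at constant `on_rate` (default 25 s⁻¹) for every unbound
  substrate site within a sharp capture radius (0.06 µm) of the sphere
  surface — no distance weighting;
- **dissociation** of each bound tether at its Bell rate evaluated at the
  current equilibrium tension;
- **activation / reversion** for catch tethers in the weak / strong state.

A waiting time is drawn from the total propensity, one event is selected by
cumulative sum (ties toward the lower index), the event is applied, the
substrate is regenerated/retired, mechanics are re-equilibrated, and time
and position are recorded.  Substrate sites are a Poisson point process
(60 µm⁻² on a strip spanning the reachable width), generated lazily ahead
of the particle and retired behind it, so memory is bounded for arbitrarily
long runs.  All randomness comes from one PCG64 generator seeded from the
config; repeat `i` of an ensemble uses `base_seed + i`.

Bonds form at their natural length (zero tension at the instant of
formation).  This choice guarantees strictly forward rolling: a bond formed
pre-tensed behind the particle centre would pull it upstream when the
mechanics re-equilibrate.  Leading bonds are therefore slack and trailing
bonds taut, which is what produces the trailing-edge localization of
strong-state bonds in the activation heatmap (snapshots of every bound
tether's position relative to the particle centre, state and tension, taken
every 2,500 steps and pooled over repeats).

On detachment (zero bonds) the default policy terminates the run and
records the reason; an optional `advect` policy translates the particle at
the near-wall free-stream velocity (0.57·γ̇·R) up to a capped distance to
allow recapture.

The kinetic constants that the published work leaves unspecified
(`on_rate`, site density, capture radius, stiffness) were fixed once, as a
set, so that the simulated dynamics straddle the 0.5 µm/s stop/roll
threshold across the 200–600 s⁻¹ shear window and the slip-vs-catch
contrast is expressed; they are configuration values, not fitted claims.

## Trajectory analysis

Identical for simulated, synthetic and experimental input: linear
interpolation to a uniform 0.01 s clock (frame-clocked data keep their
camera dt, default 60 fps); central-difference velocity smoothed by a
Savitzky–Golay filter (window 11 samples, polynomial order 2 — the filter
is exact on signals of degree ≤ 2, so these defaults only matter for noisy
data); segmentation at |v| ≥ 0.5 µm/s into maximal stop/roll runs, each
velocity sample owning one interpolation step.

Statistics follow the assay's filtering rules: trajectories under 30 frames
are dropped; `f_roll` is the fraction of retained particles whose net
displacement exceeds 1 µm (Euclidean between first and last positions);
`v_roll` is the per-particle duration-weighted mean speed over rolling
intervals, averaged across particles; `t_stop` pools interior stop dwells —
dwells truncated by the start or end of a trajectory are censored (biased
low) and are used only when a trajectory contains no interior stop at all,
e.g. a fully arrested particle; datasets retaining fewer than 30 particles
are flagged invalid.  When the interpolation span is not an integer
multiple of the grid step, the sub-step tail is dropped (both endpoints are
reproduced exactly whenever the span divides evenly).

## Synthetic data

The telegraph generator emulates the intermittent stop–roll displacement
traces of tracked particles: exponential stop and roll dwells, constant
advance speed while rolling, i.i.d. Gaussian per-frame localization noise.
The initial regime is drawn from the process's stationary occupancy, so the
stop-only and roll-only limits degenerate to a constant and a pure ramp.
Generators emit their realized regime schedule as ground truth, which is
what recovery tests compare against (the realized dwell mean of a finite
trace fluctuates around the generator parameter).  What the generator does
*not* emulate: tracking gaps and mislinking, drift, heavy-tailed
localization error, dwell-time correlations, and particle-to-particle
heterogeneity — so recovery tests validate the analysis pipeline, not the
tracking front end.

## Problem sizes and numerical choices

Reference ensembles are 5×10⁵ steps × 50 repeats (and 100 repeats for the
heatmap); the shipped end-to-end checks run a scaled-down twin — 4 shear
rates spanning ×3 (200–600 s⁻¹), 20 repeats of 5×10⁴ steps, 10 heatmap
repeats — which reproduces the qualitative contrast (slip velocity rising
monotonically with shear, catch velocity comparatively flat, catch stop
times an order of magnitude longer, strong bonds trailing the centre) at
desk scale; the full-size protocol is a configuration change.  Monte Carlo
comparisons use 3-standard-error bands.  Equilibrium tolerance is 10⁻⁶ pN
(pN·µm); interpolation uses double precision throughout, and CSV output is
written at 17 significant digits so file round-trips are bit-exact.

Degenerate inputs worth knowing about: a trace whose true rolling speed
equals the segmentation threshold exactly sits on the |v| ≥ threshold
boundary, where last-ULP differences in interpolation or smoothing flip
sample classifications — thresholding segmentation is ill-posed there, and
recovery guarantees hold only for speeds strictly away from the threshold.

## Known limitations

- Three-state chain only: no dissociation from the open-hairpin
  intermediate at very high force, no unfolding-intermediate kinetics.
- Hookean tethers; a worm-like-chain law would change the tension scale but
  sits behind the same `tether_tension` contract.
- Single particle; no inter-particle hydrodynamics, no vertical dynamics,
  no Brownian displacement between events.
- Bond parameters are declared reference values, not fits to the
  experimental curves.
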