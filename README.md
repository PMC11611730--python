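# catchroll

Catch bonds are noncovalent interactions that become *longer-lived* under
tensile force — the mechanism leukocytes and bacteria use to grip surfaces
more strongly the harder flow pulls on them, and recently realized
synthetically with engineered DNA duplexes whose cryptic "latch" domain is
exposed under tension.  `catchroll` is a Python library for studying how such
bonds change the collective adhesion of a microparticle rolling along a
functionalized surface under shear flow.  It is aimed at people modelling
mechanochemistry experiments: rolling-adhesion assays, single-bond force
spectroscopy, adhesive-dynamics simulation.

It provides, as composable modules:

- **`catchroll.bonds`** — two-state/two-pathway bond kinetics.  Every
  transition follows a Kramers–Bell law `k(F) = k0·exp(F·x‡/kBT)`; a catch
  bond is a weak state (1) and a strong state (2) with force-gated
  interconversion.  Mean lifetimes come from the mean-first-passage-time
  linear solve on the generator matrix over `{weak, strong, unbound}`;
  bonds are classified as slip / ideal / catch from the shape of the
  lifetime–force curve; the four thermodynamic design requirements of a
  functional catch bond (E² > E¹; E^IC > E¹ at low tension; E^IC < E¹ at
  high tension; ΔE₀ > 0) can be audited for any parameter set.
- **`catchroll.mechanics`** — a sphere (default 1.36 µm diameter) near a
  wall in linear shear experiences `F_shear = 1.7009·6πηR²γ̇` and torque
  `M = 0.9440·4πηR³γ̇` (wall-corrected coefficients); Hookean tension-only
  tethers anchor it to the surface, and a damped-Newton solver finds the
  quasi-static force/torque balance in (downstream position, rolling angle).
- **`catchroll.kmc`** — an event-driven Gillespie simulation: bonds form on
  a Poisson field of substrate sites, dissociate and (for catch bonds)
  activate or revert at tension-dependent rates, with mechanical
  re-equilibration after every event.  Outputs displacement trajectories,
  event logs and weak/strong activation heatmaps.
- **`catchroll.analysis`** — the trajectory-to-statistics pipeline: wall
  shear rate `γ̇ = 6Q/(h²w)` from the imposed flow; linear interpolation to
  a uniform clock (0.01 s); Savitzky–Golay-smoothed instantaneous velocity;
  stop/roll segmentation at 0.5 µm/s; per-particle statistics `f_roll`
  (fraction displacing > 1 µm), duration-weighted `v_roll`, and mean stop
  time `t_stop`, with the ≥ 30-frame and ≥ 30-particle filtering rules.
- **`catchroll.synthetic`** — telegraph-process stop–roll trace generators
  with exact ground truth, and a registry of bond presets (`slip`, `ideal`,
  `catch`, `catch_latch_2…7`).
- **`catchroll.workflow`** — shear-rate sweeps across mechanotypes and the
  slip-vs-catch verdict (is catch rolling less shear-sensitive? does it
  stop longer?).

## Worked example

```python
import numpy as np
import catchroll as cr

env = cr.Environment()                       # 20 degC water, kBT = 4.047 pN nm
catch = cr.preset("catch")

# single-bond lifetime curve: the catch signature
for F in (0, 8, 14, 20):
    print(f"tau({F:2d} pN) = {cr.mean_lifetime(catch, F, env):.2f} s")
print(cr.classify_mechanotype(catch, env, np.linspace(0, 20, 41)))
```

prints

```
tau( 0 pN) = 0.50 s
tau( 8 pN) = 1.32 s
tau(14 pN) = 6.20 s
tau(20 pN) = 4.52 s
('catch', 14.0)
```

— the bond lives 12× longer near 14 pN than at rest, the defining property
of a catch bond, while `cr.preset("slip")` gives a strictly decreasing
curve.  A rolling-adhesion simulation and its analysis:

```python
from catchroll import SimulationConfig, run_simulation, interpolate, rolling_stats

cfg = SimulationConfig(bond="catch", shear_rate=460.0, n_steps=20_000, seed=3)
traj, events, sim = run_simulation(cfg)
stats = rolling_stats([interpolate(traj.time, traj.centre_x, dt=0.01)],
                      min_frames=2, min_particles=1)
print(f"v_roll = {stats.v_roll_mean:.2f} um/s, t_stop = {stats.t_stop_mean:.2f} s")
```

```
v_roll = 1.51 um/s, t_stop = 3.44 s
```

Catch-bonded particles show second-scale arrests (trailing-edge bonds
activate to the strong state under the ~10 pN load), whereas the slip
control at the same shear rate stops only for ~0.1 s at a time.  The same
machinery is exposed on the command line:

```sh
catchroll simulate --mechanotype catch --shear-rate 460 --steps 20000 --out out/
catchroll analyze --in out/ --out stats.json
catchroll sweep --grid 200,330,460,600 --repeats 20 --out sweep/
catchroll shear-rate --Q 21 --h 50 --w 1500     # -> 560
```

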