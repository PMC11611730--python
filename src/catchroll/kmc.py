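"""Event-driven Gillespie simulation of a shear-loaded, tethered microparticle.

One kinetic Monte Carlo step:

1. enumerate every possible event and its propensity — bond formation for
   each unbound substrate site within capture range of the sphere surface,
   force-dependent dissociation for each bound tether, and (for catch bonds)
   weak->strong activation and strong->weak reversion;
2. draw an exponential waiting time from the total propensity and select one
   event proportionally to its rate;
3. apply the event, regenerate substrate sites ahead of the particle and
   retire those far behind it;
4. re-equilibrate the particle mechanics (the particle is quasi-static:
   hydrodynamics enters only through the shear force and torque);
5. record time and position.

Substrate sites are a Poisson point process of the configured density on a
strip of the wall, generated lazily ahead of the particle so arbitrarily long
runs need only a bounded live window.  Bonds form at their natural length
(zero tension at the moment of formation) so the particle only ever moves
downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .bonds import (
    BondParams,
    BondState,
    CatchBondParams,
    SlipBondParams,
    bell_rate,
)
from .environment import Environment
from ._fast import newton_equilibrate, tensions as _fast_tensions
from .mechanics import (
    EquilibrationError,
    ParticleGeometry,
    ParticleState,
    TetherSystem,
    equilibrate,
    shear_load,
)

__all__ = [
    "SimulationConfig",
    "Event",
    "EventLog",
    "Trajectory",
    "ActivationHeatmap",
    "NoEventPossible",
    "gillespie_step",
    "run_simulation",
    "accumulate_heatmap",
    "sample_bond_lifetimes",
    "RollingSimulation",
]

# integer state codes used in the hot loop
_UNBOUND, _SLIP, _WEAK, _STRONG = 0, 1, 2, 3
_CODE_TO_STATE = {
    _UNBOUND: BondState.UNBOUND,
    _SLIP: BondState.SLIP_BOUND,
    _WEAK: BondState.WEAK,
    _STRONG: BondState.STRONG,
}


class NoEventPossible(RuntimeError):
    """Total propensity is zero: the system is in an absorbing state."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one rolling-adhesion simulation.

    ``bond`` is either a :class:`SlipBondParams`/:class:`CatchBondParams`
    instance or the name of a registered preset (resolved through
    :func:`catchroll.synthetic.preset`).

    Geometry/kinetics defaults are the package's declared reference
    conditions: 1.36-um-diameter particle, substrate sites at
    ``substrate_site_density`` per um^2, sharp capture radius, Hookean
    tension-only tethers.
    """

    bond: BondParams | str = "catch"
    shear_rate: float = 400.0
    n_steps: int = 500_000
    n_repeats: int = 50
    seed: int = 0
    substrate_site_density: float = 60.0
    capture_radius: float = 0.06
    snapshot_interval: int = 2500
    detachment_policy: str = "terminate"
    geometry: ParticleGeometry = field(default_factory=ParticleGeometry)
    environment: Environment = field(default_factory=Environment)
    stiffness: float = 200.0
    advect_distance_cap: float = 5.0
    collect_snapshots: bool = False

    def __post_init__(self) -> None:
        if not self.n_steps > 0:
            raise ValueError("n_steps must be positive")
        if not self.capture_radius > 0:
            raise ValueError("capture_radius must be positive")
        if self.detachment_policy not in ("terminate", "advect"):
            raise ValueError("detachment_policy must be 'terminate' or 'advect'")
        if not self.substrate_site_density > 0:
            raise ValueError("substrate_site_density must be positive")

    def resolve_bond(self) -> BondParams:
        if isinstance(self.bond, str):
            from .synthetic import preset

            return preset(self.bond)
        return self.bond


class Event(NamedTuple):
    """One possible (or realized) kinetic Monte Carlo event."""

    kind: str  # form | dissociate | activate | revert
    site_id: int


@dataclass
class EventLog:
    """Time-ordered record of realized KMC events."""

    time: list[float] = field(default_factory=list)
    kind: list[str] = field(default_factory=list)
    tether_id: list[int] = field(default_factory=list)
    tension: list[float] = field(default_factory=list)

    def append(self, t: float, kind: str, tid: int, tension: float) -> None:
        self.time.append(t)
        self.kind.append(kind)
        self.tether_id.append(tid)
        self.tension.append(tension)

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "kind": self.kind,
                "tether_id": self.tether_id,
                "tension_pN": self.tension,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def replay(
        self,
        initial_states: dict[int, BondState],
        ground_state: BondState = BondState.WEAK,
    ) -> dict[int, BondState]:
        """Apply the logged events to a map of initial tether states.

        Returns the final state map; used to verify that the log fully
        determines the final bond configuration.
        """
        states = dict(initial_states)
        for kind, tid in zip(self.kind, self.tether_id):
            if kind == "form":
                states[tid] = ground_state
            elif kind == "dissociate":
                states[tid] = BondState.UNBOUND
            elif kind == "activate":
                states[tid] = BondState.STRONG
            elif kind == "revert":
                states[tid] = BondState.WEAK
            else:  # pragma: no cover
                raise ValueError(f"unknown event kind {kind}")
        return states


@dataclass
class Trajectory:
    """Event-timestamped displacement trace of one particle."""

    time: np.ndarray
    centre_x: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.centre_x = np.asarray(self.centre_x, dtype=float)
        if self.time.size != self.centre_x.size:
            raise ValueError("time and centre_x must have equal length")

    def write_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        pd.DataFrame({"time_s": self.time, "x_um": self.centre_x}).to_csv(
            path, index=False, float_format="%.17g"
        )
        if sidecar:
            path.with_suffix(".json").write_text(
                json.dumps(self.metadata, indent=1, default=str)
            )

    @classmethod
    def read_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        meta_path = path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(df["time_s"].to_numpy(), df["x_um"].to_numpy(), meta)


@dataclass
class ActivationHeatmap:
    """Binned observation counts and mean tether tensions per bond state.

    Bins live in the wall plane, coordinates relative to the instantaneous
    particle centre (x positive downstream).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: dict[str, np.ndarray]
    force_sum: dict[str, np.ndarray]

    @classmethod
    def empty(cls, extent: float = 1.0, bin_size: float = 0.05) -> "ActivationHeatmap":
        edges = np.arange(-extent, extent + bin_size / 2, bin_size)
        shape = (edges.size - 1, edges.size - 1)
        return cls(
            x_edges=edges,
            y_edges=edges.copy(),
            counts={s: np.zeros(shape) for s in ("weak", "strong")},
            force_sum={s: np.zeros(shape) for s in ("weak", "strong")},
        )

    def add(self, state: str, x_rel, y_rel, tension) -> None:
        c, _, _ = np.histogram2d(x_rel, y_rel, bins=(self.x_edges, self.y_edges))
        f, _, _ = np.histogram2d(
            x_rel, y_rel, bins=(self.x_edges, self.y_edges), weights=tension
        )
        self.counts[state] += c
        self.force_sum[state] += f

    def mean_force(self, state: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.counts[state] > 0,
                self.force_sum[state] / self.counts[state],
                np.nan,
            )

    def total_count(self) -> float:
        return float(sum(c.sum() for c in self.counts.values()))

    def mean_relative_x(self, state: str) -> float:
        """Count-weighted mean downstream offset of observations of a state."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        c = self.counts[state]
        total = c.sum()
        if total == 0:
            return math.nan
        return float((c.sum(axis=1) * xc).sum() / total)

    def to_dataframe(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = []
        for state in ("weak", "strong"):
            mf = self.mean_force(state)
            for i, x in enumerate(xc):
                for j, y in enumerate(yc):
                    if self.counts[state][i, j] > 0:
                        rows.append(
                            (x, y, state, self.counts[state][i, j], mf[i, j])
                        )
        return pd.DataFrame(
            rows, columns=["x_bin", "y_bin", "state", "count", "mean_force_pN"]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def gillespie_step(
    propensities: np.ndarray, rng: np.random.Generator
) -> tuple[float, int]:
    """Draw (waiting time, event index) from a propensity vector.

    Waiting time ~ Exponential(total); the event is selected by inverse-CDF
    sampling on the cumulative sum, ties broken toward the lower index.

    Raises
    ------
    NoEventPossible
        If the total propensity is zero.
    """
    p = np.asarray(propensities, dtype=float)
    if np.any(p < 0):
        raise ValueError("propensities must be non-negative")
    total = p.sum()
    if total <= 0:
        raise NoEventPossible("total propensity is zero")
    dt = rng.exponential(1.0 / total)
    r = rng.uniform(0.0, total)
    idx = int(np.searchsorted(np.cumsum(p), r, side="left"))
    idx = min(idx, p.size - 1)
    return dt, idx


# ---------------------------------------------------------------------------
# rolling simulation engine
# ---------------------------------------------------------------------------

# live site window relative to the particle centre (um)
_WINDOW_BEHIND = 0.6
_WINDOW_AHEAD = 1.2
_GEN_CHUNK = 1.0


class RollingSimulation:
    """Mutable state of one rolling-adhesion KMC run.

    Most users call :func:`run_simulation`; this class is exposed for
    step-level inspection (``enumerate_events``, ``step``) and replay tests.
    """

    def __init__(self, cfg: SimulationConfig, seed: int | None = None):
        self.cfg = cfg
        self.bond = cfg.resolve_bond()
        self.is_catch = isinstance(self.bond, CatchBondParams)
        self.env = cfg.environment
        self.geom = cfg.geometry
        self.load = shear_load(cfg.shear_rate, self.env, self.geom)
        self.seed = cfg.seed if seed is None else seed
        self.rng = np.random.default_rng(self.seed)

        # Bell-rate constants by state code, for vectorized propensities
        kbt = self.env.thermal_energy
        if self.is_catch:
            b = self.bond
            self._off_k0 = {_WEAK: b.off_weak.zero_force_rate,
                            _STRONG: b.off_strong.zero_force_rate}
            self._off_x = {_WEAK: b.off_weak.force_scale_distance / kbt,
                           _STRONG: b.off_strong.force_scale_distance / kbt}
            self._act = (b.interconvert.zero_force_rate,
                         b.interconvert.force_scale_distance / kbt)
            self._rev = (b.revert.zero_force_rate,
                         b.revert.force_scale_distance / kbt)
            self._ground = _WEAK
        else:
            b = self.bond
            self._off_k0 = {_SLIP: b.off.zero_force_rate}
            self._off_x = {_SLIP: b.off.force_scale_distance / kbt}
            self._ground = _SLIP
        self.on_rate = self.bond.on_rate

        # substrate site arrays (grow-only; retired sites are masked out)
        self.site_xy = np.empty((0, 2))
        self.site_state = np.empty(0, dtype=np.int8)
        self.site_alive = np.empty(0, dtype=bool)
        # body-frame anchor + rest length, valid only while bound
        self.site_u = np.empty((0, 3))
        self.site_L0 = np.empty(0)

        reach = (self.geom.radius + cfg.capture_radius)
        lateral = reach**2 - self.geom.centre_height**2
        if lateral <= 0:
            raise ValueError(
                "capture_radius too small: no substrate site can ever be in reach"
            )
        self._reach_sq = reach * reach
        self._y_half = math.sqrt(lateral) + 0.05
        self._x_gen = 0.0  # right edge of generated strip

        self.state = ParticleState()
        self.time = 0.0
        self.steps_done = 0
        self.termination: str | None = None
        self.log = EventLog()
        self.snapshots: list[tuple[float, np.ndarray, np.ndarray, np.ndarray]] = []
        self._times = [0.0]
        self._xs = [0.0]

        self._gen_sites_upto(_WINDOW_AHEAD)
        self._gen_sites_behind()
        self._bind_initial()
        self._rebuild_bound()
        self._equilibrate()
        self._times[0] = 0.0
        self._xs[0] = self.state.centre_x

    # -- substrate management ------------------------------------------------

    def _append_sites(self, xy: np.ndarray) -> None:
        n = xy.shape[0]
        if n == 0:
            return
        self.site_xy = np.vstack([self.site_xy, xy])
        self.site_state = np.concatenate(
            [self.site_state, np.zeros(n, dtype=np.int8)]
        )
        self.site_alive = np.concatenate([self.site_alive, np.ones(n, dtype=bool)])
        self.site_u = np.vstack([self.site_u, np.zeros((n, 3))])
        self.site_L0 = np.concatenate([self.site_L0, np.zeros(n)])

    def _gen_sites_upto(self, x_target: float) -> None:
        """Extend the Poisson site field to the right up to ``x_target``."""
        while self._x_gen < x_target:
            x0, x1 = self._x_gen, self._x_gen + _GEN_CHUNK
            area = (x1 - x0) * 2 * self._y_half
            n = self.rng.poisson(self.cfg.substrate_site_density * area)
            xy = np.column_stack(
                [
                    self.rng.uniform(x0, x1, n),
                    self.rng.uniform(-self._y_half, self._y_half, n),
                ]
            )
            self._append_sites(xy)
            self._x_gen = x1

    def _gen_sites_behind(self) -> None:
        """One-off strip behind the origin so the initial contact is complete."""
        area = _WINDOW_BEHIND * 2 * self._y_half
        n = self.rng.poisson(self.cfg.substrate_site_density * area)
        xy = np.column_stack(
            [
                self.rng.uniform(-_WINDOW_BEHIND, 0.0, n),
                self.rng.uniform(-self._y_half, self._y_half, n),
            ]
        )
        self._append_sites(xy)

    def _retire_sites(self) -> None:
        behind = self.site_xy[:, 0] < self.state.centre_x - _WINDOW_BEHIND
        unbound = self.site_state == _UNBOUND
        self.site_alive &= ~(behind & unbound)

    def _in_reach_mask(self) -> np.ndarray:
        dx = self.site_xy[:, 0] - self.state.centre_x
        dy = self.site_xy[:, 1]
        dist_sq = dx * dx + dy * dy + self.geom.centre_height**2
        return self.site_alive & (dist_sq <= self._reach_sq)

    def _bind_initial(self) -> None:
        mask = self._in_reach_mask() & (self.site_state == _UNBOUND)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            # degenerate draw: place one site directly beneath the particle
            self._append_sites(np.array([[0.0, 0.0]]))
            idx = np.array([self.site_state.size - 1])
        for i in idx:
            self._bind_site(int(i))

    def _bind_site(self, i: int) -> None:
        """Bind site ``i`` in the ground state at its natural length."""
        centre = np.array(
            [self.state.centre_x, 0.0, self.geom.centre_height]
        )
        site = np.array([self.site_xy[i, 0], self.site_xy[i, 1], 0.0])
        v = site - centre
        dist = float(np.linalg.norm(v))
        v /= dist
        th = self.state.rotation
        ct, st = math.cos(th), math.sin(th)
        # lab -> body (inverse of the rolling rotation about +y)
        bx = v[0] * ct - v[2] * st
        bz = v[0] * st + v[2] * ct
        self.site_u[i] = (bx, v[1], bz)
        self.site_L0[i] = dist - self.geom.radius
        self.site_state[i] = self._ground

    # -- mechanics glue -------------------------------------------------------

    def _rebuild_bound(self) -> None:
        bound = np.flatnonzero(self.site_state > 0)
        self._bound_idx = bound
        self._b_sub = np.ascontiguousarray(self.site_xy[bound])
        self._b_u = np.ascontiguousarray(self.site_u[bound])
        self._b_L0 = np.ascontiguousarray(self.site_L0[bound])
        self._b_kappa = np.full(bound.size, self.cfg.stiffness)

    def _as_tether_system(self) -> TetherSystem:
        sys_ = TetherSystem()
        sys_.sub = np.column_stack([self._b_sub, np.zeros(self._bound_idx.size)])
        sys_.u = self._b_u
        sys_.L0 = self._b_L0
        sys_.kappa = self._b_kappa
        return sys_

    def _equilibrate(self, tol: float = 1e-6) -> None:
        """Fast damped-Newton balance, falling back to the robust solver."""
        cx, th, resid, ok = newton_equilibrate(
            self._b_sub,
            self._b_u,
            self._b_L0,
            self._b_kappa,
            self.state.centre_x,
            self.state.rotation,
            self.load.force_x,
            self.load.torque_y,
            self.geom.centre_height,
            self.geom.radius,
            tol,
            200,
        )
        if ok:
            self.state = ParticleState(centre_x=cx, rotation=th)
        else:
            self.state = equilibrate(
                self._as_tether_system(), self.state, self.load, self.geom, tol=tol
            )
        self._tensions = _fast_tensions(
            self._b_sub,
            self._b_u,
            self._b_L0,
            self._b_kappa,
            self.state.centre_x,
            self.state.rotation,
            self.geom.centre_height,
            self.geom.radius,
        )
        self._equilibrated = True

    def bound_count(self) -> int:
        return int(np.count_nonzero(self.site_state > 0))

    def tether_states(self) -> dict[int, BondState]:
        """Map of site id -> bond state for all sites ever seen."""
        return {
            int(i): _CODE_TO_STATE[int(s)]
            for i, s in enumerate(self.site_state)
        }

    # -- propensities ---------------------------------------------------------

    def _event_space(self):
        """Raw event enumeration for the hot loop.

        Returns ``(free, bound, weak_ids, strong_ids, rates, tension)``: the
        rate vector is ordered [formations per free site | dissociations per
        bound tether | activations per weak tether | reversions per strong
        tether], with the parallel id arrays giving each block's site ids.
        """
        if not self._equilibrated:
            raise RuntimeError(
                "stale tensions: equilibrate must run before enumerate_events"
            )
        bound = self._bound_idx
        tension = self._tensions

        free = np.flatnonzero(self._in_reach_mask() & (self.site_state == _UNBOUND))
        form = np.full(free.size, self.on_rate)
        states = self.site_state[bound]

        if self.is_catch:
            weak = states == _WEAK
            strong = ~weak
            off = np.where(
                weak,
                self._off_k0[_WEAK] * np.exp(self._off_x[_WEAK] * tension),
                self._off_k0[_STRONG] * np.exp(self._off_x[_STRONG] * tension),
            )
            k0a, xa = self._act
            k0r, xr = self._rev
            act = k0a * np.exp(xa * tension[weak])
            rev = k0r * np.exp(xr * tension[strong])
            rates = np.concatenate([form, off, act, rev])
            return free, bound, bound[weak], bound[strong], rates, tension

        off = self._off_k0[_SLIP] * np.exp(self._off_x[_SLIP] * tension)
        rates = np.concatenate([form, off])
        empty = np.empty(0, dtype=int)
        return free, bound, empty, empty, rates, tension

    def enumerate_events(self) -> list[tuple[Event, float]]:
        """All currently possible events with their propensities (1/s)."""
        free, bound, weak_ids, strong_ids, rates, _ = self._event_space()
        kinds = (
            ["form"] * free.size
            + ["dissociate"] * bound.size
            + ["activate"] * weak_ids.size
            + ["revert"] * strong_ids.size
        )
        ids = np.concatenate([free, bound, weak_ids, strong_ids])
        return [
            (Event(kind=k, site_id=int(i)), float(r))
            for k, i, r in zip(kinds, ids, rates)
        ]

    # -- stepping -------------------------------------------------------------

    def step(self) -> Event | None:
        """Advance by one KMC event.  Returns the event, or None on termination."""
        free, bound, weak_ids, strong_ids, rates, tension = self._event_space()
        total = rates.sum()
        if total <= 0:
            self.termination = "frozen"
            return None
        self.time += self.rng.exponential(1.0 / total)
        r = self.rng.uniform(0.0, total)
        j = int(np.searchsorted(np.cumsum(rates), r, side="left"))
        j = min(j, rates.size - 1)

        nf, nb, nw = free.size, bound.size, weak_ids.size
        if j < nf:
            kind, sid, ev_tension = "form", int(free[j]), 0.0
            self._bind_site(sid)
        elif j < nf + nb:
            kind, sid = "dissociate", int(bound[j - nf])
            ev_tension = float(tension[j - nf])
            self.site_state[sid] = _UNBOUND
        elif j < nf + nb + nw:
            kind, sid = "activate", int(weak_ids[j - nf - nb])
            ev_tension = float(tension[np.searchsorted(bound, sid)])
            self.site_state[sid] = _STRONG
        else:
            kind, sid = "revert", int(strong_ids[j - nf - nb - nw])
            ev_tension = float(tension[np.searchsorted(bound, sid)])
            self.site_state[sid] = _WEAK
        self.log.append(self.time, kind, sid, ev_tension)
        self._equilibrated = False

        if self.bound_count() == 0:
            if not self._handle_detachment():
                return Event(kind, sid)

        self._gen_sites_upto(self.state.centre_x + _WINDOW_AHEAD)
        self._retire_sites()
        self._rebuild_bound()
        try:
            self._equilibrate()
        except EquilibrationError as exc:
            raise EquilibrationError(
                f"at step {self.steps_done}, t={self.time:.4f} s: {exc}"
            ) from exc
        self.steps_done += 1
        self._times.append(self.time)
        self._xs.append(self.state.centre_x)
        if (
            self.cfg.collect_snapshots
            and self.steps_done % self.cfg.snapshot_interval == 0
        ):
            self._take_snapshot()
        return Event(kind, sid)

    def _handle_detachment(self) -> bool:
        """Zero bonds remain.  Returns True if the particle was recaptured."""
        if self.cfg.detachment_policy == "terminate":
            self.termination = "detached"
            self._times.append(self.time)
            self._xs.append(self.state.centre_x)
            return False
        # advect: free-stream translation near the wall until a new bond forms
        # or the distance cap is exceeded
        v_free = 0.57 * self.cfg.shear_rate * self.geom.radius
        travelled = 0.0
        while travelled < self.cfg.advect_distance_cap:
            self._gen_sites_upto(self.state.centre_x + _WINDOW_AHEAD)
            n_reach = int(
                np.count_nonzero(self._in_reach_mask() & (self.site_state == _UNBOUND))
            )
            hop = 0.05
            if n_reach > 0:
                t_bind = self.rng.exponential(1.0 / (self.on_rate * n_reach))
                if t_bind * v_free <= hop:
                    self.time += t_bind
                    self.state = replace(
                        self.state, centre_x=self.state.centre_x + t_bind * v_free
                    )
                    free = np.flatnonzero(
                        self._in_reach_mask() & (self.site_state == _UNBOUND)
                    )
                    sid = int(self.rng.choice(free))
                    self._bind_site(sid)
                    self.log.append(self.time, "form", sid, 0.0)
                    return True
            self.time += hop / v_free
            self.state = replace(self.state, centre_x=self.state.centre_x + hop)
            travelled += hop
        self.termination = "detached"
        self._times.append(self.time)
        self._xs.append(self.state.centre_x)
        return False

    def _take_snapshot(self) -> None:
        bound = self._bound_idx
        rel = self.site_xy[bound] - np.array([self.state.centre_x, 0.0])
        self.snapshots.append(
            (self.time, rel, self.site_state[bound].copy(), self._tensions.copy())
        )

    def run(self) -> None:
        while self.steps_done < self.cfg.n_steps and self.termination is None:
            if self.step() is None:
                break
        if self.termination is None:
            self.termination = "completed"

    def trajectory(self) -> Trajectory:
        meta = {
            "seed": self.seed,
            "shear_rate": self.cfg.shear_rate,
            "mechanotype": getattr(self.bond, "label", "unknown"),
            "n_steps": self.steps_done,
            "termination": self.termination,
            "source": "simulated",
            "dt": None,
        }
        return Trajectory(np.array(self._times), np.array(self._xs), meta)


def run_simulation(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[Trajectory, EventLog, RollingSimulation]:
    """Run one rolling-adhesion KMC simulation to completion.

    Returns the displacement trajectory, the event log and the final
    simulation object (for state inspection and replay checks).
    """
    sim = RollingSimulation(cfg, seed=seed)
    sim.run()
    traj = sim.trajectory()
    traj.metadata["seed"] = cfg.seed if seed is None else seed
    return traj, sim.log, sim


def accumulate_heatmap(
    cfg: SimulationConfig,
    n_repeats: int | None = None,
    extent: float = 1.0,
    bin_size: float = 0.05,
) -> ActivationHeatmap:
    """Average weak/strong bond localization over repeated catch-bond runs.

    Every ``cfg.snapshot_interval`` steps the substrate-anchor position of
    each bound tether (relative to the particle centre, x downstream), its
    state and its tension are recorded; observations are pooled over
    ``n_repeats`` runs seeded ``cfg.seed + i``.

    Raises
    ------
    ValueError
        If the configured bond is not a catch bond (weak/strong states are
        undefined for slip bonds).
    """
    bond = cfg.resolve_bond()
    if not isinstance(bond, CatchBondParams):
        raise ValueError("activation heatmap requires a catch-bond mechanotype")
    n_repeats = cfg.n_repeats if n_repeats is None else n_repeats
    hm = ActivationHeatmap.empty(extent=extent, bin_size=bin_size)
    run_cfg = replace(cfg, collect_snapshots=True)
    for i in range(n_repeats):
        sim = RollingSimulation(run_cfg, seed=(cfg.seed + i) % (2**31))
        sim.run()
        for _, rel, states, tension in sim.snapshots:
            for code, name in ((_WEAK, "weak"), (_STRONG, "strong")):
                m = states == code
                if m.any():
                    hm.add(name, rel[m, 0], rel[m, 1], tension[m])
    return hm


def sample_bond_lifetimes(
    p: BondParams,
    force: float,
    n: int,
    rng: np.random.Generator,
    env: Environment | None = None,
    start_state: BondState | str = BondState.WEAK,
) -> np.ndarray:
    """Gillespie-sample ``n`` single-bond lifetimes at constant tension.

    This is the stochastic route to the same quantity that
    :func:`catchroll.bonds.mean_lifetime` computes by a linear solve; the two
    must agree within Monte Carlo error.
    """
    env = env or Environment()
    if isinstance(p, SlipBondParams):
        k = bell_rate(p.off, force, env)
        return rng.exponential(1.0 / k, n)

    kw = bell_rate(p.off_weak, force, env)
    kic = bell_rate(p.interconvert, force, env)
    krev = bell_rate(p.revert, force, env)
    ks = bell_rate(p.off_strong, force, env)

    t = np.zeros(n)
    state = np.full(
        n, _WEAK if BondState(start_state) is BondState.WEAK else _STRONG, dtype=np.int8
    )
    alive = np.ones(n, dtype=bool)
    while alive.any():
        idx = np.flatnonzero(alive)
        s = state[idx]
        total = np.where(s == _WEAK, kw + kic, ks + krev)
        t[idx] += rng.exponential(1.0, idx.size) / total
        u = rng.uniform(0.0, 1.0, idx.size)
        p_off = np.where(s == _WEAK, kw, ks) / total
        dissociate = u < p_off
        alive[idx[dissociate]] = False
        switch = idx[~dissociate]
        state[switch] = np.where(state[switch] == _WEAK, _STRONG, _WEAK)
    return t
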