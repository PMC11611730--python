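"""Hydrodynamic loading and quasi-static force balance of a tethered sphere.

A rigid sphere of radius R sits at a fixed clearance above the channel wall in
a linear shear flow.  The flow exerts a drag force along x and a torque about
the transverse (y) axis, both with the standard wall-correction factors for a
sphere adjacent to a plane wall in linear shear (F = 1.7009 * 6 pi eta R^2
gdot, M = 0.9440 * 4 pi eta R^3 gdot).

The particle has two generalized coordinates: downstream displacement
``centre_x`` and rolling rotation about y.  Tethers are Hookean,
tension-only springs between a substrate anchor in the (x, y) plane and a
body-fixed anchor on the sphere surface.  ``equilibrate`` finds the
configuration where net tether force along x and net torque about y balance
the hydrodynamic load, by damped Newton iteration with an energy-minimisation
fallback.

Units: lengths um, forces pN, torques pN um, angles rad.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .bonds import BondState
from .environment import Environment

__all__ = [
    "ParticleGeometry",
    "ShearLoad",
    "Tether",
    "ParticleState",
    "TetherSystem",
    "shear_load",
    "tether_tension",
    "equilibrate",
    "EquilibrationError",
]

# Goldman–Cox–Brenner wall-correction constants for a stationary sphere
# touching a plane wall in linear shear flow.
WALL_CORRECTION_FORCE = 1.7009
WALL_CORRECTION_TORQUE = 0.9440


class EquilibrationError(RuntimeError):
    """Force balance could not be achieved (detachment or non-convergence)."""


@dataclass(frozen=True)
class ParticleGeometry:
    """Sphere radius and fixed sphere-wall clearance, in um."""

    radius: float = 0.68
    gap_height: float = 0.02

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not self.gap_height >= 0:
            raise ValueError("gap_height must be >= 0")

    @property
    def centre_height(self) -> float:
        """Height of the sphere centre above the wall (um)."""
        return self.radius + self.gap_height


@dataclass(frozen=True)
class ShearLoad:
    """Hydrodynamic load on the particle at a given wall shear rate."""

    shear_rate: float
    force_x: float
    torque_y: float


def shear_load(shear_rate: float, env: Environment, geom: ParticleGeometry) -> ShearLoad:
    """Wall-corrected shear force (pN) and torque (pN um) on the sphere.

    F_shear = 1.7009 * 6 pi eta R^2 gdot,  M = 0.9440 * 4 pi eta R^3 gdot.
    Both scale linearly with the shear rate.
    """
    if not shear_rate >= 0:
        raise ValueError(f"shear_rate must be >= 0, got {shear_rate}")
    r_m = geom.radius * 1e-6
    # force in N -> pN;  torque in N m -> pN um
    f = WALL_CORRECTION_FORCE * 6.0 * math.pi * env.viscosity * r_m**2 * shear_rate
    m = WALL_CORRECTION_TORQUE * 4.0 * math.pi * env.viscosity * r_m**3 * shear_rate
    return ShearLoad(shear_rate=shear_rate, force_x=f * 1e12, torque_y=m * 1e18)


@dataclass
class Tether:
    """A single surface tether.

    ``substrate_anchor`` is (x, y) in the lab frame on the wall plane;
    ``sphere_anchor`` is a unit vector in the body frame pointing from the
    sphere centre to the attachment point on the surface.
    """

    substrate_anchor: tuple[float, float]
    sphere_anchor: tuple[float, float, float]
    state: BondState = BondState.SLIP_BOUND
    rest_length: float = 0.04
    stiffness: float = 150.0
    id: int = -1

    def __post_init__(self) -> None:
        n = math.sqrt(sum(c * c for c in self.sphere_anchor))
        if abs(n - 1.0) > 1e-9:
            raise ValueError("sphere_anchor must be a unit vector")
        if not self.stiffness > 0:
            raise ValueError("stiffness must be positive")


@dataclass(frozen=True)
class ParticleState:
    """Generalized coordinates: downstream position (um) and rolling angle (rad)."""

    centre_x: float = 0.0
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.centre_x) and math.isfinite(self.rotation)):
            raise ValueError("particle state must be finite")


def _anchor_positions(
    u: np.ndarray, s: ParticleState, geom: ParticleGeometry
) -> np.ndarray:
    """Lab-frame positions of body-frame unit anchors ``u`` (n x 3)."""
    c, th = s.centre_x, s.rotation
    ct, st = math.cos(th), math.sin(th)
    # Rolling-positive rotation about +y: a point at the bottom of the sphere
    # moves upstream (-x) as rotation increases, i.e. the surface rolls
    # forward.
    x = u[:, 0] * ct + u[:, 2] * st
    z = -u[:, 0] * st + u[:, 2] * ct
    r = geom.radius
    out = np.empty_like(u)
    out[:, 0] = c + r * x
    out[:, 1] = r * u[:, 1]
    out[:, 2] = geom.centre_height + r * z
    return out


def tether_tension(
    t: Tether, s: ParticleState, geom: ParticleGeometry
) -> tuple[float, float, np.ndarray]:
    """Extension (um), tension (pN) and pulling direction of one tether.

    The tether is a Hookean, tension-only spring: tension =
    stiffness * max(0, length - rest_length).  The direction is the unit
    vector from the sphere attachment point towards the substrate anchor
    (the direction in which the tether pulls the particle); for a fully
    slack or zero-length tether the direction is the zero vector.
    """
    if t.state is BondState.UNBOUND:
        raise ValueError("tether_tension called on an unbound tether")
    u = np.asarray([t.sphere_anchor], dtype=float)
    a = _anchor_positions(u, s, geom)[0]
    sub = np.array([t.substrate_anchor[0], t.substrate_anchor[1], 0.0])
    d = sub - a
    length = float(np.linalg.norm(d))
    ext = length - t.rest_length
    tension = t.stiffness * max(0.0, ext)
    direction = d / length if (length > 0 and tension > 0) else np.zeros(3)
    return ext, tension, direction


class TetherSystem:
    """Array-backed collection of bound tethers for fast force evaluation.

    Kept deliberately simple: parallel numpy arrays of substrate anchors,
    body-frame anchors, rest lengths, stiffnesses and ids.
    """

    def __init__(self, tethers: Sequence[Tether] = ()):  # noqa: D107
        self.tethers: list[Tether] = list(tethers)
        self._sync()

    def _sync(self) -> None:
        n = len(self.tethers)
        self.sub = np.zeros((n, 3))
        self.u = np.zeros((n, 3))
        self.L0 = np.zeros(n)
        self.kappa = np.zeros(n)
        for i, t in enumerate(self.tethers):
            self.sub[i, :2] = t.substrate_anchor
            self.u[i] = t.sphere_anchor
            self.L0[i] = t.rest_length
            self.kappa[i] = t.stiffness

    def __len__(self) -> int:
        return int(self.L0.size)

    def forces(
        self, s: ParticleState, geom: ParticleGeometry
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-tether tension forces.

        Returns ``(F, a, tension)``: n x 3 force vectors on the particle,
        n x 3 lab-frame attachment points, and n tensions (pN).
        """
        a = _anchor_positions(self.u, s, geom)
        d = self.sub - a
        length = np.linalg.norm(d, axis=1)
        ext = length - self.L0
        tension = self.kappa * np.maximum(0.0, ext)
        with np.errstate(invalid="ignore", divide="ignore"):
            dhat = np.where(length[:, None] > 0, d / length[:, None], 0.0)
        return tension[:, None] * dhat, a, tension

    def tensions(self, s: ParticleState, geom: ParticleGeometry) -> np.ndarray:
        return self.forces(s, geom)[2]


def _residual_and_jacobian(
    sys_: TetherSystem,
    s: ParticleState,
    load: ShearLoad,
    geom: ParticleGeometry,
):
    """Generalized force residual g = (Fx_net, My_net) and its Jacobian."""
    a = _anchor_positions(sys_.u, s, geom)
    centre = np.array([s.centre_x, 0.0, geom.centre_height])
    r = a - centre
    d = sys_.sub - a
    length = np.linalg.norm(d, axis=1)
    ext = length - sys_.L0
    active = ext > 0
    tension = np.where(active, sys_.kappa * ext, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dhat = np.where(length[:, None] > 0, d / length[:, None], 0.0)
    F = tension[:, None] * dhat

    w = np.stack([r[:, 2], np.zeros(len(sys_)), -r[:, 0]], axis=1)
    g1 = F[:, 0].sum() + load.force_x
    g2 = (w[:, 0] * F[:, 0] + w[:, 2] * F[:, 2]).sum() + load.torque_y

    # dF/da = -K,  K = kappa*active*dhat dhat^T + (T/L)(I - dhat dhat^T)
    with np.errstate(invalid="ignore", divide="ignore"):
        tl = np.where(length > 0, tension / length, 0.0)
    kd = np.where(active, sys_.kappa, 0.0)
    # e1^T K e1, e1^T K w, w^T K w  (only x and z components matter: w_y = 0)
    def quad(vax, vaz, vbx, vbz):
        va_d = vax * dhat[:, 0] + vaz * dhat[:, 2]
        vb_d = vbx * dhat[:, 0] + vbz * dhat[:, 2]
        va_vb = vax * vbx + vaz * vbz
        return kd * va_d * vb_d + tl * (va_vb - va_d * vb_d)

    ones = np.ones(len(sys_))
    zeros = np.zeros(len(sys_))
    j11 = -quad(ones, zeros, ones, zeros).sum()
    j12 = -quad(ones, zeros, w[:, 0], w[:, 2]).sum()
    j22 = -quad(w[:, 0], w[:, 2], w[:, 0], w[:, 2]).sum() + (
        -r[:, 0] * F[:, 0] - r[:, 2] * F[:, 2]
    ).sum()
    jac = np.array([[j11, j12], [j12, j22]])
    # J21 = J12 from the spring part; the geometric (dw/dtheta) term enters
    # only J22.
    jac[1, 0] = j12
    return np.array([g1, g2]), jac


def _energy(sys_: TetherSystem, q, load, geom) -> float:
    s = ParticleState(centre_x=q[0], rotation=q[1])
    a = _anchor_positions(sys_.u, s, geom)
    d = sys_.sub - a
    length = np.linalg.norm(d, axis=1)
    ext = np.maximum(0.0, length - sys_.L0)
    return float(
        0.5 * (sys_.kappa * ext**2).sum() - load.force_x * q[0] - load.torque_y * q[1]
    )


def equilibrate(
    tethers: Sequence[Tether] | TetherSystem,
    s0: ParticleState,
    load: ShearLoad,
    geom: ParticleGeometry,
    tol: float = 1e-6,
    max_iter: int = 200,
    free_rotation: bool = True,
) -> ParticleState:
    """Quasi-static mechanical equilibrium of the particle.

    Finds (centre_x, rotation) where the net tether force along x and net
    torque about y cancel the hydrodynamic load, to residuals below ``tol``
    (pN and pN um respectively).  Damped Newton iteration, falling back to
    elastic-energy minimisation (BFGS on the tension-only spring energy) if
    Newton fails to converge.

    With ``free_rotation=False`` the rotation is frozen at ``s0.rotation``
    and only the translational force balance is solved (the torque residual
    is then not driven to zero).

    Raises
    ------
    EquilibrationError
        If no tether is bound, or the solver does not converge.
    """
    sys_ = tethers if isinstance(tethers, TetherSystem) else TetherSystem(tethers)
    if len(sys_) == 0:
        raise EquilibrationError("no bound tethers: particle has detached")
    if not tol > 0:
        raise ValueError("tol must be positive")
    if not free_rotation:
        return _equilibrate_translation(sys_, s0, load, geom, tol, max_iter)

    q = np.array([s0.centre_x, s0.rotation])
    g, jac = _residual_and_jacobian(
        sys_, ParticleState(q[0], q[1]), load, geom
    )
    gn = np.abs(g).max()
    for _ in range(max_iter):
        if gn <= tol:
            return ParticleState(centre_x=float(q[0]), rotation=float(q[1]))
        try:
            step = np.linalg.solve(jac, -g)
        except np.linalg.LinAlgError:
            # singular stiffness (all tethers slack): nudge along the load
            # until a tether engages
            step = g * (0.01 / max(1.0, np.abs(g).max()))
        # cap the step to stay within the smooth region of the spring network
        cap = max(geom.radius, 1.0)
        norm = np.abs(step).max()
        if norm > cap:
            step *= cap / norm
        lam = 1.0
        for _bt in range(30):
            q_new = q + lam * step
            g_new, jac_new = _residual_and_jacobian(
                sys_, ParticleState(q_new[0], q_new[1]), load, geom
            )
            if np.abs(g_new).max() < gn:
                q, g, jac, gn = q_new, g_new, jac_new, np.abs(g_new).max()
                break
            lam *= 0.5
        else:
            break  # no descent: fall back to energy minimisation

    if gn > tol:
        def grad(x):
            g_, _ = _residual_and_jacobian(
                sys_, ParticleState(x[0], x[1]), load, geom
            )
            return -g_

        res = minimize(
            lambda x: _energy(sys_, x, load, geom),
            q,
            jac=grad,
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        q = res.x
        for _ in range(max_iter):
            g, jac = _residual_and_jacobian(
                sys_, ParticleState(q[0], q[1]), load, geom
            )
            gn = np.abs(g).max()
            if gn <= tol:
                return ParticleState(centre_x=float(q[0]), rotation=float(q[1]))
            try:
                step = np.linalg.solve(jac, -g)
            except np.linalg.LinAlgError:
                break
            if np.abs(step).max() > geom.radius:
                step *= geom.radius / np.abs(step).max()
            q = q + step
        g, _ = _residual_and_jacobian(sys_, ParticleState(q[0], q[1]), load, geom)
        if np.abs(g).max() > tol:
            raise EquilibrationError(
                f"force balance did not converge: residual {np.abs(g).max():.3g} "
                f"(tol {tol}), {len(sys_)} tethers, load {load.force_x:.3g} pN"
            )
    return ParticleState(centre_x=float(q[0]), rotation=float(q[1]))


def _equilibrate_translation(
    sys_: TetherSystem,
    s0: ParticleState,
    load: ShearLoad,
    geom: ParticleGeometry,
    tol: float,
    max_iter: int,
) -> ParticleState:
    """1-D Newton on centre_x with the rotation frozen."""
    cx = s0.centre_x
    for _ in range(max_iter):
        g, jac = _residual_and_jacobian(
            sys_, ParticleState(cx, s0.rotation), load, geom
        )
        if abs(g[0]) <= tol:
            return ParticleState(centre_x=float(cx), rotation=s0.rotation)
        d = jac[0, 0]
        step = -g[0] / d if abs(d) > 1e-300 else g[0] * 0.01 / max(1.0, abs(g[0]))
        step = float(np.clip(step, -geom.radius, geom.radius))
        cx += step
    raise EquilibrationError(
        f"translational balance did not converge: residual {g[0]:.3g}"
    )
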