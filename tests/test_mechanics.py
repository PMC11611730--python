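"""Hydrodynamic loading and quasi-static tether force balance."""

import math

import numpy as np
import pytest

from catchroll import (
    Environment,
    ParticleState,
    ShearLoad,
    Tether,
    TetherSystem,
    equilibrate,
    shear_load,
    tether_tension,
)
from catchroll.bonds import BondState
from catchroll.mechanics import (
    EquilibrationError,
    WALL_CORRECTION_FORCE,
    WALL_CORRECTION_TORQUE,
)


class TestShearLoad:
    def test_zero_shear_zero_load(self, env, geom):
        ld = shear_load(0.0, env, geom)
        assert ld.force_x == 0.0 and ld.torque_y == 0.0

    def test_wall_corrected_closed_form(self, env, geom):
        # 1.36-um particle in water at the heatmap shear rate
        ld = shear_load(560.0, env, geom)
        r = geom.radius * 1e-6
        f_expected = (
            WALL_CORRECTION_FORCE * 6 * math.pi * env.viscosity * r**2 * 560.0 * 1e12
        )
        m_expected = (
            WALL_CORRECTION_TORQUE * 4 * math.pi * env.viscosity * r**3 * 560.0 * 1e18
        )
        assert ld.force_x == pytest.approx(f_expected, rel=1e-12)
        assert ld.torque_y == pytest.approx(m_expected, rel=1e-12)
        assert ld.force_x == pytest.approx(8.3, abs=0.05)

    def test_linearity_in_shear_rate(self, env, geom):
        a = shear_load(280.0, env, geom)
        b = shear_load(560.0, env, geom)
        assert b.force_x == pytest.approx(2 * a.force_x, rel=1e-12)
        assert b.torque_y == pytest.approx(2 * a.torque_y, rel=1e-12)

    def test_negative_shear_rejected(self, env, geom):
        with pytest.raises(ValueError):
            shear_load(-1.0, env, geom)


def _bottom_tether(geom, rest_length=None, stiffness=100.0, anchor=(0.0, 0.0)):
    rest = geom.gap_height if rest_length is None else rest_length
    return Tether(
        substrate_anchor=anchor,
        sphere_anchor=(0.0, 0.0, -1.0),
        state=BondState.SLIP_BOUND,
        rest_length=rest,
        stiffness=stiffness,
    )


class TestTetherTension:
    def test_at_rest_length_no_tension(self, geom):
        t = _bottom_tether(geom)
        ext, tension, _ = tether_tension(t, ParticleState(), geom)
        assert ext == pytest.approx(0.0, abs=1e-12)
        assert tension == pytest.approx(0.0, abs=1e-9)

    def test_slack_tether_carries_no_force(self, geom):
        t = _bottom_tether(geom, rest_length=geom.gap_height + 0.1)
        ext, tension, direction = tether_tension(t, ParticleState(), geom)
        assert ext < 0 and tension == 0.0
        assert np.all(direction == 0.0)

    def test_hookean_tension_along_end_to_end_direction(self, geom):
        # 0.05 um extension at 100 pN/um must give 5 pN straight down
        t = _bottom_tether(geom, rest_length=geom.gap_height - 0.05)
        ext, tension, direction = tether_tension(t, ParticleState(), geom)
        assert ext == pytest.approx(0.05, abs=1e-12)
        assert tension == pytest.approx(5.0, rel=1e-12)
        assert direction == pytest.approx([0.0, 0.0, -1.0])

    def test_unbound_tether_rejected(self, geom):
        t = _bottom_tether(geom)
        t.state = BondState.UNBOUND
        with pytest.raises(ValueError):
            tether_tension(t, ParticleState(), geom)


def _random_taut_tethers(rng, geom, n, stiffness=200.0):
    """Bound tethers anchored under the sphere, pre-tensioned by shortening."""
    tethers = []
    for _ in range(n):
        r = rng.uniform(0.0, 0.22)
        phi = rng.uniform(0, 2 * math.pi)
        sx, sy = r * math.cos(phi), r * math.sin(phi)
        centre = np.array([0.0, 0.0, geom.centre_height])
        site = np.array([sx, sy, 0.0])
        v = site - centre
        dist = np.linalg.norm(v)
        u = v / dist
        tethers.append(
            Tether(
                substrate_anchor=(sx, sy),
                sphere_anchor=tuple(u),
                rest_length=float(dist - geom.radius) * rng.uniform(0.6, 1.0),
                stiffness=stiffness,
            )
        )
    return tethers


def _net_generalized_force(tethers, state, load, geom):
    """Independent recomputation of the residual via tether_tension."""
    fx = load.force_x
    my = load.torque_y
    centre = np.array([state.centre_x, 0.0, geom.centre_height])
    for t in tethers:
        _, tension, direction = tether_tension(t, state, geom)
        if tension == 0:
            continue
        u = np.asarray([t.sphere_anchor])
        from catchroll.mechanics import _anchor_positions

        a = _anchor_positions(u, state, geom)[0]
        r = a - centre
        f = tension * direction
        fx += f[0]
        my += r[2] * f[0] - r[0] * f[2]
    return fx, my


class TestEquilibrate:
    def test_zero_load_at_rest_returns_initial_state(self, geom):
        t = _bottom_tether(geom)
        s0 = ParticleState()
        load = ShearLoad(0.0, 0.0, 0.0)
        s = equilibrate([t], s0, load, geom)
        assert s.centre_x == pytest.approx(s0.centre_x, abs=1e-9)
        assert s.rotation == pytest.approx(s0.rotation, abs=1e-9)

    def test_one_dimensional_balance_matches_bisection_oracle(self, geom):
        # rotation frozen: displacement solves a scalar force balance that a
        # bisection oracle can find independently
        t = _bottom_tether(geom, rest_length=geom.gap_height, stiffness=300.0)
        load = ShearLoad(0.0, 2.0, 0.0)  # 2 pN downstream, no torque
        s = equilibrate([t], ParticleState(), load, geom, free_rotation=False)

        def residual_x(cx):
            st = ParticleState(centre_x=cx, rotation=0.0)
            _, tension, direction = tether_tension(t, st, geom)
            return tension * direction[0] + load.force_x

        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if residual_x(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert s.centre_x == pytest.approx(0.5 * (lo + hi), abs=1e-6)
        # displacement approximates F/kappa_effective for the engaged tether
        assert 0 < s.centre_x < 0.2

    def test_postcondition_replay_on_random_configs(self, geom, rng):
        env = Environment()
        for trial in range(20):
            tethers = _random_taut_tethers(rng, geom, n=int(rng.integers(2, 9)))
            load = shear_load(float(rng.uniform(50, 700)), env, geom)
            s = equilibrate(tethers, ParticleState(), load, geom, tol=1e-6)
            fx, my = _net_generalized_force(tethers, s, load, geom)
            assert abs(fx) <= 2e-6 and abs(my) <= 2e-6

    def test_force_closure_along_flow(self, geom, rng):
        env = Environment()
        tethers = _random_taut_tethers(rng, geom, n=6)
        load = shear_load(400.0, env, geom)
        s = equilibrate(tethers, ParticleState(), load, geom)
        fx_bonds = sum(
            tether_tension(t, s, geom)[1] * tether_tension(t, s, geom)[2][0]
            for t in tethers
        )
        assert fx_bonds == pytest.approx(-load.force_x, abs=2e-6)

    def test_permutation_symmetry(self, geom, rng):
        env = Environment()
        tethers = _random_taut_tethers(rng, geom, n=5)
        load = shear_load(300.0, env, geom)
        s1 = equilibrate(tethers, ParticleState(), load, geom)
        s2 = equilibrate(tethers[::-1], ParticleState(), load, geom)
        assert s1.centre_x == pytest.approx(s2.centre_x, abs=1e-8)
        assert s1.rotation == pytest.approx(s2.rotation, abs=1e-8)

    def test_releasing_trailing_tether_ratchets_forward(self, geom, rng):
        env = Environment()
        load = shear_load(400.0, env, geom)
        for _ in range(5):
            tethers = _random_taut_tethers(rng, geom, n=6)
            s = equilibrate(tethers, ParticleState(), load, geom)
            # most-loaded tether is the one carrying the largest tension
            tensions = [tether_tension(t, s, geom)[1] for t in tethers]
            drop = int(np.argmax(tensions))
            remaining = [t for i, t in enumerate(tethers) if i != drop]
            s2 = equilibrate(remaining, s, load, geom)
            assert s2.centre_x >= s.centre_x - 1e-9

    def test_no_bound_tethers_is_detachment(self, geom):
        with pytest.raises(EquilibrationError):
            equilibrate([], ParticleState(), ShearLoad(0, 0, 0), geom)

    def test_fast_kernel_agrees_with_reference_solver(self, geom, rng):
        from catchroll._fast import newton_equilibrate

        env = Environment()
        for _ in range(10):
            tethers = _random_taut_tethers(rng, geom, n=int(rng.integers(2, 8)))
            load = shear_load(float(rng.uniform(100, 600)), env, geom)
            sys_ = TetherSystem(tethers)
            s_ref = equilibrate(sys_, ParticleState(), load, geom, tol=1e-9)
            cx, th, resid, ok = newton_equilibrate(
                np.ascontiguousarray(sys_.sub[:, :2]),
                sys_.u,
                sys_.L0,
                sys_.kappa,
                0.0,
                0.0,
                load.force_x,
                load.torque_y,
                geom.centre_height,
                geom.radius,
                1e-9,
                200,
            )
            assert ok
            assert cx == pytest.approx(s_ref.centre_x, abs=1e-6)
            assert th == pytest.approx(s_ref.rotation, abs=1e-6)
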