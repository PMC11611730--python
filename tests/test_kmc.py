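"""Gillespie engine: event enumeration, sampling statistics, full rolling runs."""

import numpy as np
import pytest

from catchroll import (
    BellTransition,
    SimulationConfig,
    SlipBondParams,
    gillespie_step,
    mean_lifetime,
    run_simulation,
)
from catchroll.bonds import BondState
from catchroll.kmc import (
    ActivationHeatmap,
    NoEventPossible,
    RollingSimulation,
    sample_bond_lifetimes,
)


def _small_cfg(**kw):
    defaults = dict(bond="catch", shear_rate=400.0, n_steps=500, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGillespieStep:
    def test_selection_frequencies_match_binomial(self, rng):
        p = np.array([1.0, 3.0])
        picks = np.array([gillespie_step(p, rng)[1] for _ in range(100_000)])
        freq_b = (picks == 1).mean()
        se = np.sqrt(0.75 * 0.25 / picks.size)
        assert abs(freq_b - 0.75) < 3 * se

    def test_waiting_time_is_exponential_in_total_rate(self, rng):
        lam = 4.0
        dts = np.array(
            [gillespie_step(np.array([lam]), rng)[0] for _ in range(100_000)]
        )
        se = dts.std(ddof=1) / np.sqrt(dts.size)
        assert abs(dts.mean() - 1 / lam) < 3 * se

    def test_deterministic_replay_with_fixed_seed(self):
        p = np.array([0.5, 1.5, 2.0])
        a = [gillespie_step(p, np.random.default_rng(3)) for _ in range(1)]
        b = [gillespie_step(p, np.random.default_rng(3)) for _ in range(1)]
        assert a == b

    def test_zero_total_propensity_signals_absorbing_state(self, rng):
        with pytest.raises(NoEventPossible):
            gillespie_step(np.array([0.0, 0.0]), rng)

    def test_negative_propensity_rejected(self, rng):
        with pytest.raises(ValueError):
            gillespie_step(np.array([1.0, -0.5]), rng)


class TestEnumerateEvents:
    def test_single_slip_bond_no_free_sites(self):
        sim = RollingSimulation(_small_cfg(bond="slip"))
        # keep exactly one bound tether and hide every unbound site
        bound = np.flatnonzero(sim.site_state > 0)
        sim.site_state[bound[1:]] = 0
        sim.site_alive[sim.site_state == 0] = False
        sim._rebuild_bound()
        sim._equilibrate()
        events = sim.enumerate_events()
        assert len(events) == 1
        assert events[0][0].kind == "dissociate"

    def test_weak_catch_bond_offers_rupture_and_activation(self):
        sim = RollingSimulation(_small_cfg(bond="catch"))
        bound = np.flatnonzero(sim.site_state > 0)
        sim.site_state[bound[1:]] = 0
        sim.site_alive[sim.site_state == 0] = False
        sim._rebuild_bound()
        sim._equilibrate()
        kinds = sorted(ev.kind for ev, _ in sim.enumerate_events())
        assert kinds == ["activate", "dissociate"]

    def test_formation_propensity_sums_over_free_sites(self):
        p = SlipBondParams(off=BellTransition(1.0, 1.0), on_rate=2.0)
        sim = RollingSimulation(_small_cfg(bond=p))
        # exactly three free in-reach sites, one bound tether to keep the
        # particle attached
        bound = np.flatnonzero(sim.site_state > 0)
        sim.site_state[bound[1:]] = 0
        sim.site_alive[:] = False
        sim.site_alive[bound[0]] = True
        free = np.flatnonzero(sim._in_reach_mask() | (sim.site_state == 0))
        in_reach_free = [
            i for i in np.flatnonzero(sim.site_state == 0)
            if i != bound[0]
        ][:3]
        sim.site_alive[in_reach_free] = True
        sim._rebuild_bound()
        sim._equilibrate()
        total_form = sum(
            r for ev, r in sim.enumerate_events() if ev.kind == "form"
        )
        n_free = int(
            np.count_nonzero(sim._in_reach_mask() & (sim.site_state == 0))
        )
        assert total_form == pytest.approx(2.0 * n_free)

    def test_stale_tensions_rejected(self):
        sim = RollingSimulation(_small_cfg())
        sim._equilibrated = False
        with pytest.raises(RuntimeError, match="stale"):
            sim.enumerate_events()


class TestRunSimulation:
    def test_frozen_system_produces_constant_trajectory(self):
        frozen = SlipBondParams(off=BellTransition(0.0, 1.0), on_rate=0.0)
        traj, events, sim = run_simulation(_small_cfg(bond=frozen))
        assert sim.termination == "frozen"
        assert len(events) == 0
        assert np.all(traj.centre_x == traj.centre_x[0])

    def test_identical_seeds_give_bit_identical_trajectories(self):
        t1, e1, _ = run_simulation(_small_cfg(seed=42))
        t2, e2, _ = run_simulation(_small_cfg(seed=42))
        assert np.array_equal(t1.time, t2.time)
        assert np.array_equal(t1.centre_x, t2.centre_x)
        assert e1.kind == e2.kind and e1.tether_id == e2.tether_id

    def test_time_increases_and_motion_is_downstream(self):
        traj, _, _ = run_simulation(_small_cfg(bond="slip", n_steps=2000))
        assert np.all(np.diff(traj.time) >= 0)
        assert np.all(np.diff(traj.centre_x) >= -1e-6)

    def test_event_log_replay_reproduces_final_states(self):
        cfg = _small_cfg(bond="catch", n_steps=1500)
        sim0 = RollingSimulation(cfg)
        initial = sim0.tether_states()
        traj, events, sim = run_simulation(cfg)
        final = sim.tether_states()
        replayed = events.replay(initial, ground_state=BondState.WEAK)
        for sid, state in final.items():
            expected = replayed.get(sid, initial.get(sid, BondState.UNBOUND))
            assert state == expected, f"site {sid}: {state} != {expected}"

    def test_ensemble_mean_displacement_is_seed_independent(self):
        # two disjoint repeat batches must agree within Monte Carlo error
        def batch(seed0, n=8):
            out = []
            for i in range(n):
                traj, _, _ = run_simulation(
                    _small_cfg(bond="slip", n_steps=1500, seed=seed0 + i)
                )
                out.append(traj.centre_x[-1] / max(traj.time[-1], 1e-9))
            return np.array(out)

        a, b = batch(100), batch(900)
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_mean_displacement_increases_with_shear_for_slip(self):
        means = []
        for g in (250.0, 500.0):
            vs = []
            for i in range(6):
                traj, _, _ = run_simulation(
                    _small_cfg(bond="slip", shear_rate=g, n_steps=1500, seed=50 + i)
                )
                vs.append(traj.centre_x[-1] / max(traj.time[-1], 1e-9))
            means.append(np.mean(vs))
        assert means[1] > means[0]

    def test_single_bond_kmc_matches_mfpt(self, catch_params, env, rng):
        samples = sample_bond_lifetimes(catch_params, 12.0, 30_000, rng, env)
        mfpt = mean_lifetime(catch_params, 12.0, env, "weak")
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert abs(samples.mean() - mfpt) < 3 * se


class TestDetachmentPolicies:
    def test_terminate_policy_records_detachment(self):
        # high shear tears a slip-bonded particle off quickly
        traj, events, sim = run_simulation(
            _small_cfg(bond="slip", shear_rate=900.0, n_steps=5000, seed=2)
        )
        if sim.termination == "detached":
            assert sim.bound_count() == 0
        assert sim.termination in ("detached", "completed")

    def test_advect_policy_allows_recapture(self):
        cfg = _small_cfg(
            bond="slip", shear_rate=900.0, n_steps=5000, seed=2,
            detachment_policy="advect",
        )
        traj, events, sim = run_simulation(cfg)
        assert sim.termination in ("detached", "completed")
        assert np.all(np.diff(traj.centre_x) >= -1e-6)
        # same seed under terminate must not run longer than under advect
        _, _, sim_t = run_simulation(
            _small_cfg(bond="slip", shear_rate=900.0, n_steps=5000, seed=2)
        )
        assert sim.steps_done >= sim_t.steps_done


class TestActivationHeatmap:
    def test_single_observation_lands_in_its_bin(self):
        hm = ActivationHeatmap.empty(extent=1.0, bin_size=0.1)
        hm.add("weak", np.array([-0.35]), np.array([0.12]), np.array([4.0]))
        assert hm.total_count() == 1
        i = np.digitize(-0.35, hm.x_edges) - 1
        j = np.digitize(0.12, hm.y_edges) - 1
        assert hm.counts["weak"][i, j] == 1
        assert hm.mean_force("weak")[i, j] == pytest.approx(4.0)

    def test_counts_conserve_snapshot_observations(self):
        from catchroll.kmc import accumulate_heatmap

        cfg = _small_cfg(bond="catch", n_steps=4000, snapshot_interval=500)
        hm = accumulate_heatmap(cfg, n_repeats=2, extent=2.0, bin_size=0.05)
        total_obs = 0
        from dataclasses import replace

        for i in range(2):
            sim = RollingSimulation(
                replace(cfg, collect_snapshots=True), seed=(cfg.seed + i) % 2**31
            )
            sim.run()
            total_obs += sum(states.size for _, _, states, _ in sim.snapshots)
        assert hm.total_count() == total_obs

    def test_slip_mechanotype_rejected(self):
        from catchroll.kmc import accumulate_heatmap

        with pytest.raises(ValueError):
            accumulate_heatmap(_small_cfg(bond="slip"), n_repeats=1)
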