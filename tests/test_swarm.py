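import numpy as np
import pytest

from discswarm import (
    EdgeContour,
    ExplorationArea,
    InertiaSchedule,
    PolarGrid,
    SwarmConfig,
    edge_fitness,
    initialize_swarm,
    position_update,
    run_swarm,
    update_personal_best,
    update_subgroup_best,
    velocity_update,
)
from discswarm.polar import TWO_PI


class _OnesRng:
    """Stand-in RNG whose uniform draws are all exactly 1."""

    def random(self, shape=None):
        return np.ones(shape) if shape is not None else 1.0


def _flat_area(n_subgroups=4, rmin=1.0, rmax=101.0, value=0.0):
    grid = PolarGrid(center=(0.0, 0.0), rmin=rmin, rmax=rmax, delta_r=1.0,
                     delta_theta=TWO_PI / 360)
    fitness = np.full((grid.n_radial, grid.n_angular), value)
    return ExplorationArea(grid=grid, fitness=fitness, n_subgroups=n_subgroups)


class TestSwarmConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_subgroups=2),
            dict(n_particles=1),
            dict(iterations=0),
            dict(cp=-0.1),
            dict(inertia="exponential"),
            dict(velocity_clamp=0.0),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SwarmConfig(**kwargs)

    def test_unknown_inertia_error_lists_valid_names(self):
        with pytest.raises(ValueError, match="constant.*linear.*random.*chaotic"):
            SwarmConfig(inertia="bogus")


class TestInertiaSchedule:
    def test_linear_endpoints(self, rng):
        sched = InertiaSchedule(SwarmConfig(inertia="linear"), rng)
        assert sched(0, 100) == pytest.approx(0.9)
        assert sched(100, 100) == pytest.approx(0.4)

    def test_constant(self, rng):
        sched = InertiaSchedule(SwarmConfig(inertia="constant", omega=0.8), rng)
        assert all(sched(k, 100) == 0.8 for k in range(0, 101, 10))

    def test_random_range(self, rng):
        sched = InertiaSchedule(SwarmConfig(inertia="random"), rng)
        vals = np.array([sched(k % 100, 100) for k in range(500)])
        assert np.all((vals >= 0.5) & (vals <= 1.0))

    def test_chaotic_logistic_state_stays_in_unit_interval(self, rng):
        # the logistic-map state must not escape (0, 1) over a long run
        z = float(np.random.default_rng(99).random())
        for _ in range(1_000_000):
            z = 4.0 * z * (1.0 - z)
            if not (0.0 < z < 1.0):
                pytest.fail(f"logistic state left (0,1): {z}")

    def test_chaotic_weight_combines_state_and_draw(self, rng):
        sched = InertiaSchedule(SwarmConfig(inertia="chaotic"), rng)
        vals = [sched(k % 100, 100) for k in range(200)]
        assert all(0.0 < v < 1.0 for v in vals)
        assert np.std(vals) > 0.01  # actually varies


class TestInitialization:
    def test_same_label_particles_share_one_radius(self, small_area, small_config, rng):
        state = initialize_swarm(small_area, small_config, rng)
        spread = state.pos[0].max(axis=0) - state.pos[0].min(axis=0)
        np.testing.assert_array_equal(spread, 0.0)

    def test_radii_within_annulus_and_angles_at_midpoints(self, small_area, small_config, rng):
        g = small_area.grid
        state = initialize_swarm(small_area, small_config, rng)
        assert np.all((state.pos[0] >= g.rmin) & (state.pos[0] <= g.rmax))
        mid = (small_area.sector_edges[:-1] + small_area.sector_edges[1:]) / 2
        np.testing.assert_allclose(
            state.pos[1], np.broadcast_to(mid[:, None], state.pos[1].shape)
        )
        np.testing.assert_array_equal(state.vel, 0.0)

    def test_fixed_seed_reproducible(self, small_area, small_config):
        s1 = initialize_swarm(small_area, small_config, np.random.default_rng(5))
        s2 = initialize_swarm(small_area, small_config, np.random.default_rng(5))
        np.testing.assert_array_equal(s1.pos, s2.pos)
        np.testing.assert_array_equal(s1.pbest_val, s2.pbest_val)

    def test_subgroup_best_is_best_personal_best(self, small_area, small_config, rng):
        state = initialize_swarm(small_area, small_config, rng)
        np.testing.assert_array_equal(state.gbest_val, state.pbest_val.max(axis=1))


class TestVelocityUpdate:
    def test_pure_inertia(self):
        area = _flat_area()
        cfg = SwarmConfig(n_subgroups=4, n_particles=2, cp=0, cg=0, ca=0,
                          omega=1.0, velocity_clamp=1.0)
        pos = np.zeros((2, 4, 2))
        pos[0] = 50.0
        pos[1] = np.array([0.5, 2.0, 3.5, 5.0])[:, None]
        vel = np.full((2, 4, 2), 0.25)
        v = velocity_update(pos, vel, pos.copy(), pos[:, :, 0].copy(), 1.0, area, cfg,
                            np.random.default_rng(0))
        np.testing.assert_array_equal(v, vel)

    def test_converged_fixed_point(self):
        area = _flat_area()
        cfg = SwarmConfig(n_subgroups=4, n_particles=2)
        pos = np.zeros((2, 4, 2))
        pos[0] = 60.0
        pos[1] = 1.0
        vel = np.zeros_like(pos)
        v = velocity_update(pos, vel, pos.copy(), pos[:, :, 0].copy(), 0.8, area, cfg,
                            np.random.default_rng(0))
        np.testing.assert_array_equal(v, 0.0)

    def test_hand_evaluated_radial_case(self):
        # all rand forced to 1: v = 0.8*0 + 1.7*(55-50) + 1.7*(60-50)
        #                         + 0.3*(54-50) + 0.3*(52-50) = 27.3
        area = _flat_area(n_subgroups=3)
        cfg = SwarmConfig(n_subgroups=3, n_particles=2, velocity_clamp=1.0)
        pos = np.zeros((2, 3, 2))
        pos[0, :, 0] = [50.0, 54.0, 52.0]  # neighbors of subgroup 0: 54 (right), 52 (left)
        pos[1] = np.array([1.0, 3.0, 5.0])[:, None]
        vel = np.zeros_like(pos)
        pbest = pos.copy()
        pbest[0, 0, 0] = 55.0
        gbest = pos[:, :, 0].copy()
        gbest[0, 0] = 60.0
        v = velocity_update(pos, vel, pbest, gbest, 0.8, area, cfg, _OnesRng())
        assert v[0, 0, 0] == pytest.approx(27.3)

    def test_ca_zero_reduces_to_standard_pso_bitwise(self):
        # independent implementation of the standard velocity rule
        def standard_pso(pos, vel, pbest, gbest, omega, cp, cg, vmax, rng):
            dp = pbest - pos
            dg = gbest[:, :, None] - pos
            dp[1] = (dp[1] + np.pi) % (2 * np.pi) - np.pi
            dg[1] = (dg[1] + np.pi) % (2 * np.pi) - np.pi
            v = omega * vel + cp * rng.random(pos.shape) * dp + cg * rng.random(pos.shape) * dg
            v[0] = np.clip(v[0], -vmax[0], vmax[0])
            v[1] = np.clip(v[1], -vmax[1], vmax[1])
            return v

        area = _flat_area(n_subgroups=4)
        cfg = SwarmConfig(n_subgroups=4, n_particles=5, ca=0.0)
        g = area.grid
        vmax = (cfg.velocity_clamp * (g.rmax - g.rmin),
                cfg.velocity_clamp * (2 * np.pi / 4))
        state_rng = np.random.default_rng(2024)
        for _ in range(1000):
            pos = np.empty((2, 4, 5))
            pos[0] = state_rng.uniform(g.rmin, g.rmax, (4, 5))
            pos[1] = state_rng.uniform(0, 2 * np.pi, (4, 5))
            vel = state_rng.normal(0, 3, (2, 4, 5))
            pbest = pos + state_rng.normal(0, 2, pos.shape)
            gbest = pos[:, :, 0] + state_rng.normal(0, 2, (2, 4))
            omega = float(state_rng.uniform(0.2, 1.0))
            seed = int(state_rng.integers(0, 2**31))
            v_ours = velocity_update(pos, vel, pbest, gbest, omega, area, cfg,
                                     np.random.default_rng(seed))
            v_ref = standard_pso(pos, vel, pbest, gbest, omega, cfg.cp, cfg.cg, vmax,
                                 np.random.default_rng(seed))
            np.testing.assert_array_equal(v_ours, v_ref)

    def test_velocity_clamped_to_fraction_of_extents(self):
        area = _flat_area(n_subgroups=4)
        cfg = SwarmConfig(n_subgroups=4, n_particles=2, velocity_clamp=0.2)
        pos = np.zeros((2, 4, 2))
        pos[0] = 1.0  # rmin; bests far away force a large pull
        pos[1] = 0.1
        pbest = pos.copy()
        pbest[0] += 100.0
        v = velocity_update(pos, np.zeros_like(pos), pbest, pos[:, :, 0].copy(),
                            0.8, area, cfg, _OnesRng())
        assert np.all(np.abs(v[0]) <= 0.2 * (area.grid.rmax - area.grid.rmin) + 1e-12)


class TestPositionUpdate:
    def test_zero_velocity_keeps_position(self, small_area, small_config, rng):
        state = initialize_swarm(small_area, small_config, rng)
        new, _ = position_update(state.pos, np.zeros_like(state.vel), small_area)
        np.testing.assert_array_equal(new, state.pos)

    def test_radius_clamped_and_velocity_zeroed(self, small_area):
        g = small_area.grid
        pos = np.zeros((2, 4, 1))
        pos[0] = g.rmax - 1.0
        pos[1] = (small_area.sector_edges[:-1] + small_area.sector_edges[1:])[:, None] / 2
        vel = np.zeros_like(pos)
        vel[0] = 10.0
        new, v = position_update(pos, vel, small_area)
        np.testing.assert_array_equal(new[0], g.rmax)
        np.testing.assert_array_equal(v[0], 0.0)

    def test_angle_pinned_inside_own_sector(self, small_area):
        lo = small_area.sector_edges[:-1]
        hi = small_area.sector_edges[1:]
        pos = np.zeros((2, 4, 1))
        pos[0] = 50.0
        pos[1] = ((lo + hi) / 2)[:, None]
        vel = np.zeros_like(pos)
        vel[1] = 10.0  # would cross into the next sector
        new, v = position_update(pos, vel, small_area)
        dt = small_area.grid.delta_theta
        assert np.all(new[1, :, 0] <= hi - dt + 1e-12)
        assert np.all(new[1, :, 0] >= lo)
        np.testing.assert_array_equal(v[1], 0.0)


class TestBestUpdates:
    def test_tie_moves_personal_best_to_new_position(self):
        area = _flat_area(value=1.0)  # constant fitness: every move is a tie
        cfg = SwarmConfig(n_subgroups=4, n_particles=2)
        state = initialize_swarm(area, cfg, np.random.default_rng(0))
        state.pos = state.pos + np.array([1.0, 0.0])[:, None, None]
        update_personal_best(state, area)
        np.testing.assert_array_equal(state.pbest, state.pos)

    def test_worse_position_keeps_personal_best(self, small_area, small_config, rng):
        state = initialize_swarm(small_area, small_config, rng)
        old_pbest = state.pbest.copy()
        old_vals = state.pbest_val.copy()
        # move everything off-annulus conceptually: force fitness 0 positions
        state.pos[0] = small_area.grid.rmin  # low-gradient inner rim
        update_personal_best(state, small_area)
        keep = small_area.fitness_at(state.pos[0], state.pos[1]) < old_vals
        np.testing.assert_array_equal(state.pbest[:, keep], old_pbest[:, keep])

    def test_subgroup_best_matches_brute_force_max(self, small_area, small_config, rng):
        state = initialize_swarm(small_area, small_config, rng)
        state.pbest_val = rng.random(state.pbest_val.shape)
        before = state.gbest_val.copy()
        update_subgroup_best(state)
        np.testing.assert_allclose(
            state.gbest_val, np.maximum(before, state.pbest_val.max(axis=1))
        )

    def test_dominating_particle_becomes_subgroup_best(self, small_area, small_config, rng):
        state = initialize_swarm(small_area, small_config, rng)
        state.pbest_val[:] = 0.0
        state.pbest_val[:, 3] = 7.0
        update_subgroup_best(state)
        np.testing.assert_array_equal(state.gbest_val, 7.0)
        np.testing.assert_array_equal(state.gbest, state.pbest[:, :, 3])


class TestEdgeFitness:
    def test_sum_of_member_lookups(self, clean_area, rng):
        n = clean_area.n_subgroups
        r = rng.uniform(clean_area.grid.rmin, clean_area.grid.rmax, n)
        theta = (clean_area.sector_edges[:-1] + clean_area.sector_edges[1:]) / 2
        edge = EdgeContour(label=0, r=r, theta=theta, fitness=0.0)
        expected = sum(
            float(clean_area.fitness_at(np.array([ri]), np.array([ti]))[0])
            for ri, ti in zip(r, theta)
        )
        assert edge_fitness(edge, clean_area) == pytest.approx(expected)

    def test_all_members_outside_annulus_scores_zero(self, clean_area):
        n = clean_area.n_subgroups
        edge = EdgeContour(
            label=0,
            r=np.full(n, clean_area.grid.rmax + 5.0),
            theta=(clean_area.sector_edges[:-1] + clean_area.sector_edges[1:]) / 2,
            fitness=0.0,
        )
        assert edge_fitness(edge, clean_area) == 0.0

    def test_three_member_sum(self):
        area = _flat_area(n_subgroups=3, value=0.0)
        fitness = area.fitness.copy()
        # place distinct values at three known grid points (one per sector)
        cols = [area.sector_columns(i)[0] for i in range(3)]
        for c, v in zip(cols, (0.2, 0.5, 0.3)):
            fitness[5, c] = v
        area2 = ExplorationArea(grid=area.grid, fitness=fitness, n_subgroups=3)
        r = np.full(3, area.grid.radii()[5])
        theta = area.grid.angles()[cols]
        edge = EdgeContour(label=0, r=r, theta=theta, fitness=0.0)
        assert edge_fitness(edge, area2) == pytest.approx(1.0)


class TestRunSwarm:
    def test_converges_to_disc_boundary_and_sector_optima(self, clean_area):
        cfg = SwarmConfig()
        res = run_swarm(clean_area, cfg, np.random.default_rng(3), image_size=256)
        assert np.all(np.abs(res.edge.r - 60.0) <= 2 * clean_area.grid.delta_r)
        brute = sum(clean_area.sector_max(i) for i in range(clean_area.n_subgroups))
        assert res.edge.fitness >= 0.99 * brute

    def test_trace_is_non_decreasing(self, clean_area):
        res = run_swarm(clean_area, SwarmConfig(iterations=40),
                        np.random.default_rng(4), image_size=256)
        assert np.all(np.diff(res.trace) >= 0)

    def test_personal_and_subgroup_bests_monotone_and_confined(self, small_area,
                                                               small_config):
        from discswarm.swarm import InertiaSchedule as Sched

        rng = np.random.default_rng(11)
        state = initialize_swarm(small_area, small_config, rng)
        sched = Sched(small_config, rng)
        lo = small_area.sector_edges[:-1][:, None]
        hi = small_area.sector_edges[1:][:, None]
        g = small_area.grid
        prev_pp = state.pbest_val.copy()
        prev_gp = state.gbest_val.copy()
        for k in range(small_config.iterations):
            omega = sched(k, small_config.iterations)
            state.vel = velocity_update(state.pos, state.vel, state.pbest, state.gbest,
                                        omega, small_area, small_config, rng)
            state.pos, state.vel = position_update(state.pos, state.vel, small_area)
            update_personal_best(state, small_area)
            update_subgroup_best(state)
            assert np.all(state.pbest_val >= prev_pp)
            assert np.all(state.gbest_val >= prev_gp)
            assert np.all((state.pos[0] >= g.rmin) & (state.pos[0] <= g.rmax))
            assert np.all((state.pos[1] >= lo) & (state.pos[1] < hi))
            prev_pp = state.pbest_val.copy()
            prev_gp = state.gbest_val.copy()

    def test_zero_fitness_field_terminates_with_flat_trace(self):
        area = _flat_area(n_subgroups=4, value=0.0)
        res = run_swarm(area, SwarmConfig(n_subgroups=4, n_particles=3, iterations=10),
                        np.random.default_rng(0), image_size=256)
        np.testing.assert_array_equal(res.trace, 0.0)

    def test_same_seed_gives_identical_result(self, clean_area):
        cfg = SwarmConfig(iterations=20)
        r1 = run_swarm(clean_area, cfg, np.random.default_rng(8), image_size=256)
        r2 = run_swarm(clean_area, cfg, np.random.default_rng(8), image_size=256)
        np.testing.assert_array_equal(r1.edge.r, r2.edge.r)
        np.testing.assert_array_equal(r1.boundary, r2.boundary)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_radius_only_mode_keeps_angles_fixed(self, small_area, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, radius_only=True, iterations=20)
        rng = np.random.default_rng(21)
        state = initialize_swarm(small_area, cfg, rng)
        mid = state.pos[1].copy()
        res = run_swarm(small_area, cfg, np.random.default_rng(21), image_size=256)
        np.testing.assert_allclose(np.sort(res.edge.theta), np.sort(mid[:, 0]))
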