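"""Tests of the workspace, point-mass dynamics, closed loop and metrics."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from statebmi import (
    Dynamics,
    PointMassState,
    Trajectory,
    Workspace,
    closest_point_distance,
    compute_metrics,
    directed_force,
    encode_position,
    run_session_protocol,
    run_trajectory,
    step_dynamics,
    within_trajectory_variance,
)
from statebmi.bmi_sim import _clamp_to_workspace
from statebmi.neural_sim import Trial


class IdealDecoder:
    """Always returns the true region's one-hot posterior."""

    def decode(self, trial):
        p = np.zeros(4)
        p[trial.stimulus - 1] = 1.0
        return p


class AntipodalDecoder:
    """Always votes for the region opposite the true one (repulsive force)."""

    def decode(self, trial):
        p = np.zeros(4)
        p[(trial.stimulus + 1) % 4] = 1.0
        return p


class UniformDecoder:
    def decode(self, trial):
        return np.full(4, 0.25)


class NullOracle:
    """Emits empty trials; decoder stubs above only read the stimulus."""

    def emit_trial(self, stimulus):
        return Trial(0, stimulus, (np.empty(0),))


def _state(x, y, vx=0.0, vy=0.0):
    return PointMassState(position=np.array([x, y], float), velocity=np.array([vx, vy], float))


class TestWorkspace:
    def test_default_geometry(self):
        ws = Workspace()
        assert ws.side == 36.0
        np.testing.assert_allclose(ws.centroids, [[9, 9], [-9, 9], [-9, -9], [9, -9]])
        # forces point from each centroid toward the origin
        for c, f in zip(ws.centroids, ws.forces):
            np.testing.assert_allclose(f / np.linalg.norm(f), -c / np.linalg.norm(c))
            assert np.linalg.norm(f) == pytest.approx(ws.f_mag)

    @pytest.mark.parametrize(
        "pos,region",
        [((9, 9), 1), ((-9, 9), 2), ((-9, -9), 3), ((9, -9), 4),
         ((0, 5), 1), ((0, 0), 1), ((-1e-9, 5), 2), ((5, 0), 1)],
    )
    def test_encoder_quadrants_and_boundaries(self, pos, region):
        assert encode_position(np.array(pos, float), Workspace()) == region

    def test_encoder_partition_is_exhaustive_and_balanced(self, rng):
        ws = Workspace()
        pts = rng.uniform(-18, 18, size=(10000, 2))
        regions = np.array([encode_position(p, ws) for p in pts])
        counts = np.bincount(regions, minlength=5)[1:]
        assert counts.sum() == 10000
        assert (counts > 2200).all()  # ~uniform across quadrants

    def test_position_outside_workspace_rejected(self):
        with pytest.raises(ValueError):
            encode_position(np.array([19.0, 0.0]), Workspace())


class TestDynamics:
    dyn = Dynamics()

    def test_force_free_velocity_decays_exponentially(self):
        s0 = _state(0, 0, vx=1.0)
        s1 = step_dynamics(s0, np.zeros(2), self.dyn)
        expected = math.exp(-self.dyn.viscosity * self.dyn.dt / self.dyn.mass)
        assert s1.velocity[0] == pytest.approx(expected, rel=1e-12)

    def test_terminal_velocity_reached(self):
        f = np.array([0.008, 0.0])
        s = _state(0, 0)
        for _ in range(20):
            s = step_dynamics(s, f, self.dyn)
        v_terminal_cm = f[0] / self.dyn.viscosity * 100
        assert s.velocity[0] == pytest.approx(v_terminal_cm, rel=1e-9)

    def test_matches_fine_grained_integrator(self, rng):
        # independent oracle: scipy adaptive integration of the same ODE
        for _ in range(5):
            force = rng.uniform(-0.01, 0.01, 2)
            s0 = _state(*rng.uniform(-5, 5, 2), *rng.uniform(-3, 3, 2))

            def ode(t, z):
                pos_v = z[2:]
                acc = (force / self.dyn.mass) - (self.dyn.viscosity / self.dyn.mass) * pos_v
                return np.concatenate([pos_v, acc])

            z0 = np.concatenate([s0.position / 100, s0.velocity / 100])
            sol = solve_ivp(ode, (0, self.dyn.dt), z0, rtol=1e-12, atol=1e-14)
            s1 = step_dynamics(s0, force, self.dyn)
            np.testing.assert_allclose(
                s1.position, sol.y[:2, -1] * 100, atol=1e-6
            )

    def test_speed_monotone_decreasing_without_force(self):
        s = _state(0, 0, vx=3.0, vy=-2.0)
        speeds = [np.linalg.norm(s.velocity)]
        for _ in range(10):
            s = step_dynamics(s, np.zeros(2), self.dyn, dt=0.05)
            speeds.append(np.linalg.norm(s.velocity))
        assert all(b < a for a, b in zip(speeds, speeds[1:]))

    def test_clamping_zeroes_inward_velocity(self):
        ws = Workspace()
        s = _state(20.0, 0.0, vx=5.0, vy=1.0)
        c = _clamp_to_workspace(s, ws)
        assert c.position[0] == ws.side / 2
        assert c.velocity[0] == 0.0 and c.velocity[1] == 1.0

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            Dynamics(mass=-1.0)


class TestClosedLoop:
    def test_ideal_decoder_converges_from_every_start(self):
        for r in (0.5, 2.0):
            ws = Workspace(r_target=r)
            for start in ws.starts:
                traj = run_trajectory(start, ws, IdealDecoder(), NullOracle())
                assert traj.converged and traj.n_steps < 100

    def test_antipodal_decoder_never_converges(self):
        ws = Workspace(r_target=2.0)
        traj = run_trajectory((14.0, 0.0), ws, AntipodalDecoder(), NullOracle())
        assert not traj.converged and traj.n_steps == 100

    def test_trajectory_reproducible_from_seed(self):
        from statebmi.neural_sim import SessionOracle, SimParams
        from statebmi.pipeline import fit_variant_decoder
        from statebmi.bmi_sim import ClosedLoopDecoder
        from statebmi import generate_session

        p = SimParams(n_units=3, n_trials_per_stimulus=10, seed=2)
        session = generate_session(p)
        model, sched = fit_variant_decoder(session, "SI", k=4)
        dec = ClosedLoopDecoder(model, sched)
        ws = Workspace(r_target=1.0)
        runs = [
            run_trajectory((10.0, 10.0), ws, dec, SessionOracle(p, seed=3), max_steps=15)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].positions, runs[1].positions)

    def test_protocol_bookkeeping(self):
        ws = Workspace(r_target=2.0)
        trajs, metrics = run_session_protocol(
            ws, IdealDecoder(), NullOracle(), reps_per_start=3
        )
        assert len(trajs) == 8 * 3
        assert metrics.n_trajectories == 24
        assert metrics.convergence_rate == 100.0

    def test_mean_steps_decreases_with_target_radius(self):
        steps = []
        for r in (0.5, 1.0, 2.0):
            ws = Workspace(r_target=r)
            _, m = run_session_protocol(ws, IdealDecoder(), NullOracle(), reps_per_start=1)
            steps.append(m.mean_steps)
        assert steps[0] > steps[1] > steps[2]


def _traj_from_positions(positions, converged=False, start_index=0):
    states = [
        PointMassState(position=np.asarray(p, float), velocity=np.zeros(2), step=i)
        for i, p in enumerate(positions)
    ]
    n = len(positions) - 1
    return Trajectory(
        states=states,
        forces=[np.zeros(2)] * n,
        posteriors=[np.full(4, 0.25)] * n,
        stimuli=[1] * n,
        converged=converged,
        start_index=start_index,
    )


class TestMetrics:
    def test_convergence_rate_arithmetic(self):
        trajs = [
            _traj_from_positions([(5, 5), (4, 4)], converged=(i < 7), start_index=0)
            for i in range(10)
        ]
        m = compute_metrics(trajs)
        assert m.convergence_rate == pytest.approx(70.0)

    def test_closest_point_examples(self):
        through_origin = _traj_from_positions([(1, 0), (0, 0), (-1, 0)])
        assert closest_point_distance(through_origin) == 0.0
        line = _traj_from_positions(
            [(x, 0.0) for x in np.linspace(10, 2, 9)]
        )
        assert closest_point_distance(line) == pytest.approx(20.0)

    def test_closest_point_rotation_invariance(self, rng):
        pts = rng.uniform(-10, 10, size=(12, 2))
        theta = 1.1
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        a = closest_point_distance(_traj_from_positions(pts))
        b = closest_point_distance(_traj_from_positions(pts @ rot.T))
        assert a == pytest.approx(b)

    @pytest.mark.parametrize(
        "force,pos,expected",
        [((-1.0, 0.0), (5.0, 0.0), 1.0), ((0.0, 1.0), (5.0, 0.0), 0.0),
         ((-3.0, 0.0), (5.0, 0.0), 3.0)],
    )
    def test_directed_force(self, force, pos, expected):
        out = directed_force(np.array(force), np.array(pos))
        assert out == pytest.approx(expected)

    def test_directed_force_at_target_is_missing(self):
        assert math.isnan(directed_force(np.array([1.0, 0.0]), np.zeros(2)))

    def test_wtv_zero_for_identical_displacements(self):
        trajs = [
            _traj_from_positions([(0, 0), (1, 1), (2, 2), (3, 3)]) for _ in range(3)
        ]
        assert within_trajectory_variance(trajs) == pytest.approx(0.0)

    def test_wtv_three_four_five_arithmetic(self):
        # pooled displacement components with sample variances 3 and 4
        dx = np.array([1, -1, 2, -2, 1, -1], float)
        dx *= math.sqrt(3 / dx.var(ddof=1))
        dy = np.array([2, -2, 1, -1, -1, 1], float)
        dy *= math.sqrt(4 / dy.var(ddof=1))
        positions = np.zeros((7, 2))
        positions[1:, 0] = np.cumsum(dx)
        positions[1:, 1] = np.cumsum(dy)
        # split into two trajectories of three displacements each
        t1 = _traj_from_positions(positions[:4])
        rebased = positions[3:] - positions[3]  # variance unchanged
        t2 = _traj_from_positions(rebased)
        assert within_trajectory_variance([t1, t2]) == pytest.approx(5.0)

    def test_wtv_invariant_under_constant_drift(self, rng):
        pts = np.cumsum(rng.standard_normal((8, 2)), axis=0)
        base = [_traj_from_positions(pts), _traj_from_positions(pts[::-1])]
        drift = np.cumsum(np.tile([0.7, -0.3], (8, 1)), axis=0)
        shifted = [
            _traj_from_positions(pts + drift),
            _traj_from_positions(pts[::-1] + drift),
        ]
        assert within_trajectory_variance(base) == pytest.approx(
            within_trajectory_variance(shifted)
        )

    def test_wtv_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            within_trajectory_variance([_traj_from_positions([(0, 0), (1, 1)])])
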