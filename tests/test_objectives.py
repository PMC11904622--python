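"""Control losses, target construction, grid search and training loops."""

import numpy as np
import pytest

from abmcontrol import GridConfig, run
from abmcontrol.control import st_floor
from abmcontrol.grid_abm import Trajectory
from abmcontrol.objectives import (
    SteadyStateObjective,
    grid_search_theta,
    loss_J1,
    loss_J2,
    make_targets,
    reached_states,
    train_steady_state,
    train_transient_mlp,
)


def _traj(b, c):
    n = len(b)
    return Trajectory(
        a=np.zeros(n, dtype=int), b=np.asarray(b), c=np.asarray(c),
        controls=np.zeros((n - 1, 2), dtype=int),
    )


class TestReachedStates:
    def test_constant_series(self):
        traj = _traj([4575] * 11, [948] * 11)
        assert reached_states(traj, 5) == (4575.0, 948.0)

    def test_final_window_mean(self):
        traj = _traj([0, 0, 10, 20, 30], [0, 0, 1, 2, 3])
        assert reached_states(traj, 3) == (20.0, 2.0)

    def test_full_length_equals_global_mean_over_periods(self):
        b = np.arange(1, 12) * 7
        traj = _traj(b, b)
        # window = all periods (observation 0 excluded)
        assert reached_states(traj, 10)[0] == pytest.approx(np.mean(b[1:]))

    def test_window_longer_than_trajectory_rejected(self):
        with pytest.raises(ValueError):
            reached_states(_traj([1, 2], [1, 2]), 5)


class TestLossJ1:
    def test_zero_iff_targets_met(self):
        obj = SteadyStateObjective(4575, 948, Nt_star=10, horizon=100)
        assert loss_J1((4575, 948), obj) == 0.0
        assert loss_J1((4576, 948), obj) > 0.0

    def test_printed_reached_states_value(self):
        obj = SteadyStateObjective(4575, 948, Nt_star=10, horizon=100)
        assert loss_J1((4573, 956), obj) == pytest.approx(68.0)

    def test_symmetric_in_deviation_sign(self):
        obj = SteadyStateObjective(100, 50, Nt_star=1, horizon=10)
        assert loss_J1((100 + 7, 50), obj) == loss_J1((100 - 7, 50), obj)


class TestLossJ2:
    def _mtraj(self, S, R, T):
        n = len(S)
        z = np.zeros(n, dtype=int)
        from abmcontrol.reaction_abm import MetabolicTrajectory

        return MetabolicTrajectory(
            S=np.asarray(S), P=z, Q=z, R=np.asarray(R), T=np.asarray(T),
            freeA=z, freeE=z, freeI=z, freeO=z, q=np.zeros(n - 1),
        )

    def test_zero_substrate_gives_zero(self):
        assert loss_J2(self._mtraj([5, 0, 0], [1, 1, 1], [0, 1, 1])) == 0.0

    def test_direct_ratio(self):
        traj = self._mtraj([0, 100, 200], [0, 20, 30], [0, 20, 30])
        assert loss_J2(traj) == pytest.approx(300 / 100)

    def test_scale_invariance(self):
        t1 = self._mtraj([0, 100, 200], [0, 20, 30], [0, 20, 30])
        t2 = self._mtraj([0, 1000, 2000], [0, 200, 300], [0, 200, 300])
        assert loss_J2(t1) == pytest.approx(loss_J2(t2))

    def test_product_free_run_rejected(self):
        with pytest.raises(ValueError, match="product"):
            loss_J2(self._mtraj([1, 1], [0, 0], [0, 0]))


class TestMakeTargets:
    def test_study_baseline_produces_printed_targets(self):
        obj = make_targets((4159, 1896), 0.10, 0.50)
        assert (obj.b_target, obj.c_target) == (4575, 948)

    def test_zero_shift_keeps_baseline(self):
        obj = make_targets((100, 100), 0.0, 0.0)
        assert (obj.b_target, obj.c_target) == (100, 100)

    def test_plain_arithmetic(self):
        obj = make_targets((100, 100), 0.10, 0.50)
        assert (obj.b_target, obj.c_target) == (110, 50)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_targets((10, 10), -2.0, 0.0)


def _toy_rollout(b0=1000.0, c0=500.0, periods=60, Nt_star=10):
    """Deterministic removal plant: b_{k+1} = b_k - st_floor(theta1 b_k),
    c likewise; the seed is ignored."""

    def rollout(theta, seed):
        b, c = b0, c0
        bs, cs = [], []
        for _ in range(periods):
            b -= st_floor(theta[0] * b)
            c -= st_floor(theta[1] * c)
            bs.append(b)
            cs.append(c)
        return float(np.mean(bs[-Nt_star:])), float(np.mean(cs[-Nt_star:]))

    return rollout


class TestTrainSteadyState:
    def test_recovers_toy_plant_optimum(self):
        # exponential decay toward the target: theta* = 1 - (target/b0)^(1/k)
        objective = SteadyStateObjective(600, 250, Nt_star=10, horizon=60)
        rollout = _toy_rollout()
        report = train_steady_state(
            None, objective, theta0=(0.004, 0.004), n_seeds=1,
            maxiter=200, rollout=rollout,
        )
        # the trained controller must essentially meet the targets
        reached = rollout(
            (report.best_params.theta1, report.best_params.theta2), 0
        )
        assert abs(reached[0] - 600) < 12
        assert abs(reached[1] - 250) < 8

    def test_zero_control_optimal_when_targets_equal_baseline(self):
        rollout = _toy_rollout()
        baseline = rollout((0.0, 0.0), 0)
        objective = SteadyStateObjective(*baseline, Nt_star=10, horizon=60)
        report = train_steady_state(
            None, objective, theta0=(0.002, 0.002), n_seeds=1,
            maxiter=150, rollout=rollout,
        )
        assert report.best_loss <= 1.0
        # the returned controller acts as the zero controller (any theta
        # below 1/population rounds every removal down to zero)
        reached = rollout(
            (report.best_params.theta1, report.best_params.theta2), 0
        )
        assert reached == baseline

    def test_best_loss_is_minimum_of_history(self):
        objective = SteadyStateObjective(600, 250, Nt_star=10, horizon=60)
        report = train_steady_state(
            None, objective, n_seeds=1, maxiter=40, rollout=_toy_rollout()
        )
        assert report.best_loss == min(report.loss_history)


class TestGridSearch:
    def test_single_cell_is_optimum(self):
        objective = SteadyStateObjective(600, 250, Nt_star=10, horizon=60)
        res = grid_search_theta(
            None, objective, [0.01], [0.02], replicates=2, rollout=_toy_rollout()
        )
        assert res.optimum == (0.01, 0.02)

    def test_noiseless_quadratic_surface_exact_argmin(self):
        # reached states linear in theta -> J1 is an exact paraboloid
        objective = SteadyStateObjective(50, 30, Nt_star=1, horizon=10)
        rollout = lambda theta, seed: (100 - 1000 * theta[0],
                                       100 - 1000 * theta[1])
        grid = np.round(np.linspace(0.0, 0.1, 11), 3)
        res = grid_search_theta(None, objective, grid, grid, replicates=1,
                                rollout=rollout)
        assert res.optimum == (0.05, 0.07)
        assert res.sd_loss[np.argmin(res.mean_loss)] == 0.0

    def test_tie_breaks_toward_smaller_theta(self):
        objective = SteadyStateObjective(0, 0, Nt_star=1, horizon=10)
        rollout = lambda theta, seed: (0.0, 0.0)  # flat surface, all ties
        res = grid_search_theta(None, objective, [0.2, 0.1], [0.4, 0.3],
                                replicates=1, rollout=rollout)
        assert res.optimum == (0.1, 0.3)

    def test_surface_reproducible_given_seed(self, small_grid):
        objective = SteadyStateObjective(150, 60, Nt_star=20, burn_in=30,
                                         horizon=30)
        kw = dict(replicates=2, seed0=5)
        r1 = grid_search_theta(small_grid, objective, [0.0, 0.01], [0.0], **kw)
        r2 = grid_search_theta(small_grid, objective, [0.0, 0.01], [0.0], **kw)
        assert np.array_equal(r1.mean_loss, r2.mean_loss)
        assert np.array_equal(r1.mean_b, r2.mean_b)


def test_trained_optimum_matches_grid_search_oracle():
    """On the deterministic toy plant the trained two-parameter controller
    is at least as good as the grid-search optimum (within its one-s.d.
    band, which is zero here)."""
    objective = SteadyStateObjective(600, 250, Nt_star=10, horizon=60)
    rollout = _toy_rollout()
    grid = np.linspace(0.0, 0.02, 21)
    surface = grid_search_theta(None, objective, grid, grid, replicates=1,
                                rollout=rollout)
    report = train_steady_state(None, objective, theta0=(0.004, 0.004),
                                n_seeds=1, maxiter=200, rollout=rollout)
    oracle_loss = float(surface.mean_loss.min())
    i_opt = int(np.argmin(surface.mean_loss))
    assert report.best_loss <= oracle_loss + surface.sd_loss[i_opt] + 1e-9


class TestTrainTransientMLP:
    def test_toy_plant_with_known_constant_optimum(self):
        # plant: reached states are b0 + u1, c0 + u2 for the (constant)
        # action taken at k=0; optimum is u = (+25, -40)
        from abmcontrol.control import MLPParams, mlp_control
        from abmcontrol.grid_abm import Observation

        objective = SteadyStateObjective(125, 60, Nt_star=1, burn_in=0,
                                         horizon=100)

        def loss_fn(params, seed):
            obs = Observation(0, 100, 100)
            u = mlp_control(obs, 0, 100, params)
            return (100 + u[0] - 125) ** 2 + (100 + u[1] - 60) ** 2

        params0 = MLPParams.create(
            hidden=(16,), rng=np.random.default_rng(3), scale=0.5,
            b_scale=100, c_scale=100,
        )
        report = train_transient_mlp(
            None, objective, params0, n_seeds=1, n_iter=400, seed0=1,
            a0=20.0, c0=2.0, loss_fn=loss_fn,
        )
        assert report.best_loss <= 4.0

    def test_best_so_far_history_monotone(self):
        from abmcontrol.control import MLPParams

        objective = SteadyStateObjective(125, 60, Nt_star=1, burn_in=0,
                                         horizon=100)
        loss_fn = lambda params, seed: float(
            np.sum(np.concatenate([w.ravel() for w, _ in params.layers]) ** 2)
        )
        params0 = MLPParams.create(hidden=(16,),
                                   rng=np.random.default_rng(0), scale=0.5)
        report = train_transient_mlp(
            None, objective, params0, n_seeds=1, n_iter=30, loss_fn=loss_fn
        )
        hist = np.asarray(report.loss_history)
        assert np.all(np.diff(hist) <= 0)
        assert report.best_loss == hist[-1]
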