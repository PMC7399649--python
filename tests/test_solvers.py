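"""Solver correctness: the exact prox, NNLS against an active-set oracle,
group-lasso structure, and the regularization path."""

import numpy as np
import pytest
import scipy.optimize as sopt

import tractofilter as tf
from tractofilter.solvers import GroupStructure, SolverConfig


def _tight(max_iter=20000, tol=1e-14, lam=0.0):
    return SolverConfig(lam=lam, max_iter=max_iter, tol=tol)


def _random_groups(rng, n):
    """Random partition of range(n) into 1..n groups."""
    cuts = np.sort(rng.choice(np.arange(1, n), rng.integers(0, n - 1), replace=False))
    parts = np.split(rng.permutation(n), cuts)
    return GroupStructure([p for p in parts if len(p)], n)


class TestGroupProx:
    def test_norm_equal_threshold_zeroes_group(self):
        gs = GroupStructure([np.array([0, 1])], 2)
        out = tf.group_prox(np.array([3.0, 4.0]), gs, np.array([5.0]))
        assert np.all(out == 0.0)

    def test_zero_threshold_is_pure_projection(self):
        gs = GroupStructure([np.array([0, 1])], 2)
        out = tf.group_prox(np.array([-1.0, 2.0]), gs, np.array([0.0]))
        assert out == pytest.approx([0.0, 2.0])

    def test_exempt_columns_only_projected(self):
        gs = GroupStructure([np.array([0])], 3, exempt=np.array([1, 2]))
        out = tf.group_prox(np.array([5.0, -3.0, 7.0]), gs, np.array([100.0]))
        assert out == pytest.approx([0.0, 0.0, 7.0])

    def test_infinite_threshold_forces_group_inactive(self):
        gs = GroupStructure([np.array([0, 1])], 2)
        out = tf.group_prox(np.array([10.0, 10.0]), gs, np.array([np.inf]))
        assert np.all(out == 0.0)

    def test_matches_constrained_qp_oracle(self, rng):
        """prox solves min 0.5||x-v||^2 + t||x_g|| s.t. x >= 0 (100 cases)."""
        for _ in range(100):
            n = int(rng.integers(2, 11))
            gs = _random_groups(rng, n)
            v = rng.standard_normal(n) * 3.0
            t = np.abs(rng.standard_normal(len(gs.groups)))

            def objective(x):
                pen = sum(ti * np.linalg.norm(x[g]) for g, ti in zip(gs.groups, t))
                return 0.5 * np.sum((x - v) ** 2) + pen

            ours = tf.group_prox(v, gs, t)
            res = sopt.minimize(objective, np.maximum(v, 0.0), method="SLSQP",
                                bounds=[(0.0, None)] * n,
                                options={"maxiter": 500, "ftol": 1e-14})
            assert np.all(ours >= 0.0)
            assert objective(ours) <= objective(res.x) + 1e-8


class TestAdaptiveWeights:
    def test_printed_arithmetic(self):
        gs = GroupStructure([np.arange(4)], 4)
        x = np.array([1.0, 1.0, 1.0, 1.0])  # group norm 2, cardinality 4
        out = tf.compute_adaptive_weights(x, gs, lam=1.0)
        assert out.weights == pytest.approx([2.0])

    def test_zero_lambda_gives_zero_weights(self):
        gs = GroupStructure([np.array([0]), np.array([1])], 2)
        out = tf.compute_adaptive_weights(np.array([1.0, 2.0]), gs, lam=0.0)
        assert np.all(out.weights == 0.0)

    def test_zero_norm_group_gets_infinite_sentinel(self):
        gs = GroupStructure([np.array([0]), np.array([1])], 2)
        out = tf.compute_adaptive_weights(np.array([0.0, 2.0]), gs, lam=1.0)
        assert np.isinf(out.weights[0]) and np.isfinite(out.weights[1])

    def test_negative_lambda_rejected(self):
        gs = GroupStructure([np.array([0])], 1)
        with pytest.raises(ValueError):
            tf.compute_adaptive_weights(np.array([1.0]), gs, lam=-1.0)

    def test_sqrt_cardinality_variant(self):
        gs = GroupStructure([np.arange(4)], 4)
        out = tf.compute_adaptive_weights(np.ones(4), gs, lam=1.0,
                                          sqrt_cardinality=True)
        assert out.weights == pytest.approx([1.0])


class TestNNLS:
    def test_toy_recovers_csf_and_rejects_false_fiber(self, toy_nnls):
        assert toy_nnls.x[6] == pytest.approx(1.0, abs=1e-6)   # x7: CSF in voxel 4
        assert toy_nnls.x[5] == pytest.approx(0.0, abs=1e-6)   # x6: no CSF in voxel 3
        assert toy_nnls.x[2] == pytest.approx(0.0, abs=1e-6)   # x3: false fiber

    def test_zero_signal_gives_zero_solution(self, toy):
        sol = tf.solve_nnls(toy.matrix, np.zeros(toy.matrix.shape[0]))
        assert np.all(sol.x == 0.0)

    def test_matches_active_set_oracle(self, rng):
        """Objective within 1e-6 of scipy's active-set NNLS on 100 instances."""
        for _ in range(100):
            m, n = int(rng.integers(5, 12)), int(rng.integers(3, 8))
            A = rng.standard_normal((m, n))
            y = A @ np.abs(rng.standard_normal(n)) + 0.1 * rng.standard_normal(m)
            ours = tf.solve_nnls(A, y, _tight())
            x_ref, _ = sopt.nnls(A, y)
            f_ours = np.sum((A @ ours.x - y) ** 2)
            f_ref = np.sum((A @ x_ref - y) ** 2)
            assert f_ours <= f_ref + 1e-6
            assert np.all(ours.x >= 0.0)

    def test_noiseless_recovery_well_conditioned(self, rng):
        A = rng.standard_normal((8, 5))
        x_true = np.abs(rng.standard_normal(5)) + 0.1
        sol = tf.solve_nnls(A, A @ x_true, _tight())
        assert sol.x == pytest.approx(x_true, abs=1e-6)

    def test_monotone_objective_trace(self, toy):
        sol = tf.solve_nnls(toy.matrix, toy.signal)
        assert np.all(np.diff(sol.objective_trace) <= 1e-10)

    def test_non_finite_input_rejected(self, toy):
        y = np.full(toy.matrix.shape[0], np.nan)
        with pytest.raises(ValueError):
            tf.solve_nnls(toy.matrix, y)

    def test_zero_matrix_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero operator"):
            sol = tf.solve_nnls(np.zeros((4, 3)), np.ones(4))
        assert np.all(sol.x == 0.0)

    def test_kkt_stationarity_at_convergence(self, rng):
        for _ in range(10):
            A = rng.standard_normal((10, 6))
            y = rng.standard_normal(10)
            sol = tf.solve_nnls(A, y, _tight())
            assert tf.stationarity_residual(A, y, sol.x) < 1e-6


class TestGroupLasso:
    def test_lambda_zero_equals_nnls(self, rng):
        for _ in range(10):
            A = rng.standard_normal((12, 6))
            y = A @ np.abs(rng.standard_normal(6))
            gs = _random_groups(rng, 6)
            nnls = tf.solve_nnls(A, y, _tight())
            gl = tf.solve_group_lasso(A, y, gs, _tight(lam=0.0))
            f = lambda x: np.sum((A @ x - y) ** 2)
            assert abs(f(gl.x) - f(nnls.x)) <= 1e-8

    def test_large_lambda_silences_all_groups(self, rng):
        A = np.abs(rng.standard_normal((10, 4)))
        y = A @ np.abs(rng.standard_normal(4))
        gs = GroupStructure([np.array([0, 1]), np.array([2, 3])], 4)
        sol = tf.solve_group_lasso(A, y, gs, _tight(lam=1e6))
        assert sol.active_groups == []
        assert sol.residual_norm == pytest.approx(np.linalg.norm(y), rel=1e-9)

    def test_infinite_weight_group_fixed_to_zero(self, rng):
        A = rng.standard_normal((8, 4))
        y = rng.standard_normal(8)
        gs = GroupStructure([np.array([0, 1]), np.array([2, 3])], 4,
                            weights=np.array([np.inf, 0.1]))
        sol = tf.solve_group_lasso(A, y, gs, _tight())
        assert np.all(sol.x[[0, 1]] == 0.0)
        assert 0 not in sol.active_groups

    def test_solution_feasible_exactly(self, experiment):
        for sol in experiment.solutions:
            assert np.all(sol.x >= 0.0)

    def test_monotone_trace_all_solves(self, experiment):
        for sol in experiment.solutions:
            assert np.all(np.diff(sol.objective_trace) <= 1e-10)

    def test_matches_generic_oracle_small_instances(self, rng):
        """Objective within 1e-6 of SLSQP on <= 10-column problems."""
        for _ in range(20):
            n = int(rng.integers(3, 11))
            A = rng.standard_normal((n + 4, n))
            y = A @ np.abs(rng.standard_normal(n))
            gs = _random_groups(rng, n)
            lam = float(10.0 ** rng.uniform(-3, 0))
            nnls = tf.solve_nnls(A, y, _tight())
            gsw = tf.compute_adaptive_weights(nnls.x, gs, lam)
            finite = [i for i, w in enumerate(gsw.weights) if np.isfinite(w)]

            def objective(x):
                pen = sum(gsw.weights[i] * np.linalg.norm(x[gsw.groups[i]])
                          for i in finite)
                return np.sum((A @ x - y) ** 2) + pen

            ours = tf.solve_group_lasso(A, y, gsw, _tight())
            x0 = np.maximum(nnls.x, 0.0)
            for i, w in enumerate(gsw.weights):
                if not np.isfinite(w):
                    x0[gsw.groups[i]] = 0.0
            ref = sopt.minimize(objective, x0, method="SLSQP",
                                bounds=[(0.0, None)] * n,
                                options={"maxiter": 1000, "ftol": 1e-12})
            assert objective(ours.x) <= objective(ref.x) + 1e-6


class TestLasso:
    def test_equals_group_lasso_with_singletons(self, rng):
        A = rng.standard_normal((12, 5))
        y = A @ np.abs(rng.standard_normal(5))
        lam = 0.05
        lasso = tf.solve_lasso(A, y, _tight(lam=lam))
        gl = tf.solve_group_lasso(A, y, GroupStructure.singletons(5), _tight(lam=lam))
        nnls = tf.solve_nnls(A, y, _tight())
        gsw = tf.compute_adaptive_weights(nnls.x, GroupStructure.singletons(5), lam)
        finite = [i for i, w in enumerate(gsw.weights) if np.isfinite(w)]

        def objective(x):
            return np.sum((A @ x - y) ** 2) + sum(
                gsw.weights[i] * abs(x[gsw.groups[i][0]]) for i in finite)

        assert abs(objective(lasso.x) - objective(gl.x)) <= 1e-8

    def test_lambda_zero_is_nnls(self, rng):
        A = rng.standard_normal((10, 4))
        y = A @ np.abs(rng.standard_normal(4))
        lasso = tf.solve_lasso(A, y, _tight(lam=0.0))
        nnls = tf.solve_nnls(A, y, _tight())
        f = lambda x: np.sum((A @ x - y) ** 2)
        assert abs(f(lasso.x) - f(nnls.x)) <= 1e-8


class TestLambdaSweep:
    def test_single_zero_grid_is_nnls(self, rng):
        A = rng.standard_normal((8, 4))
        y = A @ np.abs(rng.standard_normal(4))
        gs = GroupStructure.singletons(4)
        sols = tf.lambda_sweep(A, y, gs, np.array([0.0]), _tight())
        nnls = tf.solve_nnls(A, y, _tight())
        assert sols[0].x == pytest.approx(nnls.x, abs=1e-8)

    def test_residual_monotone_in_lambda(self, experiment):
        res = [s.residual_norm for s in experiment.solutions]
        assert np.all(np.diff(res) >= -1e-8)

    def test_unsorted_grid_rejected(self, rng):
        A = rng.standard_normal((6, 3))
        gs = GroupStructure.singletons(3)
        with pytest.raises(ValueError, match="ascending"):
            tf.lambda_sweep(A, np.ones(6), gs, np.array([1.0, 0.5]))

    def test_empty_grid_rejected(self, rng):
        A = rng.standard_normal((6, 3))
        gs = GroupStructure.singletons(3)
        with pytest.raises(ValueError, match="empty"):
            tf.lambda_sweep(A, np.ones(6), gs, np.array([]))

    def test_warm_start_matches_cold_start(self, experiment):
        """Spot-check: a mid-grid warm-started solve equals a cold solve."""
        exp = experiment
        i = len(exp.lambda_grid) // 2
        A = tf.build_matrix(exp.tractogram.subset(exp.assignment.assigned),
                            exp.phantom.grid)
        y = exp.phantom.y_vector
        gs = tf.group_by_pairs(
            exp.assignment.subset(exp.assignment.assigned)
        ).to_group_structure(A.n_columns)
        cold = tf.solve_group_lasso(A, y, gs,
                                    SolverConfig(lam=float(exp.lambda_grid[i]),
                                                 max_iter=4000, tol=1e-10))
        warm = exp.solutions[i]
        f_pen = lambda s: s.objective_trace[-1]
        assert f_pen(cold) == pytest.approx(f_pen(warm), rel=1e-4)
        assert set(cold.active_groups) == set(warm.active_groups)
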