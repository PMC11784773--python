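"""Core multi-task model tests: forward, costs, gradients, gate updates."""

import numpy as np
import pytest

from conftest import make_regression_pair
from ttcnet.model import (
    TaskSpec,
    alpha_from_beta,
    beta_velocity,
    build_model,
    clip_gradients,
    cross_task_velocity,
    per_task_gradient,
    task_cost,
    train_step,
    update_weights,
)


class TestAlphaFromBeta:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, 0.5), (np.log(3.0), 0.75), (-np.log(3.0), 0.25)],
    )
    def test_logistic_values(self, beta, expected):
        assert alpha_from_beta(beta) == pytest.approx(expected, abs=1e-12)

    def test_stable_for_large_magnitudes(self):
        assert alpha_from_beta(800.0) == 1.0
        assert alpha_from_beta(-800.0) == 0.0
        assert alpha_from_beta(-np.inf) == 0.0


class TestTaskCost:
    def test_binary_cross_entropy_values(self):
        spec = TaskSpec("t", "classification", 1)
        assert task_cost(np.array([[0.5]]), np.array([1.0]), spec) == pytest.approx(
            np.log(2), abs=1e-9
        )
        assert task_cost(np.array([[0.9]]), np.array([1.0]), spec) == pytest.approx(
            -np.log(0.9), abs=1e-9
        )

    def test_perfect_regression_fit_has_zero_cost(self, rng):
        spec = TaskSpec("r", "regression", 1)
        y = rng.normal(size=(6, 1))
        assert task_cost(y, y, spec) == 0.0

    def test_nonfinite_inputs_rejected(self):
        spec = TaskSpec("r", "regression", 1)
        with pytest.raises(ValueError):
            task_cost(np.array([[np.nan]]), np.array([[0.0]]), spec)


class TestForward:
    def test_softmax_rows_sum_to_one(self, small_conv_arch, rng):
        model = build_model(small_conv_arch, [TaskSpec("c", "classification", 4)], seed=0)
        out = model.subnets[0].forward(rng.random((5, 8, 8)))
        assert out.shape == (5, 4)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((out > 0) & (out < 1))

    def test_identical_weights_identical_outputs(self, small_conv_arch, rng):
        tasks = [TaskSpec("a", "classification", 3), TaskSpec("b", "classification", 3)]
        model = build_model(small_conv_arch, tasks, seed=1)
        model.subnets[1].set_weights(model.subnets[0].get_weights())
        x = rng.random((4, 8, 8))
        assert np.array_equal(
            model.subnets[0].forward(x), model.subnets[1].forward(x)
        )

    def test_shape_mismatch_rejected(self, small_conv_arch, rng):
        model = build_model(small_conv_arch, [TaskSpec("c", "classification", 2)], seed=0)
        with pytest.raises(ValueError):
            model.subnets[0].forward(rng.random((2, 5, 5)))


class TestPerTaskGradient:
    def test_matches_central_finite_differences(self, tiny_dense_arch, rng):
        model = build_model(tiny_dense_arch, [TaskSpec("c", "classification", 3)], seed=3)
        x = rng.random((5, 4, 4))
        y = np.eye(3)[rng.integers(0, 3, 5)]
        grads, _ = per_task_gradient(model, (x, y), 0)
        subnet, spec = model.subnets[0], model.tasks[0]
        max_rel = 0.0
        for pi, p in enumerate(grads):
            param = subnet.params[pi]
            flat = np.argsort(np.abs(p), axis=None)[-4:]  # largest entries
            for f in flat:
                idx = np.unravel_index(f, param.shape)
                eps, orig = 1e-6, param[idx]
                param[idx] = orig + eps
                cp = task_cost(subnet.forward(x, train=True, update_stats=False), y, spec)
                param[idx] = orig - eps
                cm = task_cost(subnet.forward(x, train=True, update_stats=False), y, spec)
                param[idx] = orig
                fd = (cp - cm) / (2 * eps)
                if abs(fd) > 1e-8:
                    max_rel = max(max_rel, abs(fd - p[idx]) / max(abs(fd), abs(p[idx])))
        assert max_rel < 1e-4

    def test_zero_at_perfect_regression_fit(self, tiny_dense_arch):
        model = build_model(tiny_dense_arch, [TaskSpec("r", "regression", 1)], seed=4)
        x = np.full((3, 4, 4), 0.5)
        y = model.subnets[0].forward(x, train=True, update_stats=False)
        grads, cost = per_task_gradient(model, (x, y), 0)
        assert cost == 0.0
        assert all(np.allclose(g, 0.0, atol=1e-15) for g in grads)

    def test_empty_batch_rejected(self, tiny_dense_arch):
        model = build_model(tiny_dense_arch, [TaskSpec("r", "regression", 1)], seed=0)
        with pytest.raises(ValueError):
            per_task_gradient(model, (np.empty((0, 4, 4)), np.empty((0, 1))), 0)


class TestVelocitiesAndUpdates:
    def test_plain_sgd_velocity_scaling(self, tiny_dense_arch):
        tasks = [TaskSpec("a", "regression", 1), TaskSpec("b", "regression", 1)]
        model = build_model(tiny_dense_arch, tasks, seed=0, lr=0.1)
        g = [np.full(s, 2.0) for s in model.subnets[1].param_shapes()]
        v = cross_task_velocity(model, g, 0, 1)
        assert np.allclose(v[0], -0.2)

    def test_zero_gradient_gives_zero_velocity(self, tiny_dense_arch):
        tasks = [TaskSpec("a", "regression", 1), TaskSpec("b", "regression", 1)]
        model = build_model(tiny_dense_arch, tasks, seed=0)
        g = [np.zeros(s) for s in model.subnets[1].param_shapes()]
        v = cross_task_velocity(model, g, 0, 1)
        assert all(np.all(vi == 0) for vi in v)

    def test_missing_pair_rejected(self, tiny_dense_arch):
        model = build_model(tiny_dense_arch, [TaskSpec("a", "regression", 1)], seed=0)
        with pytest.raises(ValueError):
            update_weights(model, {})

    def test_single_task_update_is_standard_sgd(self, tiny_dense_arch, rng):
        model = build_model(tiny_dense_arch, [TaskSpec("r", "regression", 1)], seed=5, lr=0.01)
        x = rng.random((4, 4, 4))
        y = rng.normal(size=(4, 1))
        grads, _ = per_task_gradient(model, (x, y), 0)
        grads = clip_gradients(grads, model.clip_norm)
        before = model.subnets[0].get_weights()
        v = cross_task_velocity(model, grads, 0, 0)
        update_weights(model, {(0, 0): v})
        after = model.subnets[0].get_weights()
        for b, a, g in zip(before, after, grads):
            assert np.allclose(a, b - 0.01 * g, atol=1e-15)

    def test_gradient_clipping_bounds_global_norm(self, rng):
        grads = [rng.normal(0, 10, (5, 5)), rng.normal(0, 10, (7,))]
        clipped = clip_gradients(grads, 5.0)
        norm = np.sqrt(sum(np.sum(g**2) for g in clipped))
        assert norm == pytest.approx(5.0, rel=1e-9)


class TestBetaVelocity:
    def test_diagonal_pair_rejected(self, tiny_dense_arch):
        model = build_model(
            tiny_dense_arch,
            [TaskSpec("a", "regression", 1), TaskSpec("b", "regression", 1)],
            seed=0,
        )
        with pytest.raises(ValueError):
            beta_velocity(model, [], [], 0, 0)

    def test_orthogonal_gradients_give_zero_update(self, tiny_dense_arch):
        model = build_model(
            tiny_dense_arch,
            [TaskSpec("a", "regression", 1), TaskSpec("b", "regression", 1)],
            seed=0,
        )
        shapes = model.subnets[0].param_shapes()
        g_p = [np.zeros(s) for s in shapes]
        g_p[0].flat[0] = 1.0
        v_pq = [np.zeros(s) for s in shapes]
        v_pq[0].flat[1] = 1.0  # disjoint support -> zero inner product
        assert beta_velocity(model, g_p, v_pq, 0, 1) == 0.0

    def test_identical_tasks_open_the_gate(self, tiny_dense_arch, rng):
        model = make_regression_pair(tiny_dense_arch, seed=2)
        x = rng.random((6, 4, 4))
        y = rng.normal(size=(6, 1))
        g0, _ = per_task_gradient(model, (x, y), 0)
        g1, _ = per_task_gradient(model, (x, y), 1)
        v01 = cross_task_velocity(model, g1, 0, 1)
        dv = beta_velocity(model, g0, v01, 0, 1)
        assert dv > 0  # beta increases, alpha grows toward 1

    def test_surrogate_matches_directional_finite_difference(self, tiny_dense_arch, rng):
        model = make_regression_pair(tiny_dense_arch, seed=6)
        xa, ya = rng.random((6, 4, 4)), rng.normal(size=(6, 1))
        xb, yb = rng.random((6, 4, 4)), rng.normal(size=(6, 1))
        g_a, _ = per_task_gradient(model, (xa, ya), 0)
        g_b, _ = per_task_gradient(model, (xb, yb), 1)
        v_ab = cross_task_velocity(model, g_b, 0, 1)
        s = sum(float(np.sum(g * v)) for g, v in zip(g_a, v_ab))
        subnet, spec = model.subnets[0], model.tasks[0]
        w0 = subnet.get_weights()
        eps = 1e-4
        c0 = task_cost(subnet.forward(xa, train=True, update_stats=False), ya, spec)
        subnet.set_weights([w + eps * v for w, v in zip(w0, v_ab)])
        c1 = task_cost(subnet.forward(xa, train=True, update_stats=False), ya, spec)
        subnet.set_weights(w0)
        fd = (c1 - c0) / eps
        assert s == pytest.approx(fd, rel=1e-3)


class TestTrainStep:
    def test_iteration_increments_and_costs_reported(self, small_conv_arch, rng):
        model = build_model(small_conv_arch, [TaskSpec("c", "classification", 2)], seed=0)
        x = rng.random((8, 8, 8))
        y = np.eye(2)[rng.integers(0, 2, 8)]
        out = train_step(model, [(x, y)])
        assert model.iteration == 1
        assert len(out["costs"]) == 1 and np.isfinite(out["costs"][0])

    def test_loss_decreases_on_separable_toy_task(self, tiny_dense_arch):
        model = build_model(
            tiny_dense_arch, [TaskSpec("c", "classification", 2)], seed=7, lr=0.05
        )
        rng = np.random.default_rng(0)
        # two linearly separable blobs in pixel space
        x0 = rng.normal(0.25, 0.05, (32, 4, 4))
        x1 = rng.normal(0.75, 0.05, (32, 4, 4))
        x = np.clip(np.concatenate([x0, x1]), 0, 1)
        y = np.eye(2)[np.repeat([0, 1], 32)]
        costs = [train_step(model, [(x, y)])["costs"][0] for _ in range(100)]
        assert np.mean(costs[-10:]) < 0.5 * np.mean(costs[:10])

    def test_gate_range_invariant_after_steps(self, small_conv_arch, rng):
        model = make_regression_pair(small_conv_arch, seed=8, lr_beta=0.5)
        for _ in range(20):
            x = rng.random((8, 8, 8))
            y = rng.normal(size=(8, 1))
            train_step(model, [(x, y), (x, -y)])
            alpha = model.ttc.alpha
            assert alpha[0, 0] == 1.0 and alpha[1, 1] == 1.0
            assert 0.0 < alpha[0, 1] < 1.0 and 0.0 < alpha[1, 0] < 1.0

    def test_gates_disabled_equals_independent_training(self, small_conv_arch):
        tasks = [TaskSpec("a", "classification", 2), TaskSpec("b", "regression", 1)]
        multi = build_model(small_conv_arch, tasks, seed=9)
        multi.ttc.freeze_all_gates(0.0)
        singles = []
        for i, t in enumerate(tasks):
            s = build_model(small_conv_arch, [t], seed=10)
            s.subnets[0].set_weights(multi.subnets[i].get_weights())
            singles.append(s)
        rng = np.random.default_rng(11)
        for _ in range(30):
            xa, ya = rng.random((8, 8, 8)), np.eye(2)[rng.integers(0, 2, 8)]
            xb, yb = rng.random((8, 8, 8)), rng.normal(size=(8, 1))
            train_step(multi, [(xa, ya), (xb, yb)])
            train_step(singles[0], [(xa, ya)])
            train_step(singles[1], [(xb, yb)])
        for i in range(2):
            for wm, ws in zip(multi.subnets[i].get_weights(), singles[i].subnets[0].get_weights()):
                assert np.array_equal(wm, ws)

    def test_wrong_batch_count_rejected(self, tiny_dense_arch):
        model = build_model(tiny_dense_arch, [TaskSpec("r", "regression", 1)], seed=0)
        with pytest.raises(ValueError):
            train_step(model, [])
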