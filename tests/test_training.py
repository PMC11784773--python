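"""Training orchestration: splits, fitting, checkpoints, incremental tasks."""

import numpy as np
import pandas as pd
import pytest

from ttcnet.model import ArchitectureSpec, TaskSpec, build_model
from ttcnet.training import (
    TaskData,
    TrainConfig,
    add_task,
    evaluate_cost,
    fit,
    load_checkpoint,
    save_checkpoint,
    split_dataset,
)


def make_manifest(n=100, n_classes=3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "image_path": [f"im{i}.png" for i in range(n)],
            "class_label": rng.integers(0, n_classes, n),
            "regression_target": rng.random(n) * 100,
        }
    )


class TestSplitDataset:
    def test_seventy_fifteen_fifteen_sizes(self):
        m = make_manifest(100)
        tr, va, te = split_dataset(m, (0.70, 0.15, 0.15), seed=1)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_partition_disjoint_and_exhaustive(self):
        m = make_manifest(83)
        tr, va, te = split_dataset(m, (0.70, 0.15, 0.15), seed=2)
        idx = np.concatenate([tr.index, va.index, te.index])
        assert sorted(idx) == list(range(83))

    def test_stratification_preserves_class_balance(self):
        m = make_manifest(300, n_classes=3, seed=5)
        tr, va, te = split_dataset(m, (0.70, 0.15, 0.15), seed=3)
        for cls, total in m["class_label"].value_counts().items():
            in_train = (tr["class_label"] == cls).sum()
            assert abs(in_train - 0.70 * total) <= 1

    def test_deterministic_given_seed(self):
        m = make_manifest(60)
        a = split_dataset(m, seed=7)
        b = split_dataset(m, seed=7)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_tiny_class_falls_back_unstratified(self):
        m = make_manifest(20)
        m.loc[0, "class_label"] = 99  # singleton class
        with pytest.warns(UserWarning, match="unstratified"):
            tr, va, te = split_dataset(m)
        assert len(tr) + len(va) + len(te) == 20

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(make_manifest(10), (0.5, 0.3, 0.3))


def separable_dataset(rng, n=48):
    x0 = np.clip(rng.normal(0.3, 0.05, (n // 2, 8, 8)), 0, 1)
    x1 = np.clip(rng.normal(0.7, 0.05, (n // 2, 8, 8)), 0, 1)
    x = np.concatenate([x0, x1])
    y = np.eye(2)[np.repeat([0, 1], n // 2)]
    return x, y


class TestFit:
    arch = ArchitectureSpec(input_hw=(8, 8), conv_channels=(4,), hidden_dim=8)

    def test_zero_epochs_returns_model_unchanged(self, rng):
        model = build_model(self.arch, [TaskSpec("c", "classification", 2)], seed=0)
        before = model.subnets[0].get_weights()
        x, y = separable_dataset(rng)
        model, history = fit(model, [TaskData(x, y)], TrainConfig(epochs=0, batch_size=16))
        assert history.empty
        for b, a in zip(before, model.subnets[0].get_weights()):
            assert np.array_equal(b, a)

    def test_history_length_equals_epochs(self, rng):
        model = build_model(self.arch, [TaskSpec("c", "classification", 2)], seed=0)
        x, y = separable_dataset(rng)
        _, history = fit(model, [TaskData(x, y)], TrainConfig(epochs=3, batch_size=16))
        assert len(history) == 3

    def test_validation_improves_on_separable_data(self, rng):
        model = build_model(
            self.arch, [TaskSpec("c", "classification", 2)], seed=1, lr=1e-3
        )
        x, y = separable_dataset(rng, n=64)
        xv, yv = separable_dataset(rng, n=32)
        data = TaskData(x, y, xv, yv)
        initial = evaluate_cost(model, [data])[0]
        model, _ = fit(model, [data], TrainConfig(epochs=10, batch_size=16, seed=2))
        final = evaluate_cost(model, [data])[0]
        assert final < initial

    def test_reproducible_history_given_seed(self, rng):
        x, y = separable_dataset(rng)
        hists = []
        for _ in range(2):
            model = build_model(self.arch, [TaskSpec("c", "classification", 2)], seed=3)
            _, h = fit(model, [TaskData(x, y)], TrainConfig(epochs=3, batch_size=16, seed=4))
            hists.append(h)
        pd.testing.assert_frame_equal(hists[0], hists[1])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=17)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.5)
        TrainConfig(batch_size=17, learning_rate=0.5, allow_nonstandard=True)


class TestCheckpoint:
    arch = ArchitectureSpec(input_hw=(8, 8), conv_channels=(4,), hidden_dim=8)

    def test_round_trip_bit_exact(self, tmp_path, rng):
        tasks = [TaskSpec("c", "classification", 3), TaskSpec("r", "regression", 1)]
        model = build_model(self.arch, tasks, seed=5, momentum=0.9)
        x, y = separable_dataset(rng)
        yr = rng.normal(size=(len(x), 1))
        fit(
            model,
            [TaskData(x, np.eye(3)[np.zeros(len(x), int)]), TaskData(x, yr)],
            TrainConfig(epochs=2, batch_size=16),
        )
        save_checkpoint(model, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        assert loaded.iteration == model.iteration
        assert np.array_equal(loaded.ttc.beta, model.ttc.beta)
        for s1, s2 in zip(model.subnets, loaded.subnets):
            for w1, w2 in zip(s1.get_weights(), s2.get_weights()):
                assert np.array_equal(w1, w2)
            b1, b2 = s1.get_buffers(), s2.get_buffers()
            assert all(np.array_equal(b1[k], b2[k]) for k in b1)
        for key, vel in model.optimizer.state.items():
            assert all(np.array_equal(v, w) for v, w in zip(vel, loaded.optimizer.state[key]))

    def test_loaded_model_reproduces_validation_cost(self, tmp_path, rng):
        model = build_model(self.arch, [TaskSpec("c", "classification", 2)], seed=6)
        x, y = separable_dataset(rng)
        data = TaskData(x, y, x, y)
        model, _ = fit(model, [data], TrainConfig(epochs=2, batch_size=16))
        cost = evaluate_cost(model, [data])[0]
        save_checkpoint(model, tmp_path / "c2")
        loaded = load_checkpoint(tmp_path / "c2")
        assert evaluate_cost(loaded, [data])[0] == cost


class TestAddTask:
    arch = ArchitectureSpec(input_hw=(8, 8), conv_channels=(4,), hidden_dim=8)

    def _trained_two_task(self, rng):
        tasks = [TaskSpec("cls", "classification", 2), TaskSpec("area", "regression", 1)]
        model = build_model(self.arch, tasks, seed=7)
        x, y = separable_dataset(rng)
        yr = (x.mean(axis=(1, 2)) - 0.5)[:, None]
        datasets = [TaskData(x, y), TaskData(x, yr)]
        model, _ = fit(model, datasets, TrainConfig(epochs=2, batch_size=16))
        return model, datasets, x

    def test_old_weights_bit_identical_and_alpha_grows(self, rng):
        model, datasets, x = self._trained_two_task(rng)
        before = [s.get_weights() for s in model.subnets]
        buffers_before = [s.get_buffers() for s in model.subnets]
        beta_before = model.ttc.beta.copy()
        new_spec = TaskSpec("severity", "regression", 1)
        ysev = (x.std(axis=(1, 2)))[:, None]
        grown, history = add_task(
            model,
            new_spec,
            datasets + [TaskData(x, ysev)],
            TrainConfig(epochs=2, batch_size=16),
        )
        assert grown.n_tasks == 3
        assert grown.ttc.alpha.shape == (3, 3)
        assert np.all(np.diag(grown.ttc.alpha) == 1.0)
        # frozen subnets and gates: bit-identical
        for i in range(2):
            for w_old, w_new in zip(before[i], grown.subnets[i].get_weights()):
                assert np.array_equal(w_old, w_new)
            b_new = grown.subnets[i].get_buffers()
            assert all(np.array_equal(buffers_before[i][k], b_new[k]) for k in b_new)
        assert np.array_equal(grown.ttc.beta[:2, :2], beta_before)
        # gates from new task into old tasks are fully closed
        assert grown.ttc.alpha[0, 2] == 0.0 and grown.ttc.alpha[1, 2] == 0.0
        assert len(history) == 2

    def test_new_task_learns_duplicated_old_task_gate(self):
        # new task duplicates one old regression task; warm-started from
        # that task's subnet, its gate toward the duplicate should exceed
        # the gate toward an unrelated (orthogonal-target) task
        votes = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 128
            x = np.clip(r.random((n, 8, 8)), 0, 1)
            wa, wb = r.normal(0, 1, 64), r.normal(0, 1, 64)
            za = (x.reshape(n, -1) - 0.5) @ wa[:, None]
            zb = (x.reshape(n, -1) - 0.5) @ wb[:, None]
            za = (za - za.mean()) / za.std()
            zb = (zb - zb.mean()) / zb.std()
            tasks = [TaskSpec("unrel", "regression", 1), TaskSpec("area", "regression", 1)]
            model = build_model(self.arch, tasks, seed=seed)
            datasets = [TaskData(x, za), TaskData(x, zb)]
            model, _ = fit(model, datasets, TrainConfig(epochs=1, batch_size=16, seed=seed))
            grown, _ = add_task(
                model,
                TaskSpec("dup", "regression", 1),
                datasets + [TaskData(x, zb)],
                TrainConfig(epochs=8, batch_size=16, seed=seed, lr_beta=5.0),
                warm_start_from=1,
            )
            if grown.ttc.alpha[2, 1] > grown.ttc.alpha[2, 0]:
                votes += 1
        assert votes >= 4

    def test_dataset_count_must_cover_new_task(self, rng):
        model, datasets, _ = self._trained_two_task(rng)
        with pytest.raises(ValueError):
            add_task(model, TaskSpec("s", "regression", 1), datasets, TrainConfig(epochs=1))
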