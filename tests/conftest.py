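import numpy as np
import pytest

from ttcnet.model import ArchitectureSpec, TaskSpec, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dense_arch():
    """Small dense net without batch norm, suitable for gradient checks."""
    return ArchitectureSpec(
        input_hw=(4, 4), conv_channels=(), hidden_dim=6, batchnorm=False
    )


@pytest.fixture
def small_conv_arch():
    """Small conv net with batch norm: one 3x3 conv block on 8x8 inputs."""
    return ArchitectureSpec(input_hw=(8, 8), conv_channels=(4,), hidden_dim=8)


def make_regression_pair(arch, seed, lr_beta=0.01):
    """Two-regression-task model with identical initial subnets."""
    tasks = [TaskSpec("a", "regression", 1), TaskSpec("b", "regression", 1)]
    model = build_model(arch, tasks, seed=seed, lr_beta=lr_beta)
    model.subnets[1].set_weights(model.subnets[0].get_weights())
    return model


def linear_target(x, w):
    """Zero-mean learnable regression target for gate-adaptation runs."""
    return (x.reshape(len(x), -1) - 0.5) @ w[:, None]
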