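"""Multi-task CNN with learnable task-transfer connections (TTC).

Each prediction task owns a subnet of identical architecture (conv blocks
with batch normalization, activation and max pooling, then a hidden dense
layer and a task head).  Tasks are coupled during training only: every
subnet's weight update is an alpha-weighted sum of velocity terms derived
from *all* tasks' gradients, where the gate ``alpha[p][q] = sigmoid(beta[p][q])``
regulates how strongly task q's supervisory signal drives task p's subnet.
Diagonal gates are pinned to exactly 1 so each task's own signal always
dominates; off-diagonal gates live strictly inside (0, 1) and are learned.

The coupling is *gradient mixing over congruent parameter tensors*: task
q's gradient is mapped position-by-position onto subnet p wherever the
tensors have identical shape (the whole shared trunk; task heads of
differing output width receive no cross-task term).  Two degenerate limits
follow directly: with all off-diagonal gates at 0 the model decomposes into
independent single-task learners, and with identical subnets, shared
batches and uniform gates every subnet receives the same update.

Gate learning uses a first-order alignment surrogate: the sensitivity of
the receiving task's cost to the incoming velocity is the inner product
``s = <g_p, V^{W^{pq}}>``; beta moves by ``-lr_beta * s * alpha*(1-alpha)``,
so gates open between tasks whose gradients point the same way and close
between conflicting tasks.

All tensors are float64 and all randomness flows through
``numpy.random.Generator`` instances supplied by the caller, so training
trajectories are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TaskSpec",
    "ArchitectureSpec",
    "Subnet",
    "TTCState",
    "ModelState",
    "alpha_from_beta",
    "task_cost",
    "forward",
    "per_task_gradient",
    "clip_gradients",
    "cross_task_velocity",
    "update_weights",
    "beta_velocity",
    "train_step",
    "build_model",
]

EPS_PROB = 1e-7  # probability clamp before logs in cross-entropy costs
BN_EPS = 1e-5
BN_MOMENTUM = 0.1
LEAKY_SLOPE = 0.01


# --------------------------------------------------------------------------
# task and architecture specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSpec:
    """One prediction task: a classification or regression head."""

    task_id: str
    kind: Literal["classification", "regression"]
    output_dim: int
    loss_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("classification", "regression"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        if not self.loss_id:
            if self.kind == "regression":
                loss = "mean_squared_error"
            elif self.output_dim == 1:
                loss = "binary_cross_entropy"
            else:
                loss = "categorical_cross_entropy"
            object.__setattr__(self, "loss_id", loss)
        valid = {
            "classification": {"binary_cross_entropy", "categorical_cross_entropy"},
            "regression": {"mean_squared_error"},
        }
        if self.loss_id not in valid[self.kind]:
            raise ValueError(f"loss {self.loss_id!r} invalid for {self.kind} task")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Shared subnet architecture descriptor.

    ``conv_channels=()`` gives a pure dense network (useful for small
    gradient-check models); otherwise each conv block is
    3x3 conv (stride 1, same padding) -> batch norm -> activation ->
    2x2 max pool, so the input side length must be divisible by
    ``2**len(conv_channels)``.
    """

    input_hw: tuple[int, int] = (64, 64)
    in_channels: int = 1
    conv_channels: tuple[int, ...] = (8, 16, 32)
    batchnorm: bool = True
    activation: Literal["relu", "leaky_relu"] = "relu"
    hidden_dim: int = 64

    def __post_init__(self) -> None:
        h, w = self.input_hw
        f = 2 ** len(self.conv_channels)
        if self.conv_channels and (h % f or w % f):
            raise ValueError(
                f"input {self.input_hw} not divisible by pooling factor {f}"
            )

    @property
    def flat_dim(self) -> int:
        h, w = self.input_hw
        if not self.conv_channels:
            return h * w * self.in_channels
        f = 2 ** len(self.conv_channels)
        return (h // f) * (w // f) * self.conv_channels[-1]


# --------------------------------------------------------------------------
# layers (numpy forward/backward)
# --------------------------------------------------------------------------


class _Layer:
    """Base layer: ``params``/``grads`` are parallel lists of tensors."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.param_names: list[str] = []
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x, train, update_stats):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class _Conv3x3(_Layer):
    """3x3 convolution, stride 1, same (zero) padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * 9
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.param_names = ["w", "b"]

    def forward(self, x, train, update_stats):
        # x: (N, C, H, W)
        self._x_pad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(self._x_pad, (3, 3), axis=(2, 3))
        # win: (N, C, H, W, 3, 3)
        self._win = win
        w, b = self.params
        out = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
        return out + b[None, :, None, None]

    def backward(self, dout):
        w, _ = self.params
        dw = np.einsum("nchwij,nohw->ocij", self._win, dout, optimize=True)
        db = dout.sum(axis=(0, 2, 3))
        n, c, hp2, wp2 = self._x_pad.shape
        h, w_ = hp2 - 2, wp2 - 2
        dx_pad = np.zeros_like(self._x_pad)
        # scatter-add the nine kernel taps back onto the padded input
        for i in range(3):
            for j in range(3):
                contrib = np.einsum("nohw,oc->nchw", dout, w[:, :, i, j], optimize=True)
                dx_pad[:, :, i : i + h, j : j + w_] += contrib
        self.grads = [dw, db]
        return dx_pad[:, :, 1 : 1 + h, 1 : 1 + w_]


class _BatchNorm(_Layer):
    """Batch normalization over (N,) or (N, H, W) per channel/feature."""

    def __init__(self, dim: int, spatial: bool) -> None:
        super().__init__()
        self.spatial = spatial
        self.params = [np.ones(dim), np.zeros(dim)]
        self.param_names = ["gamma", "beta"]
        self.buffers = {"running_mean": np.zeros(dim), "running_var": np.ones(dim)}

    def _axes(self):
        return (0, 2, 3) if self.spatial else (0,)

    def _reshape(self, v):
        return v[None, :, None, None] if self.spatial else v[None, :]

    def forward(self, x, train, update_stats):
        axes = self._axes()
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if update_stats:
                self.buffers["running_mean"] *= 1.0 - BN_MOMENTUM
                self.buffers["running_mean"] += BN_MOMENTUM * mean
                self.buffers["running_var"] *= 1.0 - BN_MOMENTUM
                self.buffers["running_var"] += BN_MOMENTUM * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._std = np.sqrt(var + BN_EPS)
        self._xhat = (x - self._reshape(mean)) / self._reshape(self._std)
        self._m = x.size // x.shape[1]
        self._train = train
        gamma, beta = self.params
        return self._reshape(gamma) * self._xhat + self._reshape(beta)

    def backward(self, dout):
        axes = self._axes()
        gamma, _ = self.params
        dgamma = (dout * self._xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        dxhat = dout * self._reshape(gamma)
        if self._train:
            m = self._m
            dx = (
                dxhat
                - self._reshape(dxhat.sum(axis=axes)) / m
                - self._xhat * self._reshape((dxhat * self._xhat).sum(axis=axes)) / m
            ) / self._reshape(self._std)
        else:
            dx = dxhat / self._reshape(self._std)
        self.grads = [dgamma, dbeta]
        return dx


class _Activation(_Layer):
    def __init__(self, kind: str) -> None:
        super().__init__()
        self.slope = 0.0 if kind == "relu" else LEAKY_SLOPE

    def forward(self, x, train, update_stats):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        self.grads = []
        return np.where(self._mask, dout, self.slope * dout)


class _MaxPool2(_Layer):
    """2x2 max pooling, stride 2; ties go to the first window position."""

    def forward(self, x, train, update_stats):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._in_shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self.grads = []
        return dx


class _Flatten(_Layer):
    def forward(self, x, train, update_stats):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        self.grads = []
        return dout.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        b = np.zeros(d_out)
        self.params = [w, b]
        self.param_names = ["w", "b"]

    def forward(self, x, train, update_stats):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout):
        w, _ = self.params
        self.grads = [self._x.T @ dout, dout.sum(axis=0)]
        return dout @ w.T


# --------------------------------------------------------------------------
# subnet
# --------------------------------------------------------------------------


class Subnet:
    """One task's network branch; identical trunk architecture across tasks."""

    def __init__(
        self, arch: ArchitectureSpec, task: TaskSpec, rng: np.random.Generator
    ) -> None:
        self.arch = arch
        self.task = task
        layers: list[_Layer] = []
        c_in = arch.in_channels
        for c_out in arch.conv_channels:
            layers.append(_Conv3x3(c_in, c_out, rng))
            if arch.batchnorm:
                layers.append(_BatchNorm(c_out, spatial=True))
            layers.append(_Activation(arch.activation))
            layers.append(_MaxPool2())
            c_in = c_out
        layers.append(_Flatten())
        layers.append(_Dense(arch.flat_dim, arch.hidden_dim, rng))
        layers.append(_Activation(arch.activation))
        layers.append(_Dense(arch.hidden_dim, task.output_dim, rng))
        self.layers = layers

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def param_shapes(self) -> list[tuple[int, ...]]:
        return [p.shape for p in self.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    def get_buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, buf in layer.buffers.items():
                out[f"layer{i}.{name}"] = buf.copy()
        return out

    def set_buffers(self, buffers: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.buffers:
                layer.buffers[name][...] = buffers[f"layer{i}.{name}"]

    # -- execution ----------------------------------------------------------

    def _prep_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        h, w = self.arch.input_hw
        if self.arch.conv_channels:
            if x.ndim == 3:
                x = x[:, None, :, :]
            if x.shape[1:] != (self.arch.in_channels, h, w):
                raise ValueError(
                    f"input shape {x.shape[1:]} incompatible with architecture "
                    f"({self.arch.in_channels}, {h}, {w})"
                )
        else:
            x = x.reshape(x.shape[0], -1)
            if x.shape[1] != self.arch.flat_dim:
                raise ValueError(
                    f"input dim {x.shape[1]} != expected {self.arch.flat_dim}"
                )
        return x

    def forward(
        self, x: np.ndarray, train: bool = False, update_stats: bool = True
    ) -> np.ndarray:
        """Run the subnet; returns head activations (see ``task.kind``).

        Classification heads emit probabilities (softmax rows summing to 1,
        or a single sigmoid unit); regression heads emit unconstrained
        reals.
        """
        h = self._prep_input(x)
        for layer in self.layers:
            h = layer.forward(h, train, update_stats)
        self._logits = h
        if self.task.kind == "classification":
            if self.task.output_dim == 1:
                return _sigmoid(h)
            z = h - h.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return h

    def backward_from_outputs(
        self, outputs: np.ndarray, targets: np.ndarray
    ) -> list[np.ndarray]:
        """Gradient of the task cost w.r.t. all parameters.

        Uses the fused head gradient (softmax/sigmoid + cross-entropy or
        linear + MSE), which equals the derivative of :func:`task_cost`
        wherever the probability clamp is inactive.
        """
        targets = np.asarray(targets, dtype=float)
        n = outputs.shape[0]
        if self.task.kind == "classification":
            if self.task.output_dim == 1:
                dlogits = (outputs - targets.reshape(outputs.shape)) / n
            else:
                dlogits = (outputs - targets) / n
        else:
            dlogits = 2.0 * (outputs - targets.reshape(outputs.shape)) / (
                n * self.task.output_dim
            )
        d = dlogits
        grads_rev: list[np.ndarray] = []
        for layer in reversed(self.layers):
            d = layer.backward(d)
            grads_rev.extend(reversed(layer.grads))
        return list(reversed(grads_rev))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# --------------------------------------------------------------------------
# TTC state
# --------------------------------------------------------------------------


class TTCState:
    """Gate matrix alpha = sigmoid(beta) off-diagonal, exactly 1 on-diagonal.

    ``frozen[p, q]`` marks gates excluded from learning; a gate frozen with
    ``beta = -inf`` is exactly 0 (fully disconnected).  The diagonal is
    always frozen and never parameterized.
    """

    def __init__(self, n: int) -> None:
        if n < 1:
            raise ValueError("need at least one task")
        self.n = n
        self.beta = np.zeros((n, n))
        self.frozen = np.eye(n, dtype=bool)

    @property
    def alpha(self) -> np.ndarray:
        a = alpha_from_beta(self.beta)
        np.fill_diagonal(a, 1.0)
        return a

    def freeze_gate(self, p: int, q: int, alpha_value: float | None = None) -> None:
        """Freeze gate (p, q), optionally pinning it to a given alpha."""
        if p == q:
            raise ValueError("diagonal gates are always fixed at 1")
        if alpha_value is not None:
            if not (0.0 <= alpha_value < 1.0):
                raise ValueError("frozen alpha must lie in [0, 1)")
            self.beta[p, q] = (
                -np.inf if alpha_value == 0.0 else _logit(alpha_value)
            )
        self.frozen[p, q] = True

    def freeze_all_gates(self, alpha_value: float | None = None) -> None:
        for p in range(self.n):
            for q in range(self.n):
                if p != q:
                    self.freeze_gate(p, q, alpha_value)

    def grown(self) -> "TTCState":
        """Copy with one extra task appended (gates to/from it at beta=0)."""
        new = TTCState(self.n + 1)
        new.beta[: self.n, : self.n] = self.beta
        new.frozen[: self.n, : self.n] = self.frozen
        return new


def _logit(a: float) -> float:
    return float(np.log(a / (1.0 - a)))


def alpha_from_beta(beta) -> np.ndarray:
    """Numerically stable logistic sigmoid (maps -inf to exactly 0)."""
    return _sigmoid(np.asarray(beta, dtype=float))


# --------------------------------------------------------------------------
# costs
# --------------------------------------------------------------------------


def task_cost(outputs: np.ndarray, targets: np.ndarray, spec: TaskSpec) -> float:
    """Batch-mean discrepancy between outputs and targets.

    Binary cross-entropy ``-[B ln F + (1-B) ln(1-F)]`` for single-unit
    classification, its categorical generalization for multi-class, and
    mean squared error for regression.  Probabilities are clamped to
    ``[1e-7, 1 - 1e-7]`` before the logs.
    """
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if not (np.all(np.isfinite(outputs)) and np.all(np.isfinite(targets))):
        raise ValueError("non-finite values in cost inputs")
    if spec.loss_id == "mean_squared_error":
        diff = outputs - targets.reshape(outputs.shape)
        return float(np.mean(diff**2))
    f = np.clip(outputs, EPS_PROB, 1.0 - EPS_PROB)
    if spec.loss_id == "binary_cross_entropy":
        b = targets.reshape(f.shape)
        return float(np.mean(-(b * np.log(f) + (1.0 - b) * np.log(1.0 - f))))
    # categorical: targets one-hot (or already a distribution)
    if targets.shape != f.shape:
        raise ValueError(f"target shape {targets.shape} != output shape {f.shape}")
    return float(np.mean(-(targets * np.log(f)).sum(axis=1)))


def forward(subnet: Subnet, batch: np.ndarray) -> np.ndarray:
    """Inference-mode forward pass (running batch-norm statistics)."""
    return subnet.forward(batch, train=False)


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------


@dataclass
class Optimizer:
    """SGD with optional momentum, applied per ordered task pair.

    ``velocity(key, grads)`` returns ``mu * V_t - lr * g`` and stores the
    result under ``key`` when momentum is active; with ``mu = 0`` (default)
    it is stateless plain SGD.
    """

    lr: float = 0.001
    momentum: float = 0.0
    lr_beta: float = 0.01
    state: dict = field(default_factory=dict)

    def velocity(self, key, grads: Sequence[np.ndarray]) -> list[np.ndarray]:
        if self.momentum == 0.0:
            return [-self.lr * g for g in grads]
        prev = self.state.get(key)
        if prev is None:
            v = [-self.lr * g for g in grads]
        else:
            v = [self.momentum * pv - self.lr * g for pv, g in zip(prev, grads)]
        self.state[key] = v
        return v


# --------------------------------------------------------------------------
# model state and Algorithm-1 training step
# --------------------------------------------------------------------------


class ModelState:
    """All mutable training state: subnets, gates, optimizer, iteration."""

    def __init__(
        self,
        arch: ArchitectureSpec,
        tasks: Sequence[TaskSpec],
        subnets: Sequence[Subnet],
        ttc: TTCState,
        optimizer: Optimizer,
        clip_norm: float = 5.0,
    ) -> None:
        if len(tasks) != len(subnets) or len(tasks) != ttc.n:
            raise ValueError("task, subnet and gate counts must agree")
        self.arch = arch
        self.tasks = list(tasks)
        self.subnets = list(subnets)
        self.ttc = ttc
        self.optimizer = optimizer
        self.clip_norm = clip_norm
        self.iteration = 0
        self.frozen_subnets = [False] * len(tasks)

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)


def build_model(
    arch: ArchitectureSpec,
    tasks: Sequence[TaskSpec],
    seed: int | np.random.SeedSequence = 0,
    lr: float = 0.001,
    momentum: float = 0.0,
    lr_beta: float = 0.01,
    clip_norm: float = 5.0,
) -> ModelState:
    """Initialize one subnet per task from independent seed substreams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(tasks))
    subnets = [
        Subnet(arch, task, np.random.Generator(np.random.PCG64(child)))
        for task, child in zip(tasks, children)
    ]
    return ModelState(
        arch,
        tasks,
        subnets,
        TTCState(len(tasks)),
        Optimizer(lr=lr, momentum=momentum, lr_beta=lr_beta),
        clip_norm=clip_norm,
    )


def per_task_gradient(
    model: ModelState, batch: tuple[np.ndarray, np.ndarray], q: int
) -> tuple[list[np.ndarray], float]:
    """Gradient of task q's cost w.r.t. its own subnet, plus the cost value.

    Batch-norm uses the current batch's statistics; running statistics are
    only advanced for unfrozen subnets.
    """
    x, y = batch
    if len(np.asarray(x)) == 0:
        raise ValueError("empty batch")
    subnet = model.subnets[q]
    outputs = subnet.forward(
        x, train=True, update_stats=not model.frozen_subnets[q]
    )
    cost = task_cost(outputs, y, model.tasks[q])
    grads = subnet.backward_from_outputs(outputs, y)
    return grads, cost


def clip_gradients(grads: Sequence[np.ndarray], max_norm: float) -> list[np.ndarray]:
    """Scale the gradient set so its global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        return [g * scale for g in grads]
    return list(grads)


def cross_task_velocity(
    model: ModelState, g_q: Sequence[np.ndarray], p: int, q: int
) -> list[np.ndarray]:
    """Velocity contribution of task q's gradient to subnet p.

    Task q's gradient is mapped onto subnet p through the identity
    correspondence between congruent tensors; positions whose shapes
    differ (task heads of different width) receive zero.  The mapped
    gradient is then converted to a velocity by the optimizer rule.
    """
    shapes_p = model.subnets[p].param_shapes()
    shapes_q = model.subnets[q].param_shapes()
    if len(shapes_p) != len(shapes_q):
        raise ValueError("subnets have different parameter counts")
    mapped = []
    any_congruent = False
    for g, sp, sq in zip(g_q, shapes_p, shapes_q):
        if sp == sq:
            mapped.append(g)
            any_congruent = True
        else:
            mapped.append(np.zeros(sp))
    if not any_congruent:
        raise ValueError(f"no congruent tensors between subnets {p} and {q}")
    return model.optimizer.velocity(("w", p, q), mapped)


def update_weights(
    model: ModelState, velocities: dict[tuple[int, int], list[np.ndarray]]
) -> None:
    """Algorithm line: ``W^p <- W^p + sum_q alpha[p][q] * V^{W^{pq}}``."""
    alpha = model.ttc.alpha
    n = model.n_tasks
    for p in range(n):
        if model.frozen_subnets[p]:
            continue
        params = model.subnets[p].params
        deltas = [np.zeros_like(w) for w in params]
        for q in range(n):
            key = (p, q)
            if key not in velocities:
                raise ValueError(f"missing velocity for task pair {key}")
            a = alpha[p, q]
            for d, v in zip(deltas, velocities[key]):
                d += a * v
        for w, d in zip(params, deltas):
            w += d


def beta_velocity(
    model: ModelState,
    g_p: Sequence[np.ndarray],
    v_pq: Sequence[np.ndarray],
    p: int,
    q: int,
) -> float:
    """Gate update increment for the off-diagonal pair (p, q).

    The surrogate cost sensitivity is ``s = <g_p, V^{W^{pq}}>`` — the
    first-order change of task p's cost along the incoming velocity — and
    the beta step is ``-lr_beta * s * sigmoid'(beta)``.
    """
    if p == q:
        raise ValueError("diagonal gates are pinned; no beta update exists")
    s = sum(float(np.sum(g * v)) for g, v in zip(g_p, v_pq))
    a = alpha_from_beta(model.ttc.beta[p, q])
    return -model.optimizer.lr_beta * s * a * (1.0 - a)


def train_step(
    model: ModelState, batches: Sequence[tuple[np.ndarray, np.ndarray]]
) -> dict:
    """One full parameter update over all tasks.

    Runs the per-task gradients at the current weights, forms the
    cross-task velocities, applies the alpha-weighted weight updates, then
    updates the unfrozen off-diagonal gates and recomputes alpha.  Returns
    the per-task costs and the alpha matrix snapshot taken *before* the
    gate update (the values that weighted this step).
    """
    n = model.n_tasks
    if len(batches) != n:
        raise ValueError(f"expected {n} batches, got {len(batches)}")
    grads: list[list[np.ndarray]] = []
    costs: list[float] = []
    for q in range(n):
        g, c = per_task_gradient(model, batches[q], q)
        grads.append(clip_gradients(g, model.clip_norm))
        costs.append(c)

    velocities = {
        (p, q): cross_task_velocity(model, grads[q], p, q)
        for p in range(n)
        for q in range(n)
    }
    alpha_used = model.ttc.alpha
    update_weights(model, velocities)

    for p in range(n):
        for q in range(n):
            if p == q or model.ttc.frozen[p, q]:
                continue
            model.ttc.beta[p, q] += beta_velocity(
                model, grads[p], velocities[(p, q)], p, q
            )
    model.iteration += 1
    return {"costs": costs, "alpha": alpha_used}
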