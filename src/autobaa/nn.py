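"""A small, deterministic CNN engine on numpy.

Implements exactly what the detection and classification networks need:
im2col convolutions, max pooling, ReLU, dense layers, inception-style
branch/concat blocks, global average pooling, softmax cross-entropy, and
plain SGD with momentum, weight decay and a stepped learning-rate schedule.
Parameters carry per-group trainable flags so layer-wise fine-tuning depth
can freeze early groups.  All randomness flows through an explicit
``numpy.random.Generator``; identical seeds give bit-identical training
trajectories on a given platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import TrainingFailureError

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient and momentum buffer.

    ``buffer=True`` marks non-learned state (batch-norm running statistics):
    saved/restored with the model but never touched by SGD or by the
    fine-tuning freeze logic.
    """

    __slots__ = ("name", "value", "grad", "velocity", "trainable", "buffer")

    def __init__(
        self,
        name: str,
        value: np.ndarray,
        trainable: bool = True,
        buffer: bool = False,
    ):
        self.name = name
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)
        self.trainable = trainable and not buffer
        self.buffer = buffer


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, oh*ow, C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    v = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, oh * ow, c * k * k
    )
    return cols, (n, c, h, w, oh, ow)


def _col2im(dcols: np.ndarray, meta, k: int, stride: int, pad: int, out_shape):
    """Scatter-add the im2col gradient back onto the (padded) input."""
    n, c, h, w, oh, ow = meta
    dx = np.zeros((n, c, h, w), dtype=DTYPE)
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i: i + oh * stride: stride, j: j + ow * stride: stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    if dx.shape != out_shape:
        dx = dx[:, :, : out_shape[2], : out_shape[3]]
    return dx


class Conv2D(Layer):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, rng=None, name="conv"):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.stride, self.pad = stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        cols, meta = _im2col(x, self.k, self.stride, self.pad)
        y = cols @ self.weight.value.T + self.bias.value
        n, _, _, _, oh, ow = meta
        if train:
            self._cache = (cols, meta, x.shape)
        return np.ascontiguousarray(
            y.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)
        )

    def backward(self, dout):
        cols, meta, x_shape = self._cache
        n, _, _, _, oh, ow = meta
        d = dout.transpose(0, 2, 3, 1).reshape(n, oh * ow, self.out_ch)
        self.weight.grad += np.einsum("npo,npk->ok", d, cols, optimize=True)
        self.bias.grad += d.sum(axis=(0, 1))
        dcols = d @ self.weight.value
        self._cache = None
        return _col2im(dcols, meta, self.k, self.stride, self.pad, x_shape)


class MaxPool2D(Layer):
    def __init__(self, size=2, stride=None, pad=0):
        self.size = size
        self.stride = stride if stride is not None else size
        self.pad = pad
        self._cache = None

    def forward(self, x, train=False):
        s, st, p = self.size, self.stride, self.pad
        xp = x
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        v = sliding_window_view(xp, (s, s), axis=(2, 3))[:, :, ::st, ::st]
        n, c, oh, ow = v.shape[:4]
        flat = v.reshape(n, c, oh, ow, s * s)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, xp.shape, (n, c, oh, ow))
        return np.ascontiguousarray(out)

    def backward(self, dout):
        idx, x_shape, xp_shape, (n, c, oh, ow) = self._cache
        s, st, p = self.size, self.stride, self.pad
        dxp = np.zeros((n, c) + xp_shape[2:], dtype=DTYPE)
        for pos in range(s * s):
            i, j = divmod(pos, s)
            mask = idx == pos
            if not mask.any():
                continue
            target = dxp[:, :, i: i + oh * st: st, j: j + ow * st: st]
            target += np.where(mask, dout, 0.0)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        self._cache = None
        return dxp[:, :, : x_shape[2], : x_shape[3]]


class InputScale(Layer):
    """Fixed affine input remap (default [0, 1] -> [-1, 1]); no parameters."""

    def __init__(self, scale: float = 2.0, offset: float = -1.0):
        self.scale = scale
        self.offset = offset

    def forward(self, x, train=False):
        return x * DTYPE(self.scale) + DTYPE(self.offset)

    def backward(self, dout):
        return dout * DTYPE(self.scale)


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics.

    Uses batch statistics in training mode and running averages at
    inference; the learned scale/shift are ordinary parameters, the running
    statistics are buffers.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = Param(
            f"{name}.running_mean", np.zeros(channels), buffer=True
        )
        self.running_var = Param(
            f"{name}.running_var", np.ones(channels), buffer=True
        )
        self._cache = None

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean.value = (1 - m) * self.running_mean.value + m * mean
            self.running_var.value = (1 - m) * self.running_var.value + m * var
        else:
            mean = self.running_mean.value
            var = self.running_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dout):
        xhat, inv = self._cache
        self._cache = None
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        term1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        term2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / n) * (
            n * dxhat - term1 - xhat * term2
        ).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), self._shape
        ).astype(DTYPE)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng=None, name="fc"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_dim))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout):
        self.weight.grad += self._x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value.T


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Inception(Layer):
    """GoogLeNet-style block: 1x1 / 3x3 / 5x5 / pool-projection branches,
    channel-concatenated."""

    def __init__(self, in_ch, b1, b3r, b3, b5r, b5, proj, rng=None, name="inc"):
        self.branches = [
            Sequential([Conv2D(in_ch, b1, 1, rng=rng, name=f"{name}.b1"), ReLU()]),
            Sequential(
                [
                    Conv2D(in_ch, b3r, 1, rng=rng, name=f"{name}.b3r"),
                    ReLU(),
                    Conv2D(b3r, b3, 3, pad=1, rng=rng, name=f"{name}.b3"),
                    ReLU(),
                ]
            ),
            Sequential(
                [
                    Conv2D(in_ch, b5r, 1, rng=rng, name=f"{name}.b5r"),
                    ReLU(),
                    Conv2D(b5r, b5, 5, pad=2, rng=rng, name=f"{name}.b5"),
                    ReLU(),
                ]
            ),
            Sequential(
                [
                    MaxPool2D(3, stride=1, pad=1),
                    Conv2D(in_ch, proj, 1, rng=rng, name=f"{name}.proj"),
                    ReLU(),
                ]
            ),
        ]
        self.out_channels = b1 + b3 + b5 + proj
        self._splits = None

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dout):
        parts = np.split(dout, self._splits, axis=1)
        dx = None
        for branch, part in zip(self.branches, parts):
            g = branch.backward(np.ascontiguousarray(part))
            dx = g if dx is None else dx + g
        return dx


class Network:
    """Ordered named layer groups with per-group trainable control."""

    def __init__(self, groups: list[tuple[str, Layer]]):
        self.groups = groups
        self.group_names = [n for n, _ in groups]

    def params(self) -> list[Param]:
        return [p for _, layer in self.groups for p in layer.params()]

    def group_params(self, name: str) -> list[Param]:
        for n, layer in self.groups:
            if n == name:
                return layer.params()
        raise KeyError(name)

    def set_trainable_from(self, first_trainable_group: str | None):
        """Freeze groups before ``first_trainable_group``; ``None`` = all."""
        training = first_trainable_group is None
        for n, layer in self.groups:
            if n == first_trainable_group:
                training = True
            for p in layer.params():
                if not p.buffer:
                    p.trainable = training

    def forward(self, x, train=False):
        for _, layer in self.groups:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for _, layer in reversed(self.groups):
            dout = layer.backward(dout)
        return dout

    def state(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state(self, state: dict[str, np.ndarray]):
        for p in self.params():
            p.value = np.asarray(state[p.name], dtype=DTYPE).reshape(p.value.shape)
            p.velocity = np.zeros_like(p.value)
            p.grad = np.zeros_like(p.value)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


def step_lr(base_lr: float, gamma: float, epoch: int, total_epochs: int) -> float:
    """Stepped schedule: multiply by gamma at E/4, E/2 and 3E/4."""
    boundaries = [total_epochs // 4, total_epochs // 2, (3 * total_epochs) // 4]
    passed = sum(1 for b in boundaries if b > 0 and epoch >= b)
    return base_lr * gamma**passed


def sgd_step(params: list[Param], lr: float, momentum: float, weight_decay: float):
    for p in params:
        if not p.trainable:
            p.grad[...] = 0.0
            continue
        p.velocity = momentum * p.velocity - lr * (p.grad + weight_decay * p.value)
        p.value = p.value + p.velocity
        p.grad[...] = 0.0


def predict_logits(net: Network, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    outs = [
        net.forward(x[i: i + batch_size].astype(DTYPE))
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(outs, axis=0)


def _metric_fn(name):
    if callable(name):
        return name
    if name == "accuracy":
        return lambda pred, true: float((pred == true).mean())
    if name == "within1":
        return lambda pred, true: float((np.abs(pred - true) <= 1).mean())
    raise ValueError(f"unknown validation metric {name!r}")


def fit_network(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int,
    base_lr: float,
    gamma: float = 0.1,
    momentum: float = 0.9,
    weight_decay: float = 0.0,
    batch_size: int = 128,
    rng: np.random.Generator | None = None,
    augment=None,
    val_metric="accuracy",
) -> dict:
    """SGD training with best-by-validation snapshotting.

    ``augment``, if given, is called per batch as ``augment(x_batch, rng)``
    and must return a transformed batch of the same shape (on-line data
    augmentation).  ``val_metric`` scores the validation predictions for
    snapshot selection ("accuracy", "within1", or a callable); plain top-1
    validation accuracy is always logged as well.  Returns a history dict;
    the network is left holding the parameters of the best validation epoch
    (the most-trained snapshot among ties).
    """
    rng = rng or np.random.default_rng(0)
    metric = _metric_fn(val_metric)
    x = x.astype(DTYPE)
    history = {"loss": [], "train_accuracy": [], "val_accuracy": [],
               "val_metric": [], "lr": []}
    best_score, best_state = -1.0, net.state()
    best_acc = 0.0
    n = len(x)
    for epoch in range(epochs):
        lr = step_lr(base_lr, gamma, epoch, epochs)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_correct = 0
        for i in range(0, n, batch_size):
            idx = order[i: i + batch_size]
            xb = x[idx]
            if augment is not None:
                xb = augment(xb, rng).astype(DTYPE)
            logits = net.forward(xb, train=True)
            loss, grad = cross_entropy_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingFailureError(
                    f"loss diverged to {loss} at epoch {epoch}"
                )
            n_correct += int((logits.argmax(axis=1) == y[idx]).sum())
            net.backward(grad)
            sgd_step(net.params(), lr, momentum, weight_decay)
            epoch_loss += loss * len(idx)
        val_pred = predict_logits(net, x_val).argmax(axis=1)
        val_acc = float((val_pred == y_val).mean())
        val_score = metric(val_pred, y_val)
        history["loss"].append(epoch_loss / n)
        history["train_accuracy"].append(n_correct / n)
        history["val_accuracy"].append(val_acc)
        history["val_metric"].append(val_score)
        history["lr"].append(lr)
        if val_score >= best_score:
            best_score = val_score
            best_acc = val_acc
            best_state = net.state()
    net.load_state(best_state)
    history["best_val_accuracy"] = best_acc
    history["best_val_metric"] = best_score
    return history
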