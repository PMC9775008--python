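"""Minimal NumPy neural-network core.

Small convolutional classifiers trained by mini-batch SGD with momentum.
This is deliberately tiny: desk-scale presets stand in for the large CNN
families used on full microscopy datasets, while keeping the same training
contract (softmax probabilities, SGD with momentum, early stopping on
validation loss).

Arrays are NCHW float32. All randomness flows through a caller-supplied
``numpy.random.Generator`` so identical seeds give identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Residual",
    "DenseConcat",
    "Sequential",
    "TrainConfig",
    "TrainLog",
    "softmax",
    "train_classifier",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Layer:
    """Base layer: forward caches what backward needs; params/grads are lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*k*k) patches at stride 1 with zero padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # sliding_window_view gives (N, C, H, W, k, k)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
    return np.ascontiguousarray(col)


class Conv2D(Layer):
    """Same-padded stride-1 convolution with He-initialized kernels."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        scale = np.sqrt(2.0 / (cin * k * k))
        w = rng.normal(0.0, scale, size=(cout, cin * k * k)).astype(np.float32)
        b = np.zeros(cout, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._col = _im2col(x, self.k, self.k // 2)
        n, _, h, w = x.shape
        out = self._col @ self.params[0].T + self.params[1]
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        gflat = g.transpose(0, 2, 3, 1).reshape(n, h * w, self.cout)
        self.grads[0][...] = np.einsum("npo,npk->ok", gflat, self._col)
        self.grads[1][...] = gflat.sum(axis=(0, 1))
        gcol = gflat @ self.params[0]  # (N, H*W, C*k*k)
        # scatter columns back (col2im)
        k, pad = self.k, self.k // 2
        c = self.cin
        gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        gcol = gcol.reshape(n, h, w, c, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di : di + h, dj : dj + w] += gcol[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return gx[:, :, pad : pad + h, pad : pad + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2D(Layer):
    """Non-overlapping k x k max pooling; H and W must be divisible by k."""

    def __init__(self, k: int = 2) -> None:
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        xr = x.reshape(n, c, h // k, k, w // k, k)
        self._xr = xr
        out = xr.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, hh, ww = g.shape
        k = self.k
        mask = self._xr == self._out[:, :, :, None, :, None]
        # spread gradient to the (first-encountered ties share) max positions
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * (g[:, :, :, None, :, None] / counts)
        return gx.reshape(n, c, hh * k, ww * k).astype(np.float32)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None] / (h * w), self._shape).astype(
            np.float32
        )


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / nin)
        w = rng.normal(0.0, scale, size=(nin, nout)).astype(np.float32)
        b = np.zeros(nout, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.params[0].T


class Residual(Layer):
    """y = x + f(x); f must preserve shape (the skip connection of residual nets)."""

    def __init__(self, inner: list[Layer]) -> None:
        super().__init__()
        self.inner = inner

    @property
    def all_layers(self) -> list[Layer]:
        return self.inner

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x
        for layer in self.inner:
            y = layer.forward(y)
        return x + y

    def backward(self, g: np.ndarray) -> np.ndarray:
        gy = g
        for layer in reversed(self.inner):
            gy = layer.backward(gy)
        return g + gy


class DenseConcat(Layer):
    """y = concat(x, f(x)) on channels (the dense connectivity pattern)."""

    def __init__(self, inner: list[Layer]) -> None:
        super().__init__()
        self.inner = inner

    @property
    def all_layers(self) -> list[Layer]:
        return self.inner

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cin = x.shape[1]
        y = x
        for layer in self.inner:
            y = layer.forward(y)
        return np.concatenate([x, y], axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx, gy = g[:, : self._cin], g[:, self._cin :]
        gy = np.ascontiguousarray(gy)
        for layer in reversed(self.inner):
            gy = layer.backward(gy)
        return gx + gy


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def _flat(self) -> list[Layer]:
        out: list[Layer] = []
        for layer in self.layers:
            out.append(layer)
            if hasattr(layer, "all_layers"):
                out.extend(layer.all_layers)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = [softmax(self.forward(x[i : i + batch])) for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._flat() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._flat() for g in layer.grads]

    def state_arrays(self) -> list[np.ndarray]:
        return self.parameters()

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for p, a in zip(params, arrays):
            p[...] = a


@dataclass
class TrainConfig:
    """SGD settings: momentum 0.9, batch 16, at most 100 epochs, stopping
    when the validation loss stops decreasing.

    The default learning rate (0.01) suits the tiny randomly initialized
    presets; the 1e-3 rate customary for large pretrained networks is an
    order of magnitude too slow for them."""

    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 6
    min_epochs: int = 8  # early stopping armed only after this point
    val_fraction: float = 0.1


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0

    @property
    def final_val_loss(self) -> float:
        return self.val_loss[-1] if self.val_loss else float("nan")


def _ce_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    g = p
    g[np.arange(n), y] -= 1.0
    return loss, g / n


def train_classifier(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> TrainLog:
    """Train a softmax classifier with momentum SGD and early stopping.

    A validation split (cfg.val_fraction, stratification-free shuffle) is
    carved out to monitor the loss; training stops once the validation loss
    has not improved for ``patience`` consecutive epochs or at max_epochs.
    The best-so-far weights are restored on exit.
    """
    n = len(x)
    order = rng.permutation(n)
    # at least 8 validation samples (when available): a smaller split makes
    # the early-stopping signal pure noise on desk-scale datasets
    n_val = min(max(8, int(round(cfg.val_fraction * n))), max(1, n - 2))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("dataset too small to split for validation")
    xtr, ytr = x[tr_idx], y[tr_idx]
    xval, yval = x[val_idx], y[val_idx]

    params = model.parameters()
    grads = model.gradients()
    vel = [np.zeros_like(p) for p in params]
    log = TrainLog()
    best = np.inf
    best_state = [p.copy() for p in params]
    bad = 0

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(xtr))
        ep_loss = 0.0
        nb = 0
        for i in range(0, len(xtr), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            logits = model.forward(xtr[idx])
            loss, g = _ce_loss_and_grad(logits, ytr[idx])
            model.backward(g)
            for p, gr, v in zip(params, grads, vel):
                v *= cfg.momentum
                v -= cfg.lr * gr
                p += v
            ep_loss += loss
            nb += 1
        vloss, _ = _ce_loss_and_grad(model.forward(xval), yval)
        log.train_loss.append(ep_loss / max(nb, 1))
        log.val_loss.append(vloss)
        log.stopped_epoch = epoch + 1
        if vloss < best - 1e-6:
            best = vloss
            best_state = [p.copy() for p in params]
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience and epoch + 1 >= cfg.min_epochs:
                break
    model.load_state_arrays(best_state)
    # report the loss of the restored weights as the final validation loss
    vloss, _ = _ce_loss_and_grad(model.forward(xval), yval)
    log.val_loss.append(vloss)
    return log


# ---------------------------------------------------------------------------
# Desk-scale architecture presets
#
# Four tiny convolutional families with distinct inductive biases, standing
# in for the classical large CNNs: a wide-kernel shallow net, a deep 3x3
# stack, a residual (skip-connection) net, and a densely connected net.
# All expect 32x32 RGB inputs.
# ---------------------------------------------------------------------------

ARCHITECTURE_MENU = ("alexnet-tiny", "vgg-tiny", "resnet-tiny", "densenet-tiny")


def build_preset(name: str, rng: np.random.Generator, n_out: int = 2) -> Sequential:
    """Instantiate a named tiny architecture with freshly seeded weights."""
    if name == "alexnet-tiny":
        return Sequential([
            Conv2D(3, 8, 5, rng), ReLU(), MaxPool2D(2),
            Conv2D(8, 16, 3, rng), ReLU(), MaxPool2D(2),
            Flatten(), Dense(16 * 8 * 8, n_out, rng),
        ])
    if name == "vgg-tiny":
        return Sequential([
            Conv2D(3, 8, 3, rng), ReLU(),
            Conv2D(8, 8, 3, rng), ReLU(), MaxPool2D(2),
            Conv2D(8, 16, 3, rng), ReLU(), MaxPool2D(2),
            GlobalAvgPool(), Dense(16, n_out, rng),
        ])
    if name == "resnet-tiny":
        return Sequential([
            Conv2D(3, 8, 3, rng), ReLU(), MaxPool2D(2),
            Residual([Conv2D(8, 8, 3, rng), ReLU(), Conv2D(8, 8, 3, rng)]),
            ReLU(), MaxPool2D(2),
            GlobalAvgPool(), Dense(8, n_out, rng),
        ])
    if name == "densenet-tiny":
        return Sequential([
            Conv2D(3, 6, 3, rng), ReLU(), MaxPool2D(2),
            DenseConcat([Conv2D(6, 6, 3, rng), ReLU()]),
            MaxPool2D(2), GlobalAvgPool(), Dense(12, n_out, rng),
        ])
    raise ValueError(f"unknown architecture: {name!r} (menu: {ARCHITECTURE_MENU})")
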