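"""A small, deterministic feed-forward/1-D convolutional network engine.

Implements exactly the layer vocabulary the fingerprint predictor needs —
Embedding, Conv1D (valid padding, ReLU), MaxPool1D, Dropout, Flatten, and
Dense — with reverse-mode gradients, binary cross-entropy loss averaged
over all outputs, a binary-accuracy metric, and the Adam optimizer.
Everything is plain numpy; all randomness (weight init, shuffling,
dropout masks) flows through one seeded ``numpy.random.Generator`` so a
fixed seed yields bit-identical initial weights and training logs.

Weight initialization is activation-aware: He-normal for ReLU layers
(Glorot under-scales activations through stacked ReLUs, which stalls the
four-deep dense head at the all-zeros solution on imbalanced multi-label
targets), Glorot-uniform for sigmoid/linear layers, and N(0, 0.3) for
embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrainingDiverged(RuntimeError):
    """Loss became NaN/inf; training aborts with diagnostics."""


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _he(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    name = "layer"
    trainable: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return [getattr(self, n) for n in self.trainable]

    def grads(self) -> list[np.ndarray]:
        return [getattr(self, "d_" + n) for n in self.trainable]


class Embedding(Layer):
    """Integer tokens (B, L) -> dense vectors (B, L, dim)."""

    name = "embedding"
    trainable = ("W",)

    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        self.vocab, self.dim = vocab, dim
        # std 0.3 keeps token vectors near unit scale; smaller inits let the
        # signal vanish through the conv/pool/dense chain and training stalls
        # at the all-zeros solution on sparse multi-label targets
        self.W = rng.normal(0.0, 0.3, size=(vocab, dim))

    def forward(self, x, training, rng):
        self._x = x.astype(np.intp)
        return self.W[self._x]

    def backward(self, grad):
        self.d_W = np.zeros_like(self.W)
        np.add.at(self.d_W, self._x, grad)
        return np.zeros(self._x.shape)  # integer input carries no gradient


class Conv1D(Layer):
    """Valid-padding 1-D convolution with ReLU, via an im2col matmul."""

    name = "conv1d"
    trainable = ("W", "b")

    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        self.kernel, self.filters, self.in_channels = kernel, filters, in_channels
        fan_in = kernel * in_channels
        self.W = _he(rng, fan_in, (fan_in, filters))  # ReLU follows
        self.b = np.zeros(filters)

    def _windows(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        out_len = L - self.kernel + 1
        if out_len < 1:
            raise ValueError(f"sequence length {L} shorter than kernel {self.kernel}")
        s0, s1, s2 = x.strides
        win = np.lib.stride_tricks.as_strided(
            x, shape=(B, out_len, self.kernel, C), strides=(s0, s1, s1, s2), writeable=False
        )
        return win.reshape(B, out_len, self.kernel * C)

    def forward(self, x, training, rng):
        self._x_shape = x.shape
        self._cols = self._windows(np.ascontiguousarray(x))
        z = self._cols @ self.W + self.b
        self._mask = z > 0
        return z * self._mask

    def backward(self, grad):
        grad = grad * self._mask
        B, out_len, _ = grad.shape
        flat_g = grad.reshape(-1, self.filters)
        flat_c = self._cols.reshape(-1, self.kernel * self.in_channels)
        self.d_W = flat_c.T @ flat_g
        self.d_b = flat_g.sum(axis=0)
        d_cols = (flat_g @ self.W.T).reshape(B, out_len, self.kernel, self.in_channels)
        dx = np.zeros(self._x_shape)
        for k in range(self.kernel):  # scatter the overlapping windows back
            dx[:, k : k + out_len, :] += d_cols[:, :, k, :]
        return dx


class MaxPool1D(Layer):
    name = "maxpool1d"

    def __init__(self, size: int):
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size

    def forward(self, x, training, rng):
        B, L, C = x.shape
        n = L // self.size
        if n < 1:
            raise ValueError(f"sequence length {L} shorter than pool size {self.size}")
        self._in_shape = x.shape
        blocks = x[:, : n * self.size, :].reshape(B, n, self.size, C)
        self._argmax = blocks.argmax(axis=2)
        return blocks.max(axis=2)

    def backward(self, grad):
        B, n, C = grad.shape
        pooled = np.zeros((B, n, self.size, C))
        bi, ni, ci = np.ogrid[:B, :n, :C]
        pooled[bi, ni, self._argmax, ci] = grad
        dx = np.zeros(self._in_shape)
        dx[:, : n * self.size, :] = pooled.reshape(B, n * self.size, C)
        return dx


class Dropout(Layer):
    name = "dropout"

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with ReLU, sigmoid, or linear activation."""

    name = "dense"
    trainable = ("W", "b")

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        if activation not in ("relu", "sigmoid", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        if activation == "relu":
            self.W = _he(rng, n_in, (n_in, n_out))
        else:
            self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, training, rng):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        if self.activation == "sigmoid":
            self._out = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            return self._out
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        elif self.activation == "sigmoid":
            grad = grad * self._out * (1.0 - self._out)
        self.d_W = self._x.T @ grad
        self.d_b = grad.sum(axis=0)
        return grad @ self.W.T


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None
        self._t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1 - self.beta1**self._t
        b2t = 1 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def binary_cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    p = np.clip(probs, 1e-7, 1 - 1e-7)
    return float(-np.mean(targets * np.log(p) + (1 - targets) * np.log(1 - p)))


def bce_grad(probs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(probs); paired with the sigmoid backward this yields
    the usual (p - y)/N logit gradient."""
    p = np.clip(probs, 1e-7, 1 - 1e-7)
    return (p - targets) / (p * (1 - p)) / targets.size


def binary_accuracy(probs: np.ndarray, targets: np.ndarray, threshold: float = 0.5) -> float:
    return float(np.mean((probs >= threshold).astype(int) == targets))


@dataclass
class Sequential:
    """An ordered layer stack with BCE training under Adam."""

    layers: list[Layer]
    seed: int = 0
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    @property
    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, self._rng)
        return x

    predict = forward

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        epochs: int,
        batch_size: int,
        lr: float = 1e-3,
        verbose: bool = False,
    ) -> list[dict]:
        """Mini-batch Adam on mean binary cross-entropy; returns the
        per-epoch log of loss and binary accuracy."""
        if len(X) != len(Y):
            raise ValueError("X and Y must have equal length")
        opt = Adam(lr=lr)
        n = len(X)
        for epoch in range(epochs):
            order = self._rng.permutation(n)
            losses, accs, weights = [], [], []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], Y[idx]
                probs = self.forward(xb, training=True)
                loss = binary_cross_entropy(probs, yb)
                if not np.isfinite(loss):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch}, batch {start // batch_size}"
                    )
                self._backward(bce_grad(probs, yb))
                opt.step(self.parameters(), [g for layer in self.layers for g in layer.grads()])
                losses.append(loss)
                accs.append(binary_accuracy(probs, yb))
                weights.append(len(idx))
            entry = {
                "epoch": epoch,
                "loss": float(np.average(losses, weights=weights)),
                "binary_accuracy": float(np.average(accs, weights=weights)),
            }
            self.log.append(entry)
            if verbose:
                print(f"epoch {epoch}: loss={entry['loss']:.4f} acc={entry['binary_accuracy']:.4f}")
        return self.log

    # --- serialization -------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name in layer.trainable:
                out[f"{i}:{layer.name}:{name}"] = getattr(layer, name)
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.trainable:
                key = f"{i}:{layer.name}:{name}"
                current = getattr(layer, name)
                if weights[key].shape != current.shape:
                    raise ValueError(f"shape mismatch for {key}")
                setattr(layer, name, weights[key].copy())
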