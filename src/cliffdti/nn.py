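"""Minimal feed-forward network core used by the two-branch AC/DTI models.

Parameters live in named groups (compound encoder, protein encoder, head,
optional adapter) so that transfer learning can copy or freeze a group as a
unit. Frozen groups still propagate gradients to upstream layers but their
own parameters are never updated, and they remain bit-identical across a
training run.

The implementation is deliberately small: dense layers, ReLU/tanh
activations, inverted dropout, mean-squared-error and binary-cross-entropy
losses, and Adam. Everything is deterministic given a seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(z.dtype)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "linear": (lambda z: z, lambda z: np.ones_like(z)),
}


class Dense:
    """Affine layer with He-scaled Gaussian init."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(0.0, scale, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)

    @property
    def shape(self):
        return self.W.shape

    def params(self):
        return [self.W, self.b]


class Sequential:
    """A stack of dense layers forming one parameter group.

    ``activate_last`` controls whether the activation is applied after the
    final layer (encoders: yes, so embeddings are post-activation; heads:
    no, the task decides the output nonlinearity).
    """

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 activation: str = "relu", activate_last: bool = True,
                 dropout: float = 0.0):
        if any(d <= 0 for d in dims):
            raise ValueError(f"layer dims must be positive, got {dims}")
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.dims = list(dims)
        self.activation = activation
        self.activate_last = activate_last
        self.dropout = dropout
        self.layers = [Dense(dims[i], dims[i + 1], rng)
                       for i in range(len(dims) - 1)]

    @property
    def in_dim(self) -> int:
        return self.dims[0]

    @property
    def out_dim(self) -> int:
        return self.dims[-1]

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return (output, cache). Dropout is active only when training."""
        act, _ = _ACTIVATIONS[self.activation]
        cache = {"inputs": [], "pre": [], "masks": []}
        h = x
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            cache["inputs"].append(h)
            z = h @ layer.W + layer.b
            cache["pre"].append(z)
            last = i == n - 1
            h = act(z) if (not last or self.activate_last) else z
            if train and self.dropout > 0.0 and (not last or self.activate_last):
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
                cache["masks"].append(mask)
            else:
                cache["masks"].append(None)
        return h, cache

    def backward(self, cache, grad_out: np.ndarray):
        """Return (grad wrt input, [(dW, db), ...] per layer)."""
        _, dact = _ACTIVATIONS[self.activation]
        grads = [None] * len(self.layers)
        g = grad_out
        n = len(self.layers)
        for i in range(n - 1, -1, -1):
            mask = cache["masks"][i]
            if mask is not None:
                g = g * mask
            last = i == n - 1
            if not last or self.activate_last:
                g = g * dact(cache["pre"][i])
            x = cache["inputs"][i]
            grads[i] = (x.T @ g, g.sum(axis=0))
            g = g @ self.layers[i].W.T
        return g, grads

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != 2 * len(self.layers):
            raise ValueError("weight list length mismatch")
        for i, layer in enumerate(self.layers):
            W, b = weights[2 * i], weights[2 * i + 1]
            if W.shape != layer.W.shape or b.shape != layer.b.shape:
                raise ValueError(
                    f"layer {i} shape mismatch: have {layer.W.shape}, "
                    f"got {W.shape}")
            layer.W = W.copy()
            layer.b = b.copy()

    def digest(self) -> str:
        """SHA-256 over all parameter bytes; detects any in-place change."""
        h = hashlib.sha256()
        for layer in self.layers:
            h.update(np.ascontiguousarray(layer.W).tobytes())
            h.update(np.ascontiguousarray(layer.b).tobytes())
        return h.hexdigest()


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray,
                      pos_weight: float = 1.0):
    """Binary cross-entropy on logits; returns (mean loss, dL/dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    w = np.where(y == 1, pos_weight, 1.0)
    loss = -np.mean(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    grad = w * (p - y) / len(y)
    return float(loss), grad


def mse_loss_and_grad(pred: np.ndarray, y: np.ndarray):
    diff = pred - y
    return float(np.mean(diff ** 2)), 2.0 * diff / len(y)
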