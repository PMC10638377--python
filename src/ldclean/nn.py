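"""Minimal feed-forward neural-network engine for record data.

Implements the three record-model families the toolkit trains — a plain
MLP, a multi-branch MLP whose parallel input branches use contrasting
activations (sigmoid / tanh / relu), and a 1-D convolutional net — with
minibatch SGD (momentum) or Adam, inverted dropout, and softmax
cross-entropy.  Everything is plain numpy: deterministic given the seed,
no threading, and small enough to train dozens of contributors on desk
hardware.

The public surface is :func:`build_network` plus :meth:`Network.fit` /
:meth:`Network.predict_proba`; gradients are exercised by a numerical
differentiation check in the test suite.
"""

from __future__ import annotations

import numpy as np

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a**2),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60))),
        lambda z, a: a * (1.0 - a),
    ),
}


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Activation(Layer):
    def __init__(self, name: str):
        super().__init__()
        self.fn, self.deriv = _ACTIVATIONS[name]

    def forward(self, x, train, rng):
        self._z = x
        self._a = self.fn(x)
        return self._a

    def backward(self, dout):
        return dout * self.deriv(self._z, self._a)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Conv1D(Layer):
    """Valid-mode 1-d convolution over the feature axis, (B, d) -> (B, ch*L)."""

    def __init__(self, n_in: int, channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size > n_in:
            raise ValueError("kernel_size exceeds the feature dimension")
        self.k = kernel_size
        self.channels = channels
        self.L = n_in - kernel_size + 1
        self.W = rng.standard_normal((channels, kernel_size)) * np.sqrt(2.0 / kernel_size)
        self.b = np.zeros(channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.n_out = channels * self.L

    def forward(self, x, train, rng):
        # windows: (B, L, k)
        self._win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        out = np.einsum("blk,ck->bcl", self._win, self.W) + self.b[None, :, None]
        self._B, self._d = x.shape
        return out.reshape(len(x), -1)

    def backward(self, dout):
        dout = dout.reshape(self._B, self.channels, self.L)
        self.grads[0][...] = np.einsum("bcl,blk->ck", dout, self._win)
        self.grads[1][...] = dout.sum(axis=(0, 2))
        dx = np.zeros((self._B, self._d))
        for k in range(self.k):
            dx[:, k:k + self.L] += np.einsum("bcl,c->bl", dout, self.W[:, k])
        return dx


class MultiBranch(Layer):
    """Parallel dense branches on the same input, concatenated.

    Each branch carries its own activation; contrasting activations give
    the branches different inductive biases.
    """

    def __init__(self, n_in: int, branch_width: int, activations: list[str],
                 rng: np.random.Generator):
        super().__init__()
        self.branches = [
            (Dense(n_in, branch_width, rng), Activation(a)) for a in activations
        ]
        for dense, _ in self.branches:
            self.params.extend(dense.params)
            self.grads.extend(dense.grads)
        self.n_out = branch_width * len(activations)
        self.width = branch_width

    def forward(self, x, train, rng):
        outs = [act.forward(d.forward(x, train, rng), train, rng)
                for d, act in self.branches]
        return np.concatenate(outs, axis=1)

    def backward(self, dout):
        dx = 0.0
        for i, (dense, act) in enumerate(self.branches):
            sl = dout[:, i * self.width:(i + 1) * self.width]
            dx = dx + dense.backward(act.backward(sl))
        return dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A stack of layers ending in a softmax classification head."""

    def __init__(self, layers: list[Layer], n_classes: int):
        self.layers = layers
        self.n_classes = n_classes

    # -- parameter snapshots -------------------------------------------------
    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_params(self, flat: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = flat[i]
                i += 1

    def _all_params(self):
        return [(p, g) for layer in self.layers
                for p, g in zip(layer.params, layer.grads)]

    # -- forward / backward --------------------------------------------------
    def forward(self, x, train, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in evaluation mode (dropout off, deterministic)."""
        return _softmax(self.forward(np.asarray(x, dtype=float), train=False))

    def loss_and_grads(self, x, y, rng):
        """Mean cross-entropy on a batch; fills every layer's grads."""
        logits = self.forward(x, train=True, rng=rng)
        probs = _softmax(logits)
        B = len(x)
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(B), y] + eps))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        return loss

    # -- training ------------------------------------------------------------
    def fit(self, X, y, *, epochs: int, learning_rate: float = 0.05,
            batch_size: int = 32, optimizer: str = "sgd", momentum: float = 0.9,
            seed: int = 0, callback=None) -> None:
        """Minibatch training; ``callback(epoch)`` runs after each epoch."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(seed)
        pairs = self._all_params()
        if optimizer == "sgd":
            vel = [np.zeros_like(p) for p, _ in pairs]
        elif optimizer == "adam":
            m = [np.zeros_like(p) for p, _ in pairs]
            v = [np.zeros_like(p) for p, _ in pairs]
            t = 0
        else:
            raise ValueError(f"unknown optimizer {optimizer!r}")
        n = len(X)
        for epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss = self.loss_and_grads(X[idx], y[idx], rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss at epoch {epoch})"
                    )
                if optimizer == "sgd":
                    for j, (p, g) in enumerate(pairs):
                        vel[j] = momentum * vel[j] - learning_rate * g
                        p += vel[j]
                else:
                    t += 1
                    b1, b2, eps = 0.9, 0.999, 1e-8
                    for j, (p, g) in enumerate(pairs):
                        m[j] = b1 * m[j] + (1 - b1) * g
                        v[j] = b2 * v[j] + (1 - b2) * g**2
                        mh = m[j] / (1 - b1**t)
                        vh = v[j] / (1 - b2**t)
                        p -= learning_rate * mh / (np.sqrt(vh) + eps)
            if callback is not None:
                callback(epoch)


def build_network(
    architecture: str,
    input_dim: int,
    n_classes: int,
    hidden_sizes: list[int],
    *,
    branch_activations: list[str] | None = None,
    conv_channels: int = 4,
    kernel_size: int = 5,
    dropout_rate: float = 0.1,
    seed: int = 0,
) -> Network:
    """Construct one of the record-model architectures.

    ``mlp``: dense/relu stack.  ``multi_branch_mlp``: parallel dense input
    branches with the given activations, concatenated, then a dense/relu
    stack.  ``conv1d``: a valid-mode 1-d convolution front end, then dense
    layers.  Dropout follows the first hidden representation.
    """
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    if architecture == "mlp":
        width = input_dim
    elif architecture == "multi_branch_mlp":
        acts = branch_activations or ["sigmoid", "tanh", "relu"]
        if hidden_sizes:
            branch_width = max(1, hidden_sizes[0] // len(acts))
            hidden_sizes = hidden_sizes[1:]
        else:
            branch_width = 16
        front = MultiBranch(input_dim, branch_width, acts, rng)
        layers.append(front)
        width = front.n_out
    elif architecture == "conv1d":
        front = Conv1D(input_dim, conv_channels, kernel_size, rng)
        layers.append(front)
        layers.append(Activation("relu"))
        width = front.n_out
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    first_hidden = True
    for h in hidden_sizes:
        layers.append(Dense(width, h, rng))
        layers.append(Activation("relu"))
        if first_hidden:
            layers.append(Dropout(dropout_rate))
            first_hidden = False
        width = h
    layers.append(Dense(width, n_classes, rng))
    return Network(layers, n_classes)
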