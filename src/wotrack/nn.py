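"""Minimal dense neural-network engine for the embedded ON/OFF classifiers.

Implements exactly the ingredients of the four deployed network
configurations: a batch-normalization input layer, fully connected hidden
layers with ReLU/Tanh/SeLU activations, a single sigmoid output unit,
binary cross-entropy loss, and the Nadam and RMSProp optimizers.  The
forward pass is a pure function of (parameters, input), suitable for
MACC/ROM/RAM complexity accounting of microcontroller deployments; the
same code path serves training (with batch statistics) and inference
(with running statistics).

Shapes follow the row-major convention: weights W have shape (in, out),
activations are (batch, features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BN_EPS = 1e-3
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "selu":
        return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * (np.exp(z) - 1.0))
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(float)
    if name == "tanh":
        return 1.0 - a ** 2
    if name == "selu":
        return np.where(z > 0, _SELU_SCALE, a + _SELU_SCALE * _SELU_ALPHA)
    raise ValueError(f"unknown activation {name!r}")


def sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


@dataclass
class DenseNet:
    """Batch-norm input -> dense hidden chain -> 1-unit sigmoid output."""

    n_inputs: int
    hidden: tuple            # e.g. (32, 32)
    activations: tuple       # one name per hidden layer
    # batch-norm parameters and running statistics
    gamma: np.ndarray = field(default=None, repr=False)
    beta: np.ndarray = field(default=None, repr=False)
    run_mean: np.ndarray = field(default=None, repr=False)
    run_var: np.ndarray = field(default=None, repr=False)
    weights: list = field(default=None, repr=False)
    biases: list = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.hidden) != len(self.activations):
            raise ValueError("one activation per hidden layer")

    @classmethod
    def initialized(cls, n_inputs: int, hidden, activations, rng) -> "DenseNet":
        net = cls(n_inputs=n_inputs, hidden=tuple(hidden), activations=tuple(activations))
        net.gamma = np.ones(n_inputs)
        net.beta = np.zeros(n_inputs)
        net.run_mean = np.zeros(n_inputs)
        net.run_var = np.ones(n_inputs)
        net.weights, net.biases = [], []
        sizes = [n_inputs, *net.hidden, 1]
        for a, b in zip(sizes[:-1], sizes[1:]):
            net.weights.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            net.biases.append(np.zeros(b))
        return net

    # ----- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Inference scores in (0, 1) using running batch-norm statistics."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} features, got {x.shape[1]}")
        if not np.isfinite(x).all():
            raise ValueError("non-finite input")
        h = (x - self.run_mean) / np.sqrt(self.run_var + BN_EPS) * self.gamma + self.beta
        for w, b, act in zip(self.weights[:-1], self.biases[:-1], self.activations):
            h = _act(act, h @ w + b)
        return sigmoid(h @ self.weights[-1] + self.biases[-1]).ravel()

    # ----- training --------------------------------------------------------

    def _forward_train(self, x):
        mu, var = x.mean(axis=0), x.var(axis=0)
        xhat = (x - mu) / np.sqrt(var + BN_EPS)
        h = xhat * self.gamma + self.beta
        zs, hs = [], [h]
        for w, b, act in zip(self.weights[:-1], self.biases[:-1], self.activations):
            z = h @ w + b
            h = _act(act, z)
            zs.append(z)
            hs.append(h)
        z_out = h @ self.weights[-1] + self.biases[-1]
        return (mu, var, xhat), zs, hs, sigmoid(z_out).ravel()

    def _gradients(self, x, y):
        n = x.shape[0]
        (mu, var, xhat), zs, hs, p = self._forward_train(x)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = (p - y)[:, None] / n                  # dBCE/dz_out
        for li in range(len(self.weights) - 1, 0, -1):
            grads_w[li] = hs[li].T @ delta
            grads_b[li] = delta.sum(axis=0)
            delta = (delta @ self.weights[li].T) * _act_grad(
                self.activations[li - 1], zs[li - 1], hs[li])
        grads_w[0] = hs[0].T @ delta
        grads_b[0] = delta.sum(axis=0)
        dh0 = delta @ self.weights[0].T
        g_gamma = (dh0 * xhat).sum(axis=0)
        g_beta = dh0.sum(axis=0)
        return grads_w, grads_b, g_gamma, g_beta, (mu, var)

    def params_flat(self):
        parts = [self.gamma, self.beta]
        for w, b in zip(self.weights, self.biases):
            parts += [w.ravel(), b]
        return parts

    def n_params(self) -> int:
        # gamma, beta, running mean, running var + dense weights and biases
        n = 4 * self.n_inputs
        for w, b in zip(self.weights, self.biases):
            n += w.size + b.size
        return n


class _Optimizer:
    def __init__(self, params, lr):
        self.lr = lr
        self.state = [np.zeros_like(p) for p in params]


class RMSProp(_Optimizer):
    """Keras-convention RMSProp: rho = 0.9."""

    rho = 0.9

    def step(self, params, grads):
        for p, g, s in zip(params, grads, self.state):
            s *= self.rho
            s += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s) + 1e-7)


class Nadam:
    """Nesterov-momentum Adam, Keras conventions."""

    beta1, beta2, eps = 0.9, 0.999, 1e-7

    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** (self.t + 1)) + (1 - b1) * g / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def bce_loss(p, y):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_dense(
    net: DenseNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    optimizer: str = "nadam",
    lr: float = 1e-3,
    batch_size: int = 32,
    max_epochs: int = 200,
    patience: int = 20,
    bn_momentum: float = 0.99,
    rng: np.random.Generator,
) -> dict:
    """Mini-batch training with early stopping on validation BCE.

    Running batch-norm statistics are exponential moving averages of the
    batch statistics, as in the usual deployment convention.  Returns a
    small history dict; the network is left at the best-validation state.
    """
    params = net.params_flat()
    opt = {"nadam": Nadam, "rmsprop": RMSProp}[optimizer](params, lr)
    n = x_train.shape[0]
    best_val, best_state, since_best = np.inf, None, 0
    history = {"val_loss": [], "epochs_run": 0}

    def snapshot():
        return ([w.copy() for w in net.weights], [b.copy() for b in net.biases],
                net.gamma.copy(), net.beta.copy(), net.run_mean.copy(), net.run_var.copy())

    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            if idx.size < 2:
                continue
            gw, gb, gg, gbeta, (mu, var) = net._gradients(x_train[idx], y_train[idx])
            grads = [gg, gbeta]
            for w, b in zip(gw, gb):
                grads += [w.ravel(), b]
            opt.step(params, grads)
            net.run_mean = bn_momentum * net.run_mean + (1 - bn_momentum) * mu
            net.run_var = bn_momentum * net.run_var + (1 - bn_momentum) * var
        val = bce_loss(net.forward(x_val), y_val)
        history["val_loss"].append(val)
        history["epochs_run"] = epoch + 1
        if val < best_val - 1e-6:
            best_val, best_state, since_best = val, snapshot(), 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_state is not None:
        (net.weights, net.biases, net.gamma, net.beta,
         net.run_mean, net.run_var) = best_state
    history["best_val_loss"] = best_val
    return history
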