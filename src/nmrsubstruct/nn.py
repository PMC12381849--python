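"""A small NumPy neural-network engine.

Implements exactly the layer types the package's classifier architectures
need — dense, 1-D convolution, max-pooling, simple-recurrent and LSTM cells
with bidirectional wrappers — plus softmax cross-entropy and the common
first-order optimizers.  Forward and backward passes are hand-written and
checked against finite differences in the test suite.  Everything runs
single-threaded on the CPU and is bit-reproducible for a fixed seed.

Shapes: dense layers take ``(batch, features)``; sequence layers take
``(batch, time, channels)``.
"""

from __future__ import annotations

import numpy as np


class TrainingDiverged(RuntimeError):
    """Raised when a non-finite loss is encountered mid-training."""


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, _ = np.linalg.qr(a)
    return q[:n, :m] if q.shape[0] >= n else q.T[:n, :m]


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable


_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, y: (z > 0).astype(z.dtype)),
    "tanh": (np.tanh, lambda z, y: 1.0 - y * y),
    "linear": (lambda z: z, lambda z, y: np.ones_like(z)),
}


class Layer:
    """Base class: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str = "relu",
                 rng: np.random.Generator = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.activation = activation
        self._act, self._dact = _ACTIVATIONS[activation]
        self.params = {"W": _glorot(rng, (n_in, n_out)),
                       "b": np.zeros(n_out)}
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._z = x @ self.params["W"] + self.params["b"]
        self._y = self._act(self._z)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self._dact(self._z, self._y)
        self.grads["W"] += self._x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T


class Conv1D(Layer):
    """Same-padding 1-D convolution over (batch, length, channels)."""

    def __init__(self, c_in: int, filters: int, kernel: int = 3,
                 activation: str = "relu",
                 rng: np.random.Generator = None) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("odd kernel sizes only")
        rng = rng or np.random.default_rng()
        self.kernel, self.c_in, self.filters = kernel, c_in, filters
        self._act, self._dact = _ACTIVATIONS[activation]
        self.params = {"W": _glorot(rng, (kernel * c_in, filters)),
                       "b": np.zeros(filters)}
        self.zero_grads()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, length, c = x.shape
        pad = (self.kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        cols = np.stack(
            [xp[:, k : k + length, :] for k in range(self.kernel)], axis=2
        )
        return cols.reshape(b, length, self.kernel * c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x)
        self._z = self._cols @ self.params["W"] + self.params["b"]
        self._y = self._act(self._z)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, length, c = self._shape
        pad = (self.kernel - 1) // 2
        dz = dy * self._dact(self._z, self._y)
        self.grads["W"] += np.einsum("blk,blf->kf", self._cols, dz)
        self.grads["b"] += dz.sum(axis=(0, 1))
        dcols = dz @ self.params["W"].T  # (b, L, K*C)
        dcols = dcols.reshape(b, length, self.kernel, c)
        dxp = np.zeros((b, length + 2 * pad, c))
        for k in range(self.kernel):
            dxp[:, k : k + length, :] += dcols[:, :, k, :]
        return dxp[:, pad : pad + length, :]


class MaxPool1D(Layer):
    """Max-pooling with stride = pool size; output length is ceil(L/pool)."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, length, c = x.shape
        self._in_len = length
        out_len = -(-length // self.pool)
        pad = out_len * self.pool - length
        xp = np.pad(x, ((0, 0), (0, pad), (0, 0)),
                    constant_values=-np.inf)
        windows = xp.reshape(b, out_len, self.pool, c)
        self._argmax = windows.argmax(axis=2)
        return windows.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, out_len, c = dy.shape
        dxp = np.zeros((b, out_len, self.pool, c))
        bi, oi, ci = np.meshgrid(
            np.arange(b), np.arange(out_len), np.arange(c), indexing="ij"
        )
        dxp[bi, oi, self._argmax, ci] = dy
        return dxp.reshape(b, out_len * self.pool, c)[:, : self._in_len, :]


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _RecurrentBase(Layer):
    def __init__(self, n_in: int, units: int,
                 rng: np.random.Generator = None, gates: int = 1) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.n_in, self.units = n_in, units
        g = gates * units
        self.params = {
            "Wx": _glorot(rng, (n_in, g)),
            "Wh": np.concatenate(
                [_orthogonal(rng, units, units) for _ in range(gates)], axis=1
            ),
            "b": np.zeros(g),
        }
        self.zero_grads()


class SimpleRNN(_RecurrentBase):
    """tanh recurrence over (batch, T, n_in); returns (batch, T, units)."""

    def __init__(self, n_in, units, rng=None):
        super().__init__(n_in, units, rng, gates=1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        self._x = x
        self._h = np.zeros((b, t + 1, self.units))
        for step in range(t):
            self._h[:, step + 1] = np.tanh(
                x[:, step] @ self.params["Wx"]
                + self._h[:, step] @ self.params["Wh"]
                + self.params["b"]
            )
        return self._h[:, 1:]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, t, _ = self._x.shape
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((b, self.units))
        for step in range(t - 1, -1, -1):
            dh = dy[:, step] + dh_next
            h = self._h[:, step + 1]
            dz = dh * (1.0 - h * h)
            self.grads["Wx"] += self._x[:, step].T @ dz
            self.grads["Wh"] += self._h[:, step].T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, step] = dz @ self.params["Wx"].T
            dh_next = dz @ self.params["Wh"].T
        return dx


class LSTM(_RecurrentBase):
    """Standard LSTM (gate order i, f, g, o) over (batch, T, n_in)."""

    def __init__(self, n_in, units, rng=None):
        super().__init__(n_in, units, rng, gates=4)
        # forget-gate bias starts at 1 for stable early training
        self.params["b"][units : 2 * units] = 1.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        u = self.units
        self._x = x
        self._h = np.zeros((b, t + 1, u))
        self._c = np.zeros((b, t + 1, u))
        self._gates = np.zeros((b, t, 4 * u))
        for step in range(t):
            z = (x[:, step] @ self.params["Wx"]
                 + self._h[:, step] @ self.params["Wh"] + self.params["b"])
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = sigmoid(z[:, 3 * u :])
            self._gates[:, step] = np.concatenate([i, f, g, o], axis=1)
            self._c[:, step + 1] = f * self._c[:, step] + i * g
            self._h[:, step + 1] = o * np.tanh(self._c[:, step + 1])
        return self._h[:, 1:]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, t, _ = self._x.shape
        u = self.units
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((b, u))
        dc_next = np.zeros((b, u))
        for step in range(t - 1, -1, -1):
            gates = self._gates[:, step]
            i, f = gates[:, :u], gates[:, u : 2 * u]
            g, o = gates[:, 2 * u : 3 * u], gates[:, 3 * u :]
            c = self._c[:, step + 1]
            tanh_c = np.tanh(c)
            dh = dy[:, step] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c * tanh_c) + dc_next
            di = dc * g
            df = dc * self._c[:, step]
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1.0 - g * g), do * o * (1 - o)], axis=1,
            )
            self.grads["Wx"] += self._x[:, step].T @ dz
            self.grads["Wh"] += self._h[:, step].T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, step] = dz @ self.params["Wx"].T
            dh_next = dz @ self.params["Wh"].T
            dc_next = dc * f
        return dx


class Bidirectional(Layer):
    """Runs a forward and a time-reversed copy of a recurrent layer.

    With ``return_sequences`` the per-step outputs are concatenated
    (backward outputs re-reversed to align), giving (batch, T, 2*units);
    otherwise the two final hidden states are concatenated, (batch, 2*units).
    """

    def __init__(self, cell_cls, n_in: int, units: int,
                 rng: np.random.Generator = None,
                 return_sequences: bool = True) -> None:
        super().__init__()
        self.fwd = cell_cls(n_in, units, rng)
        self.bwd = cell_cls(n_in, units, rng)
        self.return_sequences = return_sequences
        self.units = units

    @property
    def children(self):
        return [self.fwd, self.bwd]

    def zero_grads(self) -> None:
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])
        if self.return_sequences:
            return np.concatenate([hf, hb[:, ::-1, :]], axis=2)
        return np.concatenate([hf[:, -1, :], hb[:, -1, :]], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        u = self.units
        if self.return_sequences:
            dhf = dy[:, :, :u]
            dhb = dy[:, :, u:][:, ::-1, :]
        else:
            b, t = dy.shape[0], self.fwd._x.shape[1]
            dhf = np.zeros((b, t, u))
            dhb = np.zeros((b, t, u))
            dhf[:, -1, :] = dy[:, :u]
            dhb[:, -1, :] = dy[:, u:]
        dxf = self.fwd.backward(dhf)
        dxb = self.bwd.backward(dhb)[:, ::-1, :]
        return dxf + dxb


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple:
    """Mean cross-entropy loss and gradient w.r.t. the logits.

    ``labels`` are integer class indices.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


# ---------------------------------------------------------------------------
# optimizers


class Optimizer:
    """Keeps per-parameter state keyed by (layer position, parameter name)."""

    def __init__(self, lr: float) -> None:
        self.lr = lr
        self.state: dict = {}
        self.t = 0

    def step(self, layers) -> None:
        self.t += 1
        for li, layer in enumerate(_expand(layers)):
            for name, param in layer.params.items():
                self._update((li, name), param, layer.grads[name])

    def _update(self, key, param, grad):  # pragma: no cover
        raise NotImplementedError

    def _get(self, key, like, slot=""):
        full = key + (slot,)
        if full not in self.state:
            self.state[full] = np.zeros_like(like)
        return self.state[full]


def _expand(layers):
    out = []
    for layer in layers:
        if isinstance(layer, Bidirectional):
            out.extend(layer.children)
        else:
            out.append(layer)
    return out


class SGD(Optimizer):
    def __init__(self, lr=0.01, momentum=0.0):
        super().__init__(lr)
        self.momentum = momentum

    def _update(self, key, param, grad):
        v = self._get(key, param, "v")
        v *= self.momentum
        v -= self.lr * grad
        param += v


class Adagrad(Optimizer):
    def __init__(self, lr=0.01, eps=1e-7):
        super().__init__(lr)
        self.eps = eps

    def _update(self, key, param, grad):
        a = self._get(key, param, "a")
        a += grad * grad
        param -= self.lr * grad / (np.sqrt(a) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, lr=0.001, rho=0.9, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, key, param, grad):
        a = self._get(key, param, "a")
        a *= self.rho
        a += (1 - self.rho) * grad * grad
        param -= self.lr * grad / (np.sqrt(a) + self.eps)


class Adadelta(Optimizer):
    def __init__(self, lr=1.0, rho=0.95, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, key, param, grad):
        a = self._get(key, param, "a")
        d = self._get(key, param, "d")
        a *= self.rho
        a += (1 - self.rho) * grad * grad
        update = grad * np.sqrt(d + self.eps) / np.sqrt(a + self.eps)
        d *= self.rho
        d += (1 - self.rho) * update * update
        param -= self.lr * update


class Adam(Optimizer):
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, key, param, grad):
        m = self._get(key, param, "m")
        v = self._get(key, param, "v")
        m *= self.beta1
        m += (1 - self.beta1) * grad
        v *= self.beta2
        v += (1 - self.beta2) * grad * grad
        mhat = m / (1 - self.beta1 ** self.t)
        vhat = v / (1 - self.beta2 ** self.t)
        param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Adam):
    def _update(self, key, param, grad):
        m = self._get(key, param, "m")
        u = self._get(key, param, "u")
        m *= self.beta1
        m += (1 - self.beta1) * grad
        np.maximum(self.beta2 * u, np.abs(grad), out=u)
        param -= self.lr * m / ((1 - self.beta1 ** self.t) * (u + self.eps))


class Nadam(Adam):
    def _update(self, key, param, grad):
        m = self._get(key, param, "m")
        v = self._get(key, param, "v")
        m *= self.beta1
        m += (1 - self.beta1) * grad
        v *= self.beta2
        v += (1 - self.beta2) * grad * grad
        mhat = (self.beta1 * m / (1 - self.beta1 ** (self.t + 1))
                + (1 - self.beta1) * grad / (1 - self.beta1 ** self.t))
        vhat = v / (1 - self.beta2 ** self.t)
        param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {
    "sgd": SGD,
    "adadelta": Adadelta,
    "adagrad": Adagrad,
    "rmsprop": RMSprop,
    "adam": Adam,
    "adamax": Adamax,
    "nadam": Nadam,
}


def make_optimizer(name: str, **kwargs) -> Optimizer:
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}"
        )
    return cls(**kwargs)


def parameter_count(layers) -> int:
    return sum(
        p.size for layer in _expand(layers) for p in layer.params.values()
    )
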