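"""Layers with explicit forward/backward passes.

Sequence tensors are (batch, length, channels); dense tensors (batch,
features).  Every layer caches what its backward pass needs on forward and
accumulates parameter gradients in ``.grads`` aligned with ``.params``.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0] += self._x.T @ grad
        self.grads[1] += grad.sum(axis=0)
        return grad @ self.W.T


class ConvPair(Layer):
    """1-D convolution with kernel length 2 and stride 2 (no padding).

    With stride equal to kernel length the convolution is a reshape into
    non-overlapping band pairs followed by a matrix product, which is how
    it is implemented; an odd trailing position is dropped, matching
    L_out = floor(L/2).
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = _glorot(rng, 2 * in_ch, out_ch, (2 * in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        B, L, C = x.shape
        Lo = L // 2
        self._in_shape = x.shape
        pairs = x[:, : 2 * Lo].reshape(B, Lo, 2 * C)
        self._pairs = pairs
        return pairs @ self.W + self.b

    def backward(self, grad):
        B, L, C = self._in_shape
        Lo = L // 2
        flat_g = grad.reshape(-1, self.out_ch)
        self.grads[0] += self._pairs.reshape(-1, 2 * C).T @ flat_g
        self.grads[1] += flat_g.sum(axis=0)
        dpairs = grad @ self.W.T
        dx = np.zeros(self._in_shape)
        dx[:, : 2 * Lo] = dpairs.reshape(B, 2 * Lo, C)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation over all leading axes.

    Keeps running statistics (momentum 0.9) for evaluation mode.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.9):
        super().__init__()
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.eps, self.momentum = eps, momentum
        self.run_mean = np.zeros(n_ch)
        self.run_var = np.ones(n_ch)

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_sd
        self._axes = axes
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        n = np.prod([grad.shape[a] for a in axes])
        self.grads[0] += (grad * self._xhat).sum(axis=axes)
        self.grads[1] += grad.sum(axis=axes)
        g = grad * self.gamma
        return self._inv_sd * (
            g - g.mean(axis=axes) - self._xhat * (g * self._xhat).sum(axis=axes) / n
        )


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Tanh(Layer):
    def forward(self, x, train):
        self._out = np.tanh(x)
        return self._out

    def backward(self, grad):
        return grad * (1.0 - self._out**2)


class AvgPool2(Layer):
    """Average pooling with window 2, stride 2 along the length axis."""

    def forward(self, x, train):
        B, L, C = x.shape
        Lo = L // 2
        self._in_shape = x.shape
        return x[:, : 2 * Lo].reshape(B, Lo, 2, C).mean(axis=2)

    def backward(self, grad):
        B, L, C = self._in_shape
        Lo = L // 2
        dx = np.zeros(self._in_shape)
        dx[:, : 2 * Lo] = np.repeat(grad, 2, axis=1) / 2.0
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    """(batch, n) -> (batch, steps, chunk); truncates n to steps*chunk."""

    def __init__(self, steps: int, chunk: int):
        super().__init__()
        self.steps, self.chunk = steps, chunk

    def forward(self, x, train):
        self._in_shape = x.shape
        used = self.steps * self.chunk
        return x[:, :used].reshape(x.shape[0], self.steps, self.chunk)

    def backward(self, grad):
        dx = np.zeros(self._in_shape)
        dx[:, : self.steps * self.chunk] = grad.reshape(grad.shape[0], -1)
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMLayer(Layer):
    """Single LSTM layer returning the final hidden state.

    Gate order in the packed weight matrix is (i, f, g, o), applied to the
    concatenation [h_{t-1}, x_t]:

        i = sigma(W_i [h, x] + b_i)        input gate
        f = sigma(W_f [h, x] + b_f)        forget gate
        g = tanh (W_g [h, x] + b_g)        cell candidate
        o = sigma(W_o [h, x] + b_o)        output gate
        c_t = f * c_{t-1} + i * g
        h_t = o * tanh(c_t)

    The forget-gate bias is initialised to 1 (standard trick to keep early
    gradients flowing).  Backpropagation through time is exact.
    """

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.input_size, self.hidden = input_size, hidden
        d = hidden + input_size
        self.W = _glorot(rng, d, 4 * hidden, (d, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        B, T, D = x.shape
        H = self.hidden
        if D != self.input_size:
            raise ValueError(f"LSTM expects {self.input_size} features, got {D}")
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        self._x_shape = x.shape
        for t in range(T):
            z_in = np.concatenate([h, x[:, t]], axis=1)
            z = z_in @ self.W + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((z_in, i, f, g, o, c, tanh_c))
            h, c = h_new, c_new
        return h

    def backward(self, grad):
        B, T, D = self._x_shape
        H = self.hidden
        dx = np.zeros(self._x_shape)
        dh = grad
        dc = np.zeros_like(grad)
        for t in reversed(range(T)):
            z_in, i, f, g, o, c_prev, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2),
                 do * o * (1 - o)],
                axis=1,
            )
            self.grads[0] += z_in.T @ dz
            self.grads[1] += dz.sum(axis=0)
            dz_in = dz @ self.W.T
            dh = dz_in[:, :H]
            dx[:, t] = dz_in[:, H:]
        return dx
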