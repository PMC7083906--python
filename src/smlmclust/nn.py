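"""Minimal sequential neural-network engine.

A compact, dependency-free implementation of the layer kinds the point
classifiers use: fully connected, 1-D convolution, max pooling, dropout
and LSTM, trained with Adam on a softmax cross-entropy loss.  Layers
follow the usual sequential-stack semantics: each consumes the previous
layer's output, convolutions use 'valid' padding, pooling is
non-overlapping, and the LSTM carries forget-gate bias 1 at
initialization.  Backward passes are exact analytic gradients (verified
against finite differences in the test suite) and all randomness
(initialization, shuffling, dropout) flows from one seed, so training is
reproducible in single-threaded execution.

This module is intentionally small: it exists to make the published
model topologies trainable with nothing beyond numpy, not to compete
with a general deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1D",
    "MaxPool1D",
    "Dropout",
    "LSTM",
    "Sequential",
]


def _act(name):
    if name in (None, "linear"):
        return lambda z: z, lambda z, a: np.ones_like(a)
    if name == "relu":
        return lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)
    if name == "tanh":
        return np.tanh, lambda z, a: 1.0 - a**2
    if name == "sigmoid":
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))
        return sig, lambda z, a: a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class Layer:
    """Base layer: holds params/grads dicts keyed by name."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        return input_shape

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, units: int, activation: str | None = "relu"):
        super().__init__()
        self.units = units
        self.activation = activation
        self._f, self._df = _act(activation)

    def build(self, input_shape, rng):
        if len(input_shape) != 1:
            # flatten anything higher-rank, Keras-style Flatten+Dense
            self._flatten_from = input_shape
            fan_in = int(np.prod(input_shape))
        else:
            self._flatten_from = None
            fan_in = input_shape[0]
        limit = np.sqrt(6.0 / (fan_in + self.units))
        self.params["W"] = rng.uniform(-limit, limit, size=(fan_in, self.units))
        self.params["b"] = np.zeros(self.units)
        return (self.units,)

    def forward(self, x, train, rng):
        if self._flatten_from is not None:
            x = x.reshape(x.shape[0], -1)
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._z = z
        self._a = self._f(z)
        return self._a

    def backward(self, dy):
        dz = dy * self._df(self._z, self._a)
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        dx = dz @ self.params["W"].T
        if self._flatten_from is not None:
            dx = dx.reshape((dx.shape[0], *self._flatten_from))
        return dx


class Conv1D(Layer):
    """1-D convolution, 'valid' padding, stride 1, channels-last."""

    def __init__(self, filters: int, width: int, activation: str | None = "relu"):
        super().__init__()
        self.filters = filters
        self.width = width
        self.activation = activation
        self._f, self._df = _act(activation)

    def build(self, input_shape, rng):
        t, c = input_shape
        if t < self.width:
            raise ValueError(f"sequence length {t} shorter than kernel width {self.width}")
        fan_in = self.width * c
        limit = np.sqrt(6.0 / (fan_in + self.filters))
        self.params["W"] = rng.uniform(
            -limit, limit, size=(self.width, c, self.filters)
        )
        self.params["b"] = np.zeros(self.filters)
        return (t - self.width + 1, self.filters)

    def forward(self, x, train, rng):
        self._x = x
        # windows: (n, t_out, c, width)
        xw = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)
        self._xw = xw
        z = np.einsum("ntcw,wcf->ntf", xw, self.params["W"]) + self.params["b"]
        self._z = z
        self._a = self._f(z)
        return self._a

    def backward(self, dy):
        dz = dy * self._df(self._z, self._a)
        self.grads["W"] = np.einsum("ntcw,ntf->wcf", self._xw, dz)
        self.grads["b"] = dz.sum(axis=(0, 1))
        dx = np.zeros_like(self._x)
        t_out = dz.shape[1]
        for w in range(self.width):
            dx[:, w : w + t_out, :] += np.einsum(
                "ntf,cf->ntc", dz, self.params["W"][w]
            )
        return dx


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; trailing remainder dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def build(self, input_shape, rng):
        t, c = input_shape
        if t < self.size:
            raise ValueError(f"sequence length {t} shorter than pool size {self.size}")
        return (t // self.size, c)

    def forward(self, x, train, rng):
        n, t, c = x.shape
        t_out = t // self.size
        xr = x[:, : t_out * self.size, :].reshape(n, t_out, self.size, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        n, t_out, c = dy.shape
        dx = np.zeros(self._in_shape)
        dxr = dx[:, : t_out * self.size, :].reshape(n, t_out, self.size, c)
        ni, ti, ci = np.ogrid[:n, :t_out, :c]
        dxr[ni, ti, self._argmax, ci] = dy
        return dx


class Dropout(Layer):
    def __init__(self, rate: float = 0.25):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class LSTM(Layer):
    """Single-direction LSTM; optionally returns the full sequence."""

    def __init__(self, units: int, return_sequences: bool = False):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences

    def build(self, input_shape, rng):
        t, c = input_shape
        h = self.units
        limit = np.sqrt(6.0 / (c + 4 * h))
        self.params["Wx"] = rng.uniform(-limit, limit, size=(c, 4 * h))
        limit_h = np.sqrt(6.0 / (h + 4 * h))
        self.params["Wh"] = rng.uniform(-limit_h, limit_h, size=(h, 4 * h))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        self.params["b"] = b
        self._t = t
        return (t, h) if self.return_sequences else (h,)

    def forward(self, x, train, rng):
        n, t, _ = x.shape
        h = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        self._x = x
        self._cache = []
        hs = np.zeros((n, t, h))
        h_t = np.zeros((n, h))
        c_t = np.zeros((n, h))
        for step in range(t):
            z = x[:, step, :] @ Wx + h_t @ Wh + b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tanh_c = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tanh_c
            hs[:, step, :] = h_t
            self._cache.append((i, f, g, o, c_prev, tanh_c, h_prev))
        self._hs = hs
        return hs if self.return_sequences else h_t

    def backward(self, dy):
        x = self._x
        n, t, c_in = x.shape
        h = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * h)
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c, h_prev = self._cache[step]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, step, :]
            elif step == t - 1:
                dh += dy
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, step, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads["Wx"] = dWx
        self.grads["Wh"] = dWh
        self.grads["b"] = db
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    """Linear stack of layers with softmax cross-entropy training."""

    def __init__(self, layers: list[Layer], input_shape: tuple, seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, self.rng)
        if len(shape) != 1:
            raise ValueError("network must end in a vector of class logits")
        self.n_out = shape[0]

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, self.rng)
        return x

    def predict_proba(self, x: np.ndarray, batch: int = 4096) -> np.ndarray:
        out = np.empty((x.shape[0], self.n_out))
        for start in range(0, x.shape[0], batch):
            sl = slice(start, start + batch)
            out[sl] = softmax(self._forward(x[sl], train=False))
        return out

    def _step(self, xb: np.ndarray, yb: np.ndarray, opt: "Adam") -> float:
        logits = self._forward(xb, train=True)
        probs = softmax(logits)
        n = xb.shape[0]
        loss = -np.log(probs[np.arange(n), yb] + 1e-12).mean()
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        dlogits = probs.copy()
        dlogits[np.arange(n), yb] -= 1.0
        dlogits /= n
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        opt.update(self.layers)
        return float(loss)

    # -- training -----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 50,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        patience: int = 5,
        verbose: bool = False,
    ) -> dict:
        """Mini-batch Adam with early stopping on validation accuracy.

        Returns a history dict with per-epoch training loss/accuracy and
        (when a validation set is given) validation accuracy.  The
        parameters of the best validation epoch are restored at the end.
        """
        opt = Adam(lr=learning_rate)
        history: dict = {"loss": [], "accuracy": [], "val_accuracy": []}
        best_val = -np.inf
        best_params = None
        since_best = 0
        for epoch in range(epochs):
            order = self.rng.permutation(x.shape[0])
            losses = []
            correct = 0
            for start in range(0, len(order), batch_size):
                sel = order[start : start + batch_size]
                try:
                    losses.append(self._step(x[sel], y[sel], opt))
                except FloatingPointError as exc:
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch + 1}: {exc}"
                    ) from exc
            preds = self.predict_proba(x).argmax(axis=1)
            acc = float((preds == y).mean())
            history["loss"].append(float(np.mean(losses)))
            history["accuracy"].append(acc)
            if x_val is not None:
                val_preds = self.predict_proba(x_val).argmax(axis=1)
                val_acc = float((val_preds == y_val).mean())
                history["val_accuracy"].append(val_acc)
                if verbose:
                    print(
                        f"epoch {epoch + 1}: loss {history['loss'][-1]:.4f} "
                        f"acc {acc:.4f} val_acc {val_acc:.4f}"
                    )
                if val_acc > best_val:
                    best_val = val_acc
                    best_params = self.get_params()
                    since_best = 0
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
        if best_params is not None:
            self.set_params(best_params)
        return history

    # -- parameter (de)serialization ---------------------------------------
    def get_params(self) -> dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for name, val in layer.params.items():
                out[f"layer{li}_{name}"] = val.copy()
        return out

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = params[f"layer{li}_{name}"].copy()


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def update(self, layers: list[Layer]) -> None:
        self.t += 1
        for li, layer in enumerate(layers):
            for name, g in layer.grads.items():
                key = (li, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(g)
                    self.v[key] = np.zeros_like(g)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
                mhat = self.m[key] / (1 - self.beta1**self.t)
                vhat = self.v[key] / (1 - self.beta2**self.t)
                layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
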