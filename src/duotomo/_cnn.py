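"""Compact, fully deterministic NumPy 1D convolutional network.

Architecture: four same-padded Conv1D layers with ReLU, max-pooling after the
second and fourth convolution, three dense layers with ReLU and dropout 0.5,
and a sigmoid output producing a probability of malignancy.  Training is
full-batch Adam on binary cross-entropy.  All randomness (weight
initialisation, dropout masks) flows from a single seed, so identical seed +
data give bit-identical weights and predictions.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Conv1D:
    def __init__(self, cin, cout, k, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / (cin * k)), (cout, cin, k))
        self.b = np.zeros(cout)
        self.k = k

    def forward(self, x, train):
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        L = x.shape[2]
        self._win = np.stack([xp[:, :, i: i + L] for i in range(self.k)], axis=0)
        return (
            np.einsum("wncl,ocw->nol", self._win, self.W, optimize=True)
            + self.b[None, :, None]
        )

    def backward(self, dout):
        pad = self.k // 2
        self.dW = np.einsum("wncl,nol->ocw", self._win, dout, optimize=True)
        self.db = dout.sum(axis=(0, 2))
        _, n, cin, L = self._win.shape
        dxp = np.zeros((n, cin, L + 2 * pad))
        for w in range(self.k):
            dxp[:, :, w: w + L] += np.einsum(
                "nol,oc->ncl", dout, self.W[:, :, w], optimize=True
            )
        return dxp[:, :, pad: pad + L]

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x, train):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m

    def params(self):
        return []


class _MaxPool1D:
    def forward(self, x, train):
        n, c, L = x.shape
        self._L = L
        half = L // 2
        self._skip = half == 0
        if self._skip:
            return x
        xt = x[:, :, : 2 * half].reshape(n, c, half, 2)
        self._arg = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, dout):
        if self._skip:
            return dout
        n, c, half = dout.shape
        dx = np.zeros((n, c, self._L))
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        dx[ni, ci, 2 * np.arange(half)[None, None, :] + self._arg] = dout
        return dx

    def params(self):
        return []


class _Dense:
    def __init__(self, din, dout, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / din), (din, dout))
        self.b = np.zeros(dout)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class _Dropout:
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._m = None
            return x
        keep = 1.0 - self.rate
        self._m = (self.rng.random(x.shape) < keep) / keep
        return x * self._m

    def backward(self, dout):
        return dout if self._m is None else dout * self._m

    def params(self):
        return []


class CNN1D:
    """Four Conv1D + two max-pool + three dense (dropout) + sigmoid head."""

    def __init__(
        self,
        n_features: int,
        channels=(16, 16, 32, 32),
        dense=(32, 16),
        kernel: int = 3,
        dropout: float = 0.5,
        seed: int = 0,
    ):
        self.n_features = int(n_features)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.conv_layers = []
        cin = 1
        L = self.n_features
        for stage, cout in enumerate(channels):
            self.conv_layers.append(_Conv1D(cin, cout, kernel, rng))
            self.conv_layers.append(_ReLU())
            cin = cout
            if stage in (1, 3):  # pool after the 2nd and 4th convolution
                self.conv_layers.append(_MaxPool1D())
                L = max(L // 2, 1)
        flat = cin * L
        self.dense_layers = []
        din = flat
        for dout in dense:
            self.dense_layers.append(_Dense(din, dout, rng))
            self.dense_layers.append(_ReLU())
            self.dense_layers.append(_Dropout(dropout, rng))
            din = dout
        self.head = _Dense(din, 1, rng)
        self._flat = flat

    # ---------------------------------------------------------------- core

    def _forward(self, X, train=False):
        x = X[:, None, :]
        for layer in self.conv_layers:
            x = layer.forward(x, train)
        self._conv_shape = x.shape
        z = x.reshape(x.shape[0], -1)
        for layer in self.dense_layers:
            z = layer.forward(z, train)
        return self.head.forward(z, train)[:, 0]

    def _backward(self, dlogit):
        d = self.head.backward(dlogit[:, None])
        for layer in reversed(self.dense_layers):
            d = layer.backward(d)
        d = d.reshape(self._conv_shape)
        for layer in reversed(self.conv_layers):
            d = layer.backward(d)

    def _all_params(self):
        out = []
        for layer in self.conv_layers + self.dense_layers + [self.head]:
            out.extend(layer.params())
        return out

    def fit(self, X, y, epochs=200, lr=0.01):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        params = self._all_params()
        m = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        v = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        losses = []
        for epoch in range(1, epochs + 1):
            logit = self._forward(X, train=True)
            p = _sigmoid(logit)
            p_c = np.clip(p, 1e-12, 1 - 1e-12)
            losses.append(float(-np.mean(y * np.log(p_c) + (1 - y) * np.log(1 - p_c))))
            self._backward((p - y) / y.size)
            for i, (name, obj) in enumerate(params):
                g = getattr(obj, "d" + name)
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g * g
                mh = m[i] / (1 - b1**epoch)
                vh = v[i] / (1 - b2**epoch)
                setattr(
                    obj, name, getattr(obj, name) - lr * mh / (np.sqrt(vh) + eps)
                )
        self.loss_history = losses
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return _sigmoid(self._forward(X, train=False))
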