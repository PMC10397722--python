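"""Minimal NumPy 1D-CNN: conv → pool blocks, dense head, Adam, early stopping.

The interior is deliberately small — im2col convolutions, non-overlapping max
pooling, inverted dropout and a softmax cross-entropy head — because the only
contract it must honor is: input shape (F, 1), softmax output of width K,
mini-batch gradient descent on categorical cross-entropy with early stopping
on validation loss. Everything is seeded through a single
``numpy.random.Generator`` so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np


class LayerSizeError(ValueError):
    pass


class _Conv1D:
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_out, c_in, kernel)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.kernel = kernel
        self.stride = stride

    def out_len(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # x: (N, c_in, L) -> (N, c_out, L_out)
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::s, :]
        # win: (N, c_in, L_out, k) -> cols (N, L_out, c_in * k)
        n, c_in, l_out, _ = win.shape
        cols = win.transpose(0, 2, 1, 3).reshape(n, l_out, c_in * k)
        w = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = cols @ w.T + self.params["b"]
        self._cols = cols
        self._x_shape = x.shape
        return out.transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, c_out, l_out = dout.shape
        dflat = dout.transpose(0, 2, 1)  # (N, L_out, c_out)
        w = self.params["W"].reshape(c_out, -1)
        self.grads["W"][...] = (
            np.einsum("nlo,nlf->of", dflat, self._cols).reshape(self.params["W"].shape)
        )
        self.grads["b"][...] = dflat.sum(axis=(0, 1))
        dcols = dflat @ w  # (N, L_out, c_in * k)
        _, c_in, length = self._x_shape
        dcols = dcols.reshape(n, l_out, c_in, k)
        dx = np.zeros(self._x_shape)
        for t in range(k):
            dx[:, :, t : t + s * l_out : s] += dcols[:, :, :, t].transpose(0, 2, 1)
        return dx


class _MaxPool1D:
    def __init__(self, pool: int):
        self.pool = pool
        self.params = {}
        self.grads = {}

    def out_len(self, length: int) -> int:
        return length // self.pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.pool
        n, c, length = x.shape
        l_out = length // p
        xr = x[:, :, : l_out * p].reshape(n, c, l_out, p)
        self._argmax = xr.argmax(axis=3)
        self._x_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.pool
        n, c, l_out = dout.shape
        dx = np.zeros(self._x_shape)
        dxr = dx[:, :, : l_out * p].reshape(n, c, l_out, p)
        ni, ci, li = np.ogrid[:n, :c, :l_out]
        dxr[ni, ci, li, self._argmax] = dout
        return dx


class _ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Flatten:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dropout:
    params: dict = {}
    grads: dict = {}

    def __init__(self, rate: float, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng, relu_gain: bool = True):
        scale = np.sqrt((2.0 if relu_gain else 1.0) / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**self.t)
                vhat = v[k] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CNN1DNet:
    """1D-CNN over an expression vector: (conv, ReLU, max-pool)* → dense head."""

    def __init__(
        self,
        n_features: int,
        n_classes: int,
        conv_filters=(32, 64),
        kernel_size: int = 16,
        stride: int = 1,
        pool_size: int = 4,
        dropout: float = 0.3,
        dense_units: int = 128,
        seed: int = 0,
    ):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1D]))
        self.rng = rng
        self.n_features = n_features
        self.n_classes = n_classes
        layers: list = []
        c_in, length = 1, n_features
        for c_out in conv_filters:
            conv = _Conv1D(c_in, c_out, min(kernel_size, length), stride, rng)
            length = conv.out_len(length)
            if length < 1:
                raise LayerSizeError(
                    f"sequence length collapsed to {length} in a conv block; "
                    f"reduce kernel/pool sizes for {n_features} features"
                )
            layers += [conv, _ReLU()]
            if pool_size > 1 and length >= pool_size:
                pool = _MaxPool1D(pool_size)
                length = pool.out_len(length)
                layers.append(pool)
            c_in = c_out
        layers.append(_Flatten())
        flat = c_in * length
        layers.append(_Dropout(dropout, rng))
        layers.append(_Dense(flat, dense_units, rng))
        layers.append(_ReLU())
        layers.append(_Dense(dense_units, n_classes, rng, relu_gain=False))
        self.layers = layers

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x[:, None, :]  # (N, 1, F)
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h  # logits (N, K)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self._forward(np.asarray(x, dtype=float), train=False))

    def _loss_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self._forward(x, train=True)
        p = _softmax(logits)
        n = x.shape[0]
        loss = -np.log(np.clip((p * y).sum(axis=1), 1e-12, None)).mean()
        dlogits = (p - y) / n
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        return loss

    def _val_loss(self, x: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(x)
        return float(-np.log(np.clip((p * y).sum(axis=1), 1e-12, None)).mean())

    def get_weights(self) -> list:
        return [
            {k: v.copy() for k, v in layer.params.items()} for layer in self.layers
        ]

    def set_weights(self, weights: list) -> None:
        for layer, saved in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k][...] = saved[k]

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        patience: int = 5,
    ) -> dict:
        x_train = np.asarray(x_train, dtype=float)
        y_train = np.asarray(y_train, dtype=float)
        opt = Adam(self.layers, lr=learning_rate)
        n = x_train.shape[0]
        best_loss = np.inf
        best_weights = self.get_weights()
        best_epoch = 0
        bad = 0
        history = {"train_loss": [], "val_loss": []}
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                losses.append(self._loss_grad(x_train[idx], y_train[idx]))
                opt.step()
            val_loss = self._val_loss(x_val, y_val)
            history["train_loss"].append(float(np.mean(losses)))
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_weights = self.get_weights()
                best_epoch = epoch
                bad = 0
            else:
                bad += 1
                if bad > patience:
                    break
        self.set_weights(best_weights)
        history["best_epoch"] = best_epoch
        history["epochs_run"] = len(history["val_loss"])
        return history
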