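"""A small 1-D convolutional network regressor over marker order.

Architecture (fixed): input -> conv -> relu -> mean-pool -> conv -> relu ->
mean-pool -> flatten -> dropout -> dense -> relu -> dropout -> dense(1).
Filters slide along the chromosome-ordered marker axis so they can absorb
local linkage-disequilibrium structure.  Training is plain mini-batch Adam
on mean-squared error, fully seeded; mean pooling keeps the backward pass
simple and deterministic.

Written directly in numpy: panel-scale problems (hundreds of individuals,
thousands of markers) need no accelerator, and a self-contained forward /
backward pass keeps the model free of heavyweight framework dependencies.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x: (B, C, L); w: (F, C, K); returns (B, F, L-K+1)."""
    windows = sliding_window_view(x, w.shape[2], axis=2)  # (B, C, T, K)
    return np.einsum("bctk,fck->bft", windows, w) + b[None, :, None]

def _conv1d_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    windows = sliding_window_view(x, w.shape[2], axis=2)
    dw = np.einsum("bft,bctk->fck", dout, windows)
    db = dout.sum(axis=(0, 2))
    # dx via full correlation of dout with w
    B, C, L = x.shape
    F, _, K = w.shape
    dx = np.zeros_like(x)
    T = dout.shape[2]
    for dk in range(K):
        # x[:, c, t+dk] receives w[f, c, dk] * dout[:, f, t]
        dx[:, :, dk:dk + T] += np.einsum("bft,fc->bct", dout, w[:, :, dk])
    return dx, dw, db

def _meanpool_forward(x: np.ndarray, pool: int) -> np.ndarray:
    B, F, L = x.shape
    Lp = L // pool
    return x[:, :, : Lp * pool].reshape(B, F, Lp, pool).mean(axis=3)

def _meanpool_backward(dout: np.ndarray, pool: int, L: int) -> np.ndarray:
    B, F, Lp = dout.shape
    dx = np.zeros((B, F, L))
    dx[:, :, : Lp * pool] = np.repeat(dout / pool, pool, axis=2)
    return dx


class CNNRegressor:
    """Seeded 1-D CNN for genomic prediction with an sklearn-like surface."""

    def __init__(
        self,
        n_filters: int = 16,
        kernel_size: int = 8,
        pool_size: int = 4,
        dense_units: int = 32,
        dropout: float = 0.20,
        learning_rate: float = 3e-3,
        n_epochs: int = 100,
        batch_size: int = 32,
        random_state: int = 0,
    ) -> None:
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dense_units = dense_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_filters", "kernel_size", "pool_size", "dense_units", "dropout",
                "learning_rate", "n_epochs", "batch_size", "random_state",
            )
        }

    def set_params(self, **params) -> "CNNRegressor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- internals ----------------------------------------------------------

    def _init_weights(self, m: int, rng: np.random.Generator) -> None:
        F, K, P = self.n_filters, self.kernel_size, self.pool_size
        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.w1 = he((F, 1, K), K)
        self.b1 = np.zeros(F)
        l1 = (m - K + 1) // P
        if l1 < K:
            raise ValueError(f"{m} markers too few for kernel {K} with pooling {P}")
        self.w2 = he((F, F, K), F * K)
        self.b2 = np.zeros(F)
        l2 = (l1 - K + 1) // P
        if l2 < 1:
            raise ValueError(f"{m} markers too few for two conv/pool stages")
        self._flat = F * l2
        self.w3 = he((self._flat, self.dense_units), self._flat)
        self.b3 = np.zeros(self.dense_units)
        self.w4 = he((self.dense_units, 1), self.dense_units)
        self.b4 = np.zeros(1)

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None):
        """x: (B, m) standardized dosages.  rng=None -> inference (no dropout)."""
        cache = {}
        a0 = x[:, None, :]
        z1 = _conv1d_forward(a0, self.w1, self.b1)
        a1 = np.maximum(z1, 0.0)
        p1 = _meanpool_forward(a1, self.pool_size)
        z2 = _conv1d_forward(p1, self.w2, self.b2)
        a2 = np.maximum(z2, 0.0)
        p2 = _meanpool_forward(a2, self.pool_size)
        flat = p2.reshape(len(x), -1)
        if rng is not None and self.dropout > 0:
            mask1 = (rng.random(flat.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask1 = np.ones_like(flat)
        d1 = flat * mask1
        z3 = d1 @ self.w3 + self.b3
        a3 = np.maximum(z3, 0.0)
        if rng is not None and self.dropout > 0:
            mask2 = (rng.random(a3.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask2 = np.ones_like(a3)
        d2 = a3 * mask2
        out = (d2 @ self.w4 + self.b4).ravel()
        cache.update(a0=a0, z1=z1, a1=a1, p1=p1, z2=z2, a2=a2, p2=p2,
                     flat=flat, mask1=mask1, d1=d1, z3=z3, a3=a3, mask2=mask2, d2=d2)
        return out, cache

    def _backward(self, dout: np.ndarray, cache) -> dict:
        B = len(dout)
        dout = dout[:, None]
        grads = {}
        grads["w4"] = cache["d2"].T @ dout
        grads["b4"] = dout.sum(axis=0)
        dd2 = dout @ self.w4.T
        da3 = dd2 * cache["mask2"]
        dz3 = da3 * (cache["z3"] > 0)
        grads["w3"] = cache["d1"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dd1 = dz3 @ self.w3.T
        dflat = dd1 * cache["mask1"]
        dp2 = dflat.reshape(cache["p2"].shape)
        da2 = _meanpool_backward(dp2, self.pool_size, cache["a2"].shape[2])
        dz2 = da2 * (cache["z2"] > 0)
        dp1, grads["w2"], grads["b2"] = _conv1d_backward(cache["p1"], self.w2, dz2)
        da1 = _meanpool_backward(dp1, self.pool_size, cache["a1"].shape[2])
        dz1 = da1 * (cache["z1"] > 0)
        _, grads["w1"], grads["b1"] = _conv1d_backward(cache["a0"], self.w1, dz1)
        for k in grads:
            grads[k] = grads[k] / B
        return grads

    # -- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.random_state)
        self._x_mean = X.mean(axis=0)
        self._x_sd = X.std(axis=0)
        self._x_sd[self._x_sd == 0] = 1.0
        self._y_mean = float(y.mean())
        self._y_sd = float(y.std()) or 1.0
        Xs = (X - self._x_mean) / self._x_sd
        ys = (y - self._y_mean) / self._y_sd

        self._init_weights(Xs.shape[1], rng)
        params = ["w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4"]
        m_adam = {k: np.zeros_like(getattr(self, k)) for k in params}
        v_adam = {k: np.zeros_like(getattr(self, k)) for k in params}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(ys)
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                if len(idx) < 2:
                    continue
                pred, cache = self._forward(Xs[idx], rng)
                dout = 2.0 * (pred - ys[idx])
                grads = self._backward(dout, cache)
                step += 1
                for k in params:
                    m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * grads[k]
                    v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m_adam[k] / (1 - beta1 ** step)
                    vhat = v_adam[k] / (1 - beta2 ** step)
                    setattr(self, k, getattr(self, k) - self.learning_rate * mhat / (np.sqrt(vhat) + eps))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self._x_mean) / self._x_sd
        preds = []
        for start in range(0, len(Xs), 256):
            out, _ = self._forward(Xs[start:start + 256], rng=None)
            preds.append(out)
        return np.concatenate(preds) * self._y_sd + self._y_mean
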