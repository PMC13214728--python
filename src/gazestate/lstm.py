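"""A small LSTM sequence classifier implemented in NumPy.

Architecture: a single LSTM layer (tanh cell, sigmoid gates) whose final
hidden state feeds dropout -> batch normalization -> a dense softmax head.
Training uses integer-label cross-entropy, the Adam optimizer, mini-batches,
and early stopping on validation loss with restoration of the best-epoch
parameters.  Gradients are computed by backpropagation through time and are
verified against finite differences in the test suite.

Problem sizes here are tiny (tens of windows per batch, 10-20 time steps,
4-5 channels, 50 hidden units), so dense NumPy batched matmuls are fast
enough without a deep-learning framework.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class LSTMClassifier:
    """LSTM -> dropout -> batch norm -> dense softmax, trained with Adam.

    Parameters mirror the published training recipe: 50 hidden units,
    dropout 0.2, batch normalization, learning rate 1e-3, batch size 32,
    up to 100 epochs with early stopping on validation loss.
    """

    def __init__(
        self,
        n_features: int,
        n_classes: int = 3,
        hidden: int = 50,
        dropout: float = 0.2,
        batch_norm: bool = True,
        lr: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 10,
        seed: int = 0,
    ) -> None:
        if not 0 <= dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.nf, self.nc, self.nh = n_features, n_classes, hidden
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.rng = np.random.default_rng(seed)
        self._init_params()
        self.bn_momentum = 0.9
        self.bn_eps = 1e-5
        self.history: list[dict] = []

    def _init_params(self) -> None:
        h, f = self.nh, self.nf
        # Glorot-style init; forget-gate bias starts at 1
        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return self.rng.uniform(-s, s, size=(n_in, n_out))

        self.params = {
            "Wx": glorot(f, 4 * h),
            "Wh": glorot(h, 4 * h),
            "b": np.zeros(4 * h),
            "Wd": glorot(h, self.nc),
            "bd": np.zeros(self.nc),
            "gamma": np.ones(h),
            "beta": np.zeros(h),
        }
        self.params["b"][h : 2 * h] = 1.0
        self.bn_mean = np.zeros(h)
        self.bn_var = np.ones(h)

    # ------------------------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool):
        """Forward pass; returns class probabilities and a cache for BPTT."""
        N, T, _ = X.shape
        h = self.nh
        p = self.params
        hs = np.zeros((T + 1, N, h))
        cs = np.zeros((T + 1, N, h))
        gates = np.empty((T, N, 4 * h))
        for t in range(T):
            z = X[:, t] @ p["Wx"] + hs[t] @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            cs[t + 1] = f * cs[t] + i * g
            hs[t + 1] = o * np.tanh(cs[t + 1])
            gates[t] = np.concatenate([i, f, g, o], axis=1)
        last = hs[T]

        if train and self.dropout > 0:
            mask = (self.rng.random(last.shape) >= self.dropout) / (1 - self.dropout)
        else:
            mask = np.ones_like(last)
        dropped = last * mask

        if self.batch_norm:
            if train:
                mu = dropped.mean(axis=0)
                var = dropped.var(axis=0)
                self.bn_mean = self.bn_momentum * self.bn_mean + (1 - self.bn_momentum) * mu
                self.bn_var = self.bn_momentum * self.bn_var + (1 - self.bn_momentum) * var
            else:
                mu, var = self.bn_mean, self.bn_var
            xhat = (dropped - mu) / np.sqrt(var + self.bn_eps)
            bn_out = p["gamma"] * xhat + p["beta"]
        else:
            mu = var = xhat = None
            bn_out = dropped

        probs = _softmax(bn_out @ p["Wd"] + p["bd"])
        cache = (X, hs, cs, gates, mask, dropped, mu, var, xhat, bn_out)
        return probs, cache

    def _loss_and_grads(self, X: np.ndarray, y: np.ndarray, train: bool = True):
        """Mean cross-entropy and parameter gradients for one batch."""
        N, T, _ = X.shape
        h = self.nh
        p = self.params
        probs, cache = self._forward(X, train)
        X_, hs, cs, gates, mask, dropped, mu, var, xhat, bn_out = cache
        loss = -np.log(probs[np.arange(N), y] + 1e-300).mean()

        dlogits = probs.copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wd"] = bn_out.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dbn = dlogits @ p["Wd"].T

        if self.batch_norm:
            grads["gamma"] = (dbn * xhat).sum(axis=0)
            grads["beta"] = dbn.sum(axis=0)
            inv = 1.0 / np.sqrt(var + self.bn_eps)
            dxhat = dbn * p["gamma"]
            ddropped = inv / N * (
                N * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
        else:
            ddropped = dbn
        dh = ddropped * mask
        dc = np.zeros((N, h))
        for t in range(T - 1, -1, -1):
            i = gates[t][:, :h]
            f = gates[t][:, h : 2 * h]
            g = gates[t][:, 2 * h : 3 * h]
            o = gates[t][:, 3 * h :]
            tc = np.tanh(cs[t + 1])
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * g
            df = dc * cs[t]
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            grads["Wx"] += X_[:, t].T @ dz
            grads["Wh"] += hs[t].T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
            dc = dc * f
        return loss, grads

    # ------------------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "LSTMClassifier":
        """Train with Adam; early-stop on validation loss when a validation
        set is supplied, restoring the best-epoch parameters."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - set(range(self.nc)):
            raise ValueError("labels outside the configured class range")
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(val) for k, val in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss, best_params, best_bn, wait = np.inf, None, None, 0
        n = X.shape[0]
        for epoch in range(self.max_epochs):
            order = self.rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if idx.size < 2 and self.batch_norm:
                    continue  # batch statistics undefined for a single sample
                loss, grads = self._loss_and_grads(X[idx], y[idx], train=True)
                ep_loss += loss * idx.size
                step += 1
                for k in self.params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
            rec = {"epoch": epoch, "train_loss": ep_loss / n}
            if X_val is not None and len(X_val):
                val_loss = self.loss(X_val, y_val)
                rec["val_loss"] = val_loss
                if val_loss < best_loss - 1e-6:
                    best_loss = val_loss
                    best_params = {k: val.copy() for k, val in self.params.items()}
                    best_bn = (self.bn_mean.copy(), self.bn_var.copy())
                    wait = 0
                else:
                    wait += 1
                if wait >= self.patience:
                    self.history.append(rec)
                    break
            self.history.append(rec)
        if best_params is not None:
            self.params = best_params
            self.bn_mean, self.bn_var = best_bn
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self.predict_proba(X)
        y = np.asarray(y, dtype=int)
        return float(-np.log(probs[np.arange(len(y)), y] + 1e-300).mean())
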