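"""A compact, fully deterministic 1D convolutional network in numpy.

Binary classifier over fixed-length 1D signals (pixel spectra): a stack of
valid-mode conv + ReLU (+ max-pool) blocks, global average pooling, dense
ReLU layers and a single sigmoid output, trained with Adam on binary
cross-entropy with early stopping on a held-out validation split.  Sized for
spectra of ~60 samples and training sets of ~10^3-10^4 points on one CPU;
all randomness (init, split, shuffling) flows from a single seed, so
training twice with the same seed reproduces the history bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet1D", "TrainingHistory"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    # softplus(z) - y*z, numerically stable
    sp = np.logaddexp(0.0, z)
    return float(np.mean(sp - y * z))


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class ConvNet1D:
    """See module docstring.  Not an sklearn estimator itself; the public
    estimator wrapper lives in :mod:`dermapa.classifier`."""

    def __init__(
        self,
        input_len: int,
        conv_filters: Sequence[int] = (16, 32),
        kernel_sizes: Sequence[int] = (9, 5),
        pool_sizes: Sequence[int] = (2, 1),
        dense_units: Sequence[int] = (16,),
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 20,
        min_delta: float = 1e-4,
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        if len(conv_filters) != len(kernel_sizes) or len(conv_filters) != len(pool_sizes):
            raise ValueError("conv_filters, kernel_sizes and pool_sizes must align")
        for k in kernel_sizes:
            if k % 2 == 0 or not (3 <= k <= 15):
                raise ValueError("kernel widths must be odd and within [3, 15]")
        self.input_len = int(input_len)
        self.conv_filters = tuple(int(f) for f in conv_filters)
        self.kernel_sizes = tuple(int(k) for k in kernel_sizes)
        self.pool_sizes = tuple(int(p) for p in pool_sizes)
        self.dense_units = tuple(int(d) for d in dense_units)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.max_epochs = int(max_epochs)
        self.patience = int(patience)
        self.min_delta = float(min_delta)
        self.validation_fraction = float(validation_fraction)
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)
        self._init_params()

    # ------------------------------------------------------------------ setup
    def _init_params(self) -> None:
        rng = self._rng
        self.params: dict[str, np.ndarray] = {}
        c_in, length = 1, self.input_len
        for i, (f, k, p) in enumerate(zip(self.conv_filters, self.kernel_sizes,
                                          self.pool_sizes)):
            length = length - k + 1
            if length < 1:
                raise ValueError("signal too short for the conv stack")
            scale = np.sqrt(2.0 / (c_in * k))
            self.params[f"Wc{i}"] = rng.normal(0.0, scale, size=(f, c_in, k))
            self.params[f"bc{i}"] = np.zeros(f)
            if p > 1:
                length = length // p
                if length < 1:
                    raise ValueError("signal too short for the pooling stack")
            c_in = f
        width = c_in  # after global average pooling
        for j, d in enumerate(self.dense_units):
            scale = np.sqrt(2.0 / width)
            self.params[f"Wd{j}"] = rng.normal(0.0, scale, size=(width, d))
            self.params[f"bd{j}"] = np.zeros(d)
            width = d
        scale = np.sqrt(1.0 / width)
        self.params["Wo"] = rng.normal(0.0, scale, size=(width, 1))
        self.params["bo"] = np.zeros(1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- forward
    def _forward(self, x: np.ndarray, cache: bool = False):
        """x: (B, L) -> logits (B,); optionally keep caches for backprop."""
        h = x[:, None, :]  # (B, 1, L)
        caches = []
        for i, (k, p) in enumerate(zip(self.kernel_sizes, self.pool_sizes)):
            W, b = self.params[f"Wc{i}"], self.params[f"bc{i}"]
            win = sliding_window_view(h, k, axis=2)  # (B, C, T, K)
            z = np.einsum("ock,bctk->bot", W, win, optimize=True) + b[None, :, None]
            a = np.maximum(z, 0.0)
            pool_arg = None
            if p > 1:
                T = a.shape[2] - a.shape[2] % p
                r = a[:, :, :T].reshape(a.shape[0], a.shape[1], T // p, p)
                pool_arg = r.argmax(axis=3)
                out = r.max(axis=3)
            else:
                out = a
            if cache:
                caches.append((h, win, z, a, pool_arg))
            h = out
        gap_in = h
        g = h.mean(axis=2)  # (B, C)
        dense_caches = []
        a = g
        for j in range(len(self.dense_units)):
            W, b = self.params[f"Wd{j}"], self.params[f"bd{j}"]
            z = a @ W + b
            if cache:
                dense_caches.append((a, z))
            a = np.maximum(z, 0.0)
        logits = (a @ self.params["Wo"] + self.params["bo"]).ravel()
        if cache:
            return logits, (caches, gap_in, g, dense_caches, a)
        return logits

    # --------------------------------------------------------------- backward
    def _backward(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        conv_caches, gap_in, g, dense_caches, a_last = caches
        grads: dict[str, np.ndarray] = {}
        dz = dlogits[:, None]  # (B, 1)
        grads["Wo"] = a_last.T @ dz
        grads["bo"] = dz.sum(axis=0)
        da = dz @ self.params["Wo"].T
        for j in reversed(range(len(self.dense_units))):
            a_in, z = dense_caches[j]
            dzj = da * (z > 0)
            grads[f"Wd{j}"] = a_in.T @ dzj
            grads[f"bd{j}"] = dzj.sum(axis=0)
            da = dzj @ self.params[f"Wd{j}"].T
        # global average pooling backward
        T = gap_in.shape[2]
        dh = np.repeat(da[:, :, None], T, axis=2) / T
        for i in reversed(range(len(self.conv_filters))):
            h_in, win, z, a, pool_arg = conv_caches[i]
            p = self.pool_sizes[i]
            if p > 1:
                B, C, Tp = dh.shape
                da_full = np.zeros_like(a)
                t_idx = (np.arange(Tp)[None, None, :] * p + pool_arg)
                b_idx = np.arange(B)[:, None, None]
                c_idx = np.arange(C)[None, :, None]
                np.add.at(da_full, (b_idx, c_idx, t_idx), dh)
            else:
                da_full = dh
            dzc = da_full * (z > 0)
            W = self.params[f"Wc{i}"]
            grads[f"Wc{i}"] = np.einsum("bot,bctk->ock", dzc, win, optimize=True)
            grads[f"bc{i}"] = dzc.sum(axis=(0, 2))
            k = self.kernel_sizes[i]
            dzp = np.pad(dzc, ((0, 0), (0, 0), (k - 1, k - 1)))
            win2 = sliding_window_view(dzp, k, axis=2)  # (B, O, L, K)
            dh = np.einsum("ock,boik->bci", W[:, :, ::-1], win2, optimize=True)
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray],
                   beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        lr = self.learning_rate
        t = self._adam_t
        for key, g in grads.items():
            m = self._adam_m[key] = beta1 * self._adam_m[key] + (1 - beta1) * g
            v = self._adam_v[key] = beta2 * self._adam_v[key] + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ------------------------------------------------------------------- API
    def fit(self, X: np.ndarray, y: np.ndarray) -> TrainingHistory:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(f"X must be (n, {self.input_len})")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        n = len(X)
        rng = self._rng
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.validation_fraction * n)))
        if n - n_val < 2:
            raise ValueError("training set too small for the validation split")
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        history = TrainingHistory()
        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        wait = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(Xtr))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                logits, caches = self._forward(xb, cache=True)
                loss = _bce_with_logits(logits, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: {loss}; "
                        f"logit range [{logits.min()}, {logits.max()}]"
                    )
                dlogits = (_sigmoid(logits) - yb) / len(yb)
                grads = self._backward(dlogits, caches)
                self._adam_step(grads)
                epoch_loss += loss
                n_batches += 1
            val_logits = self._forward(Xval)
            vloss = _bce_with_logits(val_logits, yval)
            vacc = float(np.mean((val_logits > 0) == (yval > 0.5)))
            history.train_loss.append(epoch_loss / max(1, n_batches))
            history.val_loss.append(vloss)
            history.val_accuracy.append(vacc)
            if vloss < best_val - self.min_delta:
                best_val = vloss
                best_params = {k: v.copy() for k, v in self.params.items()}
                history.best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        history.stopped_epoch = epoch
        self.params = best_params
        return history

    def predict_proba(self, X: np.ndarray, batch: int = 8192) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for start in range(0, len(X), batch):
            out[start:start + batch] = _sigmoid(self._forward(X[start:start + batch]))
        return out

    # --------------------------------------------------------- serialization
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            if k not in weights:
                raise KeyError(f"missing weight tensor {k!r}")
            if weights[k].shape != self.params[k].shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self.params[k] = np.asarray(weights[k], dtype=float).copy()
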