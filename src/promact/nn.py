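"""A small, self-contained convolutional regression network in NumPy.

The architecture operates on feature tensors of shape
``(batch, n_scales, n_windows, n_channels)``.  Convolutions run along the
window axis only (kernel height 1), so the two window scales never mix
inside a convolution; each conv layer is therefore a same-padded 1-D
convolution applied to every (sample, scale) row independently.  Every
hidden layer uses a leaky rectifier and a max-norm constraint on its
weight matrix; the optimizer is Adadelta; training uses mini-batches,
an internal validation split, and early stopping with best-weight
restoration.  All randomness flows through one ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np


DTYPE = np.float32  # single precision: ample for this loss surface, twice the throughput


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def leaky_relu(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z >= 0, z, slope * z)


def leaky_relu_grad(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z >= 0, 1.0, slope)


class _Layer:
    trainable = True
    has_weights = False


class Conv1dSame(_Layer):
    """Same-padded 1-D convolution along the window axis.

    Input ``(R, L, C_in)`` -> output ``(R, L, C_out)`` where ``R`` is
    batch x scales.  Weight shape ``(k * C_in, C_out)``, tap-major.
    """

    has_weights = True

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.W = _glorot(rng, k * c_in, k * c_out, (k * c_in, c_out))
        self.b = np.zeros(c_out, dtype=DTYPE)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        R, L, C = x.shape
        pad_l = (self.k - 1) // 2
        pad_r = self.k - 1 - pad_l
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        return np.concatenate([xp[:, i:i + L, :] for i in range(self.k)], axis=2)

    def forward(self, x: np.ndarray):
        cols = self._im2col(x)
        z = cols @ self.W + self.b
        return z, (x.shape, cols)

    def backward(self, dz: np.ndarray, cache):
        x_shape, cols = cache
        R, L, C = x_shape
        dW = np.tensordot(cols, dz, axes=([0, 1], [0, 1]))
        db = dz.sum(axis=(0, 1))
        dcols = dz @ self.W.T
        pad_l = (self.k - 1) // 2
        pad_r = self.k - 1 - pad_l
        dxp = np.zeros((R, L + self.k - 1, C), dtype=dcols.dtype)
        for i in range(self.k):
            dxp[:, i:i + L, :] += dcols[:, :, i * C:(i + 1) * C]
        dx = dxp[:, pad_l:pad_l + L, :]
        return dx, dW, db

    def apply_maxnorm(self, c: float) -> None:
        norms = np.sqrt((self.W ** 2).sum(axis=0, keepdims=True))
        factor = np.minimum(1.0, c / np.maximum(norms, 1e-12))
        self.W *= factor


class Dense(_Layer):
    has_weights = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray):
        return x @ self.W + self.b, x

    def backward(self, dz: np.ndarray, x: np.ndarray):
        dW = x.T @ dz
        db = dz.sum(axis=0)
        dx = dz @ self.W.T
        return dx, dW, db

    def apply_maxnorm(self, c: float) -> None:
        norms = np.sqrt((self.W ** 2).sum(axis=0, keepdims=True))
        factor = np.minimum(1.0, c / np.maximum(norms, 1e-12))
        self.W *= factor


class ConvNet:
    """Conv stack + two fully connected layers mapping tensors to scalars.

    With ``conv_filters=()`` the network degenerates to the two-layer
    fully connected baseline on the flattened input.
    """

    def __init__(
        self,
        input_shape=(2, 20, 3),
        conv_filters=(64, 64, 32),
        kernel_size: int = 3,
        fc_hidden: int = 128,
        leaky_slope: float = 0.1,
        max_norm: float = 3.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        self.input_shape = tuple(input_shape)
        self.conv_filters = tuple(conv_filters)
        self.kernel_size = kernel_size
        self.fc_hidden = fc_hidden
        self.leaky_slope = leaky_slope
        self.max_norm = max_norm
        n_scales, n_windows, n_channels = self.input_shape
        self.convs: list[Conv1dSame] = []
        c_in = n_channels
        for c_out in self.conv_filters:
            self.convs.append(Conv1dSame(c_in, c_out, kernel_size, rng))
            c_in = c_out
        flat = n_scales * n_windows * c_in
        self.fc1 = Dense(flat, fc_hidden, rng)
        self.fc2 = Dense(fc_hidden, 1, rng)

    # -- parameter bookkeeping -------------------------------------------
    def layers(self):
        return [*self.convs, self.fc1, self.fc2]

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers():
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers():
            layer.W = next(it).copy()
            layer.b = next(it).copy()

    def n_parameters(self) -> int:
        return sum(layer.W.size + layer.b.size for layer in self.layers())

    def freeze_convs(self) -> None:
        for layer in self.convs:
            layer.trainable = False

    # -- forward / backward ----------------------------------------------
    def forward(self, X: np.ndarray, return_cache: bool = False):
        if X.ndim != 4 or X.shape[1:] != self.input_shape:
            raise ValueError(f"expected input shape (n, {self.input_shape}), got {X.shape}")
        B = X.shape[0]
        n_scales, n_windows, _ = self.input_shape
        x = X.reshape(B * n_scales, n_windows, self.input_shape[2]).astype(DTYPE)
        caches = []
        for layer in self.convs:
            z, cache = layer.forward(x)
            caches.append((z, cache))
            x = leaky_relu(z, self.leaky_slope)
        flat = x.reshape(B, -1)
        z1, c1 = self.fc1.forward(flat)
        a1 = leaky_relu(z1, self.leaky_slope)
        z2, c2 = self.fc2.forward(a1)
        pred = z2[:, 0]
        if not return_cache:
            return pred
        return pred, (caches, flat, z1, c1, a1, c2, x.shape)

    def backward(self, dpred: np.ndarray, cache):
        caches, flat, z1, c1, a1, c2, conv_out_shape = cache
        grads = {}
        dz2 = dpred[:, None]
        da1, grads[("fc2", "W")], grads[("fc2", "b")] = self.fc2.backward(dz2, c2)
        dz1 = da1 * leaky_relu_grad(z1, self.leaky_slope)
        dflat, grads[("fc1", "W")], grads[("fc1", "b")] = self.fc1.backward(dz1, c1)
        if all(not layer.trainable for layer in self.convs):
            return grads  # frozen conv stack: no need to backpropagate further
        dx = dflat.reshape(conv_out_shape)
        for idx in range(len(self.convs) - 1, -1, -1):
            z, conv_cache = caches[idx]
            dz = dx * leaky_relu_grad(z, self.leaky_slope)
            dx, dW, db = self.convs[idx].backward(dz, conv_cache)
            grads[(f"conv{idx}", "W")] = dW
            grads[(f"conv{idx}", "b")] = db
        return grads

    def _named_layers(self):
        named = [(f"conv{idx}", layer) for idx, layer in enumerate(self.convs)]
        named += [("fc1", self.fc1), ("fc2", self.fc2)]
        return named


class Adadelta:
    """Adadelta with the classic defaults (lr=1.0, rho=0.95)."""

    def __init__(self, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-7):
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._state: dict = {}

    def step(self, net: ConvNet, grads: dict) -> None:
        for name, layer in net._named_layers():
            if not layer.trainable:
                continue
            for pname in ("W", "b"):
                g = grads[(name, pname)]
                key = (name, pname)
                if key not in self._state:
                    self._state[key] = (np.zeros_like(g), np.zeros_like(g))
                acc_g, acc_d = self._state[key]
                acc_g = self.rho * acc_g + (1 - self.rho) * g * g
                update = g * np.sqrt(acc_d + self.eps) / np.sqrt(acc_g + self.eps)
                acc_d = self.rho * acc_d + (1 - self.rho) * update * update
                self._state[key] = (acc_g, acc_d)
                param = getattr(layer, pname)
                param -= self.lr * update
            if net.max_norm and net.max_norm > 0:
                layer.apply_maxnorm(net.max_norm)


def train_network(
    net: ConvNet,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    batch_size: int = 64,
    max_epochs: int = 80,
    patience: int = 10,
    min_delta: float = 1e-4,
    validation_fraction: float = 0.2,
    restore_best: bool = True,
) -> dict:
    """Mini-batch MSE training with early stopping on a validation split.

    Rows are shuffled once, the trailing ``validation_fraction`` becomes
    the validation set, and training stops when the validation loss has
    not improved by ``min_delta`` for ``patience`` epochs.  Returns a
    history dict with per-epoch losses and the epochs actually run.
    """
    X = np.ascontiguousarray(X, dtype=DTYPE)
    y = np.asarray(y, dtype=DTYPE)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * validation_fraction)))
    train_idx, val_idx = perm[: n - n_val], perm[n - n_val:]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = Adadelta()
    best_loss = np.inf
    best_weights = net.get_weights()
    wait = 0
    history = {"train_loss": [], "val_loss": []}
    n_tr = Xtr.shape[0]
    for epoch in range(max_epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            pred, cache = net.forward(xb, return_cache=True)
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            dpred = (2.0 * err / len(idx)).astype(DTYPE)
            grads = net.backward(dpred, cache)
            opt.step(net, grads)
        val_pred = net.forward(Xval)
        val_loss = float(np.mean((val_pred - yval) ** 2))
        history["train_loss"].append(epoch_loss / n_tr)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - min_delta:
            best_loss = val_loss
            best_weights = net.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    if restore_best:
        net.set_weights(best_weights)
    history["n_epochs"] = len(history["val_loss"])
    history["best_val_loss"] = best_loss if np.isfinite(best_loss) else history["val_loss"][-1]
    return history
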