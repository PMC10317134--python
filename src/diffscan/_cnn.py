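"""A compact, dependency-free convolutional network in NumPy.

Implements exactly what the frame classifier needs and nothing more: 3×3
same-padding convolutions (im2col + GEMM), ReLU, 2×2 max pooling, inverted
dropout, dense layers, softmax cross-entropy, Adam, and early stopping on
validation loss.  All randomness (initialisation, shuffling, dropout) flows
from a single seeded Generator, so training is deterministic given the seed.

Arrays are (batch, channels, height, width) throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN"]


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Conv3x3:
    """3×3 convolution, stride 1, zero same-padding."""

    def __init__(self, rng, c_in: int, c_out: int):
        self.W = _he_init(rng, (c_out, c_in * 9), c_in * 9)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * Wd, C * 9)
        out = cols @ self.W.T + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(B, H, Wd, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray):
        cols, (B, C, H, Wd) = self._cache
        dflat = dout.transpose(0, 2, 3, 1).reshape(B, H * Wd, -1)
        self.dW = np.tensordot(dflat, cols, axes=([0, 1], [0, 1])).astype(np.float32)
        self.db = dflat.sum(axis=(0, 1)).astype(np.float32)
        dcols = (dflat @ self.W).reshape(B, H, Wd, C, 3, 3)
        dpad = np.zeros((B, C, H + 2, Wd + 2), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                dpad[:, :, ki : ki + H, kj : kj + Wd] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dpad[:, :, 1 : 1 + H, 1 : 1 + Wd]

    def grads(self):
        return [self.dW, self.db]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, d):
        return d * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class _MaxPool2:
    def forward(self, x, train):
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : 2 * H2, : 2 * W2]
        r = xc.reshape(B, C, H2, 2, W2, 2)
        out = r.max(axis=(3, 5))
        self._cache = ((B, C, H, W), r, out)
        return out

    def backward(self, d):
        (B, C, H, W), r, out = self._cache
        mask = r == out[:, :, :, None, :, None]
        # ties split the gradient rather than double-counting it
        mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        dr = mask * d[:, :, :, None, :, None]
        H2, W2 = r.shape[2], r.shape[4]
        dx = np.zeros((B, C, H, W), dtype=np.float32)
        dx[:, :, : 2 * H2, : 2 * W2] = dr.reshape(B, C, 2 * H2, 2 * W2)
        return dx

    def params(self):
        return []

    def grads(self):
        return []


class _Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, d):
        return d if self._mask is None else d * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, d):
        self.dW = (self._x.T @ d).astype(np.float32)
        self.db = d.sum(axis=0).astype(np.float32)
        return d @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class SmallCNN:
    """Six 3×3 convolution layers with interleaved max pooling and dropout,
    a dense head, softmax output.

    ``channels`` gives the six convolution widths; a 2×2 max pool + dropout
    block follows every second convolution.  Trained with Adam on softmax
    cross-entropy, minibatched, early-stopped on validation loss (best
    weights restored).
    """

    def __init__(
        self,
        input_hw: tuple[int, int],
        n_classes: int = 4,
        channels: tuple[int, ...] = (8, 8, 16, 16, 32, 32),
        dropout: float = 0.25,
        dense_units: int = 64,
        lr: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 60,
        patience: int = 8,
        seed: int = 0,
    ):
        if len(channels) != 6:
            raise ValueError("this architecture has exactly six convolution layers")
        self.config = dict(
            input_hw=tuple(input_hw), n_classes=n_classes, channels=tuple(channels),
            dropout=dropout, dense_units=dense_units, lr=lr, batch_size=batch_size,
            max_epochs=max_epochs, patience=patience, seed=seed,
        )
        self.rng = np.random.default_rng(seed)
        self.layers = []
        h, w = input_hw
        c_in = 1
        for i, c_out in enumerate(channels):
            self.layers.append(_Conv3x3(self.rng, c_in, c_out))
            self.layers.append(_ReLU())
            c_in = c_out
            if i % 2 == 1:
                self.layers.append(_MaxPool2())
                h, w = h // 2, w // 2
                self.layers.append(_Dropout(dropout, self.rng))
        self.layers.append(_Flatten())
        self.layers.append(_Dense(self.rng, c_in * h * w, dense_units))
        self.layers.append(_ReLU())
        self.layers.append(_Dropout(dropout, self.rng))
        self.layers.append(_Dense(self.rng, dense_units, n_classes))
        self.history: list[dict] = []

    # -- plumbing ---------------------------------------------------------
    def _params(self):
        return [p for layer in self.layers for p in layer.params()]

    def _grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    @staticmethod
    def _as_batch(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None, :, :]
        return X

    # -- API --------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None, verbose: bool = False,
            augment: bool = True):
        """Train on (N, H, W) images and integer labels; early stopping uses
        the validation split if given, else training loss.

        ``augment`` applies a random dihedral transform (0/90/180/270°
        rotation, optional flip) to every training sample each epoch.
        Diffraction crops are centred and their class content is
        rotation-covariant (rings are isotropic, Bragg-spot azimuths are
        arbitrary), so the label is invariant and the network is pushed to
        learn spots-on-a-radius rather than specific spot positions.
        """
        X = self._as_batch(X)
        y = np.asarray(y, dtype=np.int64)
        cfg = self.config
        opt = _Adam(self._params(), lr=cfg["lr"])
        n = len(X)
        best_loss, best_state, bad = np.inf, None, 0
        for epoch in range(cfg["max_epochs"]):
            order = self.rng.permutation(n)
            tot, seen = 0.0, 0
            for start in range(0, n, cfg["batch_size"]):
                idx = order[start : start + cfg["batch_size"]]
                xb, yb = X[idx], y[idx]
                if augment:
                    xb = xb.copy()
                    ks = self.rng.integers(0, 4, len(xb))
                    flips = self.rng.integers(0, 2, len(xb))
                    for i in range(len(xb)):
                        v = np.rot90(xb[i], ks[i], axes=(1, 2))
                        if flips[i]:
                            v = v[:, :, ::-1]
                        xb[i] = v
                logits = self._forward(xb, train=True)
                probs = _softmax(logits)
                loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
                d = (probs - np.eye(cfg["n_classes"], dtype=np.float32)[yb]) / len(yb)
                for layer in reversed(self.layers):
                    d = layer.backward(d)
                opt.step(self._grads())
                tot += loss * len(yb)
                seen += len(yb)
            train_loss = tot / seen
            if X_val is not None and len(X_val):
                val_loss = self.loss(X_val, y_val)
            else:
                val_loss = train_loss
            self.history.append({"epoch": epoch, "train_loss": float(train_loss), "val_loss": float(val_loss)})
            if verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}")
            if val_loss < best_loss - 1e-5:
                best_loss, bad = val_loss, 0
                best_state = [p.copy() for p in self._params()]
            else:
                bad += 1
                if bad >= cfg["patience"]:
                    break
        if best_state is not None:
            for p, b in zip(self._params(), best_state):
                p[:] = b
        return self

    def predict_proba(self, X, batch_size: int = 64) -> np.ndarray:
        X = self._as_batch(X)
        out = [
            _softmax(self._forward(X[i : i + batch_size], train=False))
            for i in range(0, len(X), batch_size)
        ]
        return np.vstack(out)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def loss(self, X, y) -> float:
        probs = self.predict_proba(X)
        y = np.asarray(y, dtype=np.int64)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self._params())}
        import json

        np.savez(path, config=json.dumps(self.config), **arrays)

    @classmethod
    def load(cls, path) -> "SmallCNN":
        import json

        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["config"]))
            net = cls(
                input_hw=tuple(cfg["input_hw"]), n_classes=cfg["n_classes"],
                channels=tuple(cfg["channels"]), dropout=cfg["dropout"],
                dense_units=cfg["dense_units"], lr=cfg["lr"],
                batch_size=cfg["batch_size"], max_epochs=cfg["max_epochs"],
                patience=cfg["patience"], seed=cfg["seed"],
            )
            for i, p in enumerate(net._params()):
                p[:] = z[f"p{i}"]
        return net
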