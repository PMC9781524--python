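"""1D convolutional neural network for radiomic feature vectors (NumPy).

The network mirrors the published architecture for binary GB-vs-BM
classification of a z-scored feature vector (length 74 for a single
biomarker map, 296 for all four concatenated):

    conv(8 filters, kernel 2, stride 1, same) + ReLU
    maxpool(kernel 2, stride 1, same)
    conv(8, 3, 1, same) + ReLU -> dropout 0.2
    maxpool(2, 1, same)
    conv(8, 3, 1, same) + ReLU -> dropout 0.2
    maxpool(2, stride 2, same)            # halves the sequence length
    flatten -> dense(flatten size) + ReLU -> dropout 0.2 -> dense(1, sigmoid)

"Same" padding for the even kernel 2 pads on the right.  Training uses
binary cross-entropy with the Adam optimizer (lr 1e-3, betas 0.9/0.999),
up to 300 epochs of 5 batches each with per-epoch shuffling.  Dropout is
active only during training, so inference is deterministic; all randomness
(init, shuffling, dropout) flows from one seeded generator, making training
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# layers


def _same_pad(kernel: int) -> tuple[int, int]:
    """(left, right) padding; even kernels pad the extra cell on the right."""
    total = kernel - 1
    left = total // 2
    return left, total - left


class Conv1D:
    """1D convolution, stride 1, same padding, optional ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, relu: bool = True) -> None:
        scale = np.sqrt(2.0 / (in_ch * kernel))        # He init for ReLU
        self.w = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.kernel = kernel
        self.relu = relu
        self._cache: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        left, right = _same_pad(self.kernel)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        z = np.einsum("bclk,fck->bfl", win, self.w) + self.b[None, :, None]
        out = np.maximum(z, 0.0) if self.relu else z
        self._cache = (win, z, x.shape, left)
        return out

    def backward(self, dout: np.ndarray):
        win, z, x_shape, left = self._cache
        if self.relu:
            dout = dout * (z > 0)
        dw = np.einsum("bclk,bfl->fck", win, dout)
        db = dout.sum(axis=(0, 2))
        b_, c_, l_ = x_shape
        lp = l_ + self.kernel - 1
        dxp = np.zeros((b_, c_, lp))
        for k in range(self.kernel):
            dxp[:, :, k:k + l_] += np.einsum("bfl,fc->bcl", dout, self.w[:, :, k])
        dx = dxp[:, :, left:left + l_]
        return dx, [dw, db]


class MaxPool1D:
    """Max pooling with same padding (pad value −inf)."""

    def __init__(self, kernel: int = 2, stride: int = 1) -> None:
        self.kernel = kernel
        self.stride = stride
        self._cache: tuple | None = None

    def params(self):
        return []

    def out_length(self, length: int) -> int:
        return -(-length // self.stride)        # ceil(L / stride)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b_, c_, l_ = x.shape
        out_l = self.out_length(l_)
        need = (out_l - 1) * self.stride + self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (0, need - l_)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, ::self.stride, :]
        arg = win.argmax(axis=3)
        out = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]
        self._cache = (arg, x.shape, out_l)
        return out

    def backward(self, dout: np.ndarray):
        arg, x_shape, out_l = self._cache
        b_, c_, l_ = x_shape
        dx = np.zeros((b_, c_, l_))
        src = (np.arange(out_l) * self.stride)[None, None, :] + arg
        bb, cc = np.meshgrid(np.arange(b_), np.arange(c_), indexing="ij")
        bb = np.broadcast_to(bb[..., None], src.shape)
        cc = np.broadcast_to(cc[..., None], src.shape)
        keep = src < l_          # gradients to −inf padding are dropped
        np.add.at(dx, (bb[keep], cc[keep], src[keep]), dout[keep])
        return dx, []


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray):
        if self._mask is None:
            return dout, []
        return dout * self._mask, []


class Flatten:
    def __init__(self) -> None:
        self._shape: tuple | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray):
        return dout.reshape(self._shape), []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu: bool = False, init_scale: float = 1.0) -> None:
        scale = (np.sqrt(2.0 / n_in) if relu else np.sqrt(1.0 / n_in)) * init_scale
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.relu = relu
        self._cache: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x @ self.w + self.b
        out = np.maximum(z, 0.0) if self.relu else z
        self._cache = (x, z)
        return out

    def backward(self, dout: np.ndarray):
        x, z = self._cache
        if self.relu:
            dout = dout * (z > 0)
        dw = x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.w.T
        return dx, [dw, db]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class CNNSpec:
    """Architecture description; only the input length varies (74 or 296)."""

    input_length: int
    n_filters: int = 8
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.input_length < 1:
            raise ValueError("input_length must be positive")

    @property
    def flatten_size(self) -> int:
        return -(-self.input_length // 2) * self.n_filters


def infer_shapes(spec: CNNSpec) -> list[tuple[str, int, int]]:
    """Per-layer (name, sequence length, channels) contract.

    Stride-1 same-padded layers preserve length; the final stride-2 pool
    halves it (ceiling), so input 74 flattens to 37·8 = 296 units and input
    296 to 148·8 = 1184.
    """
    length = spec.input_length
    f = spec.n_filters
    shapes = [("input", length, 1)]
    shapes.append(("conv1(k2)", length, f))
    shapes.append(("pool1(s1)", length, f))
    shapes.append(("conv2(k3)", length, f))
    shapes.append(("dropout", length, f))
    shapes.append(("pool2(s1)", length, f))
    shapes.append(("conv3(k3)", length, f))
    shapes.append(("dropout", length, f))
    half = -(-length // 2)
    shapes.append(("pool3(s2)", half, f))
    shapes.append(("flatten", half * f, 1))
    shapes.append(("dense1", half * f, 1))
    shapes.append(("dropout", half * f, 1))
    shapes.append(("dense2(sigmoid)", 1, 1))
    return shapes


@dataclass
class TrainingConfig:
    max_epochs: int = 300
    batches_per_epoch: int = 5
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    shuffle_each_epoch: bool = True
    seed: int = 0

    def batch_size(self, n_train: int) -> int:
        return -(-n_train // self.batches_per_epoch)


# ---------------------------------------------------------------------------
# model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    # softplus(z) - y*z, numerically stable
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


class CNN1D:
    """The full network; call :meth:`predict_proba` for GB probabilities."""

    def __init__(self, spec: CNNSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 1]))
        f, r = spec.n_filters, spec.dropout_rate
        self.layers = [
            Conv1D(1, f, 2, rng),
            MaxPool1D(2, 1),
            Conv1D(f, f, 3, rng),
            Dropout(r, self._dropout_rng),
            MaxPool1D(2, 1),
            Conv1D(f, f, 3, rng),
            Dropout(r, self._dropout_rng),
            MaxPool1D(2, 2),
            Flatten(),
            Dense(spec.flatten_size, spec.flatten_size, rng, relu=True),
            Dropout(r, self._dropout_rng),
            # near-zero output init: training starts at p ~ 0.5, so the
            # first-batch BCE is close to the analytic ln 2 = 0.693
            Dense(spec.flatten_size, 1, rng, relu=False, init_scale=0.01),
        ]

    # -- plumbing

    def _check_input(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.spec.input_length:
            raise ValueError(f"feature length {x.shape[1]} does not match "
                             f"spec input_length {self.spec.input_length}")
        return x[:, None, :]           # (B, 1, L)

    def forward_logits(self, features: np.ndarray, training: bool = False
                       ) -> np.ndarray:
        h = self._check_input(features)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h[:, 0]

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Probability of the positive (GB) class, dropout disabled."""
        return _sigmoid(self.forward_logits(features, training=False))

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def _backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        grads_rev: list[np.ndarray] = []
        d = dlogits[:, None]
        for layer in reversed(self.layers):
            d, gs = layer.backward(d)
            grads_rev.extend(reversed(gs))
        return list(reversed(grads_rev))

    # -- persistence

    def save(self, path: str | Path, training_config: TrainingConfig | None = None
             ) -> None:
        """One .npz artifact holding weights plus a JSON metadata record."""
        meta = {"input_length": self.spec.input_length,
                "n_filters": self.spec.n_filters,
                "dropout_rate": self.spec.dropout_rate,
                "seed": self.seed}
        if training_config is not None:
            meta["training"] = {k: getattr(training_config, k) for k in
                                ("max_epochs", "batches_per_epoch",
                                 "learning_rate", "seed")}
        arrays = {f"param_{i}": p for i, p in enumerate(self.parameters())}
        np.savez(str(path), meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CNN1D":
        data = np.load(str(path), allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        spec = CNNSpec(input_length=meta["input_length"],
                       n_filters=meta["n_filters"],
                       dropout_rate=meta["dropout_rate"])
        model = cls(spec, seed=meta["seed"])
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"param_{i}"]
        return model


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainingConfig) -> None:
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            mhat = m / (1 - c.beta1 ** self.t)
            vhat = v / (1 - c.beta2 ** self.t)
            p -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)


def train(features: np.ndarray, labels: np.ndarray, spec: CNNSpec,
          config: TrainingConfig,
          val_features: np.ndarray | None = None,
          val_labels: np.ndarray | None = None,
          ) -> tuple[CNN1D, pd.DataFrame]:
    """Train the 1D-CNN; returns the model and a per-batch history table.

    The history records per-batch training loss/accuracy and, at the end of
    each epoch, validation loss/accuracy.  When a validation set is given
    the weights with the best validation accuracy are restored at the end
    (the checkpoint rule; ties keep the earlier epoch).
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features must be (n_cases, n_features) matching labels")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        raise ValueError("labels must be binary 0/1")

    model = CNN1D(spec, seed=config.seed)
    optim = _Adam(model.parameters(), config)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = x.shape[0]
    batch = config.batch_size(n)

    rows = []
    best_val = -np.inf
    best_weights: list[np.ndarray] | None = None
    for epoch in range(config.max_epochs):
        order = np.arange(n)
        if config.shuffle_each_epoch:
            shuffle_rng.shuffle(order)
        for b in range(config.batches_per_epoch):
            sel = order[b * batch:(b + 1) * batch]
            if sel.size == 0:
                continue
            xb, yb = x[sel], y[sel]
            z = model.forward_logits(xb, training=True)
            loss = _bce_with_logits(z, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} batch {b}; "
                    "check feature scaling (inputs must be z-scored)")
            acc = float(np.mean((z > 0) == (yb > 0.5)))
            grads = model._backward((_sigmoid(z) - yb) / yb.size)
            optim.step(grads)
            rows.append({"epoch": epoch, "batch": b, "loss": loss,
                         "train_accuracy": acc,
                         "val_loss": np.nan, "val_accuracy": np.nan})
        if val_features is not None and val_labels is not None:
            zv = model.forward_logits(val_features, training=False)
            yv = np.asarray(val_labels, dtype=np.float64).ravel()
            val_loss = _bce_with_logits(zv, yv)
            val_acc = float(np.mean((zv > 0) == (yv > 0.5)))
            rows[-1]["val_loss"] = val_loss
            rows[-1]["val_accuracy"] = val_acc
            if val_acc > best_val:
                best_val = val_acc
                best_weights = [p.copy() for p in model.parameters()]
    if best_weights is not None:
        for p, w in zip(model.parameters(), best_weights):
            p[...] = w
    return model, pd.DataFrame(rows)


def predict(model: CNN1D, features: np.ndarray) -> np.ndarray:
    """Probability of the positive class for each row of ``features``."""
    return model.predict_proba(features)
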