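"""The convolutional open-chromatin classifier.

Architecture (three hidden layers, all ReLU, inverted dropout after each):

    input 4 x L one-hot
      -> conv1 (F1 filters, width k1, stride 1, valid)   -> ReLU -> dropout
      -> conv2 (F2 filters, width k2, stride 1, valid)   -> ReLU -> dropout
      -> flatten -> dense (fc_units)                     -> ReLU -> dropout
      -> dense (1) -> sigmoid

The sigmoid output is read as the probability that the input fragment lies
in open chromatin.  Training minimizes binary cross-entropy with Adam on
mini-batches; the weights with the lowest validation loss are retained.
Dropout uses the inverted convention (survivors rescaled by 1/(1-p) at
training time), so inference is a plain deterministic forward pass.

Convolutions are computed as matrix products over im2col views, which keeps
the whole model inside numpy's BLAS path; no deep-learning framework is
involved anywhere.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .data import LabeledDataset

EPS = 1e-7  # probability clip in the cross-entropy


def relu(x):
    """Elementwise max(0, x)."""
    return np.maximum(0.0, x)


def sigmoid(z):
    """Numerically safe logistic 1 / (1 + exp(-z))."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def bce_loss(p, y):
    """Mean binary cross-entropy -[y ln p + (1-y) ln(1-p)], p clipped at EPS."""
    p = np.asarray(p, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def apply_dropout(activations, p: float = 0.6, mode: str = "train", rng=None):
    """Inverted dropout: zero units with probability p, rescale survivors.

    In "infer" mode (or with p=0) this is the identity.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError("dropout probability must satisfy 0 <= p < 1")
    if mode not in ("train", "infer"):
        raise ValueError(f"unknown mode {mode!r}")
    a = np.asarray(activations, dtype=np.float64)
    if mode == "infer" or p == 0.0:
        return a
    if rng is None:
        rng = np.random.default_rng()
    mask = (rng.random(a.shape) >= p).astype(np.float64)
    return a * mask / (1.0 - p)


@dataclass
class ModelSpec:
    """Architecture and training hyperparameters.

    Defaults: 64 first-layer filters of width 19 bp (wide enough for the
    6-19 bp motifs these models recover), 32 second-layer filters of width
    11, a 200-unit fully connected layer, dropout 0.6 after every hidden
    layer, and a 120 bp input window.
    """

    conv1_filters: int = 64
    conv1_width: int = 19
    conv2_filters: int = 32
    conv2_width: int = 11
    fc_units: int = 200
    dropout_p: float = 0.6
    input_length: int = 120
    learning_rate: float = 0.05
    batch_size: int = 32
    epochs: int = 100
    optimizer: str = "sgd"  # "sgd" (momentum) or "adam"
    momentum: float = 0.9
    weight_decay: float = 1e-3  # L2 on weight matrices (not biases)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must satisfy 0 <= p < 1")
        if self.fc_units < 1:
            raise ValueError("fc_units must be >= 1")
        if self.conv1_width > self.input_length:
            raise ValueError("conv1_width exceeds input_length")
        if self.conv2_width > self.conv1_out_length:
            raise ValueError("conv2_width exceeds first feature-map length")

    @property
    def conv1_out_length(self) -> int:
        return self.input_length - self.conv1_width + 1

    @property
    def conv2_out_length(self) -> int:
        return self.conv1_out_length - self.conv2_width + 1

    @property
    def flat_units(self) -> int:
        return self.conv2_filters * self.conv2_out_length

    @property
    def n_parameters(self) -> int:
        s = self
        return (
            s.conv1_filters * 4 * s.conv1_width + s.conv1_filters
            + s.conv2_filters * s.conv1_filters * s.conv2_width + s.conv2_filters
            + s.fc_units * s.flat_units + s.fc_units
            + s.fc_units + 1
        )


_PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")


class CNNModel:
    """Weights plus forward/backward passes for the spec'd architecture."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        s = spec

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, np.ndarray] = {
            "W1": he((s.conv1_filters, 4 * s.conv1_width), 4 * s.conv1_width),
            "b1": np.zeros(s.conv1_filters),
            "W2": he(
                (s.conv2_filters, s.conv1_filters * s.conv2_width),
                s.conv1_filters * s.conv2_width,
            ),
            "b2": np.zeros(s.conv2_filters),
            "W3": he((s.fc_units, s.flat_units), s.flat_units),
            "b3": np.zeros(s.fc_units),
            "W4": he((1, s.fc_units), s.fc_units),
            "b4": np.zeros(1),
        }
        self.history: dict[str, list[float]] = {
            "train_loss": [],
            "train_acc": [],
            "val_loss": [],
            "val_acc": [],
        }
        self.trained = False

    # -- forward ---------------------------------------------------------

    @staticmethod
    def _im2col(x: np.ndarray, width: int) -> np.ndarray:
        """(N, C, L) -> (N, L-width+1, C*width) patch matrix."""
        # sliding_window_view over the position axis -> (N, C, L', width)
        v = sliding_window_view(x, width, axis=2)
        return v.transpose(0, 2, 1, 3).reshape(x.shape[0], -1, x.shape[1] * width)

    def conv1_preactivations(self, x: np.ndarray) -> np.ndarray:
        """First-layer pre-ReLU scores, shape (N, L1, F1).

        Exposed for motif extraction, which thresholds these raw scores.
        """
        cols = self._im2col(np.asarray(x, dtype=np.float64), self.spec.conv1_width)
        return cols @ self.params["W1"].T + self.params["b1"]

    def forward(self, x: np.ndarray, train: bool = False, rng=None):
        """Forward pass; returns (probabilities, cache-for-backward)."""
        s, P = self.spec, self.params
        p_drop = s.dropout_p if train else 0.0

        def drop(a):
            if p_drop == 0.0:
                return a, None
            mask = (rng.random(a.shape) >= p_drop) / (1.0 - p_drop)
            return a * mask, mask

        x = np.asarray(x, dtype=np.float64)
        cols1 = self._im2col(x, s.conv1_width)  # (N, L1, 4k1)
        z1 = cols1 @ P["W1"].T + P["b1"]
        a1 = relu(z1)
        d1, m1 = drop(a1)
        cols2 = sliding_window_view(d1, s.conv2_width, axis=1)  # (N, L2, F1, k2)
        cols2 = cols2.reshape(d1.shape[0], s.conv2_out_length, -1)
        z2 = cols2 @ P["W2"].T + P["b2"]
        a2 = relu(z2)
        d2, m2 = drop(a2)
        flat = d2.reshape(d2.shape[0], -1)
        z3 = flat @ P["W3"].T + P["b3"]
        a3 = relu(z3)
        d3, m3 = drop(a3)
        z4 = d3 @ P["W4"].T + P["b4"]
        probs = sigmoid(z4).ravel()
        cache = (cols1, z1, m1, cols2, z2, m2, flat, z3, m3, d3)
        return probs, cache

    # -- backward --------------------------------------------------------

    def backward(self, probs, y, cache):
        """Gradients of mean BCE w.r.t. every parameter."""
        s, P = self.spec, self.params
        cols1, z1, m1, cols2, z2, m2, flat, z3, m3, d3 = cache
        n = y.shape[0]
        dz4 = ((probs - y) / n)[:, None]  # BCE + sigmoid shortcut
        g = {}
        g["W4"] = dz4.T @ d3
        g["b4"] = dz4.sum(axis=0)
        dd3 = dz4 @ P["W4"]
        if m3 is not None:
            dd3 = dd3 * m3
        dz3 = dd3 * (z3 > 0)
        g["W3"] = dz3.T @ flat
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ P["W3"]
        dd2 = dflat.reshape(n, s.conv2_out_length, s.conv2_filters)
        if m2 is not None:
            dd2 = dd2 * m2
        dz2 = dd2 * (z2 > 0)
        g["W2"] = np.einsum("nlf,nlc->fc", dz2, cols2)
        g["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ P["W2"]  # (N, L2, F1*k2)
        dcols2 = dcols2.reshape(n, s.conv2_out_length, s.conv1_filters, s.conv2_width)
        dd1 = np.zeros((n, s.conv1_out_length, s.conv1_filters))
        for t in range(s.conv2_width):  # col2im scatter-add
            dd1[:, t : t + s.conv2_out_length, :] += dcols2[:, :, :, t]
        if m1 is not None:
            dd1 = dd1 * m1
        dz1 = dd1 * (z1 > 0)
        g["W1"] = np.einsum("nlf,nlc->fc", dz1, cols1)
        g["b1"] = dz1.sum(axis=(0, 1))
        return g

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def build_model(spec: ModelSpec) -> CNNModel:
    """Instantiate an untrained model with seed-deterministic init."""
    return CNNModel(spec)


def train_model(spec: ModelSpec, dataset: LabeledDataset) -> CNNModel:
    """Mini-batch gradient descent on binary cross-entropy.

    The default optimizer is plain momentum SGD with a small L2 penalty on
    the weight matrices: at the few-hundred-sample scale this package
    targets, adaptive optimizers drive the large flatten->dense layer
    straight into memorization, while SGD finds the position-shared motif
    solution that generalizes.  Adam remains available via
    ``spec.optimizer``.  The dataset's train partition supplies gradients
    and its validation partition selects the model: the epoch with the
    lowest validation loss supplies the final weights.  Fully
    deterministic for a fixed spec (seed included) and dataset.
    """
    train = dataset.subset("train")
    val = dataset.subset("validation")
    if len(train) == 0 or len(val) == 0:
        raise ValueError("dataset must provide non-empty train and validation partitions")
    if dataset.fragment_length != spec.input_length:
        raise ValueError(
            f"fragment_length {dataset.fragment_length} != spec.input_length "
            f"{spec.input_length}"
        )
    Xtr, ytr = train.encoded()
    Xva, yva = val.encoded()
    model = build_model(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD0]))

    # optimizer state: momentum buffer (sgd) or first/second moments (adam)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    t = 0
    best_val = np.inf
    best_params = model.copy_params()

    for _epoch in range(spec.epochs):
        order = rng.permutation(len(ytr))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            probs, cache = model.forward(xb, train=True, rng=rng)
            loss = bce_loss(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {_epoch}: {loss}"
                )
            losses.append(loss * len(yb))
            hits += int(np.sum((probs >= 0.5) == (yb == 1)))
            seen += len(yb)
            grads = model.backward(probs, yb, cache)
            t += 1
            for k, p in model.params.items():
                g = grads[k]
                if spec.weight_decay and k.startswith("W"):
                    g = g + spec.weight_decay * p
                if spec.optimizer == "sgd":
                    m[k] = spec.momentum * m[k] + g
                    p -= spec.learning_rate * m[k]
                else:
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g**2
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    p -= spec.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
        val_probs = predict_proba(model, Xva)
        val_loss = bce_loss(val_probs, yva)
        model.history["train_loss"].append(sum(losses) / seen)
        model.history["train_acc"].append(hits / seen)
        model.history["val_loss"].append(val_loss)
        model.history["val_acc"].append(
            float(np.mean((val_probs >= 0.5) == (yva == 1)))
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = model.copy_params()
    model.params = best_params
    model.trained = True
    return model


def predict_proba(model: CNNModel, fragments: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Deterministic open-chromatin probabilities, one per fragment.

    ``fragments`` is (n, 4, input_length); dropout is disabled.
    """
    X = np.asarray(fragments, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] != 4 or X.shape[2] != model.spec.input_length:
        raise ValueError(
            f"expected (n, 4, {model.spec.input_length}) input, got {X.shape}"
        )
    out = np.empty(X.shape[0])
    for start in range(0, X.shape[0], batch_size):
        probs, _ = model.forward(X[start : start + batch_size], train=False)
        out[start : start + len(probs)] = probs
    return out


# -- checkpoint (format version 1) ---------------------------------------

CHECKPOINT_VERSION = 1


def save_model(model: CNNModel, path) -> None:
    """Serialize spec + weights + history into a single .npz checkpoint."""
    meta = {
        "format_version": CHECKPOINT_VERSION,
        "spec": asdict(model.spec),
        "trained": model.trained,
    }
    arrays = {k: model.params[k] for k in _PARAM_NAMES}
    for key, vals in model.history.items():
        arrays[f"history_{key}"] = np.asarray(vals, dtype=np.float64)
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> CNNModel:
    """Load a checkpoint written by :func:`save_model`."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["_meta"]).decode())
        if meta.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('format_version')!r}"
            )
        model = CNNModel(ModelSpec(**meta["spec"]))
        for k in _PARAM_NAMES:
            model.params[k] = npz[k].copy()
        for key in model.history:
            model.history[key] = npz[f"history_{key}"].tolist()
        model.trained = bool(meta["trained"])
    return model
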