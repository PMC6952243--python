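"""Keypoint-regression CNN for needle-reflection centroid localisation.

The network maps a 128x128 normalised B-mode frame to the two unit-scaled
centroid coordinates.  Architecture: five alternating valid (no-padding,
stride-1) convolution and 2x2/stride-2 max-pooling stages with filter
counts 16, 32, 64, 128, 256 (kernels 3x3 then 2x2), a flatten to 2304
features, and four fully connected layers of widths 1024, 128, 16 and 2;
Leaky-ReLU on every pre-output layer and a linear 2-unit output.  With
Glorot-uniform initialisation the default model carries exactly 2 668 338
trainable parameters.

Training minimises mean absolute error in unit coordinates with Adam
(stepped learning rate: 1e-4 for the first 100 epochs, 7e-5 after) and an
L2 penalty on convolutional kernel weights only.

Everything is implemented directly on numpy arrays (im2col convolutions,
reshape-based pooling) so training and inference run identically on any
CPU; batched matrix products carry the arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    BoundsRejection,
    EmptyDataset,
    ShapeMismatch,
    SpecMismatch,
)
from .geometry import PixelPoint
from .preprocessing import (
    MODEL_INPUT_SIZE,
    bounds_check,
    resize_to_model,
    unscale_prediction,
)

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "KeypointRegressor",
    "build_model",
    "count_parameters",
    "train",
    "predict_centroid",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyper-parameters of the localisation network."""

    conv_filters: Tuple[int, ...] = (16, 32, 64, 128, 256)
    conv_kernels: Tuple[int, ...] = (3, 2, 2, 2, 2)
    fc_widths: Tuple[int, ...] = (1024, 128, 16, 2)
    input_size: int = MODEL_INPUT_SIZE
    leaky_slope: float = 0.01
    expected_flatten: Optional[int] = 2304

    def flatten_length(self) -> int:
        """Feature length after the conv/pool stack (valid conv, pool /2)."""
        s = self.input_size
        for k in self.conv_kernels:
            s = (s - k + 1) // 2  # valid convolution then 2x2/stride-2 pool
        return s * s * self.conv_filters[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol (defaults: the full-scale training schedule)."""

    batch_size: int = 128
    epochs: int = 150
    lr_initial: float = 1e-4
    lr_late: float = 7e-5
    lr_switch_epoch: int = 100  # last epoch run at lr_initial
    l2_conv: float = 1e-5       # penalty coefficient on conv kernels only
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    shuffle: bool = True
    seed: int = 0

    def learning_rate(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index."""
        return self.lr_initial if epoch <= self.lr_switch_epoch else self.lr_late


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv2DValid:
    """Stride-1 valid convolution, NHWC, via im2col + matmul.

    Kernel weights are stored flattened in (c_in, kh, kw) order so the
    sliding-window view reshapes into the column matrix without a
    transposed (cache-hostile) copy.
    """

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator,
                 first_layer: bool = False):
        fan_in = k * k * c_in
        fan_out = k * k * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.first_layer = first_layer  # input gradient not needed
        self._cols: Optional[np.ndarray] = None
        self._x_shape: Optional[Tuple[int, ...]] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w_, c = x.shape
        k = self.k
        oh, ow = h - k + 1, w_ - k + 1
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # (n, oh, ow, c, k, k)
        cols = win.reshape(n * oh * ow, c * k * k)  # copies into (c,kh,kw) order
        out = cols @ self.w + self.b
        if train:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(n, oh, ow, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, oh, ow, _ = dout.shape
        k, c = self.k, self.c_in
        dflat = dout.reshape(n * oh * ow, self.c_out)
        self.dw = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        if self.first_layer:
            self._cols = None
            return None
        dcols = (dflat @ self.w.T).reshape(n, oh, ow, c, k, k)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for i in range(k):  # scatter-add col2im; k <= 3 so this loop is tiny
            for j in range(k):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dx

    def params(self):
        return [("w", self), ("b", self)]


class _MaxPool2:
    """2x2 max pooling with stride 2 (cropping any odd trailing row/col).

    Backward splits the gradient equally among tied maxima within a
    window — a deterministic subgradient of the max.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = np.ascontiguousarray(x[:, : 2 * h2, : 2 * w2, :]).reshape(
            n, h2, 2, w2, 2, c
        )
        out = xr.max(axis=(2, 4))
        if train:
            self._xr = xr
            self._out = out
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        mask = self._xr == self._out[:, :, None, :, None, :]
        cnt = mask.sum(axis=(2, 4), dtype=np.float32)
        dxr = mask * (dout / cnt)[:, :, None, :, None, :]
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, : 2 * h2, : 2 * w2, :] = dxr.reshape(n, 2 * h2, 2 * w2, c)
        self._xr = None
        self._out = None
        return dx

    def params(self):
        return []


class _LeakyReLU:
    def __init__(self, slope: float):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # max(x, slope*x) == leaky ReLU for slope < 1
        out = np.maximum(x, np.float32(self.slope) * x)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        scale = self._mask.astype(np.float32)
        scale *= np.float32(1.0 - self.slope)
        scale += np.float32(self.slope)
        scale *= dout
        return scale

    def params(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.w.T

    def params(self):
        return [("w", self), ("b", self)]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class KeypointRegressor:
    """The centroid-localisation network (see module docstring)."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = 1
        for k, f in zip(spec.conv_kernels, spec.conv_filters):
            conv = _Conv2DValid(k, c_in, f, rng, first_layer=(not layers))
            layers += [conv, _LeakyReLU(spec.leaky_slope), _MaxPool2()]
            c_in = f
        layers.append(_Flatten())
        n_in = spec.flatten_length()
        for i, width in enumerate(spec.fc_widths):
            layers.append(_Dense(n_in, width, rng))
            if i < len(spec.fc_widths) - 1:
                layers.append(_LeakyReLU(spec.leaky_slope))  # output stays linear
            n_in = width
        self.layers = layers
        self.conv_layers = [l for l in layers if isinstance(l, _Conv2DValid)]

    # -- inference --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] != self.spec.input_size or x.shape[2] != self.spec.input_size:
            raise ShapeMismatch(
                f"expected {self.spec.input_size}x{self.spec.input_size} input, "
                f"got {x.shape[1]}x{x.shape[2]}"
            )
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_units(self, image128: np.ndarray) -> np.ndarray:
        """Unit-coordinate prediction for a single preprocessed frame."""
        return self.forward(image128, train=False)[0]

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    # -- parameters -------------------------------------------------------
    def parameter_arrays(self) -> List[np.ndarray]:
        out = []
        for layer in self.layers:
            for name, owner in layer.params():
                out.append(getattr(owner, name))
        return out

    def _param_refs(self):
        for layer in self.layers:
            is_conv = isinstance(layer, _Conv2DValid)
            for name, owner in layer.params():
                yield owner, name, (is_conv and name == "w")


def build_model(spec: ArchitectureSpec = ArchitectureSpec(), seed: int = 0) -> KeypointRegressor:
    """Instantiate the network, guarding the conv-stage geometry.

    Raises
    ------
    SpecMismatch
        If the computed flatten length differs from ``spec.expected_flatten``
        (catches padding/stride drift that would silently change the
        parameter count).
    """
    flat = spec.flatten_length()
    if spec.expected_flatten is not None and flat != spec.expected_flatten:
        raise SpecMismatch(
            f"conv/pool stack flattens to {flat}, expected {spec.expected_flatten}"
        )
    return KeypointRegressor(spec, seed=seed)


def count_parameters(model: KeypointRegressor) -> int:
    """Number of independently trainable scalars (weights + biases)."""
    return int(sum(p.size for p in model.parameter_arrays()))


def conv_stage_parameters(model: KeypointRegressor) -> int:
    """Parameter subtotal of the convolutional stage."""
    return int(sum(l.w.size + l.b.size for l in model.conv_layers))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, model: KeypointRegressor, cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.state = {}
        for owner, name, _ in model._param_refs():
            p = getattr(owner, name)
            self.state[(id(owner), name)] = (
                np.zeros_like(p), np.zeros_like(p)
            )

    def step(self, model: KeypointRegressor, lr: float) -> None:
        cfg = self.cfg
        self.t += 1
        b1t = 1.0 - cfg.adam_beta1 ** self.t
        b2t = 1.0 - cfg.adam_beta2 ** self.t
        for owner, name, is_conv_kernel in model._param_refs():
            p = getattr(owner, name)
            g = getattr(owner, "d" + name)
            if is_conv_kernel and cfg.l2_conv > 0:
                g = g + 2.0 * cfg.l2_conv * p  # gradient of l2 * sum(w^2)
            m, v = self.state[(id(owner), name)]
            m *= cfg.adam_beta1
            m += (1.0 - cfg.adam_beta1) * g
            v *= cfg.adam_beta2
            v += (1.0 - cfg.adam_beta2) * np.square(g)
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + cfg.adam_eps)


@dataclass
class TrainingHistory:
    """Per-epoch mean-absolute-error curves, in unit coordinates."""

    train_mae: List[float] = field(default_factory=list)
    val_mae: List[float] = field(default_factory=list)

    def plot(self, ax=None):
        """Loss curves (training vs validation MAE per epoch)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, len(self.train_mae) + 1)
        ax.plot(epochs, self.train_mae, label="training MAE")
        if self.val_mae:
            ax.plot(epochs, self.val_mae, label="validation MAE")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MAE (unit coordinates)")
        ax.legend()
        return ax


def _check_dataset(x: np.ndarray, y: np.ndarray, spec: ArchitectureSpec):
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if len(x) == 0:
        raise EmptyDataset("dataset is empty")
    if x.shape[1] != spec.input_size or x.shape[2] != spec.input_size:
        raise ShapeMismatch(f"images must be {spec.input_size}x{spec.input_size}")
    if y.shape != (len(x), 2):
        raise ShapeMismatch("labels must have shape (n, 2)")
    return x, y


def evaluate_mae(model: KeypointRegressor, x: np.ndarray, y: np.ndarray,
                 batch_size: int = 128) -> float:
    """Mean absolute error in unit coordinates over a dataset."""
    x, y = _check_dataset(x, y, model.spec)
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        pred = model.forward(x[i : i + batch_size])
        total += float(np.abs(pred - y[i : i + batch_size]).sum())
        n += pred.size
    return total / n


def train(
    model: KeypointRegressor,
    train_set: Tuple[np.ndarray, np.ndarray],
    val_set: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    cfg: TrainConfig = TrainConfig(),
) -> TrainingHistory:
    """Fit the network by mini-batch Adam on the MAE loss.

    Loss history is the MAE in unit-coordinate space (train: running mean
    over the epoch's batches before each update; validation: full pass
    after the epoch).  The L2 penalty applies to convolutional kernels
    only and enters through the gradient, not the reported MAE.  The
    learning rate switches from ``lr_initial`` to ``lr_late`` exactly
    after ``lr_switch_epoch``.  Deterministic under a fixed config seed.
    """
    x, y = _check_dataset(*train_set, model.spec)
    if val_set is not None:
        xv, yv = _check_dataset(*val_set, model.spec)
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model, cfg)
    history = TrainingHistory()
    n = len(x)
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.learning_rate(epoch)
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_abs, epoch_count = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            pred = model.forward(xb, train=True)
            resid = pred - yb
            epoch_abs += float(np.abs(resid).sum())
            epoch_count += resid.size
            model.backward(np.sign(resid).astype(np.float32) / resid.size)
            opt.step(model, lr)
        history.train_mae.append(epoch_abs / epoch_count)
        if val_set is not None:
            history.val_mae.append(evaluate_mae(model, xv, yv, cfg.batch_size))
    return history


# ---------------------------------------------------------------------------
# inference pipeline
# ---------------------------------------------------------------------------

def predict_centroid(model, image: np.ndarray) -> PixelPoint:
    """Localise the needle-reflection centroid in a raw frame.

    Pipeline: resize to the model input, forward pass, map the unit-range
    output back to the raw frame's integer pixel grid, then bounds-check.
    Any object exposing ``predict_units(image128) -> (2,)`` can stand in
    for the network.

    Raises
    ------
    BoundsRejection
        When the prediction falls outside the frame: retriable, capture a
        new frame.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    units = np.asarray(model.predict_units(resize_to_model(image)), dtype=float)
    p = unscale_prediction(units, w, h)
    return bounds_check(p, w, h)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: KeypointRegressor, path) -> None:
    """Portable weights file (.npz) with a JSON echo of the architecture."""
    arrays = {f"p{i}": p for i, p in enumerate(model.parameter_arrays())}
    spec = asdict(model.spec)
    with open(path, "wb") as f:
        np.savez(f, spec=np.frombuffer(json.dumps(spec).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> KeypointRegressor:
    with np.load(path) as data:
        spec_dict = json.loads(bytes(data["spec"]).decode())
        for key in ("conv_filters", "conv_kernels", "fc_widths"):
            spec_dict[key] = tuple(spec_dict[key])
        model = build_model(ArchitectureSpec(**spec_dict))
        for i, p in enumerate(model.parameter_arrays()):
            p[...] = data[f"p{i}"]
    return model
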