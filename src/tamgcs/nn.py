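"""Minimal deterministic sequential network backend.

Provides exactly the substrate the layer-scoring/pruning procedure
needs: build a small feed-forward classifier (conv2d / maxpool2d /
flatten / dense), train it with seeded SGD+momentum, evaluate it, count
its parameters, and extract flattened activations at any layer.  Images
are channels-last ``(batch, H, W, C)``; dense inputs are ``(batch, D)``.

Everything is plain NumPy, so a fixed seed gives bit-identical weights
and reports on any CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gcs import LabeledDataset

__all__ = [
    "LayerSpec",
    "TrainConfig",
    "SequentialModel",
    "build_model",
    "count_parameters",
    "train",
    "evaluate",
    "layer_activations",
    "stratified_sample",
    "save_model",
    "load_model",
]

VALID_KINDS = ("conv2d", "maxpool2d", "flatten", "dense")
VALID_ACTIVATIONS = ("relu", "softmax", "none")


@dataclass(frozen=True)
class LayerSpec:
    """Declarative layer description.

    ``conv2d`` uses ``filters`` and ``kernel_size`` (stride 1, valid
    padding); ``maxpool2d`` uses ``pool`` (size = stride); ``dense`` uses
    ``units``.  ``flatten`` takes no hyperparameters.
    """

    kind: str
    filters: int | None = None
    kernel_size: int | None = None
    pool: int | None = None
    units: int | None = None
    activation: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.activation not in VALID_ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.kind == "conv2d" and (not self.filters or not self.kernel_size):
            raise ValueError("conv2d needs filters and kernel_size")
        if self.kind == "maxpool2d" and not self.pool:
            raise ValueError("maxpool2d needs pool")
        if self.kind == "dense" and not self.units:
            raise ValueError("dense needs units")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "activation": self.activation}
        for key in ("filters", "kernel_size", "pool", "units"):
            val = getattr(self, key)
            if val is not None:
                d[key] = val
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSpec":
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Layer:
    spec: LayerSpec
    params: list
    grads: list
    trainable: bool = True

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)


class _Conv2D(_Layer):
    def __init__(self, spec: LayerSpec, in_shape, rng):
        self.spec = spec
        h, w, cin = in_shape
        k, f = spec.kernel_size, spec.filters
        if k > h or k > w:
            raise ValueError(f"kernel {k} exceeds input {in_shape}")
        fan_in = k * k * cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, cin, f))
        self.b = np.zeros(f)
        self.out_shape = (h - k + 1, w - k + 1, f)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False):
        k = self.spec.kernel_size
        cols = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # (B, H', W', C, k, k) -> (B, H', W', k, k, C)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        b, ho, wo = cols.shape[:3]
        flat = cols.reshape(b * ho * wo, -1)
        wflat = self.W.reshape(-1, self.spec.filters)
        out = flat @ wflat + self.b
        if training:
            self._cache = (x.shape, flat)
        z = out.reshape(b, ho, wo, self.spec.filters)
        if self.spec.activation == "relu":
            z = _relu(z)
            if training:
                self._relu_out = z
        return z

    def backward(self, grad):
        x_shape, flat = self._cache
        if self.spec.activation == "relu":
            grad = grad * (self._relu_out > 0)
        b, ho, wo, f = grad.shape
        gflat = grad.reshape(b * ho * wo, f)
        wflat = self.W.reshape(-1, f)
        self.dW = (flat.T @ gflat).reshape(self.W.shape)
        self.db = gflat.sum(axis=0)
        dcols = (gflat @ wflat.T).reshape(b, ho, wo, *self.W.shape[:3])
        dx = np.zeros(x_shape)
        k = self.spec.kernel_size
        for i in range(k):
            for j in range(k):
                dx[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i, j, :]
        return dx


class _MaxPool2D(_Layer):
    params: list = []
    grads: list = []

    def __init__(self, spec: LayerSpec, in_shape):
        self.spec = spec
        h, w, c = in_shape
        p = spec.pool
        self.crop = (h - h % p, w - w % p)
        self.out_shape = (self.crop[0] // p, self.crop[1] // p, c)
        self._cache = None

    def forward(self, x, training=False):
        p = self.spec.pool
        hc, wc = self.crop
        xc = x[:, :hc, :wc, :]
        b, _, _, c = xc.shape
        ho, wo = hc // p, wc // p
        tiles = xc.reshape(b, ho, p, wo, p, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            b, ho, wo, c, p * p
        )
        idx = tiles.argmax(axis=-1)
        out = np.take_along_axis(tiles, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (x.shape, idx)
        if self.spec.activation == "relu":
            out = _relu(out)
        return out

    def backward(self, grad):
        x_shape, idx = self._cache
        p = self.spec.pool
        b, ho, wo, c = grad.shape
        tiles = np.zeros((b, ho, wo, c, p * p))
        np.put_along_axis(tiles, idx[..., None], grad[..., None], axis=-1)
        hc, wc = self.crop
        dxc = tiles.reshape(b, ho, wo, c, p, p).transpose(0, 1, 4, 2, 5, 3).reshape(
            b, hc, wc, c
        )
        dx = np.zeros(x_shape)
        dx[:, :hc, :wc, :] = dxc
        return dx


class _Flatten(_Layer):
    params: list = []
    grads: list = []

    def __init__(self, spec: LayerSpec, in_shape):
        self.spec = spec
        self.out_shape = (int(np.prod(in_shape)),)
        self._in_shape = in_shape

    def forward(self, x, training=False):
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], *self._in_shape)


class _Dense(_Layer):
    def __init__(self, spec: LayerSpec, in_shape, rng):
        self.spec = spec
        if len(in_shape) != 1:
            raise ValueError(f"dense layer expects flat input, got shape {in_shape}")
        d, u = in_shape[0], spec.units
        self.W = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, u))
        self.b = np.zeros(u)
        self.out_shape = (u,)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False):
        z = x @ self.W + self.b
        if training:
            self._cache = x
        if self.spec.activation == "relu":
            z = _relu(z)
            if training:
                self._relu_out = z
        elif self.spec.activation == "softmax":
            z = _softmax(z)
        return z

    def backward(self, grad):
        # For a terminal softmax layer the incoming grad is dL/dlogits
        # (softmax and cross-entropy combined); relu masks locally.
        if self.spec.activation == "relu":
            grad = grad * (self._relu_out > 0)
        x = self._cache
        self.dW = x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


_LAYER_BUILDERS = {
    "conv2d": lambda spec, shape, rng: _Conv2D(spec, shape, rng),
    "maxpool2d": lambda spec, shape, rng: _MaxPool2D(spec, shape),
    "flatten": lambda spec, shape, rng: _Flatten(spec, shape),
    "dense": lambda spec, shape, rng: _Dense(spec, shape, rng),
}


class SequentialModel:
    """Ordered layer stack with seeded initialization.

    A classifier must end in exactly one dense softmax layer; shape
    compatibility of consecutive layers is checked at build time.
    """

    def __init__(self, specs: Sequence[LayerSpec], input_shape: tuple, seed: int = 0):
        self.specs = list(specs)
        self.input_shape = tuple(int(s) for s in input_shape)
        self.seed = int(seed)
        softmax_idx = [i for i, s in enumerate(self.specs) if s.activation == "softmax"]
        if softmax_idx and (
            len(softmax_idx) > 1
            or softmax_idx[0] != len(self.specs) - 1
            or self.specs[-1].kind != "dense"
        ):
            raise ValueError("softmax is only allowed on the terminal dense layer")
        rng = np.random.default_rng(seed)
        self.layers: list[_Layer] = []
        shape = self.input_shape
        for spec in self.specs:
            if spec.kind in ("conv2d", "maxpool2d") and len(shape) != 3:
                raise ValueError(f"{spec.kind} expects (H, W, C) input, got {shape}")
            if spec.kind == "dense" and len(shape) != 1:
                raise ValueError(f"dense expects flat input, got {shape}; insert a flatten layer")
            layer = _LAYER_BUILDERS[spec.kind](spec, shape, rng)
            self.layers.append(layer)
            shape = layer.out_shape
        self.output_shape = shape

    def __len__(self) -> int:
        return len(self.layers)

    def forward(self, x: np.ndarray, training: bool = False, upto: int | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=float)
        if out.shape[1:] != self.input_shape:
            raise ValueError(f"input shape {out.shape[1:]} != model input {self.input_shape}")
        stop = len(self.layers) if upto is None else upto + 1
        for layer in self.layers[:stop]:
            out = layer.forward(out, training=training)
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=1)

    def get_weights(self) -> list:
        return [np.copy(p) for layer in self.layers for p in layer.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError(f"expected {len(flat)} arrays, got {len(weights)}")
        for p, w in zip(flat, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w


def build_model(specs: Sequence[LayerSpec | dict], input_shape: tuple, seed: int = 0) -> SequentialModel:
    specs = [s if isinstance(s, LayerSpec) else LayerSpec.from_dict(s) for s in specs]
    return SequentialModel(specs, input_shape, seed=seed)


def count_parameters(model: SequentialModel) -> int:
    """Total number of trainable parameter elements."""
    return sum(layer.n_params for layer in model.layers)


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((y.shape[0], k))
    out[np.arange(y.shape[0]), y] = 1.0
    return out


def train(
    model: SequentialModel,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> list[dict]:
    """SGD with momentum on softmax cross-entropy; fully seeded.

    Returns a per-epoch history of mean loss and training error.  Zero
    epochs leave the weights untouched.
    """
    config = config or TrainConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if model.specs[-1].activation != "softmax":
        raise ValueError("training requires a terminal softmax dense layer")
    k = model.specs[-1].units
    rng = np.random.default_rng(config.seed)
    velocity = {
        id(layer): [np.zeros_like(p) for p in layer.params] for layer in model.layers
    }
    history = []
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, errors = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            probs = model.forward(xb, training=True)
            yh = _one_hot(yb, k)
            eps = 1e-12
            losses.append(float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))))
            errors.append(float(np.mean(probs.argmax(axis=1) != yb)))
            grad = (probs - yh) / len(yb)
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
                if layer.params and layer.trainable:
                    for p, g, v in zip(layer.params, layer.grads, velocity[id(layer)]):
                        v *= config.momentum
                        v -= config.learning_rate * g
                        p += v
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "train_error": float(np.mean(errors))}
        )
    return history


def evaluate(model: SequentialModel, x: np.ndarray, y: np.ndarray) -> float:
    """Misclassification fraction under the argmax decision rule."""
    y = np.asarray(y, dtype=np.int64)
    if y.size == 0:
        raise ValueError("empty test set")
    return float(np.mean(model.predict(np.asarray(x, dtype=float)) != y))


def stratified_sample(labels: np.ndarray, cap: int, seed: int = 0) -> np.ndarray:
    """At most ``cap`` indices, class proportions preserved, seeded, sorted."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    if cap >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    take = np.maximum(1, np.floor(counts / n * cap).astype(int))
    # distribute any remainder to the largest classes
    while take.sum() > cap:
        take[np.argmax(take)] -= 1
    while take.sum() < cap:
        room = counts - take
        take[np.argmax(room)] += 1
    picks = []
    for cls, t in zip(classes, take):
        idx = np.flatnonzero(labels == cls)
        picks.append(rng.choice(idx, size=min(t, idx.size), replace=False))
    return np.sort(np.concatenate(picks))


def save_model(model: SequentialModel, path) -> None:
    """Checkpoint: architecture (JSON), input shape, seed and weights in one NPZ."""
    import json

    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(
        path,
        arch=np.array(json.dumps([s.to_dict() for s in model.specs])),
        input_shape=np.array(model.input_shape, dtype=np.int64),
        seed=np.array(model.seed, dtype=np.int64),
        **arrays,
    )


def load_model(path) -> SequentialModel:
    import json

    with np.load(path, allow_pickle=False) as z:
        specs = [LayerSpec.from_dict(d) for d in json.loads(str(z["arch"]))]
        model = SequentialModel(specs, tuple(z["input_shape"].tolist()), seed=int(z["seed"]))
        n = sum(len(layer.params) for layer in model.layers)
        model.set_weights([z[f"w{i}"] for i in range(n)])
    return model


def layer_activations(
    model: SequentialModel,
    x: np.ndarray,
    y: np.ndarray,
    layer_index: int,
    sample_cap: int = 2000,
    seed: int = 0,
) -> LabeledDataset:
    """Flattened activations after ``layer_index`` as a labeled point set.

    The forward pass is truncated after the indexed layer; outputs are
    flattened to vectors and at most ``sample_cap`` stratified samples
    are kept (seeded).
    """
    if not 0 <= layer_index < len(model.layers):
        raise IndexError(f"layer_index {layer_index} out of range 0..{len(model.layers) - 1}")
    y = np.asarray(y)
    idx = stratified_sample(y, sample_cap, seed=seed)
    out = model.forward(np.asarray(x, dtype=float)[idx], upto=layer_index)
    return LabeledDataset(points=out.reshape(out.shape[0], -1), labels=y[idx])
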