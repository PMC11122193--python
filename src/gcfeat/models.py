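"""Declarative CNN architecture specs with analytic parameter counting.

The classification networks used downstream of the feature extraction are
small fixed-skeleton CNNs: three [conv 32 filters + ReLU + average pool]
blocks, flatten, two dense layers of 512 units, dropout 0.1, and a softmax
output. Only the kernel shapes differ between variants: the GCFE plane
(2 rows of radii/centers) uses 1x3 convolutions and 1x2 pools, while full
Laplacian inputs use 3x3 convolutions and 2x2 pools.

Nothing here needs a deep-learning framework: shapes are propagated
analytically (same-padding convolutions preserve spatial dims; pools use
stride equal to their kernel with valid padding, flooring odd dims) and
trainable parameters are counted in closed form,

    conv:  kh * kw * c_in * filters + filters
    dense: n_in * units + units

which is exact for biased layers. :func:`train_and_evaluate` is an
optional harness that requires torch at runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "ShapeError",
    "MissingBackendError",
    "build_gcfe_2d_spec",
    "build_laplacian_2d_spec",
    "count_parameters",
    "propagate_shapes",
    "split_sizes",
    "train_and_evaluate",
]

CONV_FILTERS = 32
DENSE_UNITS = 512
DROPOUT_RATE = 0.1


class ShapeError(ValueError):
    """Raised when shape propagation collapses a dimension to zero."""


class MissingBackendError(RuntimeError):
    """Raised when the optional training harness has no backend to run on."""


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | avgpool | flatten | dense | dropout | output
    kernel: tuple[int, int] | None = None
    filters: int | None = None
    units: int | None = None
    padding: str | None = None  # same | valid
    stride: tuple[int, int] | None = None
    activation: str = "none"
    dropout_rate: float | None = None


@dataclass(frozen=True)
class ModelSpec:
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int]  # (H, W, channels)
    n_classes: int

    @property
    def n_conv(self) -> int:
        return sum(1 for l in self.layers if l.kind == "conv")


def _skeleton(conv_kernel: tuple[int, int], pool_kernel: tuple[int, int],
              n_classes: int) -> tuple[LayerSpec, ...]:
    layers: list[LayerSpec] = []
    for _ in range(3):
        layers.append(LayerSpec("conv", kernel=conv_kernel, filters=CONV_FILTERS,
                                padding="same", stride=(1, 1), activation="relu"))
        layers.append(LayerSpec("avgpool", kernel=pool_kernel,
                                stride=pool_kernel, padding="valid"))
    layers.append(LayerSpec("flatten"))
    layers.append(LayerSpec("dense", units=DENSE_UNITS, activation="relu"))
    layers.append(LayerSpec("dense", units=DENSE_UNITS, activation="relu"))
    layers.append(LayerSpec("dropout", dropout_rate=DROPOUT_RATE))
    layers.append(LayerSpec("output", units=n_classes, activation="softmax"))
    return tuple(layers)


def build_gcfe_2d_spec(n_nodes_total: int, n_classes: int) -> ModelSpec:
    """2D-CNN over the GCFE feature plane (2, P*N, 1).

    Kernels are 1x3 (conv) and 1x2 (pool) so only the width shrinks;
    three halvings require ``n_nodes_total`` >= 8.
    """
    if n_nodes_total < 8:
        raise ShapeError(f"need n_nodes_total >= 8 for three pools, got {n_nodes_total}")
    spec = ModelSpec(_skeleton((1, 3), (1, 2), n_classes),
                     input_shape=(2, n_nodes_total, 1), n_classes=n_classes)
    propagate_shapes(spec)  # validates
    return spec


def build_laplacian_2d_spec(P: int, N: int, n_classes: int) -> ModelSpec:
    """2D-CNN over vertically stacked per-patch Laplacians, input (P*N, N, 1).

    Standard 3x3 convolutions and 2x2 pools; odd dims floor on pooling.
    """
    spec = ModelSpec(_skeleton((3, 3), (2, 2), n_classes),
                     input_shape=(P * N, N, 1), n_classes=n_classes)
    propagate_shapes(spec)
    return spec


def propagate_shapes(m: ModelSpec) -> list[tuple[int, ...]]:
    """Output shape after every layer; raises ShapeError on collapse."""
    h, w, c = m.input_shape
    shapes: list[tuple[int, ...]] = []
    flat: int | None = None
    for layer in m.layers:
        if layer.kind == "conv":
            if layer.padding != "same":
                raise NotImplementedError("only same-padding convolutions")
            c = layer.filters
        elif layer.kind == "avgpool":
            kh, kw = layer.kernel
            sh, sw = layer.stride
            h = (h - kh) // sh + 1
            w = (w - kw) // sw + 1
            if h <= 0 or w <= 0:
                raise ShapeError(f"pooling collapsed spatial dims to {h}x{w}")
        elif layer.kind == "flatten":
            flat = h * w * c
        elif layer.kind in ("dense", "output"):
            if flat is None:
                raise ShapeError("dense layer before flatten")
            flat = layer.units
        elif layer.kind == "dropout":
            pass
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
        shapes.append((flat,) if flat is not None else (h, w, c))
    return shapes


def count_parameters(m: ModelSpec) -> int:
    """Exact trainable parameter count of a spec (weights + biases)."""
    h, w, c = m.input_shape
    total = 0
    flat: int | None = None
    for layer in m.layers:
        if layer.kind == "conv":
            kh, kw = layer.kernel
            total += kh * kw * c * layer.filters + layer.filters
            c = layer.filters
        elif layer.kind == "avgpool":
            kh, kw = layer.kernel
            sh, sw = layer.stride
            h = (h - kh) // sh + 1
            w = (w - kw) // sw + 1
        elif layer.kind == "flatten":
            flat = h * w * c
        elif layer.kind in ("dense", "output"):
            total += flat * layer.units + layer.units
            flat = layer.units
        # dropout: no parameters
    return total


def split_sizes(n: int, ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
                ) -> tuple[int, int, int]:
    """Train/validation/test sample counts; test absorbs the remainder."""
    n_train = int(round(n * ratios[0]))
    n_val = int(round(n * ratios[1]))
    return n_train, n_val, n - n_train - n_val


def train_and_evaluate(m: ModelSpec, features, labels, epochs: int = 10,
                       split: tuple[float, float, float] = (0.7, 0.15, 0.15),
                       seed: int = 0) -> dict:
    """Train the spec'd CNN and report accuracy/F1/recall/precision.

    Optional harness: requires torch at runtime; the core package and all
    analytic operations work without any deep-learning framework.
    """
    try:
        import torch
    except ImportError as exc:  # pragma: no cover - backend present
        raise MissingBackendError(
            "train_and_evaluate requires torch; install it or use the "
            "analytic operations (count_parameters, propagate_shapes) "
            "which need no backend"
        ) from exc
    return _train_torch(torch, m, features, labels, epochs, split, seed)


def _train_torch(torch, m: ModelSpec, features, labels, epochs, split, seed):
    # Exercised only when torch is installed.
    import numpy as np
    from torch import nn

    torch.manual_seed(seed)
    rng = np.random.default_rng(seed)
    X = np.asarray(features, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    order = rng.permutation(len(X))
    X, y = X[order], y[order]
    n_train, n_val, _ = split_sizes(len(X), split)

    mods: list[nn.Module] = []
    c = m.input_shape[2]
    for layer in m.layers:
        if layer.kind == "conv":
            mods += [nn.Conv2d(c, layer.filters, layer.kernel, padding="same"),
                     nn.ReLU()]
            c = layer.filters
        elif layer.kind == "avgpool":
            mods.append(nn.AvgPool2d(layer.kernel, stride=layer.stride))
        elif layer.kind == "flatten":
            mods.append(nn.Flatten())
        elif layer.kind == "dense":
            mods += [nn.LazyLinear(layer.units), nn.ReLU()]
        elif layer.kind == "dropout":
            mods.append(nn.Dropout(layer.dropout_rate))
        elif layer.kind == "output":
            mods.append(nn.LazyLinear(layer.units))
    net = nn.Sequential(*mods)

    Xt = torch.from_numpy(X).reshape(len(X), m.input_shape[2],
                                     m.input_shape[0], m.input_shape[1])
    yt = torch.from_numpy(y)
    opt = torch.optim.Adam(net.parameters())
    loss_fn = nn.CrossEntropyLoss()
    net.train()
    for _ in range(epochs):
        opt.zero_grad()
        loss = loss_fn(net(Xt[:n_train]), yt[:n_train])
        loss.backward()
        opt.step()

    net.eval()
    with torch.no_grad():
        pred = net(Xt[n_train + n_val:]).argmax(1).numpy()
    truth = y[n_train + n_val:]
    from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                                 recall_score)
    avg = "macro"
    return {
        "accuracy": accuracy_score(truth, pred),
        "f1": f1_score(truth, pred, average=avg, zero_division=0),
        "recall": recall_score(truth, pred, average=avg, zero_division=0),
        "precision": precision_score(truth, pred, average=avg, zero_division=0),
    }
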