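"""The slice CNN: a VGG-style stack of convolutional blocks.

Each block is ``n_conv_layers x (conv -> batch norm -> PReLU)`` followed
by 2x2 max pooling; the flattened features (with the scalar 4-D label
concatenated) feed dense layers and an 8-way softmax.  The default
configuration uses blocks (32,2)(64,2)(128,2)(256,2) with 3x3 kernels and
one 512-wide hidden dense layer; the reduced configuration used for
desk-scale training works at 64x64 via average-pool input downsampling.

Model artifacts are a ``.npz`` of parameters plus a JSON sidecar carrying
the configuration and the frozen class order, so a loaded model can never
silently permute labels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ..labels import CLASS_LABELS, N_CLASSES
from ..types import SliceSample
from .layers import (AvgPoolDown, BatchNorm, ConcatScalar, Conv2D, Dense,
                     Flatten, Layer, MaxPool2D, PReLU, softmax)

ARTIFACT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture description of the slice CNN."""

    conv_blocks: list[tuple[int, int]] = field(
        default_factory=lambda: [(32, 2), (64, 2), (128, 2), (256, 2)])
    kernel_size: int = 3
    pool_size: int = 2
    dense_widths: list[int] = field(default_factory=lambda: [512])
    n_classes: int = N_CLASSES
    input_size: int = 256
    input_downsample: int = 1
    four_d_injection_point: str = "pre_dense"

    def __post_init__(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("at least one convolutional block is required")
        if any(f < 1 or l < 1 for f, l in self.conv_blocks):
            raise ValueError("conv block filters and layer counts must be positive")
        if self.n_classes != N_CLASSES:
            raise ValueError(f"the classifier is {N_CLASSES}-way; n_classes must be {N_CLASSES}")
        if self.four_d_injection_point not in ("pre_dense", "pre_output"):
            raise ValueError("four_d_injection_point must be 'pre_dense' or 'pre_output'")
        size = self.input_size // self.input_downsample
        if self.input_size % self.input_downsample:
            raise ValueError("input_downsample must divide input_size")
        for _ in self.conv_blocks:
            if size % self.pool_size:
                raise ValueError(
                    f"pooling does not divide intermediate size {size}; "
                    "adjust input_size/downsample or the number of blocks")
            size //= self.pool_size
        if size < 1:
            raise ValueError("too many pooling stages for the input size")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_blocks"] = [list(b) for b in self.conv_blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_blocks"] = [tuple(b) for b in d["conv_blocks"]]
        return cls(**d)


def reduced_config() -> ModelConfig:
    """Desk-scale configuration: 64x64 working resolution, two small blocks."""
    return ModelConfig(conv_blocks=[(8, 1), (16, 1)], dense_widths=[32],
                       input_downsample=4)


class SliceCNN:
    """The 8-class slice classifier.

    ``forward`` takes a batch of shape ``(N, 1, H, W)`` plus the per-sample
    4-D labels and returns logits; ``predict_proba`` applies the softmax.
    """

    def __init__(self, config: Optional[ModelConfig] = None, seed: int = 0) -> None:
        self.config = config or ModelConfig()
        self.class_labels = CLASS_LABELS
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        cfg = self.config

        layers: list[Layer] = []
        self.input_pool = AvgPoolDown(cfg.input_downsample)
        layers.append(self.input_pool)
        in_c = 1
        size = cfg.input_size // cfg.input_downsample
        for filters, n_conv in cfg.conv_blocks:
            for _ in range(n_conv):
                layers.append(Conv2D(in_c, filters, cfg.kernel_size, rng))
                layers.append(BatchNorm(filters))
                layers.append(PReLU(filters))
                in_c = filters
            layers.append(MaxPool2D(cfg.pool_size))
            size //= cfg.pool_size
        layers.append(Flatten())
        n_features = in_c * size * size

        self.concat = ConcatScalar()
        if cfg.four_d_injection_point == "pre_dense":
            layers.append(self.concat)
            n_features += 1
        for width in cfg.dense_widths:
            layers.append(Dense(n_features, width, rng))
            layers.append(PReLU(width))
            n_features = width
        if cfg.four_d_injection_point == "pre_output":
            layers.append(self.concat)
            n_features += 1
        layers.append(Dense(n_features, cfg.n_classes, rng))
        self.layers = layers
        for layer in layers:
            if isinstance(layer, Conv2D):
                layer.skip_input_grad = True  # no layer below it learns
                break

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, four_d: np.ndarray,
                training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected input of shape (N, 1, H, W), got {x.shape}")
        expected = self.config.input_size
        if x.shape[2] != expected or x.shape[3] != expected:
            raise ValueError(
                f"expected {expected}x{expected} slices, got {x.shape[2]}x{x.shape[3]}")
        self.concat.scalar = np.asarray(four_d, dtype=np.float32)
        out = x
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out

    def pool_input(self, x: np.ndarray) -> np.ndarray:
        """Apply the input downsampling stage alone.

        The trainer pools the whole sample matrix once up front instead of
        once per epoch; combined with :meth:`forward_pooled` this is exactly
        equivalent to :meth:`forward` (the pool has no parameters).
        """
        return self.input_pool.forward(np.asarray(x, dtype=np.float32))

    def forward_pooled(self, x_pooled: np.ndarray, four_d: np.ndarray,
                       training: bool = False) -> np.ndarray:
        self.concat.scalar = np.asarray(four_d, dtype=np.float32)
        out = np.asarray(x_pooled, dtype=np.float32)
        for layer in self.layers[1:]:
            out = layer.forward(out, training=training)
        return out

    def backward_pooled(self, grad_logits: np.ndarray) -> np.ndarray:
        g = grad_logits
        for layer in reversed(self.layers[1:]):
            g = layer.backward(g)
        return g

    def backward(self, grad_logits: np.ndarray, guided: bool = False) -> np.ndarray:
        g = grad_logits
        for layer in reversed(self.layers):
            g = layer.backward(g, guided=guided)
        return g

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, x: np.ndarray, four_d: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, four_d, training=False))

    def predict_slice(self, sample: SliceSample) -> np.ndarray:
        """8-class probabilities for one preprocessed slice."""
        x = sample.pixels[np.newaxis, np.newaxis, :, :]
        return self.predict_proba(x, np.array([sample.four_d_label]))[0]

    def predict_scan_probs(self, samples: Sequence[SliceSample]) -> np.ndarray:
        """Per-slice probabilities (n_slices x 8) for one scan's samples."""
        x = np.stack([s.pixels for s in samples])[:, np.newaxis, :, :]
        four_d = np.array([s.four_d_label for s in samples], dtype=np.float32)
        return self.predict_proba(x, four_d)

    # -- parameter access ---------------------------------------------------

    def parameter_items(self) -> list[tuple[str, Layer, str]]:
        items = []
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                items.append((f"layer{i:02d}.{type(layer).__name__}.{name}", layer, name))
        return items

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {key: layer.params[name] for key, layer, name in self.parameter_items()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"layer{i:02d}.BatchNorm.running_mean"] = layer.running_mean
                state[f"layer{i:02d}.BatchNorm.running_var"] = layer.running_var
        return state

    # -- persistence --------------------------------------------------------

    def save(self, path: Path | str) -> Path:
        """Write ``<path>`` (npz weights) and ``<path>.json`` (config sidecar)."""
        path = Path(path)
        np.savez(path, **self.state_arrays())
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = {
            "version": ARTIFACT_VERSION,
            "class_labels": list(self.class_labels),
            "model_config": self.config.to_dict(),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def load(cls, path: Path | str) -> "SliceCNN":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if tuple(sidecar["class_labels"]) != CLASS_LABELS:
            raise ValueError(
                "model artifact class order does not match this package's frozen order")
        model = cls(ModelConfig.from_dict(sidecar["model_config"]),
                    seed=sidecar.get("seed", 0))
        with np.load(path) as z:
            stored = dict(z)
        for key, layer, name in model.parameter_items():
            layer.params[name] = stored[key].copy()
        for i, layer in enumerate(model.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = stored[f"layer{i:02d}.BatchNorm.running_mean"].copy()
                layer.running_var = stored[f"layer{i:02d}.BatchNorm.running_var"].copy()
        return model
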