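"""Guided-backpropagation saliency maps.

The map is the gradient of the target class's score (pre-softmax logit)
with respect to the input pixels, computed with guided backpropagation —
negative gradients are zeroed at every rectifier on the backward pass —
and finally rectified pointwise, so the result is non-negative and
highlights only pixels whose increase would raise the class score.
"""

from __future__ import annotations

import numpy as np

from ..types import SliceSample
from .model import SliceCNN


def saliency_map(model: SliceCNN, sample: SliceSample, target_class: int) -> np.ndarray:
    """Guided-backprop saliency of ``target_class`` for one slice.

    Returns a non-negative map with the same shape as the input pixels.
    """
    n_classes = model.config.n_classes
    if not (0 <= int(target_class) < n_classes):
        raise ValueError(f"target_class must be in [0, {n_classes}), got {target_class}")
    x = sample.pixels[np.newaxis, np.newaxis, :, :].astype(np.float32)
    logits = model.forward(x, np.array([sample.four_d_label], dtype=np.float32),
                           training=False)
    grad = np.zeros_like(logits)
    grad[0, int(target_class)] = 1.0
    gx = model.backward(grad, guided=True)
    out = np.maximum(gx[0, 0], 0.0)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("saliency map contains non-finite values")
    return out.astype(np.float32)
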