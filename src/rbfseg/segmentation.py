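"""Whole-image classification and RGB rendering.

Every pixel of the input image is mapped to feature space with the scaling
constants stored at training time, pushed through the network, and assigned
the class with the largest raw output score (ties to the lowest class
index).  The class map is rendered by a palette lookup; the default palette
paints the background class white and spreads the remaining classes over
maximally separated hues.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import RBFNetwork
from .exceptions import InputError, ModelError, RenderError
from .features import FeatureScaling, image_features

__all__ = [
    "SegmentationResult",
    "default_palette",
    "classify_image",
    "render_rgb",
    "invert_palette",
    "segment",
]


@dataclass
class SegmentationResult:
    label_image: np.ndarray                  # (rows, cols) int class indices
    rgb_image: np.ndarray                    # (rows, cols, 3) uint8
    class_counts: dict[int, int]             # class index -> pixel total
    palette: dict[int, tuple[int, int, int]]

    def counts_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            sorted(self.class_counts.items()), columns=["class", "pixels"]
        ).to_csv(path, index=False)


def default_palette(n_classes: int) -> dict[int, tuple[int, int, int]]:
    """Class 0 (background) is white; classes 1..n-1 get evenly spaced hues."""
    palette = {0: (255, 255, 255)}
    k = n_classes - 1
    for j in range(1, n_classes):
        r, g, b = colorsys.hsv_to_rgb((j - 1) / max(k, 1), 1.0, 1.0)
        palette[j] = (round(r * 255), round(g * 255), round(b * 255))
    return palette


def classify_image(
    image: np.ndarray,
    network: RBFNetwork,
    scaling: FeatureScaling | None = None,
) -> np.ndarray:
    """Per-pixel class-index image by argmax of the raw network outputs.

    ``scaling`` defaults to the constants stored in the network at training
    time; passing training-image constants is what makes inference features
    commensurable with the centers.
    """
    image = np.asarray(image, dtype=float)
    scaling = scaling if scaling is not None else network.scaling
    if scaling is None:
        raise ModelError("no feature scaling available; train first or pass one")
    X, _ = image_features(image, scaling)
    if X.shape[1] != network.feature_dim:
        raise ModelError(
            f"network expects {network.feature_dim}-dimensional features, "
            f"got {X.shape[1]}"
        )
    raw = network.activations(X) @ network.weights
    return raw.argmax(axis=1).reshape(image.shape)


def render_rgb(
    label_image: np.ndarray, palette: dict[int, tuple[int, int, int]]
) -> np.ndarray:
    """Pixel-wise palette lookup; every class present must have an entry."""
    label_image = np.asarray(label_image)
    present = np.unique(label_image)
    missing = [int(v) for v in present if int(v) not in palette]
    if missing:
        raise RenderError(f"palette has no entry for classes {missing}")
    lut = np.zeros((int(present.max()) + 1, 3), dtype=np.uint8)
    for v in present:
        lut[int(v)] = palette[int(v)]
    return lut[label_image]


def invert_palette(
    rgb_image: np.ndarray, palette: dict[int, tuple[int, int, int]]
) -> np.ndarray:
    """Recover the class-index image from a palette render (palette must be
    injective on the classes present)."""
    rgb_image = np.asarray(rgb_image)
    out = np.full(rgb_image.shape[:2], -1, dtype=int)
    for cls, color in palette.items():
        mask = np.all(rgb_image == np.asarray(color, dtype=rgb_image.dtype), axis=-1)
        out[mask] = cls
    if (out < 0).any():
        raise RenderError("some pixels match no palette color")
    return out


def segment(
    image: np.ndarray,
    network: RBFNetwork,
    scaling: FeatureScaling | None = None,
) -> SegmentationResult:
    """Classify every pixel and render the class map."""
    labels = classify_image(image, network, scaling)
    palette = network.palette or default_palette(network.n_classes)
    rgb = render_rgb(labels, palette)
    counts = {
        int(v): int(c) for v, c in zip(*np.unique(labels, return_counts=True))
    }
    return SegmentationResult(
        label_image=labels, rgb_image=rgb, class_counts=counts, palette=palette
    )
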