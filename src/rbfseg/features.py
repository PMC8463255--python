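"""Per-pixel feature extraction and train/test pixel sampling.

Each pixel of a 2-D grayscale image is described by a four-component local
feature vector ``(x, y, f, |grad f|)``:

* ``x`` — column coordinate, normalized to [0, 1] by ``(cols - 1)``;
* ``y`` — row coordinate, normalized to [0, 1] by ``(rows - 1)``;
* ``f`` — intensity, min–max scaled to [0, 1] over the whole image;
* ``|grad f|`` — gradient magnitude from central differences (edge-replicated
  borders), scaled to [0, 1] by the image-wide maximum.

The scaling constants are recorded in a :class:`FeatureScaling` so the exact
same mapping can be re-applied at inference time.  Class labels, when
present, travel alongside the features as one-hot target rows; they never
enter the feature columns, so clustering and classification distances are
computed on the four continuous components only (at inference the labels are
unknown, so a distance that depended on them would be ill-defined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, SamplingError

__all__ = [
    "FeatureScaling",
    "PixelSample",
    "gradient_magnitude",
    "extract_features",
    "image_features",
    "sample_pixels",
]


@dataclass(frozen=True)
class FeatureScaling:
    """Constants that map a pixel of a given image to feature space.

    Re-applying a stored scaling to the image it was computed from
    reproduces the training features bit-exactly.
    """

    shape: tuple[int, int]          # (rows, cols) of the training image
    f_min: float                    # intensity minimum
    f_max: float                    # intensity maximum
    grad_max: float                 # image-wide max gradient magnitude

    def to_dict(self) -> dict:
        return {
            "shape": [int(self.shape[0]), int(self.shape[1])],
            "f_min": float(self.f_min),
            "f_max": float(self.f_max),
            "grad_max": float(self.grad_max),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaling":
        return cls(
            shape=(int(d["shape"][0]), int(d["shape"][1])),
            f_min=float(d["f_min"]),
            f_max=float(d["f_max"]),
            grad_max=float(d["grad_max"]),
        )

    @classmethod
    def from_image(cls, image: np.ndarray) -> "FeatureScaling":
        image = _check_image(image)
        grad = gradient_magnitude(image)
        return cls(
            shape=(image.shape[0], image.shape[1]),
            f_min=float(image.min()),
            f_max=float(image.max()),
            grad_max=float(grad.max()),
        )


@dataclass
class PixelSample:
    """A set of pixels with their features and (for training) one-hot targets.

    ``class_values[j]`` is the label-image value that one-hot column ``j``
    stands for; predictions indexed 0..n-1 map back through it.
    """

    coords: np.ndarray                      # (E, 2) int array of (row, col)
    features: np.ndarray | None = None      # (E, 4) float array
    targets: np.ndarray | None = None       # (E, n) one-hot rows
    class_values: np.ndarray | None = None  # (n,) original label values
    scaling: FeatureScaling | None = None

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def coord_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.coords}


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] < 2 or image.shape[1] < 2:
        raise InputError(
            f"expected a 2-D image with at least 2 rows and columns, "
            f"got shape {image.shape}"
        )
    return image


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude with edge-replicated borders.

    Interior: ``gx = (f[r, c+1] - f[r, c-1]) / 2`` and likewise for rows;
    at the borders the missing neighbor is replicated, which halves the
    one-sided difference there.
    """
    image = _check_image(image)
    padded = np.pad(image, 1, mode="edge")
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return np.hypot(gx, gy)


def _feature_planes(image: np.ndarray, scaling: FeatureScaling) -> np.ndarray:
    """(rows, cols, 4) array of per-pixel features under ``scaling``."""
    rows, cols = image.shape
    y = np.repeat(np.arange(rows, dtype=float)[:, None], cols, axis=1)
    x = np.repeat(np.arange(cols, dtype=float)[None, :], rows, axis=0)
    x /= max(cols - 1, 1)
    y /= max(rows - 1, 1)
    span = scaling.f_max - scaling.f_min
    f = (image - scaling.f_min) / span if span > 0 else np.zeros_like(image)
    grad = gradient_magnitude(image)
    grad = grad / scaling.grad_max if scaling.grad_max > 0 else np.zeros_like(grad)
    return np.stack([x, y, f, grad], axis=-1)


def extract_features(
    image: np.ndarray,
    coords: np.ndarray,
    scaling: FeatureScaling | None = None,
) -> tuple[np.ndarray, FeatureScaling]:
    """Feature matrix for the given pixel coordinates.

    Parameters
    ----------
    image
        2-D grayscale array.
    coords
        Sequence of (row, col) pairs; 0-based, in bounds.
    scaling
        Constants from a previous (training) extraction.  When omitted they
        are computed from ``image`` and returned for reuse.

    Returns
    -------
    features : (E, 4) array with columns (x, y, f, |grad f|), each in [0, 1]
        when ``scaling`` comes from this image.
    scaling : the constants used.
    """
    image = _check_image(image)
    coords = np.asarray(coords, dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InputError(f"coords must be (E, 2) pairs, got shape {coords.shape}")
    rows, cols = image.shape
    if coords.size and (
        coords.min() < 0
        or coords[:, 0].max() >= rows
        or coords[:, 1].max() >= cols
    ):
        raise InputError("coordinate out of image bounds")
    if scaling is None:
        scaling = FeatureScaling.from_image(image)
    planes = _feature_planes(image, scaling)
    return planes[coords[:, 0], coords[:, 1]], scaling


def image_features(
    image: np.ndarray, scaling: FeatureScaling | None = None
) -> tuple[np.ndarray, FeatureScaling]:
    """Features for every pixel, as an ``(rows*cols, 4)`` matrix in raster order."""
    image = _check_image(image)
    if scaling is None:
        scaling = FeatureScaling.from_image(image)
    planes = _feature_planes(image, scaling)
    return planes.reshape(-1, 4), scaling


def sample_pixels(
    labels: np.ndarray,
    per_class: int,
    seed: int | np.random.Generator,
    exclude: set[tuple[int, int]] | None = None,
    image: np.ndarray | None = None,
    scaling: FeatureScaling | None = None,
) -> PixelSample:
    """Seeded per-class pixel sampling without replacement.

    Draws ``per_class`` coordinates from each class present in ``labels``,
    disjoint from ``exclude`` (e.g. a previously drawn training set), and
    builds one-hot targets over the sorted distinct label values.  When
    ``image`` is given the feature matrix is filled in as well.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise InputError(f"label image must be 2-D, got shape {labels.shape}")
    if per_class < 1:
        raise InputError("per_class must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    exclude = exclude or set()

    class_values = np.unique(labels)
    n = len(class_values)
    coords_out: list[np.ndarray] = []
    targets_out: list[np.ndarray] = []
    for j, value in enumerate(class_values):
        rr, cc = np.nonzero(labels == value)
        pool = [
            (int(r), int(c))
            for r, c in zip(rr, cc)
            if (int(r), int(c)) not in exclude
        ]
        if len(pool) < per_class:
            raise SamplingError(
                f"class {value!r} has only {len(pool)} eligible pixels, "
                f"need {per_class}"
            )
        pick = rng.choice(len(pool), size=per_class, replace=False)
        coords_out.append(np.asarray([pool[i] for i in pick], dtype=int))
        onehot = np.zeros((per_class, n))
        onehot[:, j] = 1.0
        targets_out.append(onehot)

    coords = np.concatenate(coords_out, axis=0)
    targets = np.concatenate(targets_out, axis=0)
    features = None
    if image is not None:
        features, scaling = extract_features(image, coords, scaling)
    return PixelSample(
        coords=coords,
        features=features,
        targets=targets,
        class_values=class_values,
        scaling=scaling,
    )
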