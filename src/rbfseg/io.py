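"""Image reading and writing.

Grayscale images come in as PNG/TIFF (8- or 16-bit integer) or single-slice
NIfTI and are returned as float arrays in [0, 1]; integer rasters are
rescaled by their bit depth.  Label images are integer PNG/TIFF rasters and
are passed through unscaled.  Phantom images are written as 16-bit PNG so a
save/load/save cycle is stable.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import FormatError

__all__ = [
    "load_image",
    "save_image",
    "load_labels",
    "save_labels",
    "save_rgb",
]

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}
_NIFTI_SUFFIXES = {".nii", ".nii.gz"}


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _load_nifti(path: Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    squeezed = np.squeeze(data)
    if squeezed.ndim != 2:
        raise FormatError(
            f"{path.name}: expected a single-slice NIfTI, got shape {data.shape}; "
            "extract a 2-D slice explicitly"
        )
    data = np.asarray(squeezed, dtype=float)
    if data.size and (data.min() < 0 or data.max() > 1):
        span = data.max() - data.min()
        data = (data - data.min()) / span if span > 0 else np.zeros_like(data)
    return data


def load_image(path: str | Path) -> np.ndarray:
    """Read a 2-D grayscale image as floats in [0, 1].

    8-bit rasters divide by 255, 16-bit by 65535.  NIfTI data already in
    [0, 1] pass through; otherwise they are min-max rescaled.  Color or
    multi-slice inputs raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        return _load_nifti(path)
    if suffix not in _RASTER_SUFFIXES:
        raise FormatError(f"unsupported image format {suffix!r}")
    data = iio.imread(path)
    if data.ndim != 2:
        raise FormatError(
            f"{path.name}: expected a 2-D grayscale raster, got shape {data.shape}"
        )
    if data.dtype == np.uint8:
        return data.astype(float) / 255.0
    if data.dtype == np.uint16:
        return data.astype(float) / 65535.0
    raise FormatError(
        f"{path.name}: unsupported bit depth {data.dtype}; use 8- or 16-bit"
    )


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit PNG/TIFF."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FormatError(f"expected a 2-D image, got shape {image.shape}")
    if image.size and (image.min() < 0 or image.max() > 1):
        raise FormatError("image values must lie in [0, 1]")
    if _suffix(path) not in _RASTER_SUFFIXES:
        raise FormatError(f"unsupported output format {path.suffix!r}")
    iio.imwrite(path, np.round(image * 65535.0).astype(np.uint16))


def load_labels(path: str | Path) -> np.ndarray:
    """Read an integer label raster unscaled."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _suffix(path) not in _RASTER_SUFFIXES:
        raise FormatError(f"unsupported label format {path.suffix!r}")
    data = iio.imread(path)
    if data.ndim != 2:
        raise FormatError(f"label image must be 2-D, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"label image must be integer, got {data.dtype}")
    return data.astype(int)


def save_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write an integer label image as 8-bit PNG/TIFF (class indices < 256)."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise FormatError(f"label image must be 2-D, got shape {labels.shape}")
    if labels.min() < 0 or labels.max() > 255:
        raise FormatError("label values must fit in uint8")
    iio.imwrite(path, labels.astype(np.uint8))


def save_rgb(path: str | Path, rgb: np.ndarray) -> None:
    """Write an (rows, cols, 3) uint8 RGB render."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"expected (rows, cols, 3) RGB, got shape {rgb.shape}")
    iio.imwrite(Path(path), rgb.astype(np.uint8))
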