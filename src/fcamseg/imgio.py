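"""Image and label-map I/O (PNG/TIFF images, PNG-16/CSV label maps)."""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError

log = logging.getLogger("fcamseg")


def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB raster; alpha is dropped with a warning."""
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path}: expected 8-bit samples, got dtype {arr.dtype}"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:
        log.warning("%s: dropping alpha channel", path)
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path}: expected a 3-channel RGB image, got shape {arr.shape}"
        )
    return arr


def write_image(image: np.ndarray, path) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_labels(labels: np.ndarray, path) -> None:
    """Write an integer label map as 16-bit PNG or headerless CSV."""
    labels = np.asarray(labels)
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, labels, fmt="%d", delimiter=",")
        return
    if labels.min() < 0 or labels.max() > 65535:
        raise FormatError("labels outside [0, 65535] cannot be stored as PNG-16")
    iio.imwrite(path, labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    """Read a label map written by ``write_labels`` (round-trip exact)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel label map")
    return arr.astype(np.int64)


def write_boundary_overlay(image: np.ndarray, labels: np.ndarray, path) -> None:
    """Write the image with superpixel/class boundaries marked, for
    visual inspection."""
    from skimage.segmentation import mark_boundaries

    over = mark_boundaries(image, np.asarray(labels), color=(1, 1, 0), mode="thick")
    iio.imwrite(path, (over * 255).astype(np.uint8))
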