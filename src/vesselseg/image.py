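"""Fundus image handling: green-channel extraction, FOV masks, I/O.

The working representation of a fundus photograph is :class:`IntensityImage`:
the green channel kept on the native 8-bit 0-255 scale (the line-search
threshold ``S`` is expressed in these units) together with a boolean
field-of-view (FOV) mask.  All pixel coordinates in this package are
row-major, 0-based ``(row, col)`` with the row axis increasing downward.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage


@dataclass
class IntensityImage:
    """Green-channel intensities plus the FOV mask.

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Intensities on the 0-255 scale.
    fov : ndarray of bool, shape (H, W)
        Field-of-view mask; metrics and features are restricted to it.
    """

    pixels: np.ndarray
    fov: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.fov is None:
            self.fov = np.ones(self.pixels.shape, dtype=bool)
        self.fov = np.asarray(self.fov, dtype=bool)
        if self.fov.shape != self.pixels.shape:
            raise ValueError(
                f"fov shape {self.fov.shape} != pixels shape {self.pixels.shape}"
            )
        if not self.fov.any():
            raise ValueError("FOV mask is empty")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel intensities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_fov(self, fov: np.ndarray) -> "IntensityImage":
        """Return a copy of this image with a replacement FOV mask."""
        return IntensityImage(self.pixels.copy(), np.asarray(fov, dtype=bool))


def extract_green(rgb_image: np.ndarray) -> IntensityImage:
    """Extract the green channel of an RGB fundus image.

    The green channel has the highest vessel/background contrast of the
    three and is the single channel the whole pipeline operates on.  The
    FOV defaults to all-true until a mask is loaded or estimated.
    """
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise ValueError(
            f"expected a 3-channel RGB image, got shape {rgb_image.shape}"
        )
    return IntensityImage(rgb_image[:, :, 1].astype(np.float64))


def load_fov_mask(path_or_image, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Load a binary FOV mask; nonzero pixels become True.

    ``shape``, when given, is validated against the mask (it must match the
    fundus image the mask belongs to).
    """
    if isinstance(path_or_image, (str, os.PathLike)):
        arr = iio.imread(path_or_image)
    else:
        arr = np.asarray(path_or_image)
    if arr.ndim == 3:  # collapse RGB(A) masks
        arr = arr[:, :, 0]
    mask = arr != 0
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match image shape {tuple(shape)}")
    return mask


_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def estimate_fov_mask(rgb_image: np.ndarray, threshold: float = 35.0) -> np.ndarray:
    """Estimate the circular FOV from the red channel.

    Some fundus databases ship no FOV masks; the aperture is however much
    brighter than the surrounding black border in the red channel, so the
    mask is recovered as the largest 4-connected component of
    ``red > threshold`` with interior holes filled.
    """
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    bright = rgb_image[:, :, 0].astype(np.float64) > threshold
    if not bright.any():
        raise ValueError(f"no pixels exceed red-channel threshold {threshold}")
    labels, n = ndimage.label(bright, structure=_STRUCT4)
    sizes = ndimage.sum_labels(bright, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def read_image(path) -> np.ndarray:
    """Read an image file (PNG/TIFF/PPM/GIF) into an array."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def write_segmentation(path, binary: np.ndarray) -> None:
    """Write a binary vessel map as an 8-bit PNG (0 background, 255 vessel)."""
    out = np.where(np.asarray(binary, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(path, out)


def load_drive_layout(root) -> list[dict]:
    """Enumerate a DRIVE-style directory (images/, mask/, 1st_manual/).

    Returns a list of records with ``image``/``fov``/``truth`` paths matched
    on the leading numeric image id; ground truth or mask entries may be
    missing for test-only layouts.
    """
    root = os.fspath(root)
    images = _index_by_id(os.path.join(root, "images"))
    masks = _index_by_id(os.path.join(root, "mask"))
    truths = _index_by_id(os.path.join(root, "1st_manual"))
    return [
        {"id": k, "image": v, "fov": masks.get(k), "truth": truths.get(k)}
        for k, v in sorted(images.items())
    ]


def load_stare_layout(image_dir, truth_dir=None) -> list[dict]:
    """Enumerate a STARE-style layout: a directory of images and, optionally,
    a directory of ground-truth maps matched by the ``imNNNN`` stem.

    STARE ships no FOV masks; pair with :func:`estimate_fov_mask`.
    """
    images = _index_by_id(image_dir)
    truths = _index_by_id(truth_dir) if truth_dir else {}
    return [
        {"id": k, "image": v, "fov": None, "truth": truths.get(k)}
        for k, v in sorted(images.items())
    ]


def _index_by_id(directory) -> dict[str, str]:
    if directory is None or not os.path.isdir(directory):
        return {}
    out: dict[str, str] = {}
    for name in sorted(os.listdir(directory)):
        stem = name.split(".")[0]
        if stem[:1].isdigit():  # DRIVE-style "21_training", "21_manual1"
            key = stem[: next(i for i, ch in enumerate(stem + "x") if not ch.isdigit())]
        else:  # STARE-style "im0001.ah"
            digits = "".join(c for c in stem if c.isdigit())
            key = digits if digits else stem
        out.setdefault(key, os.path.join(directory, name))
    return out
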