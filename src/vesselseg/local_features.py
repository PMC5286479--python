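"""Multiscale local mean intensity and morphological-gradient features.

Vessels are darker than the retinal background, so the mean intensity of a
square window around a pixel separates vessel from background at the window
scale; six window sizes (3, 5, 11, 21, 31, 41) cover the range of vessel
widths.  The morphological gradient (grayscale dilation minus erosion with a
disk) highlights edges; averaging it over disk radii 1..6 responds to
vessels of every width:

    F_grad = (1/6) * sum_{i=1..6} (I (+) d_i - I (-) d_i)

with d_i the discrete disk {(dr, dc) : dr^2 + dc^2 <= i^2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import IntensityImage


@dataclass(frozen=True)
class IntensityFeatureConfig:
    window_sizes: tuple[int, ...] = (3, 5, 11, 21, 31, 41)

    def __post_init__(self) -> None:
        if any(w < 1 or w % 2 == 0 for w in self.window_sizes):
            raise ValueError("window sizes must be odd and >= 1")


@dataclass
class GradientImage:
    """Per-pixel averaged morphological gradient; radii used are 1..6."""

    values: np.ndarray
    radii: tuple[int, ...] = field(default=(1, 2, 3, 4, 5, 6))


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk {(dr, dc) : dr^2 + dc^2 <= radius^2}."""
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


def local_intensity_maps(
    image: IntensityImage, config: IntensityFeatureConfig | None = None
) -> np.ndarray:
    """Mean intensity of the L x L window at every pixel, one map per scale.

    Windows are clipped at the image border: the mean is taken over the
    in-bounds pixels only.  Returns shape (n_scales, H, W).
    """
    config = config or IntensityFeatureConfig()
    I = image.pixels
    out = np.empty((len(config.window_sizes),) + I.shape)
    # integral-image window sums: exact for integer-valued 8-bit intensities
    S = np.zeros((I.shape[0] + 1, I.shape[1] + 1))
    np.cumsum(np.cumsum(I, axis=0), axis=1, out=S[1:, 1:])
    N = np.zeros_like(S)
    np.cumsum(np.cumsum(np.ones_like(I), axis=0), axis=1, out=N[1:, 1:])
    H, W = I.shape
    r = np.arange(H)[:, None]
    c = np.arange(W)[None, :]
    for k, L in enumerate(config.window_sizes):
        h = L // 2
        r0, r1 = np.clip(r - h, 0, H), np.clip(r + h + 1, 0, H)
        c0, c1 = np.clip(c - h, 0, W), np.clip(c + h + 1, 0, W)
        sums = S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]
        counts = N[r1, c1] - N[r0, c1] - N[r1, c0] + N[r0, c0]
        out[k] = sums / counts
    return out


def local_intensity_features(
    image: IntensityImage,
    seed: tuple[int, int],
    config: IntensityFeatureConfig | None = None,
) -> np.ndarray:
    """The six window means at one pixel."""
    config = config or IntensityFeatureConfig()
    r, c = seed
    if not (0 <= r < image.height and 0 <= c < image.width):
        raise ValueError(f"seed {seed} outside image of shape {image.shape}")
    out = np.empty(len(config.window_sizes))
    for k, L in enumerate(config.window_sizes):
        h = L // 2
        win = image.pixels[max(r - h, 0) : r + h + 1, max(c - h, 0) : c + h + 1]
        out[k] = win.mean()
    return out


def morphological_gradient(
    image: IntensityImage, radii: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
) -> GradientImage:
    """Mean over disk radii of (grayscale dilation - erosion).

    Reflect padding at the border avoids spurious high gradients where the
    window leaves the image.
    """
    I = image.pixels
    acc = np.zeros_like(I)
    for i in radii:
        acc += ndimage.morphological_gradient(
            I, footprint=disk_footprint(i), mode="reflect"
        )
    return GradientImage(acc / len(radii), tuple(radii))
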