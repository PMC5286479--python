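"""Synthetic fundus phantoms with paired vessel ground truth.

A phantom emulates the structure the segmentation pipeline assumes of a
fundus photograph: a bright background with a smooth low-frequency
illumination field inside a circular field of view, darker curvilinear
vessels of widths in the 1-15 px range, and additive Gaussian noise
quantized to the 8-bit scale.  Vessel centerlines are smoothed random walks
with bounded curvature crossing the FOV; each is dilated to its width and
rendered ``vessel_contrast`` grey levels darker than the background.  The
paired ground truth is the union of vessel supports inside the FOV.

Real fundus images additionally contain the optic disc, fovea, branching
vessel trees, lesions and camera vignetting; phantoms model none of these,
so phantom-based tests exercise the pipeline mechanics, not clinical
performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import IntensityImage
from .local_features import disk_footprint


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic fundus phantom.

    Defaults target a vessel pixel fraction around 10-15% of the FOV, the
    range reported for expert-annotated fundus databases, with vessel
    contrast well above the line-search threshold S = 5 and noise well
    below it.
    """

    height: int = 256
    width: int = 256
    fov_radius_fraction: float = 0.94
    background_level: float = 180.0
    illumination_amplitude: float = 15.0
    n_vessels: int = 6
    vessel_width_range: tuple[int, int] = (1, 7)
    vessel_contrast: float = 40.0
    vessel_waviness: float = 0.03
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8x8")
        if not 0 < self.fov_radius_fraction <= 1:
            raise ValueError("fov_radius_fraction must be in (0, 1]")
        lo, hi = self.vessel_width_range
        if not (1 <= lo <= hi <= 15):
            raise ValueError("vessel widths must lie within [1, 15]")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if self.vessel_contrast <= self.noise_sd:
            raise ValueError("vessel_contrast must exceed noise_sd")


def _fov_disk(spec: PhantomSpec) -> np.ndarray:
    r = np.arange(spec.height)[:, None] - (spec.height - 1) / 2
    c = np.arange(spec.width)[None, :] - (spec.width - 1) / 2
    radius = spec.fov_radius_fraction * min(spec.height, spec.width) / 2
    return r**2 + c**2 <= radius**2


def _illumination(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency field with peak amplitude ~illumination_amplitude."""
    if spec.illumination_amplitude == 0:
        return np.zeros((spec.height, spec.width))
    r = np.linspace(0, 1, spec.height)[:, None]
    c = np.linspace(0, 1, spec.width)[None, :]
    field = np.zeros((spec.height, spec.width))
    for _ in range(3):
        fr, fc = rng.uniform(0.5, 1.5, size=2)
        pr, pc = rng.uniform(0, 2 * math.pi, size=2)
        field += np.sin(2 * math.pi * fr * r + pr) * np.cos(2 * math.pi * fc * c + pc)
    peak = np.abs(field).max()
    return field / peak * spec.illumination_amplitude


def _centerline(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Bounded-curvature random walk across the FOV; boolean support map."""
    H, W = spec.height, spec.width
    cy, cx = (H - 1) / 2, (W - 1) / 2
    radius = spec.fov_radius_fraction * min(H, W) / 2
    # start on the FOV rim, head inward with a random tilt
    phi = rng.uniform(0, 2 * math.pi)
    y = cy + radius * math.sin(phi)
    x = cx + radius * math.cos(phi)
    heading = phi + math.pi + rng.uniform(-0.6, 0.6)
    support = np.zeros((H, W), dtype=bool)
    for _ in range(3 * max(H, W)):
        rr, cc = int(round(y)), int(round(x))
        if 0 <= rr < H and 0 <= cc < W:
            support[rr, cc] = True
        heading += rng.normal(0.0, spec.vessel_waviness)
        y += math.sin(heading)
        x += math.cos(heading)
        if (y - cy) ** 2 + (x - cx) ** 2 > (radius + 2) ** 2:
            break
    return support


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityImage, np.ndarray]:
    """Render one phantom; deterministic given ``spec.seed``.

    Returns the :class:`~vesselseg.image.IntensityImage` (with its circular
    FOV already attached) and the boolean ground-truth vessel map.
    """
    rng = np.random.default_rng(spec.seed)
    fov = _fov_disk(spec)
    background = spec.background_level + _illumination(spec, rng)

    lo, hi = spec.vessel_width_range
    vessels = np.zeros((spec.height, spec.width), dtype=bool)
    for _ in range(spec.n_vessels):
        line = _centerline(spec, rng)
        width = int(rng.integers(lo, hi + 1))
        if width > 1:
            line = ndimage.binary_dilation(line, structure=disk_footprint(width // 2))
        vessels |= line
    truth = vessels & fov

    img = np.where(truth, background - spec.vessel_contrast, background)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255)
    return IntensityImage(img, fov), truth


def generate_phantom_set(
    n: int, base_seed: int = 0, **overrides
) -> list[tuple[IntensityImage, np.ndarray]]:
    """n phantoms with consecutive seeds, sharing all other parameters."""
    return [
        generate_phantom(PhantomSpec(seed=base_seed + i, **overrides))
        for i in range(n)
    ]


def generate_score_fixture(
    shape: tuple[int, int],
    components: list[dict],
    background: float = -1.0,
    fov: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic score image for exercising dual-threshold postprocessing.

    ``components`` are dicts with keys ``center`` (row, col), ``radius`` and
    ``score``; each paints a disk of that score onto the background (later
    entries win on overlap).  Returns the raw score array; callers wrap it
    in a :class:`~vesselseg.classifier.ScoreImage`.
    """
    scores = np.full(shape, background, dtype=np.float64)
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    for comp in components:
        (r0, c0), rad, val = comp["center"], comp["radius"], comp["score"]
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        scores[disk] = val
    if fov is not None:
        scores[~np.asarray(fov, dtype=bool)] = np.nan
    return scores
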