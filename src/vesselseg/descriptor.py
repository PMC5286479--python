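"""Assembly and normalization of the 23-component pixel descriptor.

The "reinforcement local description" of a pixel concatenates, in fixed
order: the eight line-set shape features of line set one, the eight of line
set two, the six multiscale window means, and the averaged morphological
gradient — 23 components capturing local shape, intensity and edge strength
at once.  Descriptors are standardized per image (z-score over FOV pixels)
so that illumination differences between retinas do not dominate the
feature scales; test images are normalized with their own statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .image import IntensityImage
from .lineset import LineSetConfig, compute_lineset_maps, lineset_feature_maps
from .local_features import (
    IntensityFeatureConfig,
    local_intensity_maps,
    morphological_gradient,
)

LINESET_NAMES = [f"f{i}_1" for i in range(1, 9)] + [f"f{i}_2" for i in range(1, 9)]
COMPONENT_NAMES = (
    LINESET_NAMES
    + [f"mean_{L}" for L in IntensityFeatureConfig().window_sizes]
    + ["grad"]
)
N_COMPONENTS = len(COMPONENT_NAMES)  # 8 + 8 + 6 + 1 = 23


def build_descriptors(
    image: IntensityImage,
    lineset_config: LineSetConfig | None = None,
    intensity_config: IntensityFeatureConfig | None = None,
    lineset_maps=None,
) -> pd.DataFrame:
    """Descriptor table for all FOV pixels, in row-major pixel order.

    Columns: ``row``, ``col``, then the 23 components named in
    :data:`COMPONENT_NAMES`.  Precomputed ``lineset_maps`` (the pair from
    :func:`~vesselseg.lineset.compute_lineset_maps`) may be passed to avoid
    retracing.
    """
    lineset_config = lineset_config or LineSetConfig()
    intensity_config = intensity_config or IntensityFeatureConfig()
    if lineset_maps is None:
        lineset_maps = compute_lineset_maps(image, lineset_config)
    maps1, maps2 = lineset_maps
    if maps1.ll.shape != image.shape:
        raise ValueError("line-set maps do not match the image shape")
    feats1 = lineset_feature_maps(maps1, image.fov, lineset_config)
    feats2 = lineset_feature_maps(maps2, image.fov, lineset_config)
    means = local_intensity_maps(image, intensity_config)
    grad = morphological_gradient(image).values

    rows, cols = np.nonzero(image.fov)  # row-major order
    stack = np.concatenate([feats1, feats2, means, grad[None]], axis=0)
    data = {"row": rows, "col": cols}
    for k, name in enumerate(COMPONENT_NAMES):
        data[name] = stack[k, rows, cols]
    table = pd.DataFrame(data)
    if not np.isfinite(table[COMPONENT_NAMES].to_numpy()).all():
        raise ValueError("non-finite descriptor component")
    return table


def normalize_descriptors(
    table: pd.DataFrame, scheme: str = "zscore"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each component over the image's FOV pixels.

    ``zscore`` (default) maps each column to zero mean and unit standard
    deviation; ``minmax`` maps to [0, 1].  Zero-variance (or zero-range)
    columns map to 0.  Returns the normalized table and a parameter frame
    (``center``/``scale`` per component) with which the transform inverts:
    ``values * scale + center``.
    """
    if len(table) == 0:
        raise ValueError("empty descriptor table")
    if scheme not in ("zscore", "minmax"):
        raise ValueError("scheme must be 'zscore' or 'minmax'")
    out = table.copy()
    values = table[COMPONENT_NAMES].to_numpy(dtype=np.float64)
    if scheme == "zscore":
        center = values.mean(axis=0)
        scale = values.std(axis=0)
    else:
        center = values.min(axis=0)
        scale = values.max(axis=0) - center
    safe = np.where(scale > 0, scale, 1.0)
    normed = (values - center) / safe
    normed[:, scale == 0] = 0.0
    out[COMPONENT_NAMES] = normed
    params = pd.DataFrame(
        {"component": COMPONENT_NAMES, "center": center, "scale": safe}
    )
    return out, params


def denormalize_descriptors(table: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`normalize_descriptors` with its returned parameters."""
    out = table.copy()
    center = params.set_index("component").loc[COMPONENT_NAMES, "center"].to_numpy()
    scale = params.set_index("component").loc[COMPONENT_NAMES, "scale"].to_numpy()
    out[COMPONENT_NAMES] = table[COMPONENT_NAMES].to_numpy() * scale + center
    return out
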