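"""Dual-threshold postprocessing via binary morphological reconstruction.

A single strict threshold on the SVM decision image removes noise but
breaks thin vessels into fragments; a single permissive threshold keeps the
vessels connected but admits noise blobs.  The dual-threshold scheme takes
both: the permissive cut at the class boundary (score >= 0) is the mask,
the strict cut at T is the marker, and morphological reconstruction keeps
exactly those connected components of the mask that contain at least one
marker pixel.  Discontinuities that are bridged at the permissive level are
thus reconnected, while mask components never reaching T are dropped as
noise.

For binary images reconstruction-by-geodesic-dilation to convergence is
exactly connected-component filtering, which is how it is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .classifier import ScoreImage


@dataclass(frozen=True)
class PostprocessConfig:
    base_threshold: float = 0.0
    marker_threshold: float = 0.2
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.marker_threshold <= self.base_threshold:
            raise ValueError("marker_threshold T must exceed base_threshold")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


#: decision-value marker thresholds tuned per database style
MARKER_THRESHOLD_STARE = 0.2
MARKER_THRESHOLD_DRIVE = 0.35


@dataclass
class SegmentationResult:
    """Final binary vessel map plus provenance."""

    vessels: np.ndarray
    fov: np.ndarray
    base_threshold: float
    marker_threshold: float
    connectivity: int
    model_id: str = ""

    def __post_init__(self) -> None:
        self.vessels = np.asarray(self.vessels, dtype=bool)
        self.fov = np.asarray(self.fov, dtype=bool)
        if self.vessels.shape != self.fov.shape:
            raise ValueError("vessel map and fov shapes differ")
        if (self.vessels & ~self.fov).any():
            raise ValueError("vessel pixels outside the FOV")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def binary_reconstruct(
    marker: np.ndarray, mask: np.ndarray, connectivity: int = 8
) -> np.ndarray:
    """Union of the connected components of ``mask`` touched by ``marker``.

    The marker is intersected with the mask first, so any marker is valid.
    """
    marker = np.asarray(marker, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if marker.shape != mask.shape:
        raise ValueError("marker and mask shapes differ")
    marker = marker & mask
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0 or not marker.any():
        return np.zeros_like(mask)
    hit = np.zeros(n + 1, dtype=bool)
    hit[np.unique(labels[marker])] = True
    hit[0] = False
    return hit[labels]


def postprocess(
    scores: ScoreImage, config: PostprocessConfig | None = None, model_id: str = ""
) -> SegmentationResult:
    """Apply the dual-threshold reconstruction to a decision-value image."""
    config = config or PostprocessConfig()
    # base cut is strict (decision value 0 is the class boundary itself, and
    # a strict cut keeps the step idempotent on already-binary score maps);
    # the marker cut is inclusive
    with np.errstate(invalid="ignore"):
        mask = (scores.scores > config.base_threshold) & scores.fov
        marker = (scores.scores >= config.marker_threshold) & scores.fov
    vessels = binary_reconstruct(marker, mask, config.connectivity)
    return SegmentationResult(
        vessels,
        scores.fov,
        config.base_threshold,
        config.marker_threshold,
        config.connectivity,
        model_id,
    )
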