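"""Two-line-set local shape descriptor for curvilinear structures.

For every FOV pixel, 24 line segments are traced outward at 15-degree ray
spacing (full 360-degree coverage), each segment growing while the candidate
pixel stays within ``S`` grey levels of the seed pixel, inside the image and
inside the FOV, up to a length cap.  Two caps are used: 21 pixels (line set
one, about the widest vessel) and 41 pixels (line set two, comfortably wider
than any vessel), so the pair of sets distinguishes on-vessel, edge and
background pixels by the geometry of where their rays stop.

Eight scalar shape features are derived per line set from the longest
segment length LL, shortest length LP, total length AL, the main direction
(direction index of the longest segment) and the neighbourhood statistics
SNLL/SNLP (sums of LL/LP over the 8-neighbourhood):

====  =========================================================
f1    LL
f2    LP
f3    LL - LP
f4    LL - AL/24
f5    AL/24 - LP
f6    RL + RP   (main-direction agreement along longest/shortest)
f7    \\|SNLL/8 - LL\\|
f8    \\|SNLP - LP\\|
====  =========================================================

f6-f8 depend on neighbouring pixels' own line sets, so feature extraction is
a two-pass, whole-image computation (:func:`compute_lineset_maps` then
:func:`lineset_feature_maps`); :func:`build_line_set` is the per-pixel view
of the same tracing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import IntensityImage

#: sentinel written into integer maps outside the FOV
SENTINEL = -1


@dataclass(frozen=True)
class LineSetConfig:
    """Geometry and stopping rule of the two line sets.

    ``n_directions`` rays at ``angle_step_deg`` spacing, numbered 1..24
    counter-clockwise starting from the +x axis (direction 1 points along
    +x, i.e. increasing column).  ``compare='seed'`` stops a ray when the
    candidate differs from the *seed* by at least ``s_threshold``;
    ``compare='previous'`` compares against the previous path pixel instead.
    """

    n_directions: int = 24
    angle_step_deg: float = 15.0
    max_len_one: int = 21
    max_len_two: int = 41
    s_threshold: float = 5.0
    compare: str = "seed"

    def __post_init__(self) -> None:
        if self.n_directions < 1:
            raise ValueError("n_directions must be positive")
        if not 0 < self.max_len_one < self.max_len_two:
            raise ValueError("require 0 < max_len_one < max_len_two")
        if self.s_threshold <= 0:
            raise ValueError("s_threshold must be > 0")
        if self.compare not in ("seed", "previous"):
            raise ValueError("compare must be 'seed' or 'previous'")


@dataclass
class LineSegment:
    """One traced ray: ordered pixel path starting at the seed."""

    direction_index: int
    pixel_path: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return len(self.pixel_path)


@dataclass
class LineSet:
    """The 24 segments of one pixel plus their summary statistics."""

    seed: tuple[int, int]
    segments: list[LineSegment]
    LL: int = field(init=False)
    LP: int = field(init=False)
    AL: int = field(init=False)
    main_direction: int = field(init=False)

    def __post_init__(self) -> None:
        lengths = [seg.length for seg in self.segments]
        self.LL = max(lengths)
        self.LP = min(lengths)
        self.AL = sum(lengths)
        self.main_direction = self.segments[int(np.argmax(lengths))].direction_index


@dataclass
class LineSetFeatures:
    """The eight shape features of one pixel for one line set."""

    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float
    f8: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f1, self.f2, self.f3, self.f4, self.f5, self.f6, self.f7, self.f8]
        )


def ray_offsets(direction_index: int, max_len: int, config: LineSetConfig | None = None) -> np.ndarray:
    """Pixel offsets of one ray, excluding the seed: shape (max_len-1, 2).

    The ray at angle ``(direction_index - 1) * angle_step_deg`` from the +x
    axis is sampled at unit Euclidean steps t = 1, 2, ...; each sample is
    rounded to the nearest pixel (halves away from zero, so opposite rays
    are exact mirrors) and consecutive duplicates are collapsed, yielding
    the first ``max_len - 1`` distinct pixels after the seed.  Rows increase
    downward, so a positive angle steps to smaller rows.
    """
    config = config or LineSetConfig()
    nd = config.n_directions
    if not 1 <= direction_index <= nd:
        raise ValueError(f"direction_index must be in [1, {nd}]")
    # when the fan covers the full circle, build the second half as exact
    # negations of the first so that opposite rays are pixelwise mirrors
    # (float trig alone is not exactly odd at half-integer samples)
    sign = 1.0
    k = direction_index - 1
    if nd % 2 == 0 and nd * config.angle_step_deg == 360.0 and k >= nd // 2:
        k -= nd // 2
        sign = -1.0
    theta = math.radians(k * config.angle_step_deg)
    dc, dr = sign * math.cos(theta), -sign * math.sin(theta)

    def _round(v: float) -> int:
        return int(math.copysign(math.floor(abs(v) + 0.5), v))

    offsets: list[tuple[int, int]] = []
    prev = (0, 0)
    t = 1
    while len(offsets) < max_len - 1:
        cand = (_round(t * dr), _round(t * dc))
        if cand != prev:
            offsets.append(cand)
            prev = cand
        t += 1
    return np.array(offsets, dtype=np.int64)


def trace_line(
    image: IntensityImage,
    seed: tuple[int, int],
    direction_index: int,
    max_len: int,
    s: float,
    config: LineSetConfig | None = None,
) -> LineSegment:
    """Trace one ray from ``seed``.

    The path is the maximal prefix of the rasterized ray (seed included)
    whose pixels stay inside the image and FOV and differ from the reference
    intensity by less than ``s``; tracing stops at the first violation or at
    ``max_len`` pixels.
    """
    config = config or LineSetConfig()
    r0, c0 = seed
    if not (0 <= r0 < image.height and 0 <= c0 < image.width):
        raise ValueError(f"seed {seed} outside image of shape {image.shape}")
    path = [(int(r0), int(c0))]
    ref = image.pixels[r0, c0]
    for dr, dc in ray_offsets(direction_index, max_len, config):
        r, c = r0 + int(dr), c0 + int(dc)
        if not (0 <= r < image.height and 0 <= c < image.width):
            break
        if not image.fov[r, c]:
            break
        if abs(image.pixels[r, c] - ref) >= s:
            break
        path.append((r, c))
        if config.compare == "previous":
            ref = image.pixels[r, c]
    return LineSegment(direction_index, path)


def build_line_set(
    image: IntensityImage,
    seed: tuple[int, int],
    max_len: int,
    s: float,
    config: LineSetConfig | None = None,
) -> LineSet:
    """Trace all 24 rays of one pixel and summarize them."""
    config = config or LineSetConfig()
    segments = [
        trace_line(image, seed, d, max_len, s, config)
        for d in range(1, config.n_directions + 1)
    ]
    return LineSet(tuple(seed), segments)


@dataclass
class LineSetMaps:
    """Whole-image LL/LP/AL/main-direction maps for one line set.

    Integer maps carry :data:`SENTINEL` outside the FOV.  ``lengths`` keeps
    the per-direction segment length of every pixel (shape (n_directions,
    H, W)), which the feature pass needs for the agreement ratios.
    """

    max_len: int
    lengths: np.ndarray
    ll: np.ndarray
    lp: np.ndarray
    al: np.ndarray
    main_direction: np.ndarray
    short_direction: np.ndarray


def _shifted(a: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """a evaluated at (r + dr, c + dc), with out-of-bounds cells = fill."""
    H, W = a.shape
    out = np.full_like(a, fill)
    h, w = max(0, H - abs(dr)), max(0, W - abs(dc))
    if h and w:
        r0, c0 = max(-dr, 0), max(-dc, 0)
        r1, c1 = max(dr, 0), max(dc, 0)
        out[r0 : r0 + h, c0 : c0 + w] = a[r1 : r1 + h, c1 : c1 + w]
    return out


def compute_lineset_maps(
    image: IntensityImage, config: LineSetConfig | None = None
) -> tuple[LineSetMaps, LineSetMaps]:
    """Trace both line sets for every FOV pixel in one vectorized pass.

    Because the stopping rule does not depend on the length cap, the set-one
    path of a pixel is a prefix of its set-two path; both caps are therefore
    served by a single sweep up to ``max_len_two``.
    """
    config = config or LineSetConfig()
    I, fov = image.pixels, image.fov
    H, W = I.shape
    nd = config.n_directions
    cap2 = config.max_len_two
    lengths = np.zeros((nd, H, W), dtype=np.int16)
    for d in range(1, nd + 1):
        offs = ray_offsets(d, cap2, config)
        alive = fov.copy()
        length = np.where(fov, 1, 0).astype(np.int16)
        ref = I  # seed-anchored comparison
        for dr, dc in offs:
            cand = _shifted(I, int(dr), int(dc), np.inf)
            ok = _shifted(fov, int(dr), int(dc), False)
            alive = alive & ok & (np.abs(cand - ref) < config.s_threshold)
            length += alive
            if config.compare == "previous":
                ref = np.where(alive, cand, ref)
        lengths[d - 1] = length
    maps = []
    for cap in (config.max_len_one, config.max_len_two):
        ln = np.minimum(lengths, cap)
        ll = ln.max(axis=0)
        lp = ln.min(axis=0)
        al = ln.sum(axis=0, dtype=np.int64)
        maindir = np.argmax(ln, axis=0).astype(np.int16) + 1  # ties -> lowest index
        shortdir = np.argmin(ln, axis=0).astype(np.int16) + 1
        for m in (ll, lp, maindir, shortdir):
            m[~fov] = SENTINEL
        al[~fov] = SENTINEL
        maps.append(
            LineSetMaps(cap, ln, ll.astype(np.int64), lp.astype(np.int64), al,
                        maindir.astype(np.int64), shortdir.astype(np.int64))
        )
    return maps[0], maps[1]


_K8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64)


def lineset_feature_maps(
    maps: LineSetMaps, fov: np.ndarray, config: LineSetConfig | None = None
) -> np.ndarray:
    """Compute the eight feature maps of one line set: shape (8, H, W).

    Off-FOV pixels carry NaN.  Neighbours outside the image or FOV
    contribute 0 to SNLL/SNLP while f7 keeps its fixed /8 denominator.
    """
    config = config or LineSetConfig()
    fov = np.asarray(fov, dtype=bool)
    nd = config.n_directions
    ll = maps.ll.astype(np.float64)
    lp = maps.lp.astype(np.float64)
    al = maps.al.astype(np.float64)
    mean_len = al / nd
    f1, f2 = ll, lp
    f3 = ll - lp
    f4 = ll - mean_len
    f5 = mean_len - lp

    # agreement counts along the longest / shortest segments
    M = maps.main_direction
    rl_count = np.zeros(fov.shape, dtype=np.float64)
    rp_count = np.zeros(fov.shape, dtype=np.float64)
    for d in range(1, nd + 1):
        on_long = (M == d) & fov
        on_short = (maps.short_direction == d) & fov
        if not (on_long.any() or on_short.any()):
            continue
        # ln_d equals LL at pixels whose longest ray is d, and LP at pixels
        # whose shortest ray is d, so one accumulation serves both ratios
        ln_d = maps.lengths[d - 1]
        agree_cum = np.ones(fov.shape)  # seed pixel always agrees
        for j, (dr, dc) in enumerate(ray_offsets(d, maps.max_len, config)):
            neigh_dir = _shifted(M, int(dr), int(dc), SENTINEL)
            agree_cum += (neigh_dir == M) & (ln_d >= j + 2)
        rl_count[on_long] = agree_cum[on_long]
        rp_count[on_short] = agree_cum[on_short]
    with np.errstate(invalid="ignore", divide="ignore"):
        f6 = rl_count / np.maximum(ll, 1) + rp_count / np.maximum(lp, 1)

    llz = np.where(fov, ll, 0.0)
    lpz = np.where(fov, lp, 0.0)
    snll = ndimage.correlate(llz, _K8, mode="constant", cval=0.0)
    snlp = ndimage.correlate(lpz, _K8, mode="constant", cval=0.0)
    f7 = np.abs(snll / 8.0 - ll)
    f8 = np.abs(snlp - lp)

    out = np.stack([f1, f2, f3, f4, f5, f6, f7, f8])
    out[:, ~fov] = np.nan
    return out


def lineset_features(
    seed: tuple[int, int],
    line_set: LineSet,
    ll_map: np.ndarray,
    lp_map: np.ndarray,
    maindir_map: np.ndarray,
    fov: np.ndarray | None = None,
    n_directions: int = 24,
) -> LineSetFeatures:
    """Per-pixel features of one line set, given the whole-image maps.

    The agreement ratios RL/RP walk the longest and shortest segment paths
    of ``line_set`` and compare each path pixel's main direction (from
    ``maindir_map``) with the seed's.  Neighbours outside the image or FOV
    contribute 0 to SNLL/SNLP.
    """
    r0, c0 = seed
    H, W = ll_map.shape
    if fov is None:
        fov = np.ones((H, W), dtype=bool)
    lengths = [seg.length for seg in line_set.segments]
    ll, lp, al = line_set.LL, line_set.LP, line_set.AL
    mean_len = al / n_directions
    longest = line_set.segments[int(np.argmax(lengths))]
    shortest = line_set.segments[int(np.argmin(lengths))]
    seed_dir = line_set.main_direction

    def agreement(seg: LineSegment) -> float:
        n = sum(1 for (r, c) in seg.pixel_path if maindir_map[r, c] == seed_dir)
        return n / seg.length

    f6 = agreement(longest) + agreement(shortest)
    snll = snlp = 0.0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            r, c = r0 + dr, c0 + dc
            if 0 <= r < H and 0 <= c < W and fov[r, c]:
                snll += ll_map[r, c]
                snlp += lp_map[r, c]
    return LineSetFeatures(
        f1=float(ll),
        f2=float(lp),
        f3=float(ll - lp),
        f4=float(ll - mean_len),
        f5=float(mean_len - lp),
        f6=float(f6),
        f7=abs(snll / 8.0 - ll),
        f8=abs(snlp - lp),
    )
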