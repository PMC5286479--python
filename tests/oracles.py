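"""Independent brute-force reference implementations for oracle tests.

Everything here is deliberately naive (per-pixel loops, no maps, no
vectorization) and shares no code with the package, so that agreement
between the two is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- line sets
def oracle_ray(direction_index: int, max_len: int, angle_step_deg: float = 15.0):
    """First max_len distinct pixels of the ray, seed (0,0) included.

    Unit Euclidean sampling, half-away-from-zero rounding, duplicates
    collapsed; directions 13..24 are the pixelwise mirrors of 1..12 —
    written independently of the package's rasterizer.
    """
    sign = 1
    if direction_index > 12:
        direction_index -= 12
        sign = -1
    theta = math.radians((direction_index - 1) * angle_step_deg)

    def rnd(v):
        return -math.floor(-v + 0.5) if v < 0 else math.floor(v + 0.5)

    pts = [(0, 0)]
    t = 0
    while len(pts) < max_len:
        t += 1
        p = (rnd(-sign * t * math.sin(theta)), rnd(sign * t * math.cos(theta)))
        if p != pts[-1]:
            pts.append(p)
    return pts


def oracle_trace(pixels, fov, seed, direction_index, max_len, s):
    """Pixel path of one ray under the seed-anchored stopping rule."""
    H, W = pixels.shape
    r0, c0 = seed
    ref = pixels[r0, c0]
    path = []
    for dr, dc in oracle_ray(direction_index, max_len):
        r, c = r0 + dr, c0 + dc
        if not (0 <= r < H and 0 <= c < W):
            break
        if not fov[r, c]:
            break
        if (r, c) != (r0, c0) and abs(pixels[r, c] - ref) >= s:
            break
        path.append((r, c))
    return path


def oracle_line_set(pixels, fov, seed, max_len, s):
    """LL/LP/AL/main direction and all 24 paths of one pixel."""
    paths = {
        d: oracle_trace(pixels, fov, seed, d, max_len, s) for d in range(1, 25)
    }
    lengths = {d: len(p) for d, p in paths.items()}
    ll = max(lengths.values())
    lp = min(lengths.values())
    al = sum(lengths.values())
    maindir = min(d for d, ln in lengths.items() if ln == ll)
    shortdir = min(d for d, ln in lengths.items() if ln == lp)
    return {
        "paths": paths, "lengths": lengths, "LL": ll, "LP": lp, "AL": al,
        "main": maindir, "short": shortdir,
    }


def oracle_features(pixels, fov, seed, max_len, s, _cache=None):
    """f1..f8 of one pixel, recomputing every needed line set from scratch."""
    cache = _cache if _cache is not None else {}

    def lineset_at(p):
        if p not in cache:
            cache[p] = oracle_line_set(pixels, fov, p, max_len, s)
        return cache[p]

    H, W = pixels.shape
    own = lineset_at(tuple(seed))
    ll, lp, al = own["LL"], own["LP"], own["AL"]
    mean_len = al / 24.0

    def ratio(direction):
        path = own["paths"][direction]
        n = sum(1 for p in path if lineset_at(p)["main"] == own["main"])
        return n / len(path)

    f6 = ratio(own["main"]) + ratio(own["short"])
    snll = snlp = 0.0
    r0, c0 = seed
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            r, c = r0 + dr, c0 + dc
            if 0 <= r < H and 0 <= c < W and fov[r, c]:
                neigh = lineset_at((r, c))
                snll += neigh["LL"]
                snlp += neigh["LP"]
    return np.array([
        ll, lp, ll - lp, ll - mean_len, mean_len - lp,
        f6, abs(snll / 8.0 - ll), abs(snlp - lp),
    ])


# ----------------------------------------------------------- local features
def oracle_window_mean(pixels, seed, L):
    """Double-loop clipped window mean."""
    H, W = pixels.shape
    r0, c0 = seed
    h = L // 2
    vals = [
        pixels[r, c]
        for r in range(r0 - h, r0 + h + 1)
        for c in range(c0 - h, c0 + h + 1)
        if 0 <= r < H and 0 <= c < W
    ]
    return sum(vals) / len(vals)


def oracle_gradient_at(pixels, seed, radii=(1, 2, 3, 4, 5, 6)):
    """Naive sliding max/min morphological gradient with reflect padding."""
    r0, c0 = seed
    pad = max(radii)
    padded = np.pad(pixels, pad, mode="reflect")
    total = 0.0
    for rad in radii:
        hi, lo = -np.inf, np.inf
        for dr in range(-rad, rad + 1):
            for dc in range(-rad, rad + 1):
                if dr * dr + dc * dc <= rad * rad:
                    v = padded[r0 + pad + dr, c0 + pad + dc]
                    hi, lo = max(hi, v), min(lo, v)
        total += hi - lo
    return total / len(radii)


# ------------------------------------------------------------ morphology/CC
def oracle_fill_holes(mask):
    """Holes = background not reachable from the border (4-connected BFS)."""
    H, W = mask.shape
    outside = np.zeros((H, W), dtype=bool)
    stack = [
        (r, c)
        for r in range(H)
        for c in range(W)
        if (r in (0, H - 1) or c in (0, W - 1)) and not mask[r, c]
    ]
    for p in stack:
        outside[p] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < H and 0 <= cc < W and not mask[rr, cc] and not outside[rr, cc]:
                outside[rr, cc] = True
                stack.append((rr, cc))
    return mask | ~outside


def oracle_components(mask, connectivity=8):
    """Hand-rolled BFS connected-component labelling."""
    H, W = mask.shape
    labels = np.zeros((H, W), dtype=int)
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    nxt = 0
    for r in range(H):
        for c in range(W):
            if mask[r, c] and labels[r, c] == 0:
                nxt += 1
                stack = [(r, c)]
                labels[r, c] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy, dx in neigh:
                        yy, xx = y + dy, x + dx
                        if (0 <= yy < H and 0 <= xx < W and mask[yy, xx]
                                and labels[yy, xx] == 0):
                            labels[yy, xx] = nxt
                            stack.append((yy, xx))
    return labels, nxt


def oracle_reconstruct(marker, mask, connectivity=8):
    """Reconstruction via the component definition, using BFS labels."""
    marker = marker & mask
    labels, n = oracle_components(mask, connectivity)
    keep = set(np.unique(labels[marker])) - {0}
    return np.isin(labels, sorted(keep))


def oracle_confusion(seg, truth, fov):
    """Exhaustive pixel-loop confusion counts over the FOV."""
    tp = fp = tn = fn = 0
    H, W = seg.shape
    for r in range(H):
        for c in range(W):
            if not fov[r, c]:
                continue
            if seg[r, c] and truth[r, c]:
                tp += 1
            elif seg[r, c]:
                fp += 1
            elif truth[r, c]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn
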