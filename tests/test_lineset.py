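"""Line-set tracing and shape features against brute-force oracles."""

import numpy as np
import pytest

from vesselseg import (
    IntensityImage,
    LineSetConfig,
    build_line_set,
    compute_lineset_maps,
    lineset_feature_maps,
    lineset_features,
    trace_line,
)
from vesselseg.lineset import ray_offsets

from oracles import oracle_features, oracle_line_set, oracle_ray, oracle_trace


def constant_image(value=100.0, size=101):
    return IntensityImage(np.full((size, size), value))


class TestTraceLine:
    def test_constant_image_runs_to_cap(self):
        img = constant_image()
        for d in (1, 5, 13, 24):
            assert trace_line(img, (50, 50), d, 21, 5).length == 21

    def test_immediate_contrast_stops_at_seed(self):
        img = constant_image()
        img.pixels[50, 51] = 200.0  # +100 on the +x ray's first step
        assert trace_line(img, (50, 50), 1, 21, 5).length == 1

    def test_horizontal_ramp_matches_threshold_window(self):
        # I(row, col) = col, seed col 50, S=5: cols 50..54 pass, col 55 stops
        img = IntensityImage(np.tile(np.arange(101, dtype=float), (101, 1)))
        seg = trace_line(img, (50, 50), 1, 21, 5)
        assert seg.pixel_path == [(50, c) for c in range(50, 55)]

    def test_border_truncates_path(self):
        img = constant_image(size=41)
        seg = trace_line(img, (40, 40), 1, 21, 5)  # corner, +x leaves image
        assert seg.length == 1

    def test_fov_boundary_truncates_path(self):
        img = constant_image(size=41)
        fov = np.zeros((41, 41), dtype=bool)
        fov[:, :25] = True
        img = img.with_fov(fov)
        assert trace_line(img, (20, 20), 1, 21, 5).length == 5  # cols 20..24

    def test_seed_outside_image_raises(self):
        with pytest.raises(ValueError):
            trace_line(constant_image(), (200, 0), 1, 21, 5)

    @pytest.mark.parametrize("direction", range(1, 25))
    def test_ray_rasterization_matches_oracle(self, direction):
        offs = ray_offsets(direction, 41)
        expected = oracle_ray(direction, 41)[1:]
        assert [tuple(o) for o in offs] == expected

    def test_random_image_traces_match_oracle(self, rng):
        pixels = rng.integers(0, 256, size=(41, 41)).astype(float)
        img = IntensityImage(pixels)
        for _ in range(30):
            seed = tuple(rng.integers(5, 36, size=2))
            d = int(rng.integers(1, 25))
            seg = trace_line(img, seed, d, 21, 5)
            assert seg.pixel_path == oracle_trace(pixels, img.fov, seed, d, 21, 5)

    def test_monotone_in_s(self, rng):
        # the path under a smaller S is a prefix of the path under a larger S
        pixels = rng.integers(0, 256, size=(41, 41)).astype(float)
        img = IntensityImage(pixels)
        for _ in range(20):
            seed = tuple(rng.integers(5, 36, size=2))
            d = int(rng.integers(1, 25))
            p_small = trace_line(img, seed, d, 21, 3).pixel_path
            p_large = trace_line(img, seed, d, 21, 30).pixel_path
            assert p_large[: len(p_small)] == p_small


class TestBuildLineSet:
    def test_constant_interior(self):
        ls = build_line_set(constant_image(), (50, 50), 21, 5)
        assert (ls.LL, ls.LP, ls.AL) == (21, 21, 24 * 21)
        assert ls.main_direction == 1  # tie broken to the lowest index

    def test_stripe_centerline_longest_along_stripe(self, stripe_image):
        # on-vessel pixel: the ray along the stripe runs to the cap
        ls = build_line_set(stripe_image, (30, 30), 21, 5)
        assert ls.LL == 21
        assert ls.main_direction == 1  # +x, along the stripe
        # perpendicular rays are clipped by the stripe edge
        perp = ls.segments[6]  # direction 7 = 90 degrees, straight up
        assert perp.length == 3  # centerline row 30, stripe rows 28..32

    def test_stripe_perpendicular_matches_oracle(self, stripe_image):
        ls = build_line_set(stripe_image, (30, 30), 21, 5)
        ref = oracle_line_set(stripe_image.pixels, stripe_image.fov, (30, 30), 21, 5)
        for d in range(1, 25):
            assert ls.segments[d - 1].length == ref["lengths"][d]

    def test_statistics_consistent_with_segments(self, small_phantom):
        img, _ = small_phantom
        ls = build_line_set(img, (32, 32), 41, 5)
        lengths = [s.length for s in ls.segments]
        assert ls.LL == max(lengths) and ls.LP == min(lengths)
        assert ls.AL == sum(lengths)
        assert ls.segments[ls.main_direction - 1].length == ls.LL


class TestLineSetMaps:
    def test_constant_image_interior_at_cap(self):
        img = constant_image(size=101)
        m1, m2 = compute_lineset_maps(img)
        assert m1.ll[50, 50] == 21 and m2.ll[50, 50] == 41
        assert (m1.ll[41:60, 41:60] == 21).all()

    def test_off_fov_pixels_carry_sentinel(self, small_phantom):
        img, _ = small_phantom
        m1, _ = compute_lineset_maps(img)
        assert (m1.ll[~img.fov] == -1).all()
        assert (m1.main_direction[~img.fov] == -1).all()

    def test_maps_match_per_pixel_oracle(self, small_phantom, rng):
        img, _ = small_phantom
        m1, m2 = compute_lineset_maps(img)
        fr, fc = np.nonzero(img.fov)
        for i in rng.choice(fr.size, size=10, replace=False):
            seed = (int(fr[i]), int(fc[i]))
            for m, cap in ((m1, 21), (m2, 41)):
                ref = oracle_line_set(img.pixels, img.fov, seed, cap, 5)
                assert m.ll[seed] == ref["LL"]
                assert m.lp[seed] == ref["LP"]
                assert m.al[seed] == ref["AL"]
                assert m.main_direction[seed] == ref["main"]


class TestLineSetFeatures:
    def test_constant_interior_features(self):
        img = constant_image(size=101)
        m1, _ = compute_lineset_maps(img)
        f = lineset_feature_maps(m1, img.fov)
        # interior pixel: every ray at cap, whole neighbourhood identical
        assert f[0, 50, 50] == 21 and f[1, 50, 50] == 21
        assert f[2, 50, 50] == f[3, 50, 50] == f[4, 50, 50] == 0
        assert f[5, 50, 50] == 2.0  # full agreement along both extremal rays
        assert f[6, 50, 50] == 0  # all 8 neighbours share LL

    def test_identity_f3_equals_f4_plus_f5(self, small_phantom):
        img, _ = small_phantom
        m1, m2 = compute_lineset_maps(img)
        for m in (m1, m2):
            f = lineset_feature_maps(m, img.fov)
            d = f[2][img.fov] - (f[3][img.fov] + f[4][img.fov])
            assert np.abs(d).max() < 1e-9

    def test_feature_maps_match_bruteforce(self, small_phantom, rng):
        img, _ = small_phantom
        m1, m2 = compute_lineset_maps(img)
        fr, fc = np.nonzero(img.fov)
        interior = (fr > 4) & (fr < 59) & (fc > 4) & (fc < 59)
        idx = rng.choice(np.nonzero(interior)[0], size=5, replace=False)
        for m, cap in ((m1, 21), (m2, 41)):
            f = lineset_feature_maps(m, img.fov)
            for i in idx:
                seed = (int(fr[i]), int(fc[i]))
                ref = oracle_features(img.pixels, img.fov, seed, cap, 5)
                np.testing.assert_allclose(f[:, seed[0], seed[1]], ref, atol=1e-9)

    def test_per_pixel_features_match_maps(self, stripe_image):
        img = stripe_image
        m1, _ = compute_lineset_maps(img)
        f = lineset_feature_maps(m1, img.fov)
        for seed in [(30, 30), (28, 15), (10, 40)]:
            ls = build_line_set(img, seed, 21, 5)
            got = lineset_features(seed, ls, m1.ll, m1.lp, m1.main_direction,
                                   img.fov).as_array()
            np.testing.assert_allclose(got, f[:, seed[0], seed[1]], atol=1e-9)

    def test_f6_bounds_and_nonnegativity(self, small_phantom):
        img, _ = small_phantom
        m1, _ = compute_lineset_maps(img)
        f = lineset_feature_maps(m1, img.fov)
        fov = img.fov
        assert (f[5][fov] >= 0).all() and (f[5][fov] <= 2 + 1e-12).all()
        assert (f[6][fov] >= 0).all() and (f[7][fov] >= 0).all()
        assert (f[3][fov] >= 0).all() and (f[4][fov] >= 0).all()


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LineSetConfig(max_len_one=41, max_len_two=21)
        with pytest.raises(ValueError):
            LineSetConfig(s_threshold=0)
        with pytest.raises(ValueError):
            LineSetConfig(compare="midpoint")

    def test_previous_pixel_comparison_mode(self):
        # a slow ramp never violates the previous-pixel rule but does
        # violate the seed-anchored rule once the drift accumulates
        img = IntensityImage(np.tile(np.arange(0, 202, 2, dtype=float), (101, 1)))
        cfg = LineSetConfig(compare="previous")
        assert trace_line(img, (50, 50), 1, 21, 5, cfg).length == 21
        assert trace_line(img, (50, 50), 1, 21, 5).length == 3  # seed mode

    def test_previous_mode_maps_match_tracing(self):
        img = IntensityImage(np.tile(np.arange(0, 202, 2, dtype=float), (101, 1)))
        cfg = LineSetConfig(compare="previous")
        m1, _ = compute_lineset_maps(img, cfg)
        assert m1.ll[50, 50] == 21

    def test_half_plane_angle_mode(self):
        # 7.5-degree spacing over 24 rays spans only the upper half plane
        cfg = LineSetConfig(angle_step_deg=7.5)
        img = IntensityImage(np.full((101, 101), 50.0))
        img.pixels[:50, :] = 200.0  # everything above the seed is blocked
        ls = build_line_set(img, (50, 50), 21, 5, cfg)
        lengths = [s.length for s in ls.segments]
        assert lengths[0] == 21  # along +x
        assert min(lengths) == 1  # upward rays stop immediately
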