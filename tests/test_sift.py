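import math

import numpy as np
import pytest

from adipoct.core import GreyImage
from adipoct.sift import (Keypoint, ScaleSpace, SiftConfig,
                          assign_orientations, build_scale_space,
                          compute_descriptor, detect_and_describe,
                          detect_extrema, gaussian_blur,
                          orientation_histogram, refine_keypoint)


def gaussian_blob(shape, r0, c0, sigma, amplitude=0.8):
    rr, cc = np.indices(shape, dtype=float)
    return amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


class TestScaleSpace:
    def test_layer_sigmas_follow_the_octave_formula(self, noisy_truth):
        sp = build_scale_space(noisy_truth.image, octaves=3, n_intervals=3,
                               sigma0=1.6)
        for o in range(3):
            assert len(sp.gaussians[o]) == 6      # s + 3
            assert len(sp.dogs[o]) == 5           # s + 2
            for i in range(6):
                assert sp.sigma_abs(o, i) == pytest.approx(
                    1.6 * 2 ** (o + i / 3))

    def test_octave_base_is_decimation_of_previous(self, noisy_truth):
        sp = build_scale_space(noisy_truth.image, octaves=3)
        np.testing.assert_array_equal(sp.gaussians[1][0],
                                      sp.gaussians[0][3][::2, ::2])

    def test_dog_is_adjacent_layer_difference(self, noisy_truth):
        sp = build_scale_space(noisy_truth.image, octaves=2)
        np.testing.assert_array_equal(
            sp.dogs[0][2], sp.gaussians[0][3] - sp.gaussians[0][2])

    def test_constant_image_gives_zero_dog(self):
        sp = build_scale_space(GreyImage(np.full((64, 64), 0.5)), octaves=2)
        for dog in sp.dogs:
            for layer in dog:
                assert np.abs(layer).max() < 1e-12

    def test_gaussian_semigroup_away_from_borders(self, rng):
        x = rng.random((64, 64))
        for sa, sb in [(1.6, 1.2), (2.0, 1.5)]:
            two = gaussian_blur(gaussian_blur(x, sa), sb)
            one = gaussian_blur(x, math.hypot(sa, sb))
            m = 24  # exclude the replicated-border zone
            assert np.abs(two - one)[m:-m, m:-m].max() < 1e-6

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            build_scale_space(GreyImage(np.zeros((16, 16))), octaves=4)


def brute_force_extrema(sp, border):
    hits = []
    for o, dog in enumerate(sp.dogs):
        h, w = dog[0].shape
        for i in range(1, sp.n_intervals + 1):
            for r in range(border, h - border):
                for c in range(border, w - border):
                    v = dog[i][r, c]
                    neigh = []
                    for di in (-1, 0, 1):
                        for dr in (-1, 0, 1):
                            for dc in (-1, 0, 1):
                                if di == 0 and dr == 0 and dc == 0:
                                    continue
                                neigh.append(dog[i + di][r + dr, c + dc])
                    if v > max(neigh) or v < min(neigh):
                        hits.append((o, i, r, c))
    return set(hits)


class TestDetectExtrema:
    def test_constant_image_yields_nothing(self):
        sp = build_scale_space(GreyImage(np.full((32, 32), 0.3)), octaves=1)
        assert detect_extrema(sp) == []

    def test_bright_blob_detected_near_centre(self):
        pix = np.clip(gaussian_blob((48, 48), 24, 20, 3.0), 0, 1)
        sp = build_scale_space(GreyImage(pix), octaves=2)
        kps = detect_extrema(sp, border=3)
        assert any(abs(k.row - 24) <= 1 and abs(k.col - 20) <= 1 for k in kps)

    def test_equals_brute_force_26_neighbour_scan(self, rng):
        pix = gaussian_blur(rng.random((40, 40)), 1.0)
        pix = (pix - pix.min()) / (pix.max() - pix.min())
        sp = build_scale_space(GreyImage(pix), octaves=2)
        got = {(k.octave, int(k.interval), int(k.r_oct), int(k.c_oct))
               for k in detect_extrema(sp, border=2)}
        assert got == brute_force_extrema(sp, border=2)


def quadratic_space(offset, peak=0.5, curv=(0.05, 0.04, 0.03)):
    """A fabricated 3-layer DoG stack holding one quadratic extremum at
    lattice point (8, 9) + offset; exact for second-order refinement."""
    size = 17
    rr, cc = np.indices((size, size), dtype=float)
    layers = []
    for s in range(3):
        d = peak - curv[0] * (rr - 8 - offset[0]) ** 2 \
                 - curv[1] * (cc - 9 - offset[1]) ** 2 \
                 - curv[2] * (s - 1 - offset[2]) ** 2
        layers.append(d)
    return ScaleSpace(gaussians=[[layers[0]] * 4], dogs=[layers],
                      sigma0=1.6, n_intervals=1)


class TestRefineKeypoint:
    def test_symmetric_extremum_gets_zero_offset(self):
        sp = quadratic_space((0.0, 0.0, 0.0))
        kp = Keypoint(8, 9, 1.6, 0, 1.0, 8, 9)
        out = refine_keypoint(sp, kp, contrast_T=0.04, n_intervals=1)
        assert out is not None
        assert (out.r_oct, out.c_oct) == (8.0, 9.0)

    @pytest.mark.parametrize("offset", [(0.2, -0.3, 0.1), (-0.4, 0.25, -0.35)])
    def test_recovers_analytic_subpixel_offset(self, offset):
        sp = quadratic_space(offset)
        kp = Keypoint(8, 9, 1.6, 0, 1.0, 8, 9)
        out = refine_keypoint(sp, kp, contrast_T=0.04, n_intervals=1)
        assert out is not None
        assert out.r_oct == pytest.approx(8 + offset[0], abs=1e-9)
        assert out.c_oct == pytest.approx(9 + offset[1], abs=1e-9)
        assert out.interval == pytest.approx(1 + offset[2], abs=1e-9)

    def test_low_contrast_cut_is_T_over_n_intervals(self):
        # |D̂| just below 0.04/3 must be rejected; just above survives
        # the contrast test (a flat quadratic also passes the edge test
        # because its spatial Hessian is isotropic)
        for peak, expect_kept in [(0.0132, False), (0.0135, True)]:
            sp = quadratic_space((0.0, 0.0, 0.0), peak=peak)
            kp = Keypoint(8, 9, 1.6, 0, 1.0, 8, 9)
            out = refine_keypoint(sp, kp, contrast_T=0.04, n_intervals=3)
            assert (out is not None) == expect_kept

    def test_edge_like_hessian_rejected(self):
        # strongly anisotropic curvature: a ridge, not a corner
        sp = quadratic_space((0.0, 0.0, 0.0), curv=(0.5, 0.001, 0.03))
        kp = Keypoint(8, 9, 1.6, 0, 1.0, 8, 9)
        assert refine_keypoint(sp, kp, edge_r=10.0) is None


class TestOrientation:
    def make_space_with_kp(self, pix):
        sp = build_scale_space(GreyImage(pix), octaves=1)
        kp = Keypoint(24, 24, sp.sigma_abs(0, 1), 0, 1.0, 24, 24, response=0.1)
        return sp, kp

    def test_left_to_right_ramp_points_along_plus_x(self):
        ramp = np.tile(np.linspace(0, 1, 48), (48, 1))
        sp, kp = self.make_space_with_kp(ramp)
        oriented = assign_orientations(sp, kp)
        assert len(oriented) >= 1
        deg = math.degrees(oriented[0].orientation)
        assert min(deg, 360 - deg) <= 10.0  # within one 10° bin of 0°

    def test_quarter_rotation_shifts_main_orientation_90_degrees(self, rng):
        patch = gaussian_blur(rng.random((48, 48)), 1.5)
        patch = (patch - patch.min()) / (patch.max() - patch.min())
        sp1, kp1 = self.make_space_with_kp(patch)
        # rot90 maps (r,c) -> (n-1-c, r): pure relabelling, no resampling
        sp2, kp2 = self.make_space_with_kp(np.rot90(patch, k=-1))
        kp2.r_oct, kp2.c_oct = kp1.c_oct, 48 - 1 - kp1.r_oct
        a1 = assign_orientations(sp1, kp1)[0].orientation
        a2 = assign_orientations(sp2, kp2)[0].orientation
        diff = math.degrees((a2 - a1) % (2 * math.pi))
        assert min(abs(diff - 270), abs(diff - 270 + 360)) <= 10.0

    def test_histogram_matches_direct_summation(self, rng):
        patch = gaussian_blur(rng.random((48, 48)), 1.2)
        patch = (patch - patch.min()) / (patch.max() - patch.min())
        sp, kp = self.make_space_with_kp(patch)
        hist = orientation_histogram(sp, kp)
        layer = sp.gaussians[0][1]
        sig_rel = kp.sigma
        radius = round(3 * 1.5 * sig_rel)
        want = np.zeros(36)
        for r in range(24 - radius, 24 + radius + 1):
            for c in range(24 - radius, 24 + radius + 1):
                if (r - 24) ** 2 + (c - 24) ** 2 > radius**2:
                    continue
                dr = layer[r + 1, c] - layer[r - 1, c]
                dc = layer[r, c + 1] - layer[r, c - 1]
                mag = math.hypot(dr, dc)
                ang = math.atan2(-dr, dc) % (2 * math.pi)
                w = math.exp(-((r - 24) ** 2 + (c - 24) ** 2)
                             / (2 * (1.5 * sig_rel) ** 2))
                b = min(int(ang / (2 * math.pi / 36)), 35)
                want[b] += mag * w
        np.testing.assert_allclose(hist, want, rtol=1e-9, atol=1e-12)

    def test_flat_patch_rejected(self):
        sp, kp = self.make_space_with_kp(np.full((48, 48), 0.5))
        assert assign_orientations(sp, kp) == []


class TestDescriptor:
    def test_unit_norm_128_components(self, noisy_truth):
        kps, desc = detect_and_describe(noisy_truth.image)
        assert len(kps) > 0
        assert desc.shape[1] == 128
        np.testing.assert_allclose(np.linalg.norm(desc, axis=1), 1.0,
                                   atol=1e-6)
        assert desc.min() >= 0.0

    def test_clip_at_02_then_renormalise(self, noisy_truth):
        # the default descriptor must equal: take the unclipped unit
        # vector, clip components at 0.2, renormalise
        sp = build_scale_space(noisy_truth.image)
        kps = detect_extrema(sp)
        refined = next(k for k in (refine_keypoint(sp, k) for k in kps)
                       if k is not None)
        okp = assign_orientations(sp, refined)[0]
        unclipped = compute_descriptor(sp, okp, clip=np.inf)
        manual = np.minimum(unclipped, 0.2)
        manual /= np.linalg.norm(manual)
        np.testing.assert_allclose(compute_descriptor(sp, okp), manual,
                                   atol=1e-12)
        assert unclipped.max() > 0.2  # the clip actually engages here

    def test_quarter_rotated_copy_yields_close_descriptor(self, rng):
        patch = gaussian_blur(rng.random((64, 64)), 1.5)
        patch = (patch - patch.min()) / (patch.max() - patch.min())
        kps1, d1 = detect_and_describe(GreyImage(patch), SiftConfig(octaves=1))
        kps2, d2 = detect_and_describe(GreyImage(np.rot90(patch, k=-1)),
                                       SiftConfig(octaves=1))
        assert len(kps1) and len(kps2)
        n = 64
        paired = 0
        for i, k in enumerate(kps1):
            for j, k2 in enumerate(kps2):
                if abs(k2.row - k.col) < 1.0 and abs(k2.col - (n - 1 - k.row)) < 1.0:
                    if np.linalg.norm(d1[i] - d2[j]) <= 0.2:
                        paired += 1
                        break
        assert paired >= max(1, len(kps1) // 2)


class TestPipeline:
    def test_keypoint_count_monotone_through_culling(self, noisy_truth):
        sp = build_scale_space(noisy_truth.image)
        raw = detect_extrema(sp)
        refined = [k for k in (refine_keypoint(sp, k) for k in raw)
                   if k is not None]
        oriented = [o for k in refined for o in assign_orientations(sp, k)]
        assert len(refined) <= len(raw)
        assert len(oriented) <= 2 * len(refined)

    def test_scale_covariance_under_downsampling(self):
        from adipoct.phantom import PhantomSpec, make_phantom

        t = make_phantom(PhantomSpec(rng_seed=3, shape_seed=3))
        kps, _ = detect_and_describe(t.image)
        small = GreyImage(t.image.pixels[::2, ::2])
        kps2, _ = detect_and_describe(small)
        hits = sum(
            1 for k in kps2
            if any(abs(k.row * 2 - K.row) < 3 and abs(k.col * 2 - K.col) < 3
                   and 1.2 < K.sigma / k.sigma < 3.4 for K in kps))
        assert hits >= 0.5 * len(kps2)

    def test_full_determinism(self, noisy_truth):
        kps1, d1 = detect_and_describe(noisy_truth.image)
        kps2, d2 = detect_and_describe(noisy_truth.image)
        assert [(k.row, k.col, k.sigma, k.orientation) for k in kps1] \
            == [(k.row, k.col, k.sigma, k.orientation) for k in kps2]
        np.testing.assert_array_equal(d1, d2)
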