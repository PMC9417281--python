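"""Curvature-sign (binary DoG) separation: sign mask, contour averaging,
FFT overlap scanning and affine template fitting."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from conftest import coarse_search, iou
from nanoshape.binarydog import (
    AffineSearch,
    align_rotation,
    average_contour,
    compute_binary_dog,
    fft_overlap_scan,
    fit_templates,
)
from nanoshape.contours import (
    centroid,
    radius_profile,
    resample,
    signed_area,
    transform,
)
from nanoshape.image import GrayImage
from nanoshape.synthetic import make_aggregate_scene, make_contour, render_scene


class TestComputeBinaryDog:
    def test_constant_image_empty_mask(self):
        img = GrayImage(np.full((64, 64), 0.6))
        bd = compute_binary_dog(img, sigma=2.0)
        assert not bd.mask.any()

    def test_dark_step_mask_band_at_edge(self):
        """A dark half-plane in a bright field: the DoG changes sign at the
        step, so the particle-sign mask covers the dark side near the edge
        and nothing beyond ~3 sigma on the bright side."""
        px = np.ones((64, 128))
        px[:, 64:] = 0.2
        bd = compute_binary_dog(GrayImage(px, modality="bright_field"), sigma=3.0)
        assert bd.mask[:, 66:74].all()  # dark side of the edge
        assert not bd.mask[:, : 64 - 10].any()  # bright side beyond 3 sigma

    def test_rendered_dome_disk_mask_covers_contour(self):
        disk = make_contour("ellipse", 60) + 64
        sc = render_scene([disk], image_shape=(128, 128), noise_sd=0.0)
        bd = compute_binary_dog(sc.image, sigma=3.0)
        pts = resample(disk, 200)
        ij = np.rint(pts).astype(int)
        covered = bd.mask[ij[:, 1], ij[:, 0]].mean()
        assert covered >= 0.95

    def test_parameter_validation(self):
        img = GrayImage(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            compute_binary_dog(img, sigma=0.0)
        with pytest.raises(ValueError):
            compute_binary_dog(img, sigma=1.0, ratio=0.9)


class TestAverageContour:
    def test_identity_for_rotated_copies(self):
        """Averaging rotated copies of one hexagon returns that hexagon
        (Hausdorff < 1e-2 after alignment)."""
        from scipy.spatial.distance import directed_hausdorff

        rng = np.random.default_rng(1)
        hexc = make_contour("hexagon", 2.0)
        copies = [transform(hexc, rotation=r) for r in rng.uniform(0, 2 * np.pi, 8)]
        t = average_contour(copies, M=360, class_label="hex")
        assert t.symmetry_order == 6
        u = resample(hexc / np.sqrt(signed_area(hexc)), 360)
        u = u - centroid(u)
        shift = align_rotation(radius_profile(u, 1440),
                               radius_profile(t.contour, 1440))
        ua = transform(u, rotation=shift)
        h = max(directed_hausdorff(ua, t.contour)[0],
                directed_hausdorff(t.contour, ua)[0])
        assert h < 1e-2

    def test_noise_averages_out(self):
        """i.i.d. radial noise (3% sd) averages down to < 1% mean radial
        error at N = 50."""
        rng = np.random.default_rng(2)
        base = make_contour("hexagon", 2.0, n_points=360)
        noisy = []
        for _ in range(50):
            r = 1.0 + rng.normal(0, 0.03, len(base))
            noisy.append(transform(base * r[:, None],
                                   rotation=rng.uniform(0, 2 * np.pi)))
        t = average_contour(noisy, M=360, class_label="hex")
        u = resample(base / np.sqrt(signed_area(base)), 360)
        u = u - centroid(u)
        shift = align_rotation(radius_profile(u, 1440),
                               radius_profile(t.contour, 1440))
        ua = transform(u, rotation=shift)
        prof_t = radius_profile(t.contour, 1440)
        prof_u = radius_profile(ua, 1440)
        assert np.mean(np.abs(prof_t - prof_u)) / np.mean(prof_u) < 0.01

    def test_single_contour_roundtrip(self):
        c = make_contour("rod", 3.0, aspect_ratio=1.7)
        t = average_contour([c], class_label="rod")
        assert t.source_count == 1
        assert abs(signed_area(t.contour) - 1.0) < 1e-3

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_contour([])

    def test_unit_area_invariant(self):
        for fam, ar in (("hexagon", 1.0), ("rod", 1.8), ("ellipse", 1.3)):
            t = average_contour([make_contour(fam, 7.0, aspect_ratio=ar)],
                                class_label=fam)
            assert signed_area(t.contour) == pytest.approx(1.0, abs=1e-3)


class TestFFTOverlapScan:
    def test_ring_inside_solid_mask_scores_one(self):
        ring = np.zeros((9, 9), bool)
        ring[2:7, 2:7] = True
        ring[3:6, 3:6] = False
        mask = np.ones((32, 32), bool)
        s = fft_overlap_scan(ring, mask)
        assert s.max() == pytest.approx(1.0)

    def test_empty_mask_scores_zero(self):
        ring = np.ones((5, 5), bool)
        s = fft_overlap_scan(ring, np.zeros((16, 16), bool))
        np.testing.assert_allclose(s, 0.0)

    def test_matches_direct_correlation_on_random_instances(self):
        """FFT scan equals the direct (non-FFT) sliding overlap count on
        random 64x64 instances to 1e-9."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ring = rng.random((rng.integers(4, 16), rng.integers(4, 16))) > 0.5
            if not ring.any():
                ring[0, 0] = True
            mask = rng.random((64, 64)) > rng.uniform(0.3, 0.7)
            fft_scores = fft_overlap_scan(ring, mask)
            direct = correlate2d(mask.astype(float), ring.astype(float),
                                 mode="full") / ring.sum()
            assert np.abs(fft_scores - direct).max() < 1e-9


class TestFitTemplates:
    def test_single_hexagon_fit(self):
        scene = make_aggregate_scene(
            seed=3, image_shape=(220, 220), n_isolated=1, n_touching_pairs=0,
            n_connected_pairs=0, n_triples=0,
            family_specs=[("hexagon", "hexagon", 60.0, 1.03)],
        )
        bd = compute_binary_dog(scene.image, sigma=3.0)
        tmpl = average_contour([make_contour("hexagon", 1.0, aspect_ratio=1.03)],
                               class_label="hexagon")
        fits = fit_templates(bd, [tmpl], np.pi * 30**2, search=coarse_search(),
                             score_min=0.85)
        assert len(fits) == 1
        truth_c = centroid(scene.truth_contours[0])
        assert np.hypot(*(np.array(fits[0].translation) - truth_c)) < 2.0
        assert fits[0].score >= 0.85
        assert iou(fits[0].fitted_contour, scene.truth_contours[0]) >= 0.8

    def test_touching_pair_two_fits(self):
        scene = make_aggregate_scene(
            seed=4, image_shape=(300, 300), n_isolated=0, n_touching_pairs=1,
            n_connected_pairs=0, n_triples=0,
            family_specs=[("hexagon", "hexagon", 60.0, 1.03)],
        )
        bd = compute_binary_dog(scene.image, sigma=3.0)
        tmpl = average_contour([make_contour("hexagon", 1.0, aspect_ratio=1.03)],
                               class_label="hexagon")
        fits = fit_templates(bd, [tmpl], np.pi * 30**2, search=coarse_search(),
                             score_min=0.85)
        assert len(fits) == 2
        matched = set()
        for f in fits:
            ious = [iou(f.fitted_contour, tc) for tc in scene.truth_contours]
            best = int(np.argmax(ious))
            assert ious[best] >= 0.8
            matched.add(best)
        assert matched == {0, 1}

    def test_mismatched_template_rejected(self):
        """A rod template cannot reach a high two-sided score on a
        hexagons-only scene."""
        scene = make_aggregate_scene(
            seed=5, image_shape=(220, 220), n_isolated=1, n_touching_pairs=0,
            n_connected_pairs=0, n_triples=0,
            family_specs=[("hexagon", "hexagon", 60.0, 1.03)],
        )
        bd = compute_binary_dog(scene.image, sigma=3.0)
        rod = average_contour([make_contour("rod", 1.0, aspect_ratio=1.76)],
                              class_label="rod")
        fits = fit_templates(bd, [rod], np.pi * 30**2, search=coarse_search(),
                             score_min=0.9, outer_min=0.8)
        assert fits == []

    def test_empty_mask_empty_result(self):
        from nanoshape.binarydog import BinaryDoGImage

        bd = BinaryDoGImage(np.zeros((64, 64), bool), 2.0, 1.6)
        tmpl = average_contour([make_contour("hexagon", 1.0)], class_label="h")
        assert fit_templates(bd, [tmpl], 400.0) == []

    def test_scores_bounded_and_fits_disjoint(self, aggregate_run):
        fits = aggregate_run["fits"]
        assert fits, "aggregate scene produced no fits"
        for f in fits:
            assert 0.0 <= f.score <= 1.0
            assert 0.0 <= f.outer_score <= 1.0
        for i, a in enumerate(fits):
            for b in fits[i + 1:]:
                assert iou(a.fitted_contour, b.fitted_contour) <= 0.2 + 1e-9

    def test_noise_never_improves_mean_score(self):
        """On a fixed scene with coupled additive noise (one normalized
        draw scaled along the ladder, so mask flips are nested), the mean
        truth-placement overlap score is non-increasing in the noise sd."""
        from scipy import ndimage

        from nanoshape.binarydog import rasterize_mask
        from nanoshape.image import GrayImage

        scene = make_aggregate_scene(
            seed=6, image_shape=(300, 300), n_isolated=2,
            n_touching_pairs=1, n_connected_pairs=0, n_triples=0,
        )
        base = scene.image.pixels
        z = np.random.default_rng(0).normal(size=base.shape)
        rings = []
        for tc in scene.truth_contours:
            filled = rasterize_mask(tc, base.shape)
            rings.append(filled & ~ndimage.binary_erosion(filled, iterations=2))
        means = []
        for sd in (0.0, 0.03, 0.06, 0.12):
            img = GrayImage(base + sd * z, modality=scene.image.modality)
            mask = compute_binary_dog(img, sigma=3.0).mask
            means.append(np.mean([(r & mask).sum() / r.sum() for r in rings]))
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))
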