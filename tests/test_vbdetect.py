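"""Bundle detection: candidates, active contour, inscribed-circle split."""

import math

import numpy as np
import pytest
from scipy import ndimage

from stemsect.calibration import SliceImage
from stemsect.contours import mask_from_contour
from stemsect.phantom import PhantomSpec, generate_phantom
from stemsect.traits import DistanceModel
from stemsect.vbdetect import (CandidateObject, detect_vascular_bundles,
                               flag_merged_candidates, inner_candidates,
                               inscribed_circle_decomposition,
                               level_set_refine, periphery_candidates,
                               split_candidate)
from stemsect.zones import detect_function_zones

from conftest import disk_mask


def _img(arr, ps=0.0271):
    return SliceImage(np.asarray(arr, dtype=np.uint8), pixel_size_mm=ps)


def _dumbbell(shape=(60, 100)):
    """Two radius-8 disks joined by a 2-px-wide bridge."""
    m = disk_mask(shape, (30, 25), 8) | disk_mask(shape, (30, 75), 8)
    m[29:31, 25:75] = True
    return m


class TestInnerCandidates:
    def test_phantom_count_exact(self, clean_phantom, clean_zones):
        cands = inner_candidates(clean_phantom.image, clean_zones)
        assert len(cands) == clean_phantom.counts()["inner"]

    def test_empty_inner_zone(self, clean_zones):
        blank = _img(np.zeros(clean_zones.inner_mask.shape))
        assert inner_candidates(blank, clean_zones) == []

    def test_diagonal_touch_is_one_candidate(self, clean_zones):
        a = np.zeros(clean_zones.inner_mask.shape)
        cy, cx = (int(v) for v in clean_zones.stem_center)
        a[cy - 3:cy, cx - 3:cx] = 100      # two blocks meeting at a corner
        a[cy:cy + 3, cx:cx + 3] = 100
        cands = inner_candidates(_img(a), clean_zones)
        assert len(cands) == 1


class TestLevelSetRefine:
    def test_recovers_sharp_disk_from_dilated_init(self):
        true = disk_mask((80, 80), (40, 40), 15)
        img = _img(np.where(true, 180, 10))
        init = ndimage.binary_dilation(true, iterations=4)
        contour = level_set_refine(img, init)
        result = mask_from_contour(contour, (80, 80))
        # symmetric Hausdorff distance via distance transforms
        d1 = ndimage.distance_transform_edt(~true)[result & ~true]
        d2 = ndimage.distance_transform_edt(~result)[true & ~result]
        h = max(d1.max() if d1.size else 0, d2.max() if d2.size else 0)
        assert h <= 1.5

    def test_fixed_point_on_step_edge(self):
        true = disk_mask((80, 80), (40, 40), 15)
        img = _img(np.where(true, 180, 10))
        contour = level_set_refine(img, true.copy())
        result = mask_from_contour(contour, (80, 80))
        assert (result ^ true).sum() <= 0.1 * true.sum()

    def test_blurred_disk_area_within_10pct(self):
        from scipy.ndimage import gaussian_filter
        true = disk_mask((80, 80), (40, 40), 15)
        blurred = gaussian_filter(np.where(true, 180.0, 10.0), 2.0)
        init = ndimage.binary_dilation(true, iterations=3)
        contour = level_set_refine(_img(blurred), init)
        assert abs(contour.area_px - true.sum()) / true.sum() < 0.10

    def test_init_without_foreground_rejected(self):
        img = _img(np.zeros((40, 40)))
        with pytest.raises(ValueError, match="foreground"):
            level_set_refine(img, disk_mask((40, 40), (20, 20), 5))


class TestInscribedCircles:
    def test_disk_first_circle_at_center(self):
        circles = inscribed_circle_decomposition(disk_mask((40, 40), (20, 20), 10))
        assert abs(circles[0].radius_px - 10) <= 0.5
        assert math.hypot(circles[0].center[0] - 20,
                          circles[0].center[1] - 20) <= 1.5

    def test_thin_rectangle_radii_bounded_by_half_width(self):
        m = np.zeros((20, 60), bool)
        m[7:13, 10:50] = True  # 40 x 6 rectangle
        circles = inscribed_circle_decomposition(m)
        assert circles, "half-width 3 must yield at least one circle"
        assert abs(circles[0].radius_px - 3) <= 0.5
        assert all(c.radius_px <= 3.5 for c in circles)

    def test_dumbbell_lobes_found_first(self):
        circles = inscribed_circle_decomposition(_dumbbell())
        r0, r1 = circles[0], circles[1]
        assert abs(r0.radius_px - 8) <= 0.5 and abs(r1.radius_px - 8) <= 0.5
        lobes = sorted([r0.center[1], r1.center[1]])
        assert abs(lobes[0] - 25) <= 1.5 and abs(lobes[1] - 75) <= 1.5

    def test_invariants_radii_decrease_and_inside(self):
        region = _dumbbell()
        circles = inscribed_circle_decomposition(region)
        radii = [c.radius_px for c in circles]
        assert radii == sorted(radii, reverse=True)
        yy, xx = np.indices(region.shape)
        for c in circles:
            inside = (yy - c.center[0]) ** 2 + (xx - c.center[1]) ** 2 \
                <= (c.radius_px - 1.0) ** 2
            assert (region | ~inside).all()  # circle interior ⊆ region


class TestSplitCandidate:
    def test_single_disk_returned_whole(self):
        region = disk_mask((40, 40), (20, 20), 10)
        parts = split_candidate(region,
                                inscribed_circle_decomposition(region))
        assert len(parts) == 1
        assert parts[0].area_px == region.sum()

    def test_dumbbell_splits_into_two_equal_lobes(self):
        region = _dumbbell()
        parts = split_candidate(region,
                                inscribed_circle_decomposition(region))
        assert len(parts) == 2
        lobe = disk_mask(region.shape, (30, 25), 8).sum()
        for p in parts:
            assert abs(p.area_px - region.sum() / 2) / lobe < 0.3

    def test_split_conserves_pixels(self):
        region = _dumbbell()
        parts = split_candidate(region,
                                inscribed_circle_decomposition(region))
        assert sum(p.area_px for p in parts) == region.sum()

    def test_empty_circles_returns_whole_with_warning(self):
        region = disk_mask((20, 20), (10, 10), 4)
        with pytest.warns(UserWarning, match="whole"):
            parts = split_candidate(region, [])
        assert len(parts) == 1

    def test_three_fused_ellipses_recover_centers(self):
        # three ellipses around a point, just touching: one candidate blob
        from skimage import draw
        region = np.zeros((120, 120), bool)
        centers = []
        for ang in (math.pi / 2, math.pi / 2 + 2 * math.pi / 3,
                    math.pi / 2 + 4 * math.pi / 3):
            cy = 60 + 9.0 * math.sin(ang)
            cx = 60 + 9.0 * math.cos(ang)
            rr, cc = draw.ellipse(cy, cx, 8, 6.5, shape=region.shape,
                                  rotation=ang)
            region[rr, cc] = True
            centers.append((cy, cx))
        labels, n = ndimage.label(region, structure=np.ones((3, 3), int))
        assert n == 1, "construction must be a single fused blob"
        parts = split_candidate(region, inscribed_circle_decomposition(region))
        assert len(parts) == 3
        for cy, cx in centers:
            d = min(math.hypot(p.centroid[0] - cy, p.centroid[1] - cx)
                    for p in parts)
            assert d <= 3.0

    def test_phantom_pair_clumps_split_exactly(self):
        # deliberately fused pairs rendered by the generator must resolve
        ph = generate_phantom(PhantomSpec(seed=24, noise_sd=0,
                                          fusion_fraction=0.15))
        pairs = [c for c in ph.clumps if len(c) == 2]
        assert pairs
        img = ph.image.pixels
        labels, _ = ndimage.label(img == 160, structure=np.ones((3, 3), int))
        exact = 0
        for clump in pairs:
            members = [ph.bundles[i] for i in clump]
            lbls = {labels[int(round(b.center[0])), int(round(b.center[1]))]
                    for b in members}
            region = np.isin(labels, [l for l in lbls if l > 0])
            parts = split_candidate(region,
                                    inscribed_circle_decomposition(region))
            exact += len(parts) == 2
        assert exact >= 0.8 * len(pairs)


class TestFlagMerged:
    def _model(self):
        return DistanceModel(trait="area", a=0.129, b=5.594e-4, c=0.475,
                             residual_sigma=0.005)

    def _cand(self, dc, area_mm2, ps=0.0271):
        area_px = max(int(round(area_mm2 / ps ** 2)), 10)
        r = math.sqrt(area_px / math.pi)
        mask = disk_mask((200, 200), (100, 100), r)
        from stemsect.contours import contour_from_filled
        c = contour_from_filled(mask)
        return CandidateObject(contour=c, zone="periphery", mask=mask,
                               distance_to_center_mm=dc)

    def test_on_curve_candidate_unflagged(self):
        m = self._model()
        cand = self._cand(5.0, float(m.predict(5.0)))
        flag_merged_candidates([cand], m, 0.0271)
        assert not cand.merged_flag

    def test_far_outlier_flagged(self):
        m = self._model()
        cand = self._cand(5.0, float(m.predict(5.0)) + 10 * m.residual_sigma)
        flag_merged_candidates([cand], m, 0.0271)
        assert cand.merged_flag

    def test_no_model_leaves_unflagged_with_warning(self):
        cand = self._cand(5.0, 0.5)
        with pytest.warns(UserWarning, match="unflagged"):
            flag_merged_candidates([cand], None, 0.0271)
        assert not cand.merged_flag

    def test_phantom_fusions_mostly_flagged(self):
        ph = generate_phantom(PhantomSpec(seed=31, noise_sd=5,
                                          fusion_fraction=0.06))
        z = detect_function_zones(ph.image)
        from stemsect.traits import fit_distance_model
        cands = periphery_candidates(z.adaptive_mask, z,
                                     ph.image.pixel_size_mm)
        samples = [(c.distance_to_center_mm,
                    c.contour.area_px * ph.image.pixel_size_mm ** 2)
                   for c in cands]
        model = fit_distance_model(samples, "area")
        flag_merged_candidates(cands, model, ph.image.pixel_size_mm)
        clump_centers = []
        for clump in ph.clumps:
            pts = np.array([ph.bundles[i].center for i in clump])
            clump_centers.append(pts.mean(axis=0))
        hit = 0
        for cc in clump_centers:
            for c in cands:
                if c.merged_flag and c.mask[int(round(cc[0])), int(round(cc[1]))]:
                    hit += 1
                    break
        assert hit >= math.ceil(0.8 * len(clump_centers))


class TestDetectEndToEnd:
    def test_clean_phantom_count_exact(self, clean_phantom, clean_bundles):
        assert len(clean_bundles) == clean_phantom.counts()["total"]
        by_zone = {"inner": 0, "periphery": 0}
        for b in clean_bundles:
            by_zone[b.zone] += 1
        assert by_zone["inner"] == clean_phantom.counts()["inner"]
        assert by_zone["periphery"] == clean_phantom.counts()["periphery"]

    def test_blank_image_empty(self, clean_zones):
        import dataclasses
        blank = _img(np.zeros(clean_zones.inner_mask.shape))
        # zone geometry from a real slice, but nothing to segment
        z = dataclasses.replace(clean_zones, adaptive_mask=None)
        assert detect_vascular_bundles(blank, z) == []

    def test_bundle_masks_pairwise_disjoint(self, noisy_bundles):
        total = None
        count = 0
        for b in noisy_bundles:
            count += b.mask.sum()
            total = b.mask if total is None else (total | b.mask)
        assert count == total.sum()
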