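import math
from dataclasses import replace

import numpy as np
import pytest

from topoimage import compute_h0, synthetic, tim, tip


class TestSelectThreshold:
    def test_hand_enumerated_gaps(self):
        r = tip.select_threshold([10, 9.5, 4, 3.8, 3.5])
        assert r.largest_gap == pytest.approx(5.5)
        assert r.tau == pytest.approx(6.75)
        assert r.n_selected == 2
        assert r.mean_gap == pytest.approx(1.625)
        assert r.stability_ratio == pytest.approx(5.5 / 1.625)
        assert r.low_contrast  # 3.38 < 4

    def test_single_lifetime_selected_with_infinite_ratio(self):
        r = tip.select_threshold([7.0])
        assert r.n_selected == 1
        assert math.isinf(r.stability_ratio)
        assert not r.low_contrast

    def test_all_equal_lifetimes_select_all(self):
        r = tip.select_threshold([5.0, 5.0, 5.0])
        assert r.n_selected == 3
        assert r.stability_ratio == 0.0
        assert r.low_contrast

    def test_order_invariant(self):
        a = tip.select_threshold([3.5, 10, 3.8, 9.5, 4])
        b = tip.select_threshold([10, 9.5, 4, 3.8, 3.5])
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tip.select_threshold([])


class TestMarkObjects:
    @staticmethod
    def two_blob_image():
        img = np.full((12, 12), 0.9)
        img[2:5, 2:5] = 0.1
        img[7:10, 6:10] = 0.2
        img[7, 2] = 0.85  # a shallow dimple: short-lived clutter below the gap
        return tim.border_modify(img, 1)

    def test_two_interior_blobs_marked_exactly(self):
        img = self.two_blob_image()
        d = compute_h0(img)
        thr = tip.select_threshold(d.finite_lifetimes())
        marking = tip.mark_objects(img, d, thr.tau)
        assert len(marking) == 2
        masks = sorted(marking.masks, key=lambda m: m.sum())
        blob1 = np.zeros((12, 12), dtype=bool)
        blob1[2:5, 2:5] = True
        blob2 = np.zeros((12, 12), dtype=bool)
        blob2[7:10, 6:10] = True
        found = {tuple(np.argwhere(m)[0]) for m in masks}
        assert np.array_equal(masks[0] | masks[1], blob1 | blob2)
        assert not (masks[0] & masks[1]).any()

    def test_masks_contain_birth_pixels(self):
        img = self.two_blob_image()
        d = compute_h0(img)
        marking = tip.mark_objects(img, d, tip.select_threshold(d.finite_lifetimes()).tau)
        for mask, point in zip(marking.masks, marking.points):
            assert mask[point.birth_pixel]

    def test_tau_above_all_lifetimes_empty_marking(self):
        img = self.two_blob_image()
        d = compute_h0(img)
        marking = tip.mark_objects(img, d, tau=10.0)
        assert len(marking) == 0

    def test_no_finite_points_is_an_error(self):
        d = compute_h0(np.full((5, 5), 0.5))
        with pytest.raises(ValueError):
            tip.mark_objects(np.full((5, 5), 0.5), d, 0.1)


class TestIdwFill:
    @staticmethod
    def marking_from(masks):
        return tip.ObjectMarking(
            masks=list(masks), points=[], tau=0.0, extraction_level=0.0
        )

    def test_single_component_copies_nearest_value(self):
        img = np.linspace(0, 1, 25).reshape(5, 5)
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        out = tip.idw_fill(img, self.marking_from([mask]))
        assert np.allclose(out, img[2, 2])

    def test_equidistant_pixel_averages_two_components(self):
        img = np.zeros((1, 5))
        img[0, 0], img[0, 4] = 0.2, 0.8
        m1 = np.zeros((1, 5), dtype=bool)
        m1[0, 0] = True
        m2 = np.zeros((1, 5), dtype=bool)
        m2[0, 4] = True
        for power in (0.5, 1.0, 2.0, 3.0):
            out = tip.idw_fill(img, self.marking_from([m1, m2]), power=power)
            assert out[0, 2] == pytest.approx(0.5, abs=1e-9)

    def test_hand_computed_weights(self):
        # distances 1 and 2 to components valued 0.2 and 0.8 at power 2
        img = np.zeros((1, 4))
        img[0, 0], img[0, 3] = 0.2, 0.8
        m1 = np.zeros((1, 4), dtype=bool)
        m1[0, 0] = True
        m2 = np.zeros((1, 4), dtype=bool)
        m2[0, 3] = True
        out = tip.idw_fill(img, self.marking_from([m1, m2]), power=2.0)
        assert out[0, 1] == pytest.approx((0.2 * 1 + 0.8 * 0.25) / 1.25, abs=1e-9)

    def test_marked_pixels_keep_modified_values(self, rng):
        img = rng.random((8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        out = tip.idw_fill(img, self.marking_from([mask]))
        assert np.array_equal(out[mask], img[mask])

    def test_background_values_within_component_range(self, rng):
        img = rng.random((10, 10))
        m1 = np.zeros((10, 10), dtype=bool)
        m1[1:3, 1:3] = True
        m2 = np.zeros((10, 10), dtype=bool)
        m2[7:9, 6:9] = True
        out = tip.idw_fill(img, self.marking_from([m1, m2]))
        src = np.concatenate([img[m1], img[m2]])
        bg = ~(m1 | m2)
        assert out[bg].min() >= src.min() - 1e-12
        assert out[bg].max() <= src.max() + 1e-12

    def test_empty_marking_is_an_error(self):
        with pytest.raises(ValueError):
            tip.idw_fill(np.zeros((3, 3)), self.marking_from([]))


class TestProcess:
    def test_lesion_fixture_marks_single_interior_lesion(self, lesion_fixture):
        img, truth = lesion_fixture
        res = tip.process(img, seed=0)
        assert res.status == "ok"
        assert len(res.marking) == 1
        cy, cx = np.argwhere(truth).mean(axis=0).astype(int)
        assert res.marking.masks[0][cy, cx]

    def test_masks_never_touch_border_band(self, lesion_fixture):
        img, _ = lesion_fixture
        res = tip.process(img, seed=0)
        band = tim.band_mask(img.shape, res.params.l)
        assert not (res.marking.union() & band).any()

    def test_flat_image_reports_no_objects(self):
        res = tip.process(np.full((32, 32), 0.5), params=tim.TimParams(k=3, l=2, sigma=0.0))
        assert res.status == "no objects"
        assert len(res.marking) == 0

    def test_deterministic_given_seed(self, lesion_fixture):
        img, _ = lesion_fixture
        a = tip.process(img, seed=3)
        b = tip.process(img, seed=3)
        assert np.array_equal(a.values, b.values)
        assert a.threshold == b.threshold

    def test_two_lobed_lesion_marks_two_objects(self):
        img, _ = synthetic.lesion_scene(seed=0, two_lobed=True)
        res = tip.process(img, seed=0)
        assert len(res.marking) == 2
        assert not (res.marking.masks[0] & res.marking.masks[1]).any()

    def test_low_contrast_flag_raised_and_cleared(self):
        lo = synthetic.low_contrast_scene(seed=0)
        hi = synthetic.low_contrast_scene(seed=0, contrast=0.2)
        p = replace(tim.default_params(lo), sigma=0.0)
        assert tip.process(lo, params=p).low_contrast
        assert not tip.process(hi, params=p).low_contrast

    def test_processing_time_scales_near_linearly(self):
        # empirical slope of runtime vs pixel count stays well below quadratic
        import time

        times, sizes = [], [64, 128, 256]
        for s in sizes:
            img, _ = synthetic.lesion_scene(
                spec=synthetic.SceneSpec(
                    size=(s, s), lesion_radii=(s * 0.18, s * 0.14)
                ),
            )
            t0 = time.perf_counter()
            tip.process(img, seed=0)
            times.append(time.perf_counter() - t0)
        slope = np.polyfit(np.log([s * s for s in sizes]), np.log(times), 1)[0]
        assert slope < 1.6
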