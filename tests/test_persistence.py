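import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import minimum_filter

from topoimage import (
    Diagram,
    PersistencePoint,
    betti_curve_oracle,
    bottleneck_distance,
    compute_h0,
    compute_h1,
)


def random_image(seed: int, shape=(12, 12)) -> np.ndarray:
    return np.random.default_rng(seed).random(shape)


class TestH0:
    def test_three_pixel_strip(self):
        d = compute_h0(np.array([[0.2, 0.8, 0.3]]))
        pairs = sorted((p.birth, p.death) for p in d.points)
        assert pairs == [(0.2, math.inf), (0.3, 0.8)]

    def test_constant_image_single_immortal_component(self):
        d = compute_h0(np.full((5, 7), 0.4))
        assert [(p.birth, p.death) for p in d.points] == [(0.4, math.inf)]

    def test_infinite_point_born_at_global_minimum(self, rng):
        for _ in range(20):
            img = rng.random((10, 11))
            d = compute_h0(img)
            inf_pts = d.infinite
            assert len(inf_pts) == 1
            assert inf_pts[0].birth == img.min()
            assert img[inf_pts[0].birth_pixel] == img.min()

    def test_point_count_equals_local_minima(self, rng):
        # with unique values a component is born exactly at each strict local
        # minimum of the 8-neighbourhood
        for _ in range(10):
            img = rng.permutation(100).reshape(10, 10) / 100.0
            d = compute_h0(img)
            minima = int((img == minimum_filter(img, size=3, mode="reflect")).sum())
            assert len(d.points) == minima

    def test_elder_rule_killer_is_born_earlier(self, rng):
        img = rng.random((12, 12))
        d = compute_h0(img)
        births = sorted(p.birth for p in d.points)
        for p in d.finite:
            # the component that absorbed p was born no later than p
            assert any(b <= p.birth for b in births if b != p.birth) or p.birth == births[0]
            assert p.death >= p.birth

    def test_monotone_relabeling_preserves_pairing(self, rng):
        img = rng.random((10, 10))
        d1 = compute_h0(img)
        d2 = compute_h0(np.exp(2.0 * img))  # strictly increasing map
        assert len(d1) == len(d2)
        key = lambda p: (p.birth_pixel, p.death_pixel)
        for a, b in zip(sorted(d1.points, key=key), sorted(d2.points, key=key)):
            assert a.birth_pixel == b.birth_pixel
            assert a.death_pixel == b.death_pixel
            assert b.birth == pytest.approx(math.exp(2.0 * a.birth))

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError):
            compute_h0(np.array([[0.1, np.nan]]))


class TestH1:
    def test_constant_image_has_no_holes(self):
        assert len(compute_h1(np.full((6, 6), 0.3))) == 0

    def test_dark_annulus_single_hole(self):
        img = np.full((11, 11), 0.9)
        img[3:8, 3:8] = 0.1
        img[4:7, 4:7] = 0.9
        d = compute_h1(img)
        assert [(p.birth, p.death) for p in d.points] == [(0.1, 0.9)]

    def test_double_annulus_two_holes(self):
        img = np.full((17, 9), 0.9)
        for r0 in (2, 9):
            img[r0 : r0 + 5, 2:7] = 0.1
            img[r0 + 1 : r0 + 4, 3:6] = 0.9
        d = compute_h1(img)
        assert len(d.points) == 2
        for p in d.points:
            assert (p.birth, p.death) == (0.1, 0.9)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_alive_counts_match_bfs_oracle(self, seed):
        img = random_image(seed, shape=(9 + seed % 5, 8 + seed % 7))
        d0, d1 = compute_h0(img), compute_h1(img)
        ts = np.linspace(img.min() - 0.05, img.max() + 0.05, 20)
        assert [d0.alive_count(t) for t in ts] == betti_curve_oracle(img, 0, ts)
        assert [d1.alive_count(t) for t in ts] == betti_curve_oracle(img, 1, ts)

    def test_oracle_trivial_thresholds(self, rng):
        img = rng.random((8, 8))
        assert betti_curve_oracle(img, 0, [img.min() - 1]) == [0]
        assert betti_curve_oracle(img, 0, [img.max() + 1]) == [1]
        assert betti_curve_oracle(img, 1, [img.max() + 1]) == [0]

    def test_binary_eight_glyph(self):
        # an '8' (two stacked square annuli) at a threshold above glyph value
        img = np.full((13, 9), 0.9)
        for r0 in (1, 5):  # the two annuli share a row, like a real '8'
            img[r0 : r0 + 5, 2:7] = 0.1
            img[r0 + 1 : r0 + 4, 3:6] = 0.9
        assert betti_curve_oracle(img, 0, [0.5]) == [1]
        assert betti_curve_oracle(img, 1, [0.5]) == [2]


class TestBottleneck:
    def test_identical_diagrams(self, rng):
        d = compute_h0(rng.random((8, 8)))
        assert bottleneck_distance(d, d) == 0.0

    def test_single_point_vs_empty(self):
        d1 = Diagram([PersistencePoint(0.0, 2.0, 0)], 0)
        assert bottleneck_distance(d1, Diagram([], 0)) == pytest.approx(1.0)

    def test_infinite_points_match_by_birth(self):
        d1 = Diagram(
            [PersistencePoint(0.0, 2.0, 0), PersistencePoint(0.0, math.inf, 0)], 0
        )
        d2 = Diagram(
            [PersistencePoint(0.5, 2.5, 0), PersistencePoint(0.2, math.inf, 0)], 0
        )
        assert bottleneck_distance(d1, d2) == pytest.approx(0.5)

    def test_unequal_infinite_counts_is_infinite(self):
        d1 = Diagram([PersistencePoint(0.0, math.inf, 0)], 0)
        assert bottleneck_distance(d1, Diagram([], 0)) == math.inf

    def test_mixed_dimensions_rejected(self):
        with pytest.raises(ValueError):
            bottleneck_distance(Diagram([], 0), Diagram([], 1))

    @pytest.mark.parametrize("seed", range(10))
    def test_stability_under_perturbation(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((16, 16))
        pert = img + rng.uniform(-0.05, 0.05, img.shape)
        eps = float(np.abs(img - pert).max())
        d = bottleneck_distance(compute_h0(img), compute_h0(pert))
        assert d <= eps + 1e-12

    def test_symmetry(self, rng):
        a = compute_h0(rng.random((8, 8)))
        b = compute_h0(rng.random((8, 8)))
        assert bottleneck_distance(a, b) == pytest.approx(bottleneck_distance(b, a))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_h0_invariants_property(seed):
    """One immortal component born at the minimum; elder rule on every merge."""
    img = np.random.default_rng(seed).random((8, 9))
    d = compute_h0(img)
    assert len(d.infinite) == 1
    assert d.infinite[0].birth == img.min()
    for p in d.finite:
        assert p.death >= p.birth
        assert img[p.birth_pixel] == p.birth


class TestSerialization:
    def test_csv_round_trip(self, tmp_path, rng):
        d = compute_h0(rng.random((8, 8)))
        path = tmp_path / "diagram.csv"
        d.to_csv(path)
        back = Diagram.from_csv(path)
        assert len(back) == len(d)
        orig = sorted((p.birth, p.death, p.birth_pixel) for p in d.points)
        rt = sorted((p.birth, p.death, p.birth_pixel) for p in back.points)
        for (b1, de1, bp1), (b2, de2, bp2) in zip(orig, rt):
            assert b1 == pytest.approx(b2)
            assert de1 == de2 or de1 == pytest.approx(de2)
            assert bp1 == bp2
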