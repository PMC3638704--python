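"""Co-occurrence matrices, Haralick statistics and sliding texture maps."""

import numpy as np
import pytest

from dcetex import (
    ParameterPseudoImages,
    TextureConfig,
    cooccurrence_matrix,
    haralick_stats,
    quantize_volume,
    sliding_texture_maps,
    texture_stage,
)
from dcetex.texture import STATISTIC_NAMES

from oracles import glcm_brute, haralick_brute, random_symmetric_glcm

DIRECTIONS = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


class TestQuantize:
    def test_linear_endpoints(self):
        vol = np.linspace(0, 1, 1000).reshape(10, 10, 10)
        q = quantize_volume(vol, np.ones(vol.shape, bool), 16)
        assert q[vol == vol.min()].min() == 1
        assert q[vol == vol.max()].max() == 16

    def test_constant_volume_warns_all_ones(self):
        with pytest.warns(UserWarning):
            q = quantize_volume(np.full((4, 4, 4), 3.0), np.ones((4, 4, 4), bool), 16)
        assert np.all(q == 1)

    def test_matches_digitize_oracle(self, rng):
        vol = rng.normal(size=(8, 8, 4))
        mask = np.ones(vol.shape, bool)
        G = 4
        q = quantize_volume(vol, mask, G)
        lo, hi = np.percentile(vol, [1.0, 99.0])
        edges = np.linspace(lo, hi, G + 1)
        expected = np.digitize(np.clip(vol, lo, hi), edges[1:-1], right=False) + 1
        # digitize puts values == internal edge into the upper bin; floor-binning
        # does the same, so histograms must agree exactly
        assert np.array_equal(
            np.bincount(q.ravel(), minlength=G + 2),
            np.bincount(expected.ravel(), minlength=G + 2),
        )

    def test_outside_mask_level_one(self, rng):
        vol = rng.uniform(1, 2, (6, 6, 3))
        mask = np.zeros(vol.shape, bool)
        mask[2:5, 2:5, :] = True
        q = quantize_volume(vol, mask, 8)
        assert np.all(q[~mask] == 1)


class TestCooccurrence:
    def test_constant_window_single_entry(self):
        cm = cooccurrence_matrix(np.full((5, 5, 2), 3), (1, 0, 0), 1, 16)
        assert cm.P[2, 2] == 1.0
        assert cm.P.sum() == 1.0

    def test_alternating_levels_along_x(self):
        win = np.tile(np.array([1, 2, 1, 2, 1])[:, None, None], (1, 5, 2))
        cm = cooccurrence_matrix(win, (1, 0, 0), 1, 2)
        assert cm.P[0, 1] == pytest.approx(0.5)
        assert cm.P[1, 0] == pytest.approx(0.5)
        assert cm.P[0, 0] == cm.P[1, 1] == 0.0

    def test_pair_counts_for_default_window(self):
        win = np.ones((5, 5, 2), int)
        assert cooccurrence_matrix(win, (1, 0, 0), 1, 2).pair_count == 80
        assert cooccurrence_matrix(win, (0, 0, 1), 1, 2).pair_count == 50

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            win = rng.integers(1, 9, (5, 5, 2))
            for off in DIRECTIONS:
                cm = cooccurrence_matrix(win, off, 1, 8)
                P_ref, pairs_ref = glcm_brute(win, off, 8)
                assert np.abs(cm.P - P_ref).max() < 1e-12
                assert cm.pair_count == pairs_ref

    def test_sum_one_and_symmetric(self, rng):
        for _ in range(20):
            win = rng.integers(1, 17, (5, 5, 2))
            cm = cooccurrence_matrix(win, (0, 1, 0), 1, 16)
            assert cm.P.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.array_equal(cm.P, cm.P.T)

    def test_no_valid_pair_raises(self):
        with pytest.raises(ValueError):
            cooccurrence_matrix(np.ones((5, 5, 2), int), (0, 0, 1), 5, 2)


class TestHaralick:
    def test_degenerate_single_entry(self):
        P = np.zeros((16, 16))
        P[4, 4] = 1.0
        s = dict(zip(STATISTIC_NAMES, haralick_stats(P)))
        assert s["asm"] == 1.0
        assert s["entropy"] == 0.0
        assert s["contrast"] == 0.0
        assert s["idm"] == 1.0
        assert s["variance"] == 0.0
        assert s["correlation"] == 0.0

    def test_uniform_two_level_hand_values(self):
        P = np.full((2, 2), 0.25)
        s = dict(zip(STATISTIC_NAMES, haralick_stats(P)))
        assert s["asm"] == pytest.approx(0.25)
        assert s["entropy"] == pytest.approx(2.0)
        assert s["contrast"] == pytest.approx(0.5)
        assert s["idm"] == pytest.approx(0.75)
        assert s["sum_average"] == pytest.approx(3.0)

    def test_matches_literal_formula_oracle(self, rng):
        for _ in range(50):
            P = random_symmetric_glcm(rng, 8)
            assert np.abs(haralick_stats(P) - haralick_brute(P)).max() < 1e-10

    def test_invariant_ranges(self, rng):
        G = 8
        for _ in range(30):
            s = dict(zip(STATISTIC_NAMES, haralick_stats(random_symmetric_glcm(rng, G))))
            assert 0 <= s["asm"] <= 1
            assert 0 <= s["entropy"] <= 2 * np.log2(G)
            assert 0 < s["idm"] <= 1
            assert 0 <= s["contrast"] <= (G - 1) ** 2

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            haralick_stats(np.ones((4, 4)))


class TestSlidingMaps:
    def test_map_count_per_parameter(self, rng):
        vol = rng.integers(1, 17, (10, 10, 4))
        tp = sliding_texture_maps(vol, TextureConfig())
        assert len(tp.maps) == 30

    def test_constant_volume_degenerate_maps(self):
        tp = sliding_texture_maps(np.full((8, 8, 4), 5), TextureConfig())
        v = tp.validity_mask
        assert np.all(tp.maps[("param", "asm", (1, 0, 0))][v] == 1.0)
        assert np.all(tp.maps[("param", "entropy", (0, 0, 1))][v] == 0.0)
        assert not tp.maps[("param", "asm", (1, 0, 0))][~v].any()

    def test_spot_check_against_direct_window_recomputation(self, rng):
        cfg = TextureConfig()
        vol = rng.integers(1, 17, (16, 16, 8))
        tp = sliding_texture_maps(vol, cfg)
        c = cfg.centroid
        for _ in range(5):
            pos = tuple(int(rng.integers(0, s - w + 1)) for s, w in zip(vol.shape, cfg.svoi_shape))
            win = vol[pos[0] : pos[0] + 5, pos[1] : pos[1] + 5, pos[2] : pos[2] + 2]
            cent = tuple(p + cc for p, cc in zip(pos, c))
            for d in cfg.directions:
                expected = haralick_stats(cooccurrence_matrix(win, d, 1, 16))
                got = [tp.maps[("param", s, d)][cent] for s in cfg.statistics]
                assert np.allclose(got, expected, atol=1e-12)

    def test_translation_property(self, rng):
        vol = rng.integers(1, 9, (12, 12, 6))
        cfg = TextureConfig(levels=8)
        t1 = sliding_texture_maps(vol, cfg)
        t2 = sliding_texture_maps(np.roll(vol, 1, axis=0), cfg)
        common = t1.validity_mask & np.roll(t1.validity_mask, 1, axis=0)
        for key in t1.maps:
            shifted = np.roll(t1.maps[key], 1, axis=0)
            assert np.allclose(shifted[common], t2.maps[key][common])

    def test_volume_smaller_than_svoi_raises(self):
        with pytest.raises(ValueError):
            sliding_texture_maps(np.ones((4, 4, 1), int), TextureConfig())


class TestTextureStage:
    def _pseudo(self, rng, shape=(10, 10, 4)):
        body = np.ones(shape, bool)
        return ParameterPseudoImages(
            rng.uniform(0, 2, shape), rng.uniform(0, 1, shape), rng.uniform(0, 0.1, shape), body
        )

    def test_ninety_maps_default(self, rng):
        tex = texture_stage(self._pseudo(rng))
        assert len(tex.maps) == 90

    def test_thirty_maps_single_direction(self, rng):
        cfg = TextureConfig(directions=((1, 0, 0),))
        tex = texture_stage(self._pseudo(rng), cfg)
        assert len(tex.maps) == 30

    def test_parameter_order_independence(self, rng):
        p1 = self._pseudo(rng)
        p2 = ParameterPseudoImages(p1.k_el, p1.k_ep, p1.A, p1.body_mask)
        t1, t2 = texture_stage(p1), texture_stage(p2)
        for s in STATISTIC_NAMES:
            for d in DIRECTIONS:
                assert np.array_equal(t1.maps[("A", s, d)], t2.maps[("k_el", s, d)])

    def test_feature_stack_shape_and_order(self, rng):
        tex = texture_stage(self._pseudo(rng))
        stack, keys = tex.feature_stack()
        assert stack.shape == (10, 10, 4, 90)
        assert keys[0][0] == "A" and keys[-1][0] == "k_el"
        assert np.array_equal(stack[..., 0], tex.maps[keys[0]])
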