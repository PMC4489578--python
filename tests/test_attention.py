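import math

import numpy as np
import pytest

from v1action.attention import (GroupingSpec, SaliencyProducts, combine_masks,
                                conspicuity, extract_mask, facilitative_weight,
                                feature_maps, group, grouping_extent,
                                normalize_map)
from v1action.gabor import BankSpec, EnergyStack


class TestGroupingExtent:
    def test_endpoints(self):
        assert grouping_extent(np.array(1.0), 1.6) == 1
        assert grouping_extent(np.array(0.0), 1.6) == math.floor(math.e ** 1.6)
        assert grouping_extent(np.array(0.0), 1.6) == 4

    def test_non_increasing_in_contrast(self):
        grid = np.linspace(0, 1, 100)
        n = grouping_extent(grid, 1.6)
        assert (np.diff(n) <= 0).all()

    def test_zeta_bounds(self):
        with pytest.raises(ValueError):
            GroupingSpec(zeta=2.5)
        with pytest.raises(ValueError):
            GroupingSpec(zeta=0.0)


def _stack(values: dict, stage="suppressed"):
    return EnergyStack({k: np.asarray(v, dtype=np.float32)
                        for k, v in values.items()}, stage)


class TestGroup:
    def test_zero_weight_identity(self):
        shape = (2, 6, 6)
        R = _stack({(1.0, 0.0): np.random.default_rng(0).random(shape)})
        h = _stack({(1.0, 0.0): np.zeros(shape)}, "facilitative")
        O = group(R, h)
        assert np.allclose(O.channels[(1.0, 0.0)], R.channels[(1.0, 0.0)])

    def test_kappa_is_one_at_global_max_channel(self):
        shape = (1, 4, 4)
        a = np.zeros(shape); a[0, 1, 1] = 2.0
        b = np.zeros(shape); b[0, 2, 2] = 1.0
        R = _stack({(1.0, 0.0): np.zeros(shape), (1.0, 1.0): np.zeros(shape)})
        h = _stack({(1.0, 0.0): a, (1.0, 1.0): b}, "facilitative")
        O = group(R, h)
        # channel holding the global max gets kappa = 1 -> O = h there
        assert O.channels[(1.0, 0.0)][0, 1, 1] == pytest.approx(2.0)
        # sibling gets kappa = 1/2
        assert O.channels[(1.0, 1.0)][0, 2, 2] == pytest.approx(0.5)

    def test_grouped_never_below_input(self):
        shape = (2, 8, 8)
        rng = np.random.default_rng(1)
        R = _stack({(1.0, 0.0): rng.random(shape), (1.0, None): rng.random(shape)})
        h = _stack({(1.0, 0.0): rng.random(shape), (1.0, None): rng.random(shape)},
                   "facilitative")
        O = group(R, h)
        for key in R.channels:
            assert (O.channels[key] >= R.channels[key] - 1e-6).all()


def test_collinear_fragments_bridge():
    """Grouping pushes energy into the gap between collinear fragments."""
    shape = (1, 9, 32)
    R = np.zeros(shape, dtype=np.float32)
    R[0, 4, 4:12] = 1.0    # fragment 1
    R[0, 4, 20:28] = 1.0   # fragment 2
    bank = BankSpec(speeds=(1.0,), orientations=(0.0,),
                    include_non_oriented=False, calibrate=False)
    stackR = _stack({(1.0, 0.0): R})
    h = facilitative_weight(stackR, GroupingSpec(), bank)
    O = group(stackR, h)
    gap = (slice(0, 1), slice(3, 6), slice(13, 19))
    assert O.channels[(1.0, 0.0)][gap].sum() > R[gap].sum()


class TestFeatureMaps:
    def test_single_scale_identity(self):
        R = _stack({(1.0, 0.0): np.ones((1, 3, 3))}, "grouped")
        F = feature_maps({2.0: R})
        assert np.allclose(F.channels[(1.0, 0.0)], 1.0)

    def test_three_identical_scales_triple(self):
        R = {k: _stack({(1.0, 0.0): np.full((1, 3, 3), 2.0)}, "grouped")
             for k in (2.0, 3.0, 4.0)}
        F = feature_maps(R)
        assert np.allclose(F.channels[(1.0, 0.0)], 6.0)

    def test_missing_scale(self):
        with pytest.raises(ValueError):
            feature_maps({})


class TestConspicuity:
    def test_speed_split(self):
        shape = (1, 4, 4)
        feats = _stack({(1.0, None): np.ones(shape),
                        (1.0, 0.0): np.full(shape, 2.0),
                        (3.0, None): np.full(shape, 3.0),
                        (3.0, 0.0): np.full(shape, 4.0)}, "feature")
        sp = conspicuity(feats, 1.0)
        assert np.allclose(sp.F, 1.0)
        assert np.allclose(sp.Fo, 2.0)
        assert np.allclose(sp.M, 3.0)
        assert np.allclose(sp.Mo, 4.0)

    def test_all_zero_features(self):
        shape = (1, 4, 4)
        feats = _stack({(1.0, None): np.zeros(shape),
                        (3.0, None): np.zeros(shape)}, "feature")
        sp = conspicuity(feats, 1.0)
        for m in (sp.F, sp.M, sp.S):
            assert not m.any()

    def test_empty_split_side_warns(self):
        feats = _stack({(1.0, None): np.ones((1, 4, 4))}, "feature")
        with pytest.warns(UserWarning):
            sp = conspicuity(feats, 1.0)
        assert not sp.M.any()


class TestNormalizeMap:
    def test_zero_stays_zero(self):
        assert not normalize_map(np.zeros((8, 8))).any()

    def test_range_in_unit_interval(self, rng):
        m = rng.random((16, 16)).astype(np.float32)
        out = normalize_map(m)
        assert out.min() >= 0 and out.max() <= 1 + 1e-6

    def test_single_peak_promoted_over_many_equal_peaks(self):
        one = np.zeros((17, 17)); one[8, 8] = 1.0
        many = np.zeros((17, 17))
        many[2::6, 2::6] = 1.0
        assert normalize_map(one).max() > normalize_map(many).max()


def test_saliency_is_sum_of_components(rng):
    maps = {n: rng.random((2, 8, 8)).astype(np.float32)
            for n in ("F", "Fo", "M", "Mo")}
    sp = SaliencyProducts(**maps)
    assert np.allclose(sp.S, sp.S1 + sp.S2, atol=1e-6)
    assert (sp.S >= 0).all()


class TestExtractMask:
    def test_uniform_map_empty(self):
        assert extract_mask(np.ones((20, 20)), win=5, k_th=1.0) == []

    def test_single_block_survives(self):
        """Brute-force oracle: with one bright block on zeros, exactly the
        windows overlapping the block exceed the mean salient degree."""
        m = np.zeros((40, 40)); m[10:20, 10:20] = 1.0
        regs = extract_mask(m, win=10, k_th=1.0, morph_radius=0)
        assert len(regs) == 1
        covered = regs[0]
        assert covered[12:18, 12:18].all()
        assert not covered[0:5, 0:5].any()

    def test_two_blobs_two_regions(self):
        m = np.zeros((48, 48))
        m[6:14, 6:14] = 1.0
        m[32:40, 32:40] = 1.0
        regs = extract_mask(m, win=6, k_th=1.0, morph_radius=2)
        assert len(regs) == 2

    def test_empty_map(self):
        assert extract_mask(np.zeros((10, 10)), win=4) == []

    def test_bad_window(self):
        with pytest.raises(ValueError):
            extract_mask(np.zeros((10, 10)), win=0)


class TestCombineMasks:
    def _reg(self, ys, xs, shape=(20, 20)):
        m = np.zeros(shape, dtype=bool)
        m[ys, xs] = True
        return m

    def test_disjoint_bm1_region_dropped(self):
        r1 = self._reg(slice(0, 3), slice(0, 3))
        r2 = self._reg(slice(10, 13), slice(10, 13))
        ch = combine_masks([r1], [r2], [r2])
        assert ch.bm3 == []
        assert ch.bm == []

    def test_intersecting_regions_unioned_then_kept_verbatim(self):
        r1 = self._reg(slice(0, 4), slice(0, 4))
        r2 = self._reg(slice(2, 6), slice(2, 6))
        r4 = self._reg(slice(3, 5), slice(3, 5))
        ch = combine_masks([r1], [r2], [r4])
        assert len(ch.bm3) == 1
        assert np.array_equal(ch.bm3[0], r1 | r2)   # completion by union
        assert len(ch.bm) == 1
        assert np.array_equal(ch.bm[0], ch.bm3[0])  # kept verbatim, no r4 union

    def test_no_motion_evidence_removes_region(self):
        r1 = self._reg(slice(0, 4), slice(0, 4))
        r2 = self._reg(slice(2, 6), slice(2, 6))
        far = self._reg(slice(15, 18), slice(15, 18))
        ch = combine_masks([r1], [r2], [far])
        assert ch.bm3 and ch.bm == []
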