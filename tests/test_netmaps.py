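import numpy as np
import pytest
from scipy import ndimage

from connparc.netmaps import (
    NetworkCategory,
    assign_categories,
    group_onesample_stat,
    signflip_fwe,
    tfce_transform,
    venn_counts,
)
from connparc.volio import BinaryMask, VolumeGrid
from oracles import brute_tfce


class TestGroupStat:
    def test_hand_computed_t(self, full_mask):
        mask = full_mask((2, 2, 2))
        maps = [np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)]
        t = group_onesample_stat(maps, mask)
        np.testing.assert_allclose(t, 2.0 / (1.0 / np.sqrt(3)), atol=1e-12)

    def test_symmetric_values_give_zero(self, full_mask):
        mask = full_mask((2, 2, 2))
        t = group_onesample_stat(
            [np.full((2, 2, 2), -1.0), np.full((2, 2, 2), 1.0)], mask
        )
        np.testing.assert_allclose(t, 0.0)

    def test_identical_subjects_hit_sd_floor(self, full_mask):
        mask = full_mask((2, 2, 2))
        t = group_onesample_stat([np.full((2, 2, 2), 0.5)] * 3, mask)
        assert np.all(np.isfinite(t)) and np.all(t > 1e10)

    def test_single_subject_rejected(self, full_mask):
        with pytest.raises(ValueError):
            group_onesample_stat([np.zeros((2, 2, 2))], full_mask((2, 2, 2)))


class TestTfce:
    def test_zero_map_stays_zero(self, full_mask):
        mask = full_mask((4, 4, 4))
        np.testing.assert_array_equal(
            tfce_transform(np.zeros((4, 4, 4)), mask), np.zeros((4, 4, 4))
        )

    def test_single_voxel_closed_form(self, full_mask):
        # sum_{i=1..100} (0.01 i)^2 * 0.01 with unit extent = 0.33835
        mask = full_mask((9, 9, 9))
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 1.0
        enhanced = tfce_transform(vol, mask, E=0.5, H=2.0, dh=0.01)
        np.testing.assert_allclose(enhanced[4, 4, 4], 0.33835, atol=1e-9)
        assert enhanced.sum() == pytest.approx(0.33835, abs=1e-9)

    def test_constant_map_scales_with_sqrt_extent(self, full_mask):
        mask = full_mask((9, 9, 9))
        enhanced = tfce_transform(np.ones((9, 9, 9)), mask, dh=0.01)
        np.testing.assert_allclose(enhanced, np.sqrt(729) * 0.33835, atol=1e-6)

    def test_matches_brute_force_oracle(self, rng, full_mask):
        mask = full_mask((8, 8, 8))
        for _ in range(5):
            vol = ndimage.gaussian_filter(rng.standard_normal((8, 8, 8)), 1.0)
            got = tfce_transform(vol, mask, n_steps=50)
            want = brute_tfce(vol, n_steps=50)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_monotone_under_positive_scaling(self, rng, full_mask):
        mask = full_mask((6, 6, 6))
        vol = ndimage.gaussian_filter(rng.standard_normal((6, 6, 6)), 1.0)
        base = tfce_transform(vol, mask)
        scaled = tfce_transform(2.0 * vol, mask)
        assert np.all(scaled >= base - 1e-12)

    def test_step_refinement_converges(self, rng, full_mask):
        mask = full_mask((8, 8, 8))
        vol = np.abs(ndimage.gaussian_filter(rng.standard_normal((8, 8, 8)), 1.5))
        coarse = tfce_transform(vol, mask, n_steps=100)
        fine = tfce_transform(vol, mask, n_steps=200)
        sel = coarse > 0.2 * coarse.max()
        rel = np.abs(fine[sel] - coarse[sel]) / coarse[sel]
        assert rel.max() < 0.02  # Riemann-sum convergence away from the floor

    def test_negative_values_contribute_nothing(self, full_mask):
        mask = full_mask((4, 4, 4))
        vol = np.full((4, 4, 4), -2.0)
        np.testing.assert_array_equal(tfce_transform(vol, mask), 0.0)

    def test_nonfinite_rejected(self, full_mask):
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = np.nan
        with pytest.raises(ValueError):
            tfce_transform(vol, full_mask((3, 3, 3)))


class TestSignFlipFwe:
    def test_strong_signal_recovered_and_limited_to_region(self, rng, full_mask):
        shape = (8, 8, 8)
        mask = full_mask(shape)
        signal = np.zeros(shape)
        signal[2:5, 2:5, 2:5] = 1.0
        maps = [signal + rng.normal(0, 0.1, shape) for _ in range(12)]
        stat_map, binary = signflip_fwe(maps, mask, n_perms=200, seed=0)
        assert np.all(binary.data[2:5, 2:5, 2:5])
        outside = binary.data & (signal == 0)
        assert outside.sum() / (signal == 0).sum() < 0.05

    def test_corrected_p_monotone_in_enhanced(self, rng, full_mask):
        mask = full_mask((6, 6, 6))
        maps = [rng.standard_normal((6, 6, 6)) for _ in range(8)]
        stat_map, _ = signflip_fwe(maps, mask, n_perms=150, seed=1)
        enhanced = stat_map.enhanced[mask.data]
        p = stat_map.corrected_p[mask.data]
        order = np.argsort(enhanced)
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_corrected_p_bounds_and_binary_consistency(self, rng, full_mask):
        mask = full_mask((5, 5, 5))
        maps = [rng.standard_normal((5, 5, 5)) + 0.3 for _ in range(10)]
        stat_map, binary = signflip_fwe(maps, mask, n_perms=120, alpha=0.2, seed=2)
        p = stat_map.corrected_p[mask.data]
        assert np.all((p >= 1 / 121) & (p <= 1.0))
        np.testing.assert_array_equal(binary.data[mask.data], p < 0.2)

    def test_alpha_one_keeps_everything_below_ceiling(self, rng, full_mask):
        mask = full_mask((4, 4, 4))
        maps = [rng.standard_normal((4, 4, 4)) + 2.0 for _ in range(10)]
        _, binary = signflip_fwe(maps, mask, n_perms=100, alpha=1.0, seed=3)
        assert binary.n_inside == mask.n_inside

    def test_too_few_perms_or_subjects_rejected(self, rng, full_mask):
        mask = full_mask((3, 3, 3))
        maps = [rng.standard_normal((3, 3, 3)) for _ in range(6)]
        with pytest.raises(ValueError):
            signflip_fwe(maps, mask, n_perms=50)
        with pytest.raises(ValueError):
            signflip_fwe(maps[:2], mask, n_perms=100)


class TestCategoriesAndVenn:
    def _mask(self, shape, where):
        data = np.zeros(shape, dtype=bool)
        for idx in where:
            data[idx] = True
        return BinaryMask(VolumeGrid(shape), data)

    def test_membership_triples(self):
        shape = (2, 2, 2)
        mea = self._mask(shape, [(0, 0, 0), (0, 0, 1)])
        coa = self._mask(shape, [(0, 0, 0), (0, 1, 0)])
        pac = self._mask(shape, [(0, 0, 0)])
        cat = assign_categories(mea, coa, pac).categories
        assert cat[0, 0, 0] == NetworkCategory.ALL
        assert cat[0, 0, 1] == NetworkCategory.MEA_ONLY
        assert cat[0, 1, 0] == NetworkCategory.COA_ONLY
        assert cat[1, 1, 1] == NetworkCategory.NONE

    def test_constructed_venn_counts_exact(self):
        shape = (6, 6, 6)
        flat = lambda idxs: [np.unravel_index(i, shape) for i in idxs]
        mea = self._mask(shape, flat(range(0, 17)))          # 10 only + 5 w/CoA + 2 all
        coa = self._mask(shape, flat(range(10, 17)))
        pac = self._mask(shape, flat(range(15, 17)))
        counts = venn_counts(assign_categories(mea, coa, pac))
        assert counts[NetworkCategory.MEA_ONLY] == 10
        assert counts[NetworkCategory.MEA_COA] == 5
        assert counts[NetworkCategory.ALL] == 2
        assert counts[NetworkCategory.COA_ONLY] == 0

    def test_empty_maps_all_zero(self):
        shape = (3, 3, 3)
        empty = self._mask(shape, [])
        counts = venn_counts(assign_categories(empty, empty, empty))
        assert all(v == 0 for v in counts.values())

    def test_partition_conserves_union(self, rng):
        shape = (7, 7, 7)
        grid = VolumeGrid(shape)
        for _ in range(20):
            a, b, c = (BinaryMask(grid, rng.random(shape) < 0.3) for _ in range(3))
            counts = venn_counts(assign_categories(a, b, c))
            union = np.sum(a.data | b.data | c.data)
            assert sum(counts.values()) == union

    def test_grid_mismatch_rejected(self):
        a = self._mask((2, 2, 2), [])
        b = self._mask((3, 3, 3), [])
        from connparc.errors import GridMismatchError

        with pytest.raises(GridMismatchError):
            assign_categories(a, a, b)
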