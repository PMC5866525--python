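"""Mask geometry: distance transforms, margins, grouping, PTV-OPT."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oargroup import (EmptyStructureError, Grid, Role, StructureMask,
                      StructureSet, distance_to_structure, expand_mask,
                      group_oars, make_ptv_opt, mask_volume)

from conftest import brute_force_distance, make_random_mask


def single_voxel_mask(grid: Grid, index, name="m", role=Role.TARGET):
    vox = np.zeros(grid.shape, dtype=bool)
    vox[index] = True
    return StructureMask(grid, vox, name, role)


class TestDistance:
    def test_axial_neighbor_distance_equals_spacing(self):
        grid = Grid((5, 5, 5), (10.0, 10.0, 10.0))
        mask = single_voxel_mask(grid, (2, 2, 2))
        d = distance_to_structure(mask)
        assert d[3, 2, 2] == pytest.approx(10.0)
        assert d[2, 2, 2] == 0.0
        assert d[3, 3, 2] == pytest.approx(10.0 * np.sqrt(2))

    def test_zero_inside_mask(self):
        grid = Grid((6, 6, 6), (2.0, 3.0, 4.0))
        mask = make_random_mask(grid, np.random.default_rng(0), p=0.2)
        d = distance_to_structure(mask)
        assert np.all(d[mask.voxels] == 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_anisotropic_grid(self, seed):
        grid = Grid((16, 16, 16), (2.0, 3.5, 4.0)) if seed % 2 else \
            Grid((16, 16, 16), (4.0, 4.0, 4.0))
        mask = make_random_mask(grid, np.random.default_rng(seed), p=0.01)
        np.testing.assert_allclose(distance_to_structure(mask),
                                   brute_force_distance(mask),
                                   rtol=1e-9, atol=1e-9)

    def test_empty_mask_is_an_error(self):
        grid = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        empty = StructureMask(grid, np.zeros(grid.shape, bool), "e", Role.TARGET)
        with pytest.raises(EmptyStructureError):
            distance_to_structure(empty)


class TestExpand:
    def test_zero_margin_is_identity(self):
        grid = Grid((8, 8, 8), (3.0, 3.0, 3.0))
        mask = make_random_mask(grid, np.random.default_rng(1), p=0.1)
        out = expand_mask(mask, 0.0)
        assert np.array_equal(out.voxels, mask.voxels)
        assert out.grid == mask.grid

    def test_single_voxel_margin_one_spacing_gives_plus_shape(self):
        # At 10 mm isotropic spacing, a 10 mm margin reaches the 6 axial
        # neighbors but not the in-plane diagonals at ~14.1 mm.
        grid = Grid((5, 5, 5), (10.0, 10.0, 10.0))
        out = expand_mask(single_voxel_mask(grid, (2, 2, 2)), 10.0)
        assert out.voxel_count == 7
        assert out.voxels[3, 2, 2] and out.voxels[2, 1, 2]
        assert not out.voxels[3, 3, 2]

    @pytest.mark.parametrize("margin", [4.0, 12.0])
    def test_equals_brute_force_threshold(self, margin):
        grid = Grid((12, 12, 12), (3.0, 4.0, 5.0))
        mask = make_random_mask(grid, np.random.default_rng(2), p=0.02)
        out = expand_mask(mask, margin)
        assert np.array_equal(out.voxels,
                              brute_force_distance(mask) <= margin)

    def test_negative_margin_rejected(self):
        grid = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            expand_mask(single_voxel_mask(grid, (1, 1, 1)), -1.0)


def two_oar_set(grid, target_idx, oar_indices):
    target = single_voxel_mask(grid, target_idx, "ptv", Role.TARGET)
    masks = [target]
    for i, idx in enumerate(oar_indices):
        masks.append(single_voxel_mask(grid, idx, f"oar{i}", Role.PRIMARY_OAR))
    return StructureSet(grid, masks)


class TestGroupOars:
    def test_inclusion_and_exclusion_around_the_limit(self):
        # OAR voxels 20 mm and 40 mm from the target: only the first grouped.
        grid = Grid((9, 9, 9), (10.0, 10.0, 10.0))
        ss = two_oar_set(grid, (4, 4, 4), [(6, 4, 4), (8, 4, 4)])
        grouped = group_oars(ss, distance_limit=30.0)
        assert grouped.voxels[6, 4, 4]
        assert not grouped.voxels[8, 4, 4]
        assert grouped.role is Role.PRIMARY_OAR

    def test_boundary_inclusive(self):
        grid = Grid((9, 9, 9), (10.0, 10.0, 10.0))
        ss = two_oar_set(grid, (4, 4, 4), [(7, 4, 4)])  # exactly 30 mm
        assert group_oars(ss, 30.0).voxels[7, 4, 4]

    @pytest.mark.parametrize("seed", range(3))
    def test_volume_matches_brute_force_ring_count(self, seed):
        grid = Grid((16, 16, 16), (5.0, 5.0, 5.0))
        rng = np.random.default_rng(seed)
        target = make_random_mask(grid, rng, p=0.01, name="ptv",
                                  role=Role.TARGET)
        oars = [make_random_mask(grid, rng, p=0.03, name=f"oar{i}")
                for i in range(4)]
        ss = StructureSet(grid, [target] + oars)
        grouped = group_oars(ss, 30.0)
        dist = brute_force_distance(target)
        union = np.zeros(grid.shape, bool)
        for o in oars:
            union |= o.voxels
        assert grouped.voxel_count == int(np.count_nonzero(union & (dist <= 30.0)))

    def test_subset_of_union_and_superset_of_overlap(self):
        grid = Grid((12, 12, 12), (4.0, 4.0, 4.0))
        rng = np.random.default_rng(5)
        target = make_random_mask(grid, rng, p=0.05, name="ptv", role=Role.TARGET)
        oars = [make_random_mask(grid, rng, p=0.1, name=f"oar{i}")
                for i in range(3)]
        ss = StructureSet(grid, [target] + oars)
        grouped = group_oars(ss)
        union = np.zeros(grid.shape, bool)
        for o in oars:
            union |= o.voxels
        assert not np.any(grouped.voxels & ~union)
        assert np.all(grouped.voxels[union & target.voxels])

    def test_monotone_in_distance_limit(self):
        grid = Grid((12, 12, 12), (4.0, 4.0, 4.0))
        rng = np.random.default_rng(6)
        target = make_random_mask(grid, rng, p=0.03, name="ptv", role=Role.TARGET)
        oar = make_random_mask(grid, rng, p=0.15, name="oar")
        ss = StructureSet(grid, [target, oar])
        prev = np.zeros(grid.shape, bool)
        for limit in (5.0, 15.0, 30.0, 60.0):
            cur = group_oars(ss, limit).voxels
            assert np.all(cur[prev])
            prev = cur

    def test_no_primary_oars_is_an_error(self):
        grid = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        ss = StructureSet(grid, [single_voxel_mask(grid, (1, 1, 1), "ptv")])
        with pytest.raises(EmptyStructureError):
            group_oars(ss)


class TestPtvOpt:
    def test_no_overlap_returns_ptv_unchanged(self):
        grid = Grid((12, 12, 12), (10.0, 10.0, 10.0))
        target = single_voxel_mask(grid, (2, 2, 2), "ptv", Role.TARGET)
        far = single_voxel_mask(grid, (10, 10, 10), "oar", Role.PRIMARY_OAR)
        out = make_ptv_opt(target, [far], margin=5.0)
        assert np.array_equal(out.voxels, target.voxels)

    def test_full_overlap_yields_empty_flag(self):
        grid = Grid((6, 6, 6), (4.0, 4.0, 4.0))
        target = single_voxel_mask(grid, (3, 3, 3), "ptv", Role.TARGET)
        oar = StructureMask(grid, np.ones(grid.shape, bool), "oar",
                            Role.PRIMARY_OAR)
        out = make_ptv_opt(target, [oar], margin=8.0)
        assert out.is_empty

    def test_sphere_case_matches_voxel_oracle(self):
        grid = Grid((20, 20, 20), (4.0, 4.0, 4.0))
        centers = grid.voxel_centers()
        c = np.array([40.0, 40.0, 40.0])
        ptv_vox = (np.sum((centers - c) ** 2, axis=1) <= 20.0 ** 2
                   ).reshape(grid.shape)
        oar_vox = (np.sum((centers - c - [25.0, 0, 0]) ** 2, axis=1) <= 10.0 ** 2
                   ).reshape(grid.shape)
        target = StructureMask(grid, ptv_vox, "ptv", Role.TARGET)
        oar = StructureMask(grid, oar_vox, "oar", Role.PRIMARY_OAR)
        out = make_ptv_opt(target, [oar], margin=5.0)
        expected = ptv_vox & ~(brute_force_distance(oar) <= 5.0)
        assert np.array_equal(out.voxels, expected)

    def test_antitone_in_margin(self):
        grid = Grid((14, 14, 14), (4.0, 4.0, 4.0))
        rng = np.random.default_rng(7)
        target = make_random_mask(grid, rng, p=0.2, name="ptv", role=Role.TARGET)
        oar = make_random_mask(grid, rng, p=0.05, name="oar")
        prev = None
        for margin in (0.0, 4.0, 8.0, 16.0):
            cur = make_ptv_opt(target, [oar], margin).voxels
            if prev is not None:
                assert np.all(prev[cur])  # larger margin -> subset
            prev = cur


class TestMaskProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), margin=st.floats(0.0, 25.0),
           density=st.floats(0.02, 0.5))
    def test_expand_contains_mask_and_respects_oracle(self, seed, margin,
                                                      density):
        grid = Grid((8, 8, 8), (3.0, 4.0, 5.0))
        mask = make_random_mask(grid, np.random.default_rng(seed), p=density)
        out = expand_mask(mask, margin)
        assert np.all(out.voxels[mask.voxels])
        assert np.array_equal(out.voxels, brute_force_distance(mask) <= margin)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6),
           limits=st.tuples(st.floats(0.0, 40.0), st.floats(0.0, 40.0)))
    def test_grouping_monotone_and_bounded(self, seed, limits):
        grid = Grid((8, 8, 8), (5.0, 5.0, 5.0))
        rng = np.random.default_rng(seed)
        target = make_random_mask(grid, rng, p=0.05, name="ptv",
                                  role=Role.TARGET)
        oar = make_random_mask(grid, rng, p=0.2, name="oar")
        ss = StructureSet(grid, [target, oar])
        lo, hi = sorted(limits)
        g_lo, g_hi = group_oars(ss, lo), group_oars(ss, hi)
        assert np.all(g_hi.voxels[g_lo.voxels])
        dist = brute_force_distance(target)
        if not g_hi.is_empty:
            assert dist[g_hi.voxels].max() <= hi


class TestVolume:
    def test_empty_and_unit_conversion(self):
        grid = Grid((10, 10, 10), (1.0, 1.0, 1.0))
        empty = StructureMask(grid, np.zeros(grid.shape, bool), "e",
                              Role.PRIMARY_OAR)
        assert mask_volume(empty) == 0.0
        full = StructureMask(grid, np.ones(grid.shape, bool), "f", Role.TARGET)
        assert mask_volume(full) == pytest.approx(1.0)  # 1000 mm^3 = 1 cm^3

    def test_structure_set_validation(self):
        grid = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        t = single_voxel_mask(grid, (0, 0, 0), "a", Role.TARGET)
        with pytest.raises(ValueError):
            StructureSet(grid, [t, single_voxel_mask(grid, (1, 1, 1), "a",
                                                     Role.PRIMARY_OAR)])
        with pytest.raises(ValueError):
            StructureSet(grid, [t, single_voxel_mask(grid, (1, 1, 1), "b",
                                                     Role.TARGET)])
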