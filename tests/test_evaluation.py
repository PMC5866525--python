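"""DVH metrics, constraint normalization and the comparison report."""

import numpy as np
import pytest

from oargroup import (ConstraintSpec, CoverageReport, Grid, Role,
                      StructureMask, StructureSet, compare_plans, coverage_at,
                      dose_to_hottest_fraction, dose_to_hottest_volume, dvh,
                      mask_volume, max_dose, normalize_plan,
                      pancreatic_constraints)
from oargroup.evaluation import evaluate_constraint_metric


def flat_mask(grid, n, name="m", role=Role.PRIMARY_OAR):
    vox = np.zeros(grid.n_voxels, bool)
    vox[:n] = True
    return StructureMask(grid, vox.reshape(grid.shape), name, role)


def sorting_oracle(dose, mask, volume_cm3):
    """Independent D_vcc: sort descending, accumulate, interpolate."""
    d = np.sort(dose[mask.voxels])[::-1]
    vol = mask.grid.voxel_volume_cm3
    cum = (np.arange(d.size) + 1) * vol
    if volume_cm3 <= cum[0]:
        return d[0]
    return float(np.interp(volume_cm3, cum, d))


GRID = Grid((10, 10, 10), (10.0, 10.0, 10.0))  # 1 cm^3 voxels


class TestDvh:
    def test_uniform_dose_single_step(self):
        mask = flat_mask(GRID, 10)
        dose = np.full(GRID.shape, 10.0)
        curve = dvh(dose, mask)
        assert curve.total_volume_cm3 == pytest.approx(mask_volume(mask))
        assert np.all(curve.dose == 10.0)
        assert curve.cumulative_pct[-1] == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sort_and_accumulate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = flat_mask(GRID, 500)
        dose = rng.uniform(0, 60, GRID.shape)
        curve = dvh(dose, mask)
        d = np.sort(dose[mask.voxels])[::-1]
        np.testing.assert_array_equal(curve.dose, d)
        np.testing.assert_allclose(
            curve.cumulative_cm3, (np.arange(500) + 1) * 1.0)

    def test_volume_conservation(self):
        rng = np.random.default_rng(9)
        mask = flat_mask(GRID, 137)
        curve = dvh(rng.uniform(0, 60, GRID.shape), mask)
        assert curve.total_volume_cm3 == pytest.approx(mask_volume(mask))


class TestHottestVolumeMetrics:
    def test_uniform_dose_any_volume(self):
        mask = flat_mask(GRID, 20)
        dose = np.full(GRID.shape, 30.0)
        for v in (0.5, 5.0, 20.0):
            assert dose_to_hottest_volume(dose, mask, v) == pytest.approx(30.0)

    def test_full_volume_gives_minimum_dose(self):
        rng = np.random.default_rng(1)
        mask = flat_mask(GRID, 50)
        dose = rng.uniform(10, 60, GRID.shape)
        assert dose_to_hottest_volume(dose, mask, mask_volume(mask)) == \
            pytest.approx(dose[mask.voxels].min())
        assert dose_to_hottest_fraction(dose, mask, 1.0) == \
            pytest.approx(dose[mask.voxels].min())

    @pytest.mark.parametrize("seed", range(5))
    def test_d05cc_matches_sorting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = Grid((8, 8, 8), (6.0, 7.0, 5.0))
        mask = flat_mask(grid, 200)
        dose = rng.uniform(0, 55, grid.shape)
        assert dose_to_hottest_volume(dose, mask, 0.5) == \
            pytest.approx(sorting_oracle(dose, mask, 0.5), rel=1e-12)

    def test_non_increasing_in_volume(self):
        rng = np.random.default_rng(2)
        mask = flat_mask(GRID, 300)
        dose = rng.uniform(0, 55, GRID.shape)
        vols = np.linspace(0.5, mask_volume(mask), 40)
        vals = [dose_to_hottest_volume(dose, mask, v) for v in vols]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_volume_beyond_structure_is_an_error(self):
        mask = flat_mask(GRID, 5)
        with pytest.raises(ValueError):
            dose_to_hottest_volume(np.ones(GRID.shape), mask, 6.0)

    def test_max_dose(self):
        rng = np.random.default_rng(3)
        mask = flat_mask(GRID, 80)
        assert max_dose(np.zeros(GRID.shape), mask) == 0.0
        dose = rng.uniform(0, 50, GRID.shape)
        assert max_dose(dose, mask) == pytest.approx(dose[mask.voxels].max())


class TestCoverage:
    def test_full_coverage(self):
        mask = flat_mask(GRID, 40)
        dose = np.full(GRID.shape, 55.0)
        assert coverage_at(dose, mask, 1.0, 50.0) == 100.0

    def test_counting_example_80_of_100(self):
        mask = flat_mask(GRID, 100)
        dose = np.zeros(GRID.shape)
        dose.ravel()[:80] = 48.0  # >= 0.95 * 50
        assert coverage_at(dose, mask, 0.95, 50.0) == pytest.approx(80.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = flat_mask(GRID, 333)
        dose = rng.uniform(0, 60, GRID.shape)
        expected = 100.0 * np.count_nonzero(
            dose[mask.voxels] >= 0.95 * 50.0) / 333
        assert coverage_at(dose, mask, 0.95, 50.0) == pytest.approx(expected)

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(4)
        mask = flat_mask(GRID, 200)
        dose = rng.uniform(0, 60, GRID.shape)
        cov = [coverage_at(dose, mask, t, 50.0)
               for t in np.linspace(0.5, 1.3, 30)]
        assert np.all(np.diff(cov) <= 1e-12)


def normalization_anatomy():
    """PTV + two primary OARs + cord + kidneys with hand-set doses."""
    grid = Grid((10, 10, 10), (10.0, 10.0, 10.0))
    names_roles = [("ptv", Role.TARGET), ("stomach", Role.PRIMARY_OAR),
                   ("duodenum", Role.PRIMARY_OAR), ("cord", Role.R_OAR),
                   ("kidneys", Role.R_OAR)]
    masks, start = [], 0
    for name, role in names_roles:
        vox = np.zeros(grid.n_voxels, bool)
        vox[start:start + 100] = True
        masks.append(StructureMask(grid, vox.reshape(grid.shape), name, role))
        start += 100
    return grid, StructureSet(grid, masks)


class TestNormalization:
    def constraints(self):
        return [ConstraintSpec("stomach", "dose_to_volume_cc", 0.5, 45.0),
                ConstraintSpec("duodenum", "dose_to_volume_cc", 0.5, 45.0),
                ConstraintSpec("cord", "max_dose", None, 40.0),
                ConstraintSpec("kidneys", "dose_to_volume_fraction", 0.5, 15.0)]

    def test_primary_oar_branch_binds_at_45(self):
        grid, ss = normalization_anatomy()
        dose = np.zeros(grid.shape).ravel()
        dose[100:200] = 30.0  # hottest primary OAR D0.5cc = 30 Gy
        dose[300:400] = 10.0  # cord max 10
        dose[400:500] = 2.0   # kidney D50% 2
        dose = dose.reshape(grid.shape)
        res = normalize_plan(dose, ss, self.constraints())
        assert res.scale == pytest.approx(1.5)
        assert res.binding_constraint.structure == "stomach"
        after = evaluate_constraint_metric(res.dose, ss, self.constraints()[0])
        assert after == pytest.approx(45.0, rel=1e-12)

    def test_cord_branch_comes_first(self):
        grid, ss = normalization_anatomy()
        dose = np.zeros(grid.shape).ravel()
        dose[100:200] = 20.0
        dose[300:400] = 36.0
        dose = dose.reshape(grid.shape)
        res = normalize_plan(dose, ss, self.constraints())
        assert res.scale == pytest.approx(10.0 / 9.0)
        assert res.binding_constraint.kind == "max_dose"

    @pytest.mark.parametrize("seed", range(3))
    def test_binding_equality_and_no_violation_on_random_plans(self, seed):
        grid, ss = normalization_anatomy()
        rng = np.random.default_rng(seed)
        dose = rng.uniform(0, 50, grid.shape)
        res = normalize_plan(dose, ss, self.constraints())
        metrics = {c.describe(): evaluate_constraint_metric(res.dose, ss, c)
                   for c in self.constraints()}
        bind = metrics[res.binding_constraint.describe()]
        assert bind == pytest.approx(res.binding_constraint.limit, rel=1e-9)
        for c in self.constraints():
            assert metrics[c.describe()] <= c.limit * (1 + 1e-9)

    def test_scale_equivariance(self):
        grid, ss = normalization_anatomy()
        rng = np.random.default_rng(11)
        dose = rng.uniform(0, 50, grid.shape)
        r1 = normalize_plan(dose, ss, self.constraints())
        r2 = normalize_plan(3.0 * dose, ss, self.constraints())
        assert r2.scale == pytest.approx(r1.scale / 3.0, rel=1e-12)
        np.testing.assert_allclose(r1.dose, r2.dose, rtol=1e-12)

    def test_zero_dose_is_undefined(self):
        grid, ss = normalization_anatomy()
        with pytest.raises(ValueError, match="zero"):
            normalize_plan(np.zeros(grid.shape), ss, self.constraints())

    def test_kidney_union_resolution(self):
        grid = Grid((6, 6, 6), (10.0, 10.0, 10.0))
        t = np.zeros(grid.n_voxels, bool); t[:10] = True
        kl = np.zeros(grid.n_voxels, bool); kl[20:30] = True
        kr = np.zeros(grid.n_voxels, bool); kr[30:40] = True
        ss = StructureSet(grid, [
            StructureMask(grid, t.reshape(grid.shape), "ptv", Role.TARGET),
            StructureMask(grid, kl.reshape(grid.shape), "kidney_left", Role.R_OAR),
            StructureMask(grid, kr.reshape(grid.shape), "kidney_right", Role.R_OAR)])
        dose = np.zeros(grid.n_voxels)
        dose[20:30] = 10.0
        dose[30:40] = 20.0
        c = ConstraintSpec("kidneys", "dose_to_volume_fraction", 0.5, 15.0)
        # union is 20 voxels; its hottest half is the 10 voxels at 20 Gy
        assert evaluate_constraint_metric(dose.reshape(grid.shape), ss, c) == \
            pytest.approx(20.0)

    def test_constraint_validation(self):
        with pytest.raises(ValueError):
            ConstraintSpec("cord", "max_dose", 0.5, 40.0)
        with pytest.raises(ValueError):
            ConstraintSpec("stomach", "dose_to_volume_cc", None, 45.0)
        with pytest.raises(ValueError):
            ConstraintSpec("kidneys", "dose_to_volume_fraction", 1.5, 15.0)
        assert len(pancreatic_constraints()) == 6


class TestCompareReport:
    def fraction_anatomy(self):
        grid = Grid((10, 10, 10), (10.0, 10.0, 10.0))
        ptv = np.zeros(grid.n_voxels, bool); ptv[:100] = True
        oar = np.zeros(grid.n_voxels, bool); oar[500:600] = True
        return StructureSet(grid, [
            StructureMask(grid, ptv.reshape(grid.shape), "ptv", Role.TARGET),
            StructureMask(grid, oar.reshape(grid.shape), "stomach",
                          Role.PRIMARY_OAR)])

    def test_identical_pairs_report_all_zero_and_not_improved(self):
        ss = self.fraction_anatomy()
        dose = np.full(ss.grid.shape, 55.0)
        rep = compare_plans([(dose, dose)] * 3, [ss] * 3, prescription=50.0)
        for m in ("ptv_d95", "ptv_d100", "ptv_opt_d95"):
            assert rep.aggregate[m]["pct_fractions_improved"] == 0.0
            assert rep.aggregate[m]["mean_diff"] == 0.0
            assert rep.aggregate[m]["min_diff"] == 0.0

    def test_two_fraction_hand_computation(self):
        ss = self.fraction_anatomy()
        conv1 = np.zeros(ss.grid.shape); conv1.ravel()[:70] = 50.0
        grp1 = np.zeros(ss.grid.shape); grp1.ravel()[:90] = 50.0
        conv2 = np.full(ss.grid.shape, 50.0)
        grp2 = np.zeros(ss.grid.shape); grp2.ravel()[:80] = 50.0
        rep = compare_plans([(conv1, grp1), (conv2, grp2)], [ss, ss], 50.0)
        d100 = rep.aggregate["ptv_d100"]
        # fraction 1: 90 - 70 = +20 points; fraction 2: 80 - 100 = -20
        assert d100["pct_fractions_improved"] == pytest.approx(50.0)
        assert d100["mean_diff"] == pytest.approx(0.0)
        assert d100["min_diff"] == pytest.approx(-20.0)
        assert d100["max_diff"] == pytest.approx(20.0)

    def test_empty_ptv_opt_reported_not_applicable(self):
        grid = Grid((6, 6, 6), (10.0, 10.0, 10.0))
        ptv = np.zeros(grid.n_voxels, bool); ptv[:20] = True
        ss = StructureSet(grid, [
            StructureMask(grid, ptv.reshape(grid.shape), "ptv", Role.TARGET),
            StructureMask(grid, ptv.reshape(grid.shape), "stomach",
                          Role.PRIMARY_OAR)])  # OAR covers the whole target
        dose = np.full(grid.shape, 55.0)
        rep = compare_plans([(dose, dose)], [ss], 50.0)
        assert np.isnan(rep.per_fraction["ptv_opt_d95_diff"].iloc[0])
        assert rep.aggregate["ptv_opt_d95"]["n_valid"] == 0
        assert rep.aggregate["ptv_d95"]["n_valid"] == 1

    def test_report_round_trips_bit_exact(self):
        ss = self.fraction_anatomy()
        rng = np.random.default_rng(5)
        pairs = [(rng.uniform(0, 60, ss.grid.shape),
                  rng.uniform(0, 60, ss.grid.shape)) for _ in range(3)]
        rep = compare_plans(pairs, [ss] * 3, 50.0)
        text = rep.to_json()
        again = CoverageReport.from_json(text)
        assert again.to_json() == text

    def test_mismatched_lists_rejected(self):
        ss = self.fraction_anatomy()
        dose = np.zeros(ss.grid.shape)
        with pytest.raises(ValueError):
            compare_plans([(dose, dose)], [ss, ss], 50.0)
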