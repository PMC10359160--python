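import numpy as np
import pytest

from planct.errors import DegenerateInputError, GridMismatchError
from planct.metrics import (
    cohort_summary,
    dsc,
    evaluate_case,
    hausdorff,
    rassd,
)
from planct.volumes import (
    BinaryMask,
    DisplacementField,
    ScalarVolume,
    VolumeGrid,
    warp,
    warp_mask,
)


def _grid(shape=(6, 6, 6), s=2.5):
    return VolumeGrid(shape, (s, s, s))


def _brute_force_hausdorff(x: BinaryMask, y: BinaryMask) -> float:
    """O(n^2) double loop over surface voxels."""
    from scipy import ndimage

    def surface(m):
        er = ndimage.binary_erosion(
            m.values, ndimage.generate_binary_structure(3, 1), border_value=0)
        pts = np.argwhere(m.values & ~er).astype(float)
        return pts * np.asarray(m.grid.spacing)

    pa, pb = surface(x), surface(y)
    d_ab = max(min(np.sqrt(((a - b) ** 2).sum()) for b in pb) for a in pa)
    d_ba = max(min(np.sqrt(((a - b) ** 2).sum()) for a in pa) for b in pb)
    return max(d_ab, d_ba)


class TestRassd:
    def test_identical_zero(self, rng):
        g = _grid()
        v = ScalarVolume(g, rng.normal(size=g.shape))
        assert rassd(v, v) == 0.0

    def test_constant_difference(self, rng):
        g = _grid()
        a = ScalarVolume(g, rng.normal(size=g.shape))
        b = ScalarVolume(g, a.values + 4.0)
        assert rassd(a, b) == pytest.approx(4.0)

    def test_hand_computed_2x2x2(self):
        g = _grid((2, 2, 2))
        a = ScalarVolume(g, np.zeros((2, 2, 2)))
        diffs = np.array([1, 1, 1, 1, 3, 3, 3, 3], float).reshape(2, 2, 2)
        b = ScalarVolume(g, diffs)
        assert rassd(a, b) == pytest.approx(np.sqrt(5.0), abs=1e-12)

    def test_matches_brute_force_on_random_volumes(self, rng):
        g = _grid((5, 4, 6))
        for _ in range(10):
            a = ScalarVolume(g, rng.normal(size=g.shape))
            b = ScalarVolume(g, rng.normal(size=g.shape))
            brute = np.sqrt(sum(
                (a.values[i] - b.values[i]) ** 2
                for i in np.ndindex(g.shape)) / np.prod(g.shape))
            assert rassd(a, b) == pytest.approx(brute, abs=1e-10)

    def test_empty_region_rejected(self, rng):
        g = _grid()
        v = ScalarVolume(g, rng.normal(size=g.shape))
        empty = BinaryMask(g, np.zeros(g.shape, bool))
        with pytest.raises(DegenerateInputError):
            rassd(v, v, empty)


class TestDsc:
    def test_identical_nonempty(self, rng):
        g = _grid()
        m = BinaryMask(g, rng.random(g.shape) > 0.5)
        assert dsc(m, m) == 1.0

    def test_disjoint_zero(self):
        g = _grid()
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dsc(BinaryMask(g, a), BinaryMask(g, b)) == 0.0

    def test_counting_example(self):
        g = _grid((10, 10, 10))
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a.ravel()[:100] = True
        b.ravel()[60:120] = True  # |Y| = 60, overlap = 40
        assert dsc(BinaryMask(g, a), BinaryMask(g, b)) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        g = _grid()
        e = BinaryMask(g, np.zeros(g.shape, bool))
        assert dsc(e, e) == 1.0

    def test_symmetry_and_erosion_monotonicity(self, rng):
        from scipy import ndimage

        g = _grid((12, 12, 12))
        x, y, z = np.mgrid[:12, :12, :12]
        outer = ((x - 6) ** 2 + (y - 6) ** 2 + (z - 6) ** 2) < 25
        m = BinaryMask(g, outer)
        prev = 1.0
        shrink = outer
        for _ in range(3):
            shrink = ndimage.binary_erosion(shrink)
            cur = dsc(BinaryMask(g, shrink), m)
            assert dsc(m, BinaryMask(g, shrink)) == cur
            assert cur <= prev
            prev = cur


class TestHausdorff:
    def test_identical_zero(self, rng):
        g = _grid()
        m = BinaryMask(g, rng.random(g.shape) > 0.6)
        assert hausdorff(m, m) == 0.0

    def test_two_points_four_voxels_apart(self):
        g = _grid((8, 8, 8), 2.5)
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a[2, 2, 2] = True
        b[6, 2, 2] = True
        assert hausdorff(BinaryMask(g, a), BinaryMask(g, b)) == pytest.approx(10.0)

    def test_empty_mask_rejected(self):
        g = _grid()
        e = BinaryMask(g, np.zeros(g.shape, bool))
        m = BinaryMask(g, np.ones(g.shape, bool))
        with pytest.raises(DegenerateInputError):
            hausdorff(e, m)

    def test_matches_brute_force_on_random_masks(self, rng):
        g = VolumeGrid((7, 6, 8), (2.5, 2.0, 1.5))
        for _ in range(10):
            a = BinaryMask(g, rng.random(g.shape) > 0.8)
            b = BinaryMask(g, rng.random(g.shape) > 0.8)
            if not a.values.any() or not b.values.any():
                continue
            assert hausdorff(a, b) == pytest.approx(
                _brute_force_hausdorff(a, b), abs=1e-12)

    def test_triangle_type_bound(self, rng):
        g = _grid((8, 8, 8))
        for _ in range(10):
            ms = [BinaryMask(g, rng.random(g.shape) > 0.85) for _ in range(3)]
            if not all(m.values.any() for m in ms):
                continue
            ab = hausdorff(ms[0], ms[1])
            bc = hausdorff(ms[1], ms[2])
            ac = hausdorff(ms[0], ms[2])
            assert ac <= ab + bc + 1e-12


class TestEvaluateCase:
    def test_self_comparison_is_perfect(self, phantom_case_48):
        case = phantom_case_48
        report = evaluate_case(case.pct, case.pct, case.masks_pct,
                               case.masks_pct,
                               DisplacementField.zeros(case.pct.grid))
        for m in report.structures.values():
            assert m.rassd == 0.0 and m.dsc == 1.0 and m.hd == 0.0
        assert report.folding_fraction == 0.0

    def test_ground_truth_warp_recovers_lungs(self, phantom_case_48):
        case = phantom_case_48
        sct = warp(case.dct, case.true_dvf)
        masks_s = {k: warp_mask(m, case.true_dvf)
                   for k, m in case.masks_dct.items()}
        report = evaluate_case(sct, case.pct, masks_s, case.masks_pct,
                               case.true_dvf)
        assert report.structures["lungs"].dsc > 0.95
        assert report.folding_fraction == 0.0

    def test_z_range_matches_slice_scan(self, phantom_case_48):
        case = phantom_case_48
        # truncate the sct body mask in z to force a partial overlap
        masks_s = {k: BinaryMask(m.grid, m.values.copy())
                   for k, m in case.masks_pct.items()}
        masks_s["body"].values[:, :, :10] = False
        report = evaluate_case(case.pct, case.pct, masks_s, case.masks_pct,
                               DisplacementField.zeros(case.pct.grid))
        za = [k for k in range(48) if masks_s["body"].values[:, :, k].any()]
        zb = [k for k in range(48)
              if case.masks_pct["body"].values[:, :, k].any()]
        assert report.z_range_used == (max(za[0], zb[0]), min(za[-1], zb[-1]))

    def test_mismatched_structures_rejected(self, phantom_case_48):
        case = phantom_case_48
        partial = {"body": case.masks_pct["body"]}
        with pytest.raises(ValueError):
            evaluate_case(case.pct, case.pct, partial, case.masks_pct,
                          DisplacementField.zeros(case.pct.grid))


class TestCohortSummary:
    def _report(self, case, dvf=None):
        dvf = dvf or DisplacementField.zeros(case.pct.grid)
        return evaluate_case(case.pct, case.pct, case.masks_pct,
                             case.masks_pct, dvf)

    def test_single_report_equals_itself(self, phantom_case_48):
        rep = self._report(phantom_case_48)
        table = cohort_summary([rep])
        row = table[(table.structure == "lungs") & (table.metric == "dsc")]
        assert row["mean"].iloc[0] == rep.structures["lungs"].dsc

    def test_mean_of_two(self, phantom_case_48):
        rep = self._report(phantom_case_48)
        rep2 = self._report(phantom_case_48)
        rep2.structures["lungs"].dsc = 0.8
        rep.structures["lungs"].dsc = 1.0
        table = cohort_summary([rep, rep2])
        row = table[(table.structure == "lungs") & (table.metric == "dsc")]
        assert row["mean"].iloc[0] == pytest.approx(0.9)

    def test_shape_structures_times_metrics(self, phantom_case_48):
        table = cohort_summary([self._report(phantom_case_48)])
        assert len(table) == 3 * 4  # 3 structures x (rassd, dsc, hd, folding)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])
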