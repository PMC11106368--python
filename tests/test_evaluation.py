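import numpy as np
import pytest

from lcseg.evaluation import (binarize_lcc, cohort_stats, combine_soft, dice,
                              loocv, sensitivity)
from lcseg.geometry import dice_cap
from lcseg.io_core import SoftMask
from sklearn.base import BaseEstimator

from conftest import make_binary, make_volume


def _soft(data, voxel=1.0):
    v = make_volume(data, voxel)
    return SoftMask(np.clip(v.data, 0, 1), v.affine)


class TestDice:
    def test_identical_masks(self):
        data = np.zeros((5, 5, 5))
        data[1:3, 1:3, 1:3] = 1
        m = make_binary(data)
        assert dice(m, make_binary(data)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5, 5)); a[0, 0, 0] = 1
        b = np.zeros((5, 5, 5)); b[4, 4, 4] = 1
        assert dice(make_binary(a), make_binary(b)) == 0.0

    def test_formula_on_constructed_overlap(self):
        # |a| = 30, |b| = 20, |a ∩ b| = 15 -> 2*15/50 = 0.6
        a = np.zeros((5, 5, 5)); b = np.zeros((5, 5, 5))
        a.reshape(-1)[:30] = 1
        b.reshape(-1)[15:35] = 1
        assert dice(make_binary(a), make_binary(b)) == pytest.approx(0.6)

    def test_symmetry(self, rng):
        a = make_binary((rng.random((6, 6, 6)) > 0.5).astype(float))
        b = make_binary((rng.random((6, 6, 6)) > 0.5).astype(float))
        assert dice(a, b) == dice(b, a)

    def test_both_empty_warns_and_returns_one(self):
        e = make_binary(np.zeros((3, 3, 3)))
        with pytest.warns(UserWarning):
            assert dice(e, make_binary(np.zeros((3, 3, 3)))) == 1.0

    def test_grid_mismatch_rejected(self):
        a = make_binary(np.zeros((3, 3, 3)), voxel=1.0)
        b = make_binary(np.zeros((3, 3, 3)), voxel=0.7)
        with pytest.raises(ValueError):
            dice(a, b)

    def test_nested_masks_match_dice_cap(self):
        # Cross-module consistency: Dice(A, B) with B ⊆ A equals the cap
        # at the volume ratio.
        b = np.zeros((6, 6, 6)); b.reshape(-1)[:20] = 1
        a = np.zeros((6, 6, 6)); a.reshape(-1)[:54] = 1
        assert dice(make_binary(a), make_binary(b)) == pytest.approx(
            dice_cap(54 / 20))


class TestSensitivity:
    def test_superset_prediction(self):
        t = np.zeros((5, 5, 5)); t[2, 2, 2] = 1
        p = np.ones((5, 5, 5))
        truth = make_binary(t)
        assert sensitivity(make_binary(p), truth) == 1.0
        assert dice(make_binary(p), truth) == pytest.approx(
            dice_cap(125 / 1))

    def test_complete_miss(self):
        t = np.zeros((5, 5, 5)); t[0, 0, 0] = 1
        p = np.zeros((5, 5, 5)); p[4, 4, 4] = 1
        assert sensitivity(make_binary(p), make_binary(t)) == 0.0

    def test_half_coverage(self):
        t = np.zeros((5, 5, 5)); t.reshape(-1)[:10] = 1
        p = np.zeros((5, 5, 5)); p.reshape(-1)[:5] = 1
        assert sensitivity(make_binary(p), make_binary(t)) == 0.5

    def test_empty_truth_rejected(self):
        p = make_binary(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            sensitivity(p, make_binary(np.zeros((3, 3, 3))))


class TestBinarizeLcc:
    def test_keeps_largest_component(self):
        data = np.zeros((10, 10, 10))
        data[1:3, 1:6, 1:2] = 0.9   # 10 voxels
        data[7:8, 7:10, 7:8] = 0.9  # 3 voxels
        out = binarize_lcc(_soft(data), 0.5)
        assert out.data.sum() == 10
        assert out.data[1, 1, 1] == 1 and out.data[7, 7, 7] == 0

    def test_all_below_threshold_gives_empty(self):
        out = binarize_lcc(_soft(np.full((4, 4, 4), 0.2)), 0.5)
        assert out.data.sum() == 0

    def test_tie_breaks_to_smallest_flat_index(self):
        data = np.zeros((8, 8, 8))
        data[6, 6, 6] = 0.9  # flat index larger
        data[1, 1, 1] = 0.9  # flat index smaller
        out = binarize_lcc(_soft(data), 0.5)
        assert out.data[1, 1, 1] == 1 and out.data[6, 6, 6] == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize_lcc(_soft(np.zeros((3, 3, 3))), 0.0)

    def test_26_connectivity_joins_diagonals(self):
        data = np.zeros((6, 6, 6))
        data[2, 2, 2] = 0.9
        data[3, 3, 3] = 0.9  # diagonal neighbour: one 26-connected blob
        out = binarize_lcc(_soft(data), 0.5)
        assert out.data.sum() == 2


class TestCombineSoft:
    def test_self_combination(self, rng):
        a = _soft(rng.random((6, 6, 6)))
        sq = _soft(np.asarray(a.data) ** 2)
        assert np.array_equal(combine_soft(a, a, 0.5).data,
                              binarize_lcc(sq, 0.5).data)

    def test_neutral_element(self, rng):
        a = _soft(rng.random((6, 6, 6)))
        ones = _soft(np.ones((6, 6, 6)))
        assert np.array_equal(combine_soft(a, ones, 0.5).data,
                              binarize_lcc(a, 0.5).data)

    def test_product_support_matches_hand_computation(self):
        a = np.zeros((5, 5, 5)); b = np.zeros((5, 5, 5))
        a[1:4, 1:4, 1:4] = 0.9
        b[2:5, 2:5, 2:5] = 0.7
        out = combine_soft(_soft(a), _soft(b), 0.5)
        expected = (a * b) > 0.5  # 0.63 in the intersection cube
        assert np.array_equal(out.data.astype(bool), expected)


class _OracleEstimator(BaseEstimator):
    """Returns the held-out case's own mask: the upper bound."""

    def __init__(self, side="left", cases_by_id=None):
        self.side = side
        self.cases_by_id = cases_by_id

    def fit(self, cases, y=None):
        return self

    def predict(self, test):
        key = test.data.tobytes()
        case = self.cases_by_id[key]
        return SoftMask(case.mask(self.side).data.astype(float),
                        test.affine.copy())


class _EmptyEstimator(BaseEstimator):
    def __init__(self, side="left"):
        self.side = side

    def fit(self, cases, y=None):
        return self

    def predict(self, test):
        return SoftMask(np.zeros(test.shape), test.affine.copy())


class TestLoocv:
    def test_fold_accounting_and_oracle(self, cohort6):
        lookup = {c.image.data.tobytes(): c for c in cohort6}
        rep = loocv(cohort6, _OracleEstimator(cases_by_id=lookup),
                    side="left")
        assert len(rep.per_case) == len(cohort6)
        assert set(rep.per_case.subject_id) == {c.subject_id for c in cohort6}
        assert np.allclose(rep.per_case.dice, 1.0)
        assert rep.summary["dice_sem"] == 0.0

    def test_constant_empty_method_scores_zero_with_flags(self, cohort6):
        rep = loocv(cohort6, _EmptyEstimator(), side="right")
        assert np.allclose(rep.per_case.dice, 0.0)
        assert rep.per_case.failure_flag.all()

    def test_order_invariance(self, cohort6):
        lookup = {c.image.data.tobytes(): c for c in cohort6}
        est = _OracleEstimator(cases_by_id=lookup)
        a = loocv(cohort6, est, side="left")
        b = loocv(list(reversed(cohort6)), est, side="left")
        sa = a.per_case.sort_values("subject_id").reset_index(drop=True)
        sb = b.per_case.sort_values("subject_id").reset_index(drop=True)
        assert sa.equals(sb)

    def test_too_few_cases(self, cohort6):
        with pytest.raises(ValueError):
            loocv(cohort6[:1], _EmptyEstimator())


class TestCohortStats:
    def test_identical_sides_degenerate(self):
        out = cohort_stats([1, 2, 3], [1, 2, 3], [0.5, 0.5, 0.5],
                           [0.6, 0.6, 0.6])
        assert out["volume_t"] == 0.0 and out["volume_p"] == 1.0
        assert out["dice_r_flag"]

    def test_constant_shift_gives_extreme_t_and_r_one(self, rng):
        left = rng.random(10) + 5
        right = left - 1.0
        out = cohort_stats(left, right, left, right)
        assert abs(out["volume_t"]) > 1e6 or out["volume_p"] < 1e-10
        assert out["dice_r"] == pytest.approx(1.0)

    def test_matches_textbook_formulas(self, rng):
        # Independent recomputation of paired t and Pearson r from their
        # definitional formulas.
        n = 20
        x = rng.standard_normal(n) + 10
        y = x + 0.5 * rng.standard_normal(n)
        out = cohort_stats(x, y, x, y)
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        assert out["volume_t"] == pytest.approx(t_ref, rel=1e-10)
        xc, yc = x - x.mean(), y - y.mean()
        r_ref = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert out["dice_r"] == pytest.approx(r_ref, rel=1e-10)
        from scipy import stats as ss
        t_r = r_ref * np.sqrt((n - 2) / (1 - r_ref**2))
        assert out["dice_r_p"] == pytest.approx(2 * ss.t.sf(abs(t_r), n - 2),
                                                rel=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohort_stats([1, 2, 3], [1, 2])
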