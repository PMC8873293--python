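"""Qualitative rubric, fault detection, lesion localization and kappa."""

import copy
import itertools
import math

import numpy as np
import pytest

from couinaud3d.clinical import (
    Grade,
    Lesion,
    UnlocalizableLesion,
    classify_quality,
    detect_fault,
    filter_lesions,
    grade_shift,
    localize_lesion,
    measure_plane_shift,
    quality_report,
    weighted_kappa,
)
from couinaud3d.geometry import assign_couinaud_labels, build_separating_planes
from couinaud3d.grid import LabelMap


class TestGradeShift:
    @pytest.mark.parametrize(
        "mag,role,expected",
        [
            (4.0, "MID", Grade.SLIGHT),
            (5.0, "RHV", Grade.SLIGHT),      # boundary binds to slight
            (7.5, "MID", Grade.MODERATE),
            (10.0, "LHV_LLF", Grade.SEVERE),  # boundary binds to severe
            (12.0, "MID", Grade.SEVERE),
            (2.0, "RPV_H", Grade.SLIGHT),
            (3.0, "LPV_H", Grade.MODERATE),
            (5.0, "RPV_H", Grade.SEVERE),
            (math.inf, "MID", Grade.SEVERE),
        ],
    )
    def test_thresholds(self, mag, role, expected):
        assert grade_shift(mag, role) is expected

    def test_unknown_role_raises(self):
        with pytest.raises(ValueError):
            grade_shift(1.0, "DIAGONAL")


def rubric_oracle(grades, fault):
    """Independent transcription of the three quality rules."""
    counts = {g: sum(x is g for x in grades) for g in Grade}
    if fault:
        return "poor"
    if counts[Grade.SEVERE] > 0:
        return "poor"
    slights, moderates = counts[Grade.SLIGHT], counts[Grade.MODERATE]
    good = (moderates == 0 and slights <= 2) or (moderates == 1 and slights == 0)
    return "good" if good else "moderate"


class TestClassifyQuality:
    def test_quoted_examples(self):
        s, n, m, v = Grade.SLIGHT, Grade.NONE, Grade.MODERATE, Grade.SEVERE
        assert classify_quality([s, s, n, n, n], False) == "good"
        assert classify_quality([m, n, n, n, n], False) == "good"
        assert classify_quality([v, n, n, n, n], False) == "poor"
        assert classify_quality([s, s, s, n, n], False) == "moderate"
        assert classify_quality([m, s, n, n, n], False) == "moderate"
        assert classify_quality([m, m, n, n, n], False) == "moderate"
        assert classify_quality([n, n, n, n, n], True) == "poor"

    def test_exhaustive_decision_table(self):
        """All 4^5 x 2 grade/fault inputs classify consistently with the rules."""
        for grades in itertools.product(list(Grade), repeat=5):
            for fault in (False, True):
                assert classify_quality(list(grades), fault) == rubric_oracle(grades, fault)

    def test_wrong_cardinality_raises(self):
        with pytest.raises(ValueError):
            classify_quality([Grade.NONE] * 4, False)


class TestPlaneShift:
    def test_identity_measures_zero_everywhere(self, small_case):
        for role in ("MID", "RHV", "LHV_LLF", "RPV_H", "LPV_H"):
            assert measure_plane_shift(small_case.labels, small_case.labels, role) < 1e-6

    def test_translated_rhv_plane_measured(self, default_case):
        lm = default_case.landmarks
        ref = default_case.labels
        normal = build_separating_planes(lm)["RHV"].normal
        lm2 = copy.deepcopy(lm)
        lm2.rhv = lm.rhv + 6.0 * normal
        pred = assign_couinaud_labels(default_case.liver_mask, lm2)
        measured = measure_plane_shift(pred, ref, "RHV")
        assert abs(measured - 6.0) <= max(default_case.labels.spacing)

    def test_portal_level_shift_in_slices(self, default_case):
        lm = default_case.landmarks
        ref = default_case.labels
        lm2 = copy.deepcopy(lm)
        lm2.rpv = lm.rpv + np.array([0.0, 0.0, 3 * default_case.labels.spacing[2]])
        pred = assign_couinaud_labels(default_case.liver_mask, lm2)
        assert measure_plane_shift(pred, ref, "RPV_H") == pytest.approx(3.0, abs=1.0)

    def test_missing_boundary_is_unmeasurable(self, small_case):
        arr = np.asarray(small_case.labels.data).copy()
        arr[arr == 4] = 2  # destroy the LHV_LLF boundary pair
        pred = LabelMap(arr, small_case.labels.spacing)
        assert math.isinf(measure_plane_shift(pred, small_case.labels, "LHV_LLF"))


class TestDetectFault:
    def test_identity_and_plane_shift_are_not_faults(self, default_case):
        ref = default_case.labels
        assert detect_fault(ref, ref) is False
        lm2 = copy.deepcopy(default_case.landmarks)
        normal = build_separating_planes(default_case.landmarks)["RHV"].normal
        lm2.rhv = default_case.landmarks.rhv + 6.0 * normal
        pred = assign_couinaud_labels(default_case.liver_mask, lm2)
        assert detect_fault(pred, ref) is False

    def test_deep_irregular_blob_is_a_fault(self, default_case):
        from scipy import ndimage

        ref = default_case.labels
        arr = np.asarray(ref.data).copy()
        # deepest point of S7: farthest (mm) from any non-S7 voxel
        depth = ndimage.distance_transform_edt(arr == 7, sampling=ref.spacing)
        center = ref.world_coords(np.argwhere(depth == depth.max())[0])
        gx, gy, gz = ref.coordinate_grids()
        ball = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2 <= 15**2
        arr2 = arr.copy()
        arr2[ball & (arr == 7)] = 2
        assert detect_fault(LabelMap(arr2, ref.spacing, ref.origin), ref) is True

    def test_quality_report_end_to_end(self, small_case):
        report = quality_report(small_case.labels, small_case.labels)
        assert report.overall == "good"
        assert report.fault is False
        assert all(s.grade is Grade.NONE for s in report.shifts)


def _lesion(idx, diameter, segments={5}):
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = True
    return Lesion(id=idx, center_mm=np.zeros(3), diameter_mm=diameter, mask=mask,
                  true_segments=frozenset(segments))


class TestFilterLesions:
    def test_small_dropped_then_five_largest_kept(self):
        diameters = [4.0, 20.0, 18.0, 9.0, 8.0, 7.0, 6.0]
        lesions = [_lesion(i, d) for i, d in enumerate(diameters)]
        kept = filter_lesions(lesions)
        assert [l.diameter_mm for l in kept] == [20.0, 18.0, 9.0, 8.0, 7.0]

    def test_all_too_small_gives_empty(self):
        assert filter_lesions([_lesion(i, 5.0) for i in range(3)]) == []

    def test_exactly_five_eligible_all_kept(self):
        lesions = [_lesion(i, 6.0 + i) for i in range(5)]
        assert len(filter_lesions(lesions)) == 5

    def test_ties_broken_by_lower_id(self):
        lesions = [_lesion(i, 10.0) for i in range(7)]
        assert [l.id for l in filter_lesions(lesions)] == [0, 1, 2, 3, 4]


class TestLocalize:
    def _pred(self, labels_array):
        return LabelMap(np.asarray(labels_array, dtype=np.int16), (1, 1, 1))

    def test_fully_inside_one_segment(self):
        arr = np.full((6, 6, 6), 5)
        lesion = _lesion(0, 6.0)
        lesion.mask = np.zeros((6, 6, 6), dtype=bool)
        lesion.mask[2:4, 2:4, 2:4] = True
        assert localize_lesion(lesion, self._pred(arr)) == {5}

    def test_straddling_lesion_gets_both(self):
        arr = np.full((6, 6, 6), 4)
        arr[3:] = 8
        lesion = _lesion(0, 6.0)
        lesion.mask = np.zeros((6, 6, 6), dtype=bool)
        lesion.mask[2:5, 2:4, 2:4] = True  # 1/3 in S4, 2/3 in S8
        assert localize_lesion(lesion, self._pred(arr)) == {4, 8}

    def test_small_spill_below_10pct_ignored(self):
        arr = np.full((25, 2, 2), 4)
        arr[24:] = 8
        lesion = _lesion(0, 6.0)
        lesion.mask = np.zeros((25, 2, 2), dtype=bool)
        lesion.mask[:] = True  # 96 voxels in S4, 4 in S8 (~4%)
        assert localize_lesion(lesion, self._pred(arr)) == {4}

    def test_outside_liver_is_unlocalizable(self):
        arr = np.zeros((4, 4, 4))
        lesion = _lesion(0, 6.0)
        lesion.mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(UnlocalizableLesion):
            localize_lesion(lesion, self._pred(arr))


class TestWeightedKappa:
    CATS = ("good", "moderate", "poor")

    def test_perfect_agreement(self):
        a = ["good", "moderate", "poor", "good", "poor"]
        assert weighted_kappa(a, a, self.CATS) == pytest.approx(1.0)

    def test_balanced_negation_two_categories(self):
        a = ["good", "poor"] * 10
        b = ["poor", "good"] * 10
        assert weighted_kappa(a, b, ("good", "poor")) == pytest.approx(-1.0)

    def test_matches_sklearn_linear_weights(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 60)
        b = np.clip(a + rng.integers(-1, 2, 60), 0, 2)
        ours = weighted_kappa(a.tolist(), b.tolist(), (0, 1, 2))
        theirs = sklearn_metrics.cohen_kappa_score(a, b, weights="linear")
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_equals_unweighted_kappa_for_two_categories(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 80)
        b = np.where(rng.random(80) < 0.7, a, 1 - a)
        ours = weighted_kappa(a.tolist(), b.tolist(), (0, 1))
        theirs = sklearn_metrics.cohen_kappa_score(a, b)  # unweighted
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.integers(0, 3, 30).tolist()
            b = rng.integers(0, 3, 30).tolist()
            k = weighted_kappa(a, b, (0, 1, 2))
            assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12

    def test_too_few_ratings_raise(self):
        with pytest.raises(ValueError):
            weighted_kappa(["good"], ["good"], self.CATS)
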