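import math

import numpy as np
import pytest

from thermoface.geometry import ROIBox
from thermoface.relocation import (
    LocationProbabilities,
    location_probabilities,
    relocate_rois,
    relocation_report_rows,
    select_reference_roi,
    write_relocation_report,
)
from thermoface.roi_placement import FACIAL_ROI_IDS, ROISet
from thermoface.synthetic_fixtures import jittered_roi_set


def shift_roi(rois, k, dx, dy):
    facial = dict(rois.facial)
    facial[k] = facial[k].translated(dx, dy)
    return ROISet(rois.head, facial, rois.frame_index)


class TestLocationProbabilities:
    def test_perfect_placement_is_uniform(self, annotation):
        probs = location_probabilities(annotation, annotation)
        assert np.allclose(probs.pbx, 1 / 11)
        assert np.allclose(probs.pby, 1 / 11)
        assert np.allclose(probs.pb, 1 / 11)

    def test_axes_sum_to_one(self, annotation, rng):
        for _ in range(20):
            rois = jittered_roi_set(annotation, 1, 10.0, rng)
            probs = location_probabilities(rois, annotation)
            assert abs(probs.pbx.sum() - 1.0) <= 1e-12
            assert abs(probs.pby.sum() - 1.0) <= 1e-12
            assert np.all(probs.pb <= probs.pbx) and np.all(probs.pb <= probs.pby)

    def test_single_displacement_closed_form(self, annotation):
        # ROI 1 displaced by exactly 0.5 in normalized x
        dx = annotation.head.w // 2
        assert dx / annotation.head.w == 0.5
        rois = shift_roi(annotation, 1, dx, 0)
        rois = ROISet(rois.head, dict(rois.facial), rois.frame_index)
        probs = location_probabilities(rois, annotation)
        denom = math.exp(-0.5) + 10
        assert probs.pbx[0] == pytest.approx(math.exp(-0.5) / denom, rel=1e-12)
        for i in range(1, 11):
            assert probs.pbx[i] == pytest.approx(1 / denom, rel=1e-12)
        assert np.allclose(probs.pby, 1 / 11)

    def test_zero_head_dimension_rejected(self, annotation):
        bad = ROISet(
            ROIBox(annotation.head.x, annotation.head.y, 1, 1, 0),
            dict(annotation.facial),
        )
        # ROIBox forbids zero sizes; the guard triggers on the annotation side
        with pytest.raises(ValueError):
            LocationProbabilities(np.zeros(11), np.zeros(11), np.zeros(11))

    def test_invariant_entries_open_interval(self, annotation, rng):
        rois = jittered_roi_set(annotation, 3, 25.0, rng)
        probs = location_probabilities(rois, annotation)
        assert np.all(probs.pb > 0) and np.all(probs.pb < 1)


class TestSelectReferenceRoi:
    def test_all_equal_ties_to_first(self, annotation):
        probs = location_probabilities(annotation, annotation)
        assert select_reference_roi(probs) == 1

    def test_unperturbed_roi_wins(self, annotation, rng):
        for keep in (1, 5, 11):
            rois = jittered_roi_set(annotation, keep, 8.0, rng)
            probs = location_probabilities(rois, annotation)
            assert select_reference_roi(probs) == keep

    def test_min_rule_penalizes_y_displacement(self, annotation):
        # ROI 2 displaced only in y still loses to the fully correct ROI 5
        rois = shift_roi(annotation, 2, 0, 15)
        for k in FACIAL_ROI_IDS:
            if k not in (2, 5):
                rois = shift_roi(rois, k, 7, 7)
        probs = location_probabilities(rois, annotation)
        assert select_reference_roi(probs) == 5
        i2 = 1
        assert probs.pb[i2] == probs.pby[i2] < probs.pbx[i2]

    def test_worst_mode(self, annotation, rng):
        rois = jittered_roi_set(annotation, 4, 8.0, rng)
        probs = location_probabilities(rois, annotation)
        assert select_reference_roi(probs, "worst") == int(np.argmin(probs.pb)) + 1

    def test_unknown_mode(self, annotation):
        probs = location_probabilities(annotation, annotation)
        with pytest.raises(ValueError):
            select_reference_roi(probs, "middling")


class TestRelocateRois:
    def test_reference_roi_maps_to_itself(self, annotation, rng):
        rois = jittered_roi_set(annotation, 6, 5.0, rng)
        moved = relocate_rois(rois, 6, annotation)
        assert moved.facial[6] == rois.facial[6]

    def test_same_head_and_correct_reference_recovers_annotation(self, annotation, rng):
        rois = jittered_roi_set(annotation, 3, 6.0, rng)
        moved = relocate_rois(rois, 3, annotation)
        for k in FACIAL_ROI_IDS:
            assert moved.facial[k].corner == annotation.facial[k].corner

    def test_doubled_head_doubles_offsets(self, annotation):
        head2 = ROIBox(
            annotation.head.x,
            annotation.head.y,
            2 * annotation.head.w,
            2 * annotation.head.h,
            0,
        )
        rois2 = ROISet(head2, dict(annotation.facial), 1)
        moved = relocate_rois(rois2, 5, annotation)
        ref = annotation.facial[5]
        for k in FACIAL_ROI_IDS:
            anno = annotation.facial[k]
            assert moved.facial[k].x == ref.x + 2 * (anno.x - ref.x)
            assert moved.facial[k].y == ref.y + 2 * (anno.y - ref.y)

    def test_sizes_unchanged(self, annotation, rng):
        rois = jittered_roi_set(annotation, 2, 9.0, rng)
        moved = relocate_rois(rois, 2, annotation)
        for k in FACIAL_ROI_IDS:
            assert (moved.facial[k].w, moved.facial[k].h) == (
                rois.facial[k].w,
                rois.facial[k].h,
            )

    def test_idempotent(self, annotation, rng):
        rois = jittered_roi_set(annotation, 7, 4.0, rng)
        once = relocate_rois(rois, 7, annotation)
        twice = relocate_rois(once, 7, annotation)
        assert once == twice

    def test_invalid_reference_rejected(self, annotation):
        with pytest.raises(ValueError):
            relocate_rois(annotation, 0, annotation)
        with pytest.raises(ValueError):
            relocate_rois(annotation, 12, annotation)


class TestExactRecoveryAndErrorReduction:
    def test_exact_recovery_one_clean_roi(self, annotation, rng):
        for _ in range(25):
            keep = int(rng.integers(1, 12))
            rois = jittered_roi_set(annotation, keep, 5.0, rng)
            probs = location_probabilities(rois, annotation)
            k_ref = select_reference_roi(probs)
            assert k_ref == keep
            moved = relocate_rois(rois, k_ref, annotation)
            for k in FACIAL_ROI_IDS:
                assert moved.facial[k].corner == annotation.facial[k].corner

    def test_recovery_with_scaled_head_within_one_pixel(self, annotation, rng):
        for scale in (0.5, 1.5, 2.0):
            rois = jittered_roi_set(annotation, 5, 6.0, rng, head_scale=scale)
            moved = relocate_rois(rois, 5, annotation)
            w_ratio = rois.head.w / annotation.head.w
            h_ratio = rois.head.h / annotation.head.h
            for k in FACIAL_ROI_IDS:
                gx = annotation.facial[k].x * w_ratio
                gy = annotation.facial[k].y * h_ratio
                assert abs(moved.facial[k].x - gx) <= 1.0
                assert abs(moved.facial[k].y - gy) <= 1.0

    def test_mean_error_not_increased_by_relocation(self, annotation, rng):
        raw_err, rel_err = [], []
        for i in range(100):
            facial = {}
            for k in FACIAL_ROI_IDS:
                anno = annotation.facial[k]
                facial[k] = ROIBox(
                    anno.x + int(round(rng.normal(0, 3))),
                    anno.y + int(round(rng.normal(0, 3))),
                    anno.w,
                    anno.h,
                    k,
                )
            rois = ROISet(annotation.head, facial, i)
            probs = location_probabilities(rois, annotation)
            moved = relocate_rois(rois, select_reference_roi(probs), annotation)
            for k in FACIAL_ROI_IDS:
                ax, ay = annotation.facial[k].corner
                raw_err.append(math.hypot(rois.facial[k].x - ax, rois.facial[k].y - ay))
                rel_err.append(math.hypot(moved.facial[k].x - ax, moved.facial[k].y - ay))
        assert np.mean(rel_err) <= np.mean(raw_err)


class TestReport:
    def test_report_rows_and_csv(self, tmp_path, annotation, rng):
        rois = jittered_roi_set(annotation, 1, 4.0, rng)
        probs = location_probabilities(rois, annotation)
        k_ref = select_reference_roi(probs)
        moved = relocate_rois(rois, k_ref, annotation)
        rows = relocation_report_rows(rois, probs, k_ref, moved)
        assert len(rows) == 11
        assert sum(r["selected"] for r in rows) == 1
        path = tmp_path / "report.csv"
        write_relocation_report(path, rows)
        header = path.read_text().splitlines()[0]
        assert header.split(",") == [
            "frame_index", "roi_id", "pbx", "pby", "pb", "selected",
            "x_before", "y_before", "x_after", "y_after",
        ]
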