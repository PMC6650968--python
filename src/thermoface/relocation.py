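"""Probability-scored ROI relocation against the expert reference frame.

Every automatically placed ROI is scored by how well its head-normalized
corner agrees with the expert annotation, through a softmax of negative
absolute deviations computed separately per axis.  The ROI with the best
score anchors the frame: all other ROI corners are re-derived from it using
the annotated inter-ROI offsets rescaled by the head-size ratio.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .geometry import ROIBox, round_half_away
from .roi_placement import FACIAL_ROI_IDS, AnnotationReference, ROISet

__all__ = [
    "LocationProbabilities",
    "location_probabilities",
    "select_reference_roi",
    "relocate_rois",
    "relocation_report_rows",
    "write_relocation_report",
]


@dataclass(frozen=True)
class LocationProbabilities:
    """Per-ROI placement-agreement probabilities for one frame.

    ``pbx[k-1]`` / ``pby[k-1]`` measure the x / y axis agreement of ROI k
    with the annotation; each vector sums to 1.  ``pb`` is the per-ROI
    minimum of the two.
    """

    pbx: np.ndarray
    pby: np.ndarray
    pb: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        for name in ("pbx", "pby", "pb"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (11,):
                raise ValueError(f"{name} must have 11 entries")
            if np.any(v <= 0) or np.any(v >= 1):
                raise ValueError(f"{name} entries must lie in (0, 1)")
            v.flags.writeable = False
            object.__setattr__(self, name, v)
        for name in ("pbx", "pby"):
            if abs(getattr(self, name).sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1")


def _softmax_agreement(auto: np.ndarray, ref: np.ndarray) -> np.ndarray:
    scores = -np.abs(auto - ref)
    scores -= scores.max()  # overflow guard; softmax is shift-invariant
    e = np.exp(scores)
    return e / e.sum()


def location_probabilities(
    rois_b: ROISet, annotation: AnnotationReference
) -> LocationProbabilities:
    """Score all eleven ROI placements of a frame against the annotation."""
    wb, hb = rois_b.head_width, rois_b.head_height
    wa, ha = annotation.head_width, annotation.head_height
    if wb <= 0 or hb <= 0 or wa <= 0 or ha <= 0:
        raise ValueError("head width/height must be positive on both frames")

    cx_b = np.array([rois_b.facial[k].x for k in FACIAL_ROI_IDS], dtype=float)
    cy_b = np.array([rois_b.facial[k].y for k in FACIAL_ROI_IDS], dtype=float)
    cx_a = np.array([annotation.facial[k].x for k in FACIAL_ROI_IDS], dtype=float)
    cy_a = np.array([annotation.facial[k].y for k in FACIAL_ROI_IDS], dtype=float)

    pbx = _softmax_agreement(cx_b / wb, cx_a / wa)
    pby = _softmax_agreement(cy_b / hb, cy_a / ha)
    pb = np.minimum(pbx, pby)
    return LocationProbabilities(pbx, pby, pb, rois_b.frame_index)


def select_reference_roi(
    probs: LocationProbabilities,
    mode: Literal["best", "worst"] = "best",
) -> int:
    """Pick the anchor ROI id (1..11).

    ``"best"`` (default) takes the highest combined probability, i.e. the
    ROI whose placement agrees most with the expert; ``"worst"`` takes the
    lowest and is kept selectable for comparison.  Ties break toward the
    smallest ROI id.
    """
    if mode == "best":
        idx = int(np.argmax(probs.pb))
    elif mode == "worst":
        idx = int(np.argmin(probs.pb))
    else:
        raise ValueError(f"mode must be 'best' or 'worst', got {mode!r}")
    return idx + 1


def relocate_rois(
    rois_b: ROISet, k_ref: int, annotation: AnnotationReference
) -> ROISet:
    """Re-derive every ROI corner from the anchor ROI ``k_ref``.

    The annotated offset of ROI k from the anchor is rescaled by the ratio
    of the current head size to the annotated head size and added to the
    anchor's current corner.  Sizes are unchanged; the anchor maps to
    itself.  Rounding to integer pixels happens last.
    """
    if k_ref not in FACIAL_ROI_IDS:
        raise ValueError(f"k_ref must be in 1..11, got {k_ref}")
    w_ratio = rois_b.head_width / annotation.head_width
    h_ratio = rois_b.head_height / annotation.head_height
    ref_b = rois_b.facial[k_ref]
    ref_a = annotation.facial[k_ref]

    facial: dict[int, ROIBox] = {}
    for k in FACIAL_ROI_IDS:
        box = rois_b.facial[k]
        anno = annotation.facial[k]
        new_x = ref_b.x + (anno.x - ref_a.x) * w_ratio
        new_y = ref_b.y + (anno.y - ref_a.y) * h_ratio
        facial[k] = box.with_corner(round_half_away(new_x), round_half_away(new_y))
    return ROISet(rois_b.head, facial, rois_b.frame_index)


# ---------------------------------------------------------------------------
# per-frame relocation report

def relocation_report_rows(
    rois_before: ROISet,
    probs: LocationProbabilities,
    k_ref: int,
    rois_after: ROISet,
) -> list[dict]:
    rows = []
    for i, k in enumerate(FACIAL_ROI_IDS):
        before = rois_before.facial[k]
        after = rois_after.facial[k]
        rows.append(
            {
                "frame_index": rois_before.frame_index,
                "roi_id": k,
                "pbx": probs.pbx[i],
                "pby": probs.pby[i],
                "pb": probs.pb[i],
                "selected": int(k == k_ref),
                "x_before": before.x,
                "y_before": before.y,
                "x_after": after.x,
                "y_after": after.y,
            }
        )
    return rows


def write_relocation_report(path: str | Path, rows: Iterable[dict]) -> None:
    rows = list(rows)
    if not rows:
        raise ValueError("relocation report is empty")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
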