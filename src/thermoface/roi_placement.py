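"""Placement of the eleven facial ROIs from head/eye/nose detections.

Eleven square regions are laid out on every frame: right/left forehead
(1, 2), right/left periorbital (3, 4), nose tip (5), right/left cheek
(6, 7), right/left perinasal (8, 9) and right/left chin (10, 11).  Each
region's side is a fixed percentage of the detected head width.  Where each
region sits relative to its anchor detection is learned once from a single
expert-annotated frame and re-applied on every other frame.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol

from .geometry import ROIBox, round_half_away

__all__ = [
    "FACIAL_ROI_IDS",
    "ROI_REGION",
    "REGION_PROPORTIONS",
    "REFERENCE_PRIORITY",
    "ROIBox",
    "ROISet",
    "AnnotationReference",
    "DetectionSet",
    "OffsetTable",
    "roi_sizes_from_head_width",
    "roi_size_for",
    "reference_offsets",
    "place_rois",
    "InvalidFrameError",
    "Detector",
    "CascadeDetector",
    "detect_sequence",
    "read_roi_csv",
    "write_roi_csv",
    "read_detection_csv",
    "write_detection_csv",
]

FACIAL_ROI_IDS: tuple[int, ...] = tuple(range(1, 12))

#: region class of each facial ROI id
ROI_REGION: dict[int, str] = {
    1: "forehead",
    2: "forehead",
    3: "periorbital",
    4: "periorbital",
    5: "nose",
    6: "cheek",
    7: "cheek",
    8: "perinasal",
    9: "perinasal",
    10: "chin",
    11: "chin",
}

#: square side of each region class as a fraction of the head width
REGION_PROPORTIONS: dict[str, float] = {
    "nose": 0.0649,
    "forehead": 0.1428,
    "periorbital": 0.0324,
    "cheek": 0.0974,
    "perinasal": 0.0324,
    "chin": 0.0519,
}

#: which detected box anchors each ROI, in fallback order.  The forehead and
#: chin regions can be anchored to the head box when the eye/nose detection
#: is unavailable; the periorbital/nose/cheek/perinasal regions require
#: their local detection.
REFERENCE_PRIORITY: dict[int, tuple[str, ...]] = {
    1: ("eyes", "head"),
    2: ("eyes", "head"),
    3: ("nose",),
    4: ("nose",),
    5: ("nose",),
    6: ("eyes",),
    7: ("eyes",),
    8: ("eyes",),
    9: ("eyes",),
    10: ("nose", "head"),
    11: ("nose", "head"),
}


class InvalidFrameError(RuntimeError):
    """Raised when a frame has no usable detections and no fallback."""


@dataclass(frozen=True)
class ROISet:
    """Head box plus the eleven facial boxes of one frame."""

    head: ROIBox
    facial: dict[int, ROIBox]
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.head.roi_id != 0:
            raise ValueError("head box must have roi_id 0")
        if sorted(self.facial) != list(FACIAL_ROI_IDS):
            raise ValueError("ROISet needs exactly the 11 facial boxes (ids 1..11)")
        for k, box in self.facial.items():
            if box.roi_id != k:
                raise ValueError(f"facial box keyed {k} carries roi_id {box.roi_id}")

    @property
    def head_width(self) -> int:
        return self.head.w

    @property
    def head_height(self) -> int:
        return self.head.h

    def boxes(self) -> list[ROIBox]:
        return [self.head] + [self.facial[k] for k in FACIAL_ROI_IDS]


@dataclass(frozen=True)
class AnnotationReference(ROISet):
    """Expert-annotated ROISet of the single reference frame."""


@dataclass(frozen=True)
class DetectionSet:
    """Head/eyes/nose boxes returned by the detector for one frame."""

    head_box: ROIBox | None = None
    eyes_box: ROIBox | None = None
    nose_box: ROIBox | None = None
    frame_index: int = 0

    def get(self, kind: str) -> ROIBox | None:
        return {"head": self.head_box, "eyes": self.eyes_box, "nose": self.nose_box}[kind]


#: normalized corner offsets keyed by (roi_id, reference kind)
OffsetTable = Mapping[tuple[int, str], tuple[float, float]]


def roi_sizes_from_head_width(head_width: int) -> dict[str, int]:
    """Square side per region class for a given head width.

    Sides are ``round(proportion * head_width)`` (halves away from zero) with
    a 1-px floor.
    """
    if head_width < 1:
        raise ValueError(f"head width must be >= 1, got {head_width}")
    return {
        region: max(1, round_half_away(prop * head_width))
        for region, prop in REGION_PROPORTIONS.items()
    }


def roi_size_for(roi_id: int, head_width: int) -> int:
    return roi_sizes_from_head_width(head_width)[ROI_REGION[roi_id]]


def reference_offsets(
    annotation: AnnotationReference, detections_a: DetectionSet
) -> dict[tuple[int, str], tuple[float, float]]:
    """Learn, from the annotated frame, where each ROI sits on its anchor.

    For every (ROI, anchor kind) combination available on the annotated
    frame the stored offset is the ROI corner minus the anchor box corner,
    divided by the anchor box width/height.  Re-applying the offsets on the
    annotated frame reproduces the annotation exactly.
    """
    offsets: dict[tuple[int, str], tuple[float, float]] = {}
    for k in FACIAL_ROI_IDS:
        roi = annotation.facial[k]
        found = False
        for kind in REFERENCE_PRIORITY[k]:
            ref = detections_a.get(kind)
            if ref is None:
                continue
            offsets[(k, kind)] = (
                (roi.x - ref.x) / ref.w,
                (roi.y - ref.y) / ref.h,
            )
            found = True
        if not found:
            raise InvalidFrameError(
                f"annotated frame lacks every anchor detection for ROI {k} "
                f"(needs one of {REFERENCE_PRIORITY[k]})"
            )
    return offsets


def place_rois(
    detections_b: DetectionSet,
    offsets: OffsetTable,
    annotation: AnnotationReference,
) -> ROISet:
    """Lay out the eleven ROIs on a frame from its detections.

    Each ROI corner is its anchor box corner plus the learned normalized
    offset scaled by the anchor dimensions; the side comes from the head
    width and the region proportion.  Anchors are tried in fallback order.
    """
    if detections_b.head_box is None:
        raise InvalidFrameError(
            f"frame {detections_b.frame_index}: no head detection"
        )
    head = ROIBox(
        detections_b.head_box.x,
        detections_b.head_box.y,
        detections_b.head_box.w,
        detections_b.head_box.h,
        0,
    )
    sizes = roi_sizes_from_head_width(head.w)
    facial: dict[int, ROIBox] = {}
    for k in FACIAL_ROI_IDS:
        box = None
        for kind in REFERENCE_PRIORITY[k]:
            ref = detections_b.get(kind)
            if ref is None or (k, kind) not in offsets:
                continue
            ox, oy = offsets[(k, kind)]
            side = sizes[ROI_REGION[k]]
            box = ROIBox(
                round_half_away(ref.x + ox * ref.w),
                round_half_away(ref.y + oy * ref.h),
                side,
                side,
                k,
            )
            break
        if box is None:
            raise InvalidFrameError(
                f"frame {detections_b.frame_index}: no usable anchor for ROI {k}"
            )
        facial[k] = box
    return ROISet(head, facial, detections_b.frame_index)


# ---------------------------------------------------------------------------
# detector adapters

class Detector(Protocol):
    """Pluggable per-frame head/eyes/nose detector."""

    def detect(self, frame) -> DetectionSet:  # pragma: no cover - protocol
        ...


class CascadeDetector:
    """Viola-Jones cascade adapter over OpenCV's pre-trained models.

    Optional: requires ``opencv-python``.  When several detections fire, the
    largest-area box wins.
    """

    def __init__(self) -> None:
        try:
            import cv2
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "CascadeDetector requires opencv-python (install extra "
                "'thermoface[detect]'); tests and the synthetic pipeline use "
                "ground-truth DetectionSets instead"
            ) from exc
        self._cv2 = cv2
        base = Path(cv2.data.haarcascades)
        self._cascades = {
            "head": cv2.CascadeClassifier(str(base / "haarcascade_frontalface_default.xml")),
            "eyes": cv2.CascadeClassifier(str(base / "haarcascade_eye.xml")),
            "nose": cv2.CascadeClassifier(str(base / "haarcascade_mcs_nose.xml")),
        }

    def detect(self, frame) -> DetectionSet:  # pragma: no cover - optional dependency
        gray = frame.pixels
        if gray.ndim == 3:
            gray = self._cv2.cvtColor(gray, self._cv2.COLOR_RGB2GRAY)
        boxes: dict[str, ROIBox | None] = {}
        for kind, cascade in self._cascades.items():
            hits = cascade.detectMultiScale(gray)
            if len(hits) == 0:
                boxes[kind] = None
                continue
            x, y, w, h = max(hits, key=lambda b: b[2] * b[3])
            boxes[kind] = ROIBox(int(x), int(y), int(w), int(h), 0)
        return DetectionSet(boxes["head"], boxes["eyes"], boxes["nose"], frame.index)


def detect_sequence(detections: Iterable[DetectionSet]) -> list[DetectionSet]:
    """Fill missing eyes/nose boxes by carrying the previous frame's forward.

    A frame without a head box (and no earlier frame to borrow from) is
    invalid and raises.
    """
    out: list[DetectionSet] = []
    prev: DetectionSet | None = None
    for det in detections:
        head = det.head_box
        eyes = det.eyes_box
        nose = det.nose_box
        if head is None:
            raise InvalidFrameError(f"frame {det.frame_index}: no head detection")
        if eyes is None and prev is not None:
            eyes = prev.eyes_box
        if nose is None and prev is not None:
            nose = prev.nose_box
        filled = DetectionSet(head, eyes, nose, det.frame_index)
        out.append(filled)
        prev = filled
    return out


# ---------------------------------------------------------------------------
# CSV I/O: frame_index, roi_id, x, y, w, h
# roi_id 0 = head, 1..11 = facial ROIs, -1 = eyes detection, -2 = nose.

def write_roi_csv(path: str | Path, roi_sets: Iterable[ROISet]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "roi_id", "x", "y", "w", "h"])
        for rs in roi_sets:
            for box in rs.boxes():
                writer.writerow([rs.frame_index, box.roi_id, box.x, box.y, box.w, box.h])


def read_roi_csv(path: str | Path) -> list[ROISet]:
    by_frame: dict[int, dict[int, ROIBox]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            b = int(row["frame_index"])
            k = int(row["roi_id"])
            by_frame.setdefault(b, {})[k] = ROIBox(
                int(row["x"]), int(row["y"]), int(row["w"]), int(row["h"]), k
            )
    out = []
    for b in sorted(by_frame):
        boxes = by_frame[b]
        if 0 not in boxes:
            raise ValueError(f"frame {b}: ROI CSV is missing the head box (roi_id 0)")
        out.append(ROISet(boxes[0], {k: v for k, v in boxes.items() if k > 0}, b))
    return out


_DET_IDS = {"head": 0, "eyes": -1, "nose": -2}


def write_detection_csv(path: str | Path, detections: Iterable[DetectionSet]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "roi_id", "x", "y", "w", "h"])
        for det in detections:
            for kind, rid in _DET_IDS.items():
                box = det.get(kind)
                if box is not None:
                    writer.writerow([det.frame_index, rid, box.x, box.y, box.w, box.h])


def read_detection_csv(path: str | Path) -> list[DetectionSet]:
    by_frame: dict[int, dict[int, ROIBox]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            b = int(row["frame_index"])
            rid = int(row["roi_id"])
            by_frame.setdefault(b, {})[rid] = ROIBox(
                int(row["x"]), int(row["y"]), int(row["w"]), int(row["h"]), 0
            )
    return [
        DetectionSet(
            by_frame[b].get(0), by_frame[b].get(-1), by_frame[b].get(-2), b
        )
        for b in sorted(by_frame)
    ]
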