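"""Thermal appearance descriptor: 14 features per ROI, 154 per frame.

Per ROI patch, seven static statistics are computed (global mean, variance
and median; means of per-row variances and medians; means of per-column
variances and medians) plus their seven differences from the previous
frame, giving 11 x 14 = 154 values per frame.

Conventions: the median of an even-count sample is the mean of the two
middle values; sample variances use an n-1 divisor, defined as 0 when the
divisor degenerates (single pixel, single row/column entry); first-frame
temporal differences are 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import ROIBox
from .imaging import Frame
from .roi_placement import FACIAL_ROI_IDS, ROISet

__all__ = [
    "EMOTION_LABELS",
    "N_STATIC",
    "N_PER_ROI",
    "N_FEATURES",
    "ROIPatch",
    "FeatureVector",
    "extract_patch",
    "extract_patches",
    "static_features",
    "temporal_differences",
    "frame_feature_vector",
    "extract_sequence_features",
    "feature_column_names",
    "write_feature_csv",
    "read_feature_csv",
]

EMOTION_LABELS = ("disgust", "fear", "happiness", "sadness", "surprise")

N_STATIC = 7
N_PER_ROI = 14
N_FEATURES = len(FACIAL_ROI_IDS) * N_PER_ROI  # 154


@dataclass(frozen=True)
class ROIPatch:
    """Thermal pixels cropped under one ROI box."""

    pixels: np.ndarray
    roi_id: int = 0
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("patch must be a non-empty 2-D grid")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("patch intensities must lie in [0, 255]")
        px.flags.writeable = False
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class FeatureVector:
    """154 thermal features of one frame, ordered (k=1..11) x (c=1..14)."""

    values: np.ndarray
    frame_index: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} entries")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        v.flags.writeable = False
        object.__setattr__(self, "values", v)


def extract_patch(frame: Frame, box: ROIBox) -> ROIPatch:
    """Crop the box from a thermal frame, clipping it to the frame bounds."""
    x0 = max(0, box.x)
    y0 = max(0, box.y)
    x1 = min(frame.width, box.x + box.w)
    y1 = min(frame.height, box.y + box.h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(
            f"ROI {box.roi_id} box {box} lies outside the {frame.width}x"
            f"{frame.height} frame"
        )
    return ROIPatch(frame.pixels[y0:y1, x0:x1], box.roi_id, frame.index)


def extract_patches(frame: Frame, rois: ROISet) -> dict[int, ROIPatch]:
    return {k: extract_patch(frame, rois.facial[k]) for k in FACIAL_ROI_IDS}


def _var(values: np.ndarray) -> float:
    # sample variance, 0 when the n-1 divisor degenerates
    return float(np.var(values, ddof=1)) if values.size > 1 else 0.0


def static_features(patch: ROIPatch) -> np.ndarray:
    """The seven single-frame statistics of one ROI patch (c = 1..7)."""
    px = patch.pixels
    return np.array(
        [
            float(px.mean()),
            _var(px.ravel()),
            float(np.median(px)),
            float(np.mean([_var(row) for row in px])),
            float(np.mean(np.median(px, axis=1))),
            float(np.mean([_var(col) for col in px.T])),
            float(np.mean(np.median(px, axis=0))),
        ]
    )


def temporal_differences(
    curr: np.ndarray, prev: np.ndarray | None = None
) -> np.ndarray:
    """Consecutive-frame differences (c = 8..14); zeros on the first frame."""
    curr = np.asarray(curr, dtype=float)
    if curr.shape != (N_STATIC,):
        raise ValueError(f"expected {N_STATIC} static features")
    if prev is None:
        return np.zeros(N_STATIC)
    prev = np.asarray(prev, dtype=float)
    if prev.shape != (N_STATIC,):
        raise ValueError(f"expected {N_STATIC} previous static features")
    return curr - prev


def frame_feature_vector(
    patches: Mapping[int, ROIPatch],
    prev_statics: Mapping[int, np.ndarray] | None = None,
    frame_index: int = 0,
    label: str | None = None,
) -> tuple[FeatureVector, dict[int, np.ndarray]]:
    """Assemble the 154-feature vector of one frame.

    Returns the vector together with the per-ROI static features, to be
    passed as ``prev_statics`` for the next frame.
    """
    if sorted(patches) != list(FACIAL_ROI_IDS):
        raise ValueError("exactly the 11 facial patches (ids 1..11) are required")
    statics: dict[int, np.ndarray] = {}
    blocks = []
    for k in FACIAL_ROI_IDS:
        s = static_features(patches[k])
        statics[k] = s
        prev = prev_statics.get(k) if prev_statics is not None else None
        blocks.append(np.concatenate([s, temporal_differences(s, prev)]))
    return FeatureVector(np.concatenate(blocks), frame_index, label), statics


def extract_sequence_features(
    frames: Sequence[Frame],
    roi_sets: Sequence[ROISet],
    labels: Sequence[str] | None = None,
    drop_first: bool = False,
) -> list[FeatureVector]:
    """Run per-frame extraction over a sequence, threading the temporal state.

    ``drop_first=True`` discards the first frame instead of zero-filling its
    temporal differences.
    """
    if len(frames) != len(roi_sets):
        raise ValueError("frames and ROI sets must align one-to-one")
    if labels is not None and len(labels) != len(frames):
        raise ValueError("labels must align with frames")
    out: list[FeatureVector] = []
    prev: dict[int, np.ndarray] | None = None
    for i, (frame, rois) in enumerate(zip(frames, roi_sets)):
        patches = extract_patches(frame, rois)
        vec, prev = frame_feature_vector(
            patches, prev, frame.index, labels[i] if labels is not None else None
        )
        out.append(vec)
    return out[1:] if drop_first else out


# ---------------------------------------------------------------------------
# CSV layout: frame_index, f{k}_{c} for k=1..11 and c=1..14, optional label

def feature_column_names() -> list[str]:
    return [f"f{k}_{c}" for k in FACIAL_ROI_IDS for c in range(1, N_PER_ROI + 1)]


def write_feature_csv(path: str | Path, vectors: Iterable[FeatureVector]) -> None:
    vectors = list(vectors)
    has_labels = any(v.label is not None for v in vectors)
    cols = ["frame_index"] + feature_column_names() + (["label"] if has_labels else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for v in vectors:
            row = [v.frame_index] + [repr(float(x)) for x in v.values]
            if has_labels:
                row.append(v.label if v.label is not None else "")
            writer.writerow(row)


def read_feature_csv(path: str | Path) -> list[FeatureVector]:
    cols = feature_column_names()
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            values = np.array([float(row[c]) for c in cols])
            label = row.get("label") or None
            out.append(FeatureVector(values, int(row["frame_index"]), label))
    return out
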