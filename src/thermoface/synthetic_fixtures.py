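"""Synthetic paired visual/thermal face-phantom sequences with ground truth.

The phantom is a warm elliptical "head" on a cool background, rendered
consistently on both camera planes, with configurable head motion, detector
jitter, a fixed-pattern noise field (identical in every frame), salt-and-
pepper noise and per-emotion thermal offsets on individual facial regions.
Everything is deterministic given the seed, so the whole pipeline can be
exercised without any external recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .geometry import ROIBox, round_half_away
from .imaging import Frame, NoiseReference
from .roi_placement import (
    FACIAL_ROI_IDS,
    ROI_REGION,
    AnnotationReference,
    DetectionSet,
    ROISet,
    roi_sizes_from_head_width,
)
from .thermal_features import EMOTION_LABELS

__all__ = [
    "DEFAULT_ROI_LAYOUT",
    "DEFAULT_CLASS_OFFSETS",
    "PhantomConfig",
    "GroundTruth",
    "generate_sequence",
    "jittered_roi_set",
    "generate_feature_dataset",
]

#: left-upper ROI corners as fractions of the head box (x, y)
DEFAULT_ROI_LAYOUT: dict[int, tuple[float, float]] = {
    1: (0.22, 0.10),  # right forehead
    2: (0.64, 0.10),  # left forehead
    3: (0.27, 0.35),  # right periorbital
    4: (0.70, 0.35),  # left periorbital
    5: (0.47, 0.52),  # nose tip
    6: (0.16, 0.55),  # right cheek
    7: (0.72, 0.55),  # left cheek
    8: (0.40, 0.67),  # right perinasal
    9: (0.57, 0.67),  # left perinasal
    10: (0.35, 0.85),  # right chin
    11: (0.60, 0.85),  # left chin
}

#: eyes/nose detection bands as (x, y, w, h) fractions of the head box
_EYES_FRACTION = (0.20, 0.30, 0.60, 0.15)
_NOSE_FRACTION = (0.40, 0.45, 0.20, 0.25)

#: per-emotion brightness offsets per ROI (autonomic-style patterns, e.g.
#: nose-tip cooling for fear, periorbital warming for surprise)
DEFAULT_CLASS_OFFSETS: dict[str, dict[int, float]] = {
    "disgust": {5: -10, 8: 8, 9: 8},
    "fear": {5: -20, 3: 6, 4: 6},
    "happiness": {6: 10, 7: 10, 10: 6, 11: 6},
    "sadness": {1: -6, 2: -6, 5: -5},
    "surprise": {3: 12, 4: 12, 1: 8, 2: 8},
}


@dataclass(frozen=True)
class PhantomConfig:
    width: int = 240
    height: int = 240
    head_center: tuple[float, float] = (120.0, 110.0)
    head_axes: tuple[float, float] = (55.0, 75.0)  # semi-axes (x, y)
    roi_layout: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_LAYOUT)
    )
    class_offsets: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_OFFSETS.items()}
    )
    labels: Sequence[str] | None = None  # per frame; None -> no emotion offsets
    translation_amplitude: float = 0.0  # px of sinusoidal head drift
    scale_amplitude: float = 0.0  # fractional head-size oscillation
    jitter_sd: float = 0.0  # detector corner jitter, px
    fpn_amplitude: int = 0  # fixed-pattern noise peak
    salt_pepper_rate: float = 0.0
    n_frames: int = 10
    rate_hz: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sd < 0 or self.fpn_amplitude < 0 or self.salt_pepper_rate < 0:
            raise ValueError("noise rates/amplitudes must be >= 0")
        for k, (fx, fy) in self.roi_layout.items():
            if not (0 <= fx <= 1 and 0 <= fy <= 1):
                raise ValueError(f"ROI {k} layout fractions must lie in [0, 1]")
        cx, cy = self.head_center
        ax, ay = self.head_axes
        if ax < 5 or ay < 5:
            raise ValueError("head axes too small to carry 11 ROIs")
        if not (0 <= cx < self.width and 0 <= cy < self.height):
            raise ValueError("head center must lie inside the image")
        if self.labels is not None:
            if len(self.labels) != self.n_frames:
                raise ValueError("labels must have one entry per frame")
            unknown = set(self.labels) - set(EMOTION_LABELS)
            if unknown:
                raise ValueError(f"unknown emotion labels: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    roi_sets: list[ROISet]  # true thermal-plane ROI layout per frame
    detections_true: list[DetectionSet]
    detections_jittered: list[DetectionSet]
    labels: list[str | None]
    noise_reference: NoiseReference
    annotation: AnnotationReference  # frame 0's true layout


def _fraction_box(head: ROIBox, frac: tuple[float, float, float, float]) -> ROIBox:
    fx, fy, fw, fh = frac
    return ROIBox(
        round_half_away(head.x + fx * head.w),
        round_half_away(head.y + fy * head.h),
        max(1, round_half_away(fw * head.w)),
        max(1, round_half_away(fh * head.h)),
        0,
    )


def _true_roi_set(config: PhantomConfig, head: ROIBox, frame_index: int) -> ROISet:
    sizes = roi_sizes_from_head_width(head.w)
    facial = {}
    for k in FACIAL_ROI_IDS:
        fx, fy = config.roi_layout[k]
        side = sizes[ROI_REGION[k]]
        facial[k] = ROIBox(
            round_half_away(head.x + fx * head.w),
            round_half_away(head.y + fy * head.h),
            side,
            side,
            k,
        )
    return ROISet(head, facial, frame_index)


def _head_box(config: PhantomConfig, b: int) -> ROIBox:
    phase = 2 * math.pi * b / max(config.n_frames, 2)
    dx = config.translation_amplitude * math.sin(phase)
    dy = config.translation_amplitude * math.cos(phase)
    scale = 1.0 + config.scale_amplitude * math.sin(phase)
    cx, cy = config.head_center
    ax = config.head_axes[0] * scale
    ay = config.head_axes[1] * scale
    return ROIBox(
        round_half_away(cx + dx - ax),
        round_half_away(cy + dy - ay),
        max(1, round_half_away(2 * ax)),
        max(1, round_half_away(2 * ay)),
        0,
    )


def _ellipse_mask(config: PhantomConfig, head: ROIBox) -> np.ndarray:
    yy, xx = np.mgrid[0 : config.height, 0 : config.width]
    cx = head.x + head.w / 2.0
    cy = head.y + head.h / 2.0
    ax = head.w / 2.0
    ay = head.h / 2.0
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _jitter_box(
    box: ROIBox, sd: float, rng: np.random.Generator, width: int, height: int
) -> ROIBox:
    if sd == 0:
        return box
    # jitter the corner, truncated so the box stays inside the frame
    dx = round_half_away(float(rng.normal(0, sd)))
    dy = round_half_away(float(rng.normal(0, sd)))
    x = int(np.clip(box.x + dx, 0, max(0, width - box.w)))
    y = int(np.clip(box.y + dy, 0, max(0, height - box.h)))
    return ROIBox(x, y, box.w, box.h, box.roi_id)


def generate_sequence(
    config: PhantomConfig,
) -> tuple[list[Frame], list[Frame], GroundTruth]:
    """Render the phantom sequence.

    Returns ``(visual_frames, thermal_frames, ground_truth)``.  The thermal
    model is additive: smooth clean face + per-ROI emotion offsets +
    fixed-pattern noise + salt-and-pepper, clipped to [0, 255]; subtracting
    the emitted noise reference recovers the clean image wherever no
    clipping or impulse noise hit.
    """
    rng = np.random.default_rng(config.seed)
    fpn = rng.integers(0, config.fpn_amplitude + 1, (config.height, config.width)).astype(
        np.int16
    )
    noise_ref = NoiseReference(fpn.astype(np.uint8))

    visual_frames: list[Frame] = []
    thermal_frames: list[Frame] = []
    roi_sets: list[ROISet] = []
    det_true: list[DetectionSet] = []
    det_jit: list[DetectionSet] = []
    labels: list[str | None] = []

    for b in range(config.n_frames):
        head = _head_box(config, b)
        rois = _true_roi_set(config, head, b)
        mask = _ellipse_mask(config, head)

        clean = np.full((config.height, config.width), 40.0)
        clean[mask] = 170.0
        label = config.labels[b] if config.labels is not None else None
        if label is not None:
            for k, offset in config.class_offsets.get(label, {}).items():
                box = rois.facial[k]
                clean[box.y : box.y + box.h, box.x : box.x + box.w] += offset
        clean = ndimage.gaussian_filter(clean, sigma=3.0)
        thermal = np.clip(np.rint(clean).astype(np.int16) + fpn, 0, 255)

        if config.salt_pepper_rate > 0:
            hits = rng.random((config.height, config.width)) < config.salt_pepper_rate
            values = np.where(rng.random((config.height, config.width)) < 0.5, 0, 255)
            thermal = np.where(hits, values, thermal)

        visual = np.full((config.height, config.width, 3), 60, dtype=np.uint8)
        skin = np.array([200, 160, 130], dtype=np.uint8)
        visual[mask] = skin

        timestamp = b / config.rate_hz
        thermal_frames.append(Frame(thermal.astype(np.uint8), timestamp, "thermal", b))
        visual_frames.append(Frame(visual, timestamp, "visual", b))

        eyes = _fraction_box(head, _EYES_FRACTION)
        nose = _fraction_box(head, _NOSE_FRACTION)
        det_true.append(DetectionSet(head, eyes, nose, b))
        det_jit.append(
            DetectionSet(
                _jitter_box(head, config.jitter_sd, rng, config.width, config.height),
                _jitter_box(eyes, config.jitter_sd, rng, config.width, config.height),
                _jitter_box(nose, config.jitter_sd, rng, config.width, config.height),
                b,
            )
        )
        roi_sets.append(rois)
        labels.append(label)

    annotation = AnnotationReference(
        roi_sets[0].head, dict(roi_sets[0].facial), roi_sets[0].frame_index
    )
    truth = GroundTruth(roi_sets, det_true, det_jit, labels, noise_ref, annotation)
    return visual_frames, thermal_frames, truth


def jittered_roi_set(
    annotation: AnnotationReference,
    keep_roi: int,
    jitter_sd: float,
    rng: np.random.Generator,
    frame_index: int = 0,
    head_scale: float = 1.0,
) -> ROISet:
    """A frame whose ROI ``keep_roi`` sits exactly at its annotated
    head-normalized position while the other ten corners get i.i.d. jitter.

    With ``head_scale`` != 1 the head box and the true corners are scaled
    about the origin, so recovery is exact up to corner rounding.
    """
    if keep_roi not in FACIAL_ROI_IDS:
        raise ValueError(f"keep_roi must be in 1..11, got {keep_roi}")
    head = ROIBox(
        round_half_away(annotation.head.x * head_scale),
        round_half_away(annotation.head.y * head_scale),
        max(1, round_half_away(annotation.head.w * head_scale)),
        max(1, round_half_away(annotation.head.h * head_scale)),
        0,
    )
    w_ratio = head.w / annotation.head.w
    h_ratio = head.h / annotation.head.h
    facial = {}
    for k in FACIAL_ROI_IDS:
        anno = annotation.facial[k]
        x = round_half_away(anno.x * w_ratio)
        y = round_half_away(anno.y * h_ratio)
        if k != keep_roi:
            # nonzero rounded displacement on both axes, else pixel rounding
            # can tie a perturbed ROI with the clean one under the min rule
            dx = round_half_away(float(rng.normal(0, jitter_sd))) or 1
            dy = round_half_away(float(rng.normal(0, jitter_sd))) or 1
            x += dx
            y += dy
        facial[k] = ROIBox(x, y, anno.w, anno.h, k)
    return ROISet(head, facial, frame_index)


def generate_feature_dataset(
    n_per_class: int,
    n_classes: int = 5,
    separation: float = 5.0,
    d: int = 154,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled Gaussian feature dataset with controllable class separation.

    Class means sit ``separation`` (in within-class sd units) from the
    origin along random directions; features have unit within-class sd.
    Returns ``(X, y)`` with labels 1..n_classes, balanced by construction.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_classes, d))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    means = separation * directions
    x = np.vstack(
        [means[c] + rng.normal(size=(n_per_class, d)) for c in range(n_classes)]
    )
    y = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    return x, y
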