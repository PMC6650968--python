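"""End-to-end orchestration of the ROI localization + feature pipeline.

Stage order follows the system overview: calibrate -> preprocess ->
place -> project -> relocate -> extract, with an optional placement
evaluation against ground truth.  All outputs are written only after every
stage has completed, so a failing input never leaves partial results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import calibration, imaging, placement_evaluation, relocation, roi_placement
from . import synthetic_fixtures as synth
from . import thermal_features
from .calibration import Homography
from .roi_placement import AnnotationReference, DetectionSet, InvalidFrameError, ROISet

logger = logging.getLogger("thermoface")

__all__ = ["PipelineConfig", "PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # synthetic source (used when no frame paths are given)
    synthetic: dict = field(default_factory=dict)
    # file source
    thermal_dir: str | None = None
    visual_dir: str | None = None
    annotation_csv: str | None = None
    annotation_detections_csv: str | None = None
    detections_csv: str | None = None
    noise_reference: str | None = None
    homography_json: str | None = None
    correspondences_csv: str | None = None
    # stage parameters
    pairing_rate_hz: float = 2.0
    median_kernel: int = 3
    relocate: bool = True
    relocation_mode: str = "best"
    max_invalid_fraction: float = 0.2

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"missing config file: {p}")
    data = yaml.safe_load(p.read_text()) or {}
    if not isinstance(data, dict):
        raise PipelineError(f"config file {p} must hold a mapping")
    return PipelineConfig.from_dict(data)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise PipelineError(f"missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"missing required input: {what} ({p})")
    return p


def project_roi_set(h: Homography, rois: ROISet) -> ROISet:
    """Carry a full ROISet across camera planes box by box."""
    head = calibration.project_box(h, rois.head)
    facial = {k: calibration.project_box(h, box) for k, box in rois.facial.items()}
    return ROISet(head, facial, rois.frame_index)


def _load_inputs(config: PipelineConfig):
    """Resolve frames, annotation, detections, homography and noise ref."""
    if config.thermal_dir is None:
        pconf = synth.PhantomConfig(**{"seed": config.seed, **config.synthetic})
        visual, thermal, truth = synth.generate_sequence(pconf)
        homography = Homography.identity()
        return (
            visual,
            thermal,
            truth.annotation,
            truth.detections_true[0],
            truth.detections_jittered,
            truth.noise_reference,
            homography,
            truth,
        )

    thermal_dir = _require(config.thermal_dir, "thermal frames directory")
    sidecar = imaging.read_timestamp_sidecar(thermal_dir / "timestamps.csv")
    thermal = [
        imaging.read_frame(thermal_dir / f"frame_{idx:05d}.png", "thermal", ts, idx)
        for idx, ts in sorted(sidecar.items())
    ]
    visual = None
    if config.visual_dir is not None:
        visual_dir = _require(config.visual_dir, "visual frames directory")
        vside = imaging.read_timestamp_sidecar(visual_dir / "timestamps.csv")
        visual = [
            imaging.read_frame(visual_dir / f"frame_{idx:05d}.png", "visual", ts, idx)
            for idx, ts in sorted(vside.items())
        ]

    anno_path = _require(config.annotation_csv, "annotation CSV")
    try:
        anno_sets = roi_placement.read_roi_csv(anno_path)
    except (ValueError, KeyError) as exc:
        raise PipelineError(f"corrupt annotation file {anno_path}: {exc}") from exc
    if len(anno_sets) != 1:
        raise PipelineError("annotation CSV must describe exactly one frame")
    a = anno_sets[0]
    annotation = AnnotationReference(a.head, dict(a.facial), a.frame_index)

    det_a_path = _require(config.annotation_detections_csv, "annotation detections CSV")
    det_a = roi_placement.read_detection_csv(det_a_path)[0]
    det_path = _require(config.detections_csv, "detections CSV")
    detections = roi_placement.read_detection_csv(det_path)

    noise_ref = None
    if config.noise_reference is not None:
        ref_path = _require(config.noise_reference, "noise reference frame")
        noise_ref = imaging.NoiseReference(
            imaging.read_frame(ref_path, "thermal").pixels
        )

    if config.homography_json is not None:
        homography = calibration.load_homography(
            _require(config.homography_json, "homography JSON")
        )
    elif config.correspondences_csv is not None:
        corrs = calibration.read_correspondences(
            _require(config.correspondences_csv, "correspondences CSV")
        )
        homography = calibration.estimate_homography(corrs)
    else:
        homography = Homography.identity()
    return visual, thermal, annotation, det_a, detections, noise_ref, homography, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the feature table plus reports.

    Returns a summary dict with per-stage counts and output paths.
    """
    (
        visual,
        thermal,
        annotation,
        det_a,
        detections,
        noise_ref,
        homography,
        truth,
    ) = _load_inputs(config)
    logger.info("loaded %d thermal frames", len(thermal))

    # preprocess
    if noise_ref is not None:
        thermal = [imaging.subtract_noise_reference(f, noise_ref) for f in thermal]
    thermal = [imaging.median_filter(f, config.median_kernel) for f in thermal]

    # offsets learned once on the annotated frame; the annotation lives on
    # the thermal plane, so detections are projected there first
    h_inv = homography.inverse()  # noqa: F841  (kept for visual-plane outputs)
    det_a_thermal = DetectionSet(
        None if det_a.head_box is None else calibration.project_box(homography, det_a.head_box),
        None if det_a.eyes_box is None else calibration.project_box(homography, det_a.eyes_box),
        None if det_a.nose_box is None else calibration.project_box(homography, det_a.nose_box),
        det_a.frame_index,
    )
    offsets = roi_placement.reference_offsets(annotation, det_a_thermal)

    detections = roi_placement.detect_sequence(detections)
    placed: list[ROISet] = []
    kept_frames = []
    invalid = 0
    for frame, det in zip(thermal, detections):
        det_thermal = DetectionSet(
            None if det.head_box is None else calibration.project_box(homography, det.head_box),
            None if det.eyes_box is None else calibration.project_box(homography, det.eyes_box),
            None if det.nose_box is None else calibration.project_box(homography, det.nose_box),
            det.frame_index,
        )
        try:
            placed.append(roi_placement.place_rois(det_thermal, offsets, annotation))
            kept_frames.append(frame)
        except InvalidFrameError as exc:
            logger.warning("skipping frame: %s", exc)
            invalid += 1
    if not placed or invalid / len(thermal) > config.max_invalid_fraction:
        raise PipelineError(
            f"{invalid}/{len(thermal)} frames invalid, above the "
            f"{config.max_invalid_fraction:.0%} threshold"
        )

    # relocation
    report_rows = []
    final_sets = placed
    if config.relocate:
        final_sets = []
        for rois in placed:
            probs = relocation.location_probabilities(rois, annotation)
            k_ref = relocation.select_reference_roi(probs, config.relocation_mode)
            moved = relocation.relocate_rois(rois, k_ref, annotation)
            report_rows.extend(
                relocation.relocation_report_rows(rois, probs, k_ref, moved)
            )
            final_sets.append(moved)

    # feature extraction
    labels = None
    if truth is not None and any(lbl is not None for lbl in truth.labels):
        labels = [truth.labels[rs.frame_index] for rs in final_sets]
    vectors = thermal_features.extract_sequence_features(kept_frames, final_sets, labels)

    # placement evaluation against ground truth when available
    summary = None
    tests = None
    if truth is not None:
        manual = [truth.roi_sets[rs.frame_index] for rs in placed]
        comps = placement_evaluation.compare_roi_sets(placed, manual, "raw")
        if config.relocate:
            comps += placement_evaluation.compare_roi_sets(
                final_sets, manual, "relocated"
            )
        summary = placement_evaluation.summarize_by_roi(comps)
        if config.relocate:
            tests = {}
            for k in sorted(placed[0].facial):
                raw_d = [c.distance for c in comps if c.roi_id == k and c.method == "raw"]
                rel_d = [
                    c.distance for c in comps if c.roi_id == k and c.method == "relocated"
                ]
                diffs = np.array(raw_d) - np.array(rel_d)
                tests[k] = placement_evaluation.wilcoxon_zero_median(diffs)

    # all stages succeeded: write outputs
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    feat_path = out_dir / "features.csv"
    thermal_features.write_feature_csv(feat_path, vectors)
    outputs["features"] = str(feat_path)
    rois_path = out_dir / "rois.csv"
    roi_placement.write_roi_csv(rois_path, final_sets)
    outputs["rois"] = str(rois_path)
    if report_rows:
        rep_path = out_dir / "relocation_report.csv"
        relocation.write_relocation_report(rep_path, report_rows)
        outputs["relocation_report"] = str(rep_path)
    if summary is not None:
        eval_path = out_dir / "placement_report.csv"
        placement_evaluation.write_placement_report(eval_path, summary, tests)
        outputs["placement_report"] = str(eval_path)

    counts = {
        "frames": len(thermal),
        "invalid_frames": invalid,
        "placed": len(placed),
        "features": len(vectors),
    }
    logger.info("pipeline done: %s", counts)
    return {"outputs": outputs, "counts": counts}
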