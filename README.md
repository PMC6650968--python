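# thermoface

Facial ROI localization and emotion recognition from paired visual +
infrared-thermal video.

The package implements the full processing chain for dual-camera facial
thermography:

- **imaging** — 8-bit frame model, 2-fps stream pairing, fixed-pattern-noise
  subtraction against a uniform-temperature reference frame, and median
  denoising.
- **calibration** — visual-to-thermal homography by normalized DLT from
  chessboard correspondences; point and box projection between camera planes.
- **roi_placement** — eleven facial ROIs (forehead, periorbital, nose tip,
  cheek, perinasal, chin; right/left) sized as fixed proportions of the head
  width and anchored on head/eyes/nose detections, with the anchor offsets
  learned once from a single expert-annotated frame.
- **relocation** — each placed ROI is scored against the expert annotation by
  a per-axis softmax of negative absolute deviations of head-normalized
  corners; the best-scoring ROI re-derives all other ROI positions.
- **thermal_features** — 7 static statistics per ROI patch plus 7
  consecutive-frame differences: 14 per ROI, 154 per frame.
- **recognition** — z-score normalization, SVD-based PCA (default 60
  components), closed-form Gaussian discriminant classifiers (LDA/QDA with
  full or diagonal covariance, Mahalanobis, naive Bayes) plus a delegated
  linear SVM, stratified k-fold cross-validation, and accuracy / Cohen's
  kappa / per-class TPR-FPR metrics.
- **placement_evaluation** — Euclidean corner distances, per-ROI mean ±
  standard error, and a Wilcoxon signed-rank test for zero median (exact up
  to n = 25, continuity-corrected normal approximation beyond).
- **synthetic_fixtures** — deterministic face-phantom generator (paired
  visual/thermal frames, ground-truth ROI layouts, head motion, detector
  jitter, fixed-pattern and salt-and-pepper noise, per-emotion thermal
  offsets) and a labeled Gaussian feature-dataset generator, so every stage
  is testable without external recordings.

## CLI

The `thermoface` entry point chains the pipeline stages:

```sh
thermoface simulate --out sim --n-frames 20 --seed 1      # phantom sequence + ground truth
thermoface calibrate --correspondences corrs.csv --out h.json
thermoface preprocess --frames sim/thermal --noise-ref sim/noise_reference.png --out pre
thermoface place --detections sim/detections.csv --annotation sim/annotation.csv \
    --annotation-detections sim/annotation_detections.csv --out rois.csv
thermoface relocate --rois rois.csv --annotation sim/annotation.csv \
    --out relocated.csv --report relocation_report.csv
thermoface extract --frames pre --rois relocated.csv --out features.csv
thermoface train --features sim/features.csv --components 60 \
    --classifier lda_full --kfold 3 --runs 10 --seed 0 --out eval.json
thermoface evaluate --auto rois.csv --manual sim/ground_truth_rois.csv \
    --relocated relocated.csv --out placement.csv
```

or runs everything from a YAML config:

```sh
thermoface run --config config.yaml --seed 1
```

A config without frame paths uses the synthetic phantom source; see
`thermoface.pipeline.PipelineConfig` for the available keys.

## Conventions

Coordinates are 0-based, x rightward, y downward; boxes are `(x, y, w, h)`
with half-open extent. Thermal intensities are 8-bit brightness (0–255,
brighter = warmer); no radiometric temperature calibration is performed.
Feature CSVs use columns `f{k}_{c}` for ROI `k` = 1..11 and feature
`c` = 1..14, plus `frame_index` and an optional `label` column.
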