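"""Visual-to-thermal homography estimation (normalized DLT) and projection.

The two cameras view the face from nearly the same axis, so a single 3x3
projective transform estimated from chessboard correspondences is used to
carry boxes from the visual plane onto the thermal plane.  The face is not
planar, so the homography is an approximation; no residual model is fitted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import ROIBox, round_half_away

__all__ = [
    "Correspondence",
    "Homography",
    "estimate_homography",
    "apply_homography",
    "project_box",
    "save_homography",
    "load_homography",
    "read_correspondences",
    "write_correspondences",
]


@dataclass(frozen=True)
class Correspondence:
    """A matched point pair: visual-plane (x, y) vs thermal-plane (x, y)."""

    visual_point: tuple[float, float]
    thermal_point: tuple[float, float]

    def __post_init__(self) -> None:
        pts = (*self.visual_point, *self.thermal_point)
        if not all(np.isfinite(p) for p in pts):
            raise ValueError("correspondence coordinates must be finite")


@dataclass(frozen=True)
class Homography:
    """3x3 projective map, lower-right element normalized to 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(m[2, 2]) < 1e-12:
            raise ValueError("cannot normalize: matrix[2,2] ~ 0")
        m = m / m[2, 2]
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography must be invertible")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))


def _normalization_transform(points: np.ndarray) -> np.ndarray:
    """Hartley conditioning: translate centroid to origin, mean norm sqrt(2)."""
    centroid = points.mean(axis=0)
    dists = np.linalg.norm(points - centroid, axis=1)
    mean_dist = dists.mean()
    scale = np.sqrt(2.0) / mean_dist if mean_dist > 1e-12 else 1.0
    return np.array(
        [
            [scale, 0.0, -scale * centroid[0]],
            [0.0, scale, -scale * centroid[1]],
            [0.0, 0.0, 1.0],
        ]
    )


def estimate_homography(correspondences: Sequence[Correspondence]) -> Homography:
    """Estimate the visual->thermal homography by normalized DLT.

    Requires at least 4 correspondences with non-collinear source points.
    For homography-consistent input the estimate is exact to numerical
    tolerance; otherwise it minimizes the algebraic error of the conditioned
    system.
    """
    if len(correspondences) < 4:
        raise ValueError("at least 4 correspondences are required")
    src = np.array([c.visual_point for c in correspondences], dtype=float)
    dst = np.array([c.thermal_point for c in correspondences], dtype=float)

    # collinear source points leave the system rank-deficient
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate configuration: source points are collinear")

    t_src = _normalization_transform(src)
    t_dst = _normalization_transform(dst)
    src_h = np.column_stack([src, np.ones(len(src))]) @ t_src.T
    dst_h = np.column_stack([dst, np.ones(len(dst))]) @ t_dst.T

    rows = []
    for (sx, sy, sw), (dx, dy, dw) in zip(src_h, dst_h):
        rows.append([0, 0, 0, -dw * sx, -dw * sy, -dw * sw, dy * sx, dy * sy, dy * sw])
        rows.append([dw * sx, dw * sy, dw * sw, 0, 0, 0, -dx * sx, -dx * sy, -dx * sw])
    a = np.asarray(rows, dtype=float)

    _, s, vt = np.linalg.svd(a)
    if s[7] / s[0] < 1e-10:
        raise ValueError("degenerate configuration: DLT system is rank-deficient")
    h_cond = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ h_cond @ t_src
    return Homography(h)


def apply_homography(h: Homography, point: tuple[float, float]) -> tuple[float, float]:
    """Project one point; raises if it maps to the line at infinity."""
    x, y = point
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("point coordinates must be finite")
    v = h.matrix @ np.array([x, y, 1.0])
    if abs(v[2]) < 1e-12:
        raise ValueError("point projects to infinity (w ~ 0)")
    return (float(v[0] / v[2]), float(v[1] / v[2]))


def project_box(h: Homography, box: ROIBox) -> ROIBox:
    """Map a box through ``h``.

    The four corners are projected and the output is their axis-aligned
    bounding box, rounded to integer pixels (halves away from zero) with a
    1-px minimum side.
    """
    pts = [apply_homography(h, p) for p in box.corners]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    x0 = round_half_away(min(xs))
    y0 = round_half_away(min(ys))
    w = max(1, round_half_away(max(xs)) - x0)
    h_out = max(1, round_half_away(max(ys)) - y0)
    return ROIBox(x0, y0, w, h_out, box.roi_id)


# ---------------------------------------------------------------------------
# serialization: homography as row-major JSON, correspondences as CSV

def save_homography(path: str | Path, h: Homography) -> None:
    Path(path).write_text(json.dumps({"matrix": h.matrix.ravel().tolist()}))


def load_homography(path: str | Path) -> Homography:
    data = json.loads(Path(path).read_text())
    return Homography(np.array(data["matrix"], dtype=float).reshape(3, 3))


def read_correspondences(path: str | Path) -> list[Correspondence]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Correspondence(
                    (float(row["vx"]), float(row["vy"])),
                    (float(row["tx"]), float(row["ty"])),
                )
            )
    return out


def write_correspondences(path: str | Path, corrs: Iterable[Correspondence]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vx", "vy", "tx", "ty"])
        for c in corrs:
            writer.writerow([*c.visual_point, *c.thermal_point])
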