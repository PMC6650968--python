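"""Placement accuracy evaluation: corner distances, per-ROI summaries and a
Wilcoxon signed-rank test for zero median of paired differences.

Distances are Euclidean between the automatic and manual left-upper
corners.  The Wilcoxon test discards zero differences, uses midranks for
ties, the exact null distribution up to n = 25 and a continuity-corrected
normal approximation beyond.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PlacementComparison",
    "WilcoxonResult",
    "corner_distance",
    "compare_roi_sets",
    "summarize_by_roi",
    "wilcoxon_zero_median",
    "significance_stars",
    "write_placement_report",
]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class PlacementComparison:
    """Automatic vs manual corner of one ROI on one frame."""

    frame_index: int
    roi_id: int
    auto: tuple[float, float]
    manual: tuple[float, float]
    method: str  # "raw" | "relocated"

    @property
    def distance(self) -> float:
        return corner_distance(self.auto, self.manual)


def corner_distance(auto: Sequence[float], manual: Sequence[float]) -> float:
    """Euclidean distance between automatic and manual corners; 0 means
    perfect agreement."""
    ax, ay = auto
    mx, my = manual
    if not all(math.isfinite(v) for v in (ax, ay, mx, my)):
        raise ValueError("corner coordinates must be finite")
    return math.hypot(ax - mx, ay - my)


def compare_roi_sets(auto_sets, manual_sets, method: str) -> list[PlacementComparison]:
    """Pairwise corner comparisons for aligned lists of ROISets."""
    out = []
    for auto, manual in zip(auto_sets, manual_sets, strict=True):
        for k in sorted(auto.facial):
            out.append(
                PlacementComparison(
                    auto.frame_index,
                    k,
                    auto.facial[k].corner,
                    manual.facial[k].corner,
                    method,
                )
            )
    return out


def summarize_by_roi(
    comparisons: Iterable[PlacementComparison],
) -> dict[tuple[int, str], dict[str, float]]:
    """Mean and standard error of the corner distance per (roi_id, method).

    SE is ``sd/sqrt(n)`` with sample sd; a single observation gives SE 0.
    """
    groups: dict[tuple[int, str], list[float]] = {}
    for comp in comparisons:
        groups.setdefault((comp.roi_id, comp.method), []).append(comp.distance)
    if not groups:
        raise ValueError("no comparisons to summarize")
    out = {}
    for key, dists in groups.items():
        arr = np.asarray(dists, dtype=float)
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        out[key] = {"mean": float(arr.mean()), "se": se, "n": len(arr)}
    return out


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float
    n: int  # nonzero differences used
    exact: bool
    stars: str
    degenerate: bool = False  # all differences were zero


def significance_stars(p: float) -> str:
    if p <= 1e-4:
        return ">***"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def _exact_p_two_sided(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by dynamic programming over sign assignments.

    Midranks may be half-integers; everything is doubled so the rank sums
    stay integral.  Equivalent to enumerating all 2^n sign vectors.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    # counts[s] = number of sign assignments with doubled rank sum s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_zero_median(differences: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test that the differences have zero
    median.

    Zeros are discarded before ranking.  If every difference is zero the
    result is flagged degenerate (no evidence either way) with p = 1.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, True, "n.s.", degenerate=True)

    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    n = int(d.size)

    if n <= EXACT_N_MAX:
        p = _exact_p_two_sided(w_plus, ranks)
        exact = True
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= ((tie_counts**3 - tie_counts).sum()) / 48.0
        if var <= 0:
            p = 1.0
        else:
            # continuity correction toward the mean
            z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        exact = False
    return WilcoxonResult(w_plus, p, n, exact, significance_stars(p))


def write_placement_report(
    path: str | Path,
    summary: dict[tuple[int, str], dict[str, float]],
    tests: dict[int, WilcoxonResult] | None = None,
) -> None:
    """CSV report: roi_id, method, n, mean, se, p, stars."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["roi_id", "method", "n", "mean", "se", "p", "stars"])
        for (roi_id, method), row in sorted(summary.items()):
            test = tests.get(roi_id) if tests else None
            writer.writerow(
                [
                    roi_id,
                    method,
                    row["n"],
                    row["mean"],
                    row["se"],
                    "" if test is None else test.p_value,
                    "" if test is None else test.stars,
                ]
            )
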