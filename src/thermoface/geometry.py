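"""Shared pixel-box geometry."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ROIBox", "round_half_away"]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (2.5 -> 3, -2.5 -> -3)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned pixel box ``(x, y, w, h)``; extent is half-open.

    ``roi_id`` is 0 for the head box and 1..11 for the facial regions
    (1/2 forehead, 3/4 periorbital, 5 nose tip, 6/7 cheek, 8/9 perinasal,
    10/11 chin; right side first).
    """

    x: int
    y: int
    w: int
    h: int
    roi_id: int = 0

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"box must have w, h >= 1, got {self.w}x{self.h}")
        if not 0 <= self.roi_id <= 11:
            raise ValueError(f"roi_id must be in 0..11, got {self.roi_id}")

    @property
    def corner(self) -> tuple[int, int]:
        """Left-upper corner ``(x, y)``."""
        return (self.x, self.y)

    @property
    def corners(self) -> list[tuple[float, float]]:
        """The four corner points of the box extent."""
        return [
            (self.x, self.y),
            (self.x + self.w, self.y),
            (self.x, self.y + self.h),
            (self.x + self.w, self.y + self.h),
        ]

    def translated(self, dx: int, dy: int) -> "ROIBox":
        return ROIBox(self.x + dx, self.y + dy, self.w, self.h, self.roi_id)

    def with_corner(self, x: int, y: int) -> "ROIBox":
        return ROIBox(x, y, self.w, self.h, self.roi_id)
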