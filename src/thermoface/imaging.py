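"""Frame model, stream pairing, fixed-pattern-noise removal and median denoising.

Thermal frames are single-channel 8-bit images whose brightness (0-255)
encodes skin temperature (brighter = warmer).  Visual frames are 8-bit RGB.
The coordinate convention used throughout the package is 0-based, x
rightward, y downward; boxes are ``(x, y, w, h)`` with half-open extent
``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Frame",
    "NoiseReference",
    "FramePair",
    "subtract_noise_reference",
    "median_filter",
    "pair_streams",
    "read_frame",
    "write_frame",
    "read_timestamp_sidecar",
    "write_timestamp_sidecar",
]


@dataclass(frozen=True)
class Frame:
    """One image of either stream.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array for thermal frames, 3-D ``(h, w, 3)`` for visual.
    timestamp
        Acquisition time in seconds.
    kind
        ``"thermal"`` or ``"visual"``.
    index
        Position ``b`` of the frame in its stream.
    """

    pixels: np.ndarray
    timestamp: float = 0.0
    kind: str = "thermal"
    index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if self.kind == "thermal":
            if px.ndim != 2:
                raise ValueError("thermal frames must be single-channel 2-D")
        elif self.kind == "visual":
            if px.ndim not in (2, 3):
                raise ValueError("visual frames must be 2-D or 3-D")
        else:
            raise ValueError(f"unknown frame kind {self.kind!r}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("frame must have width, height >= 1")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class NoiseReference:
    """Fixed-pattern noise frame recorded from a uniform-temperature target."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("noise reference must be single-channel 2-D")
        object.__setattr__(self, "pixels", px.astype(np.uint8))


@dataclass(frozen=True)
class FramePair:
    visual: Frame
    thermal: Frame
    pair_timestamp: float


def subtract_noise_reference(frame: Frame, ref: NoiseReference) -> Frame:
    """Remove the sensor's fixed-pattern noise by pixel-wise subtraction.

    Output is clipped to ``[0, 255]``; negative differences saturate at 0.
    """
    if frame.kind != "thermal":
        raise ValueError("noise subtraction applies to thermal frames only")
    if frame.pixels.shape != ref.pixels.shape:
        raise ValueError(
            f"dimension mismatch: frame {frame.pixels.shape} vs "
            f"reference {ref.pixels.shape}"
        )
    diff = frame.pixels.astype(np.int16) - ref.pixels.astype(np.int16)
    out = np.clip(diff, 0, 255).astype(np.uint8)
    return Frame(out, frame.timestamp, frame.kind, frame.index)


def median_filter(frame: Frame, kernel: int = 3) -> Frame:
    """Median-filter a thermal frame to suppress salt-and-pepper noise.

    Border pixels use edge replication so the output keeps the input size.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {kernel}")
    out = ndimage.median_filter(frame.pixels, size=kernel, mode="nearest")
    return Frame(out, frame.timestamp, frame.kind, frame.index)


def pair_streams(
    visual_frames: Sequence[Frame],
    thermal_frames: Sequence[Frame],
    rate_hz: float = 2.0,
) -> list[FramePair]:
    """Pair the two streams at a fixed rate (default 2 fps).

    Ticks are laid out every ``1/rate_hz`` seconds across the overlapping
    time span of the two streams.  Each tick is matched to the
    nearest-timestamp frame of each stream; ticks whose best match in either
    stream is farther than half a period are dropped.  The result is sorted
    by ``pair_timestamp`` by construction.
    """
    if not visual_frames or not thermal_frames:
        raise ValueError("both streams must be non-empty")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    vis_ts = np.array([f.timestamp for f in visual_frames], dtype=float)
    thm_ts = np.array([f.timestamp for f in thermal_frames], dtype=float)
    for ts in (vis_ts, thm_ts):
        if np.any(np.diff(ts) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")

    period = 1.0 / rate_hz
    start = max(vis_ts[0], thm_ts[0])
    end = min(vis_ts[-1], thm_ts[-1])
    if end < start:
        return []

    pairs: list[FramePair] = []
    tick = start
    eps = 1e-9
    while tick <= end + eps:
        iv = int(np.argmin(np.abs(vis_ts - tick)))
        it = int(np.argmin(np.abs(thm_ts - tick)))
        if (
            abs(vis_ts[iv] - tick) <= period / 2 + eps
            and abs(thm_ts[it] - tick) <= period / 2 + eps
        ):
            pairs.append(FramePair(visual_frames[iv], thermal_frames[it], tick))
        tick += period
    return pairs


# ---------------------------------------------------------------------------
# I/O helpers (PNG/TIFF frames plus a frame_index,timestamp sidecar CSV)

def read_frame(
    path: str | Path,
    kind: str = "thermal",
    timestamp: float = 0.0,
    index: int = 0,
) -> Frame:
    import imageio.v3 as iio

    px = iio.imread(path)
    if kind == "thermal" and px.ndim == 3:
        px = px[..., 0]
    return Frame(px, timestamp, kind, index)


def write_frame(path: str | Path, frame: Frame) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, frame.pixels)


def read_timestamp_sidecar(path: str | Path) -> dict[int, float]:
    """Read a ``frame_index,timestamp`` CSV into a mapping."""
    out: dict[int, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[int(row["frame_index"])] = float(row["timestamp"])
    return out


def write_timestamp_sidecar(path: str | Path, stamps: dict[int, float]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "timestamp"])
        for idx in sorted(stamps):
            writer.writerow([idx, stamps[idx]])
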