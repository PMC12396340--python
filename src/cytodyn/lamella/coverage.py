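"""Covered area of moving lamellipodia from pairwise mask subtraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from ..core import ImageSeries

__all__ = ["CoverageResult", "coverage"]

Mode = Literal["symmetric", "additions"]


@dataclass
class CoverageResult:
    """Per-interval moving-pixel counts and their sum over the span."""

    per_interval: np.ndarray     # px per consecutive frame pair
    total_px: int
    total_um2: Optional[float]
    span_s: Optional[float]
    mode: str

    def __post_init__(self) -> None:
        assert self.total_px == int(self.per_interval.sum())


def coverage(
    masks: ImageSeries,
    span_s: Optional[float] = 300.0,
    mode: Mode = "symmetric",
) -> CoverageResult:
    """Sum of moving pixels between consecutive binarized frames.

    Each consecutive pair of masks contributes its symmetric set
    difference (pixels gained or lost; ``mode="additions"`` counts only
    gains).  Frames are restricted to the analysis span when the frame
    interval is known; otherwise all frames contribute.
    """
    data = np.asarray(masks.data).astype(bool)
    if data.shape[0] < 2:
        raise ValueError("coverage needs at least 2 mask frames")

    n_frames = data.shape[0]
    if span_s is not None and masks.frame_interval_s:
        n_frames = min(n_frames, int(np.floor(span_s / masks.frame_interval_s)) + 1)
        if n_frames < 2:
            raise ValueError("analysis span shorter than one frame interval")
        data = data[:n_frames]

    prev, nxt = data[:-1], data[1:]
    if mode == "symmetric":
        moving = prev ^ nxt
    elif mode == "additions":
        moving = nxt & ~prev
    else:
        raise ValueError(f"unknown mode {mode!r}")
    per_interval = moving.reshape(len(moving), -1).sum(axis=1)
    total = int(per_interval.sum())
    total_um2 = None
    if masks.pixel_size_nm:
        total_um2 = total * (masks.pixel_size_nm * 1e-3) ** 2
    return CoverageResult(per_interval=per_interval, total_px=total,
                          total_um2=total_um2, span_s=span_s, mode=mode)
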