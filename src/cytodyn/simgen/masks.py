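"""Translating binary masks: ground truth for coverage and motility."""

from __future__ import annotations

from typing import Tuple

import numpy as np

from ..core import ImageSeries

__all__ = ["make_translating_mask_series"]


def make_translating_mask_series(
    shape: np.ndarray,
    step_px: Tuple[int, int],
    n_frames: int,
    field: Tuple[int, int] | None = None,
    pixel_size_nm: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageSeries:
    """Translate a binary shape by an integer step per frame.

    Frame k holds ``shape`` shifted by ``k * step_px`` (dx, dy).  The
    shape must stay inside the field for every frame; otherwise the
    call is rejected.
    """
    shape = np.asarray(shape, dtype=bool)
    if shape.ndim != 2 or not shape.any():
        raise ValueError("shape must be a non-empty 2D binary mask")
    dx, dy = (int(step_px[0]), int(step_px[1]))
    if (dx, dy) != (step_px[0], step_px[1]):
        raise ValueError("step_px must be integer")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    ys, xs = np.nonzero(shape)
    if field is None:
        pad_x = abs(dx) * (n_frames - 1)
        pad_y = abs(dy) * (n_frames - 1)
        field = (shape.shape[0] + pad_y + 1, shape.shape[1] + pad_x + 1)
    fy, fx = field

    frames = np.zeros((n_frames, fy, fx), dtype=bool)
    for k in range(n_frames):
        yy = ys + k * dy
        xx = xs + k * dx
        if yy.min() < 0 or xx.min() < 0 or yy.max() >= fy or xx.max() >= fx:
            raise ValueError(f"shape leaves the field at frame {k}")
        frames[k, yy, xx] = True
    return ImageSeries(data=frames, pixel_size_nm=pixel_size_nm,
                       frame_interval_s=frame_interval_s)
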