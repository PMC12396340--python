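"""Puncta detection by top-percentile thresholding.

The binary mask keeps the brightest ``threshold_percent`` of pixels
(area-fraction semantics; an intensity-fraction mode is available).
Connected components at least ``min_size`` pixels large become puncta
with intensity-weighted centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional

import numpy as np
from scipy import ndimage

__all__ = ["PunctaSet", "detect_puncta"]


@dataclass
class PunctaSet:
    """Detected or planted puncta in one channel.

    Centroids are physical (x, y[, z]) nm; footprints are flat pixel
    index arrays into the source image.
    """

    centroids: np.ndarray                 # (n, 2) or (n, 3) nm
    footprints: List[np.ndarray]
    intensities: np.ndarray
    channel: str = ""
    pixel_size_nm: float = 1.0
    image_shape: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(
            -1, self.centroids.shape[-1] if np.size(self.centroids) else 2)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.footprints) != len(self.centroids):
            raise ValueError("footprints and centroids must align")

    def __len__(self) -> int:
        return len(self.centroids)


def detect_puncta(
    image: np.ndarray,
    threshold_percent: float = 1.10,
    min_size: int = 4,
    pixel_size_nm: float = 1.0,
    voxel_size_nm: Optional[tuple] = None,
    mode: Literal["area", "intensity"] = "area",
    channel: str = "",
) -> PunctaSet:
    """Detect bright puncta in a single-channel 2D or 3D image.

    Parameters
    ----------
    threshold_percent : float
        In ``area`` mode (default) the brightest ``threshold_percent``
        of pixels are kept; in ``intensity`` mode pixels above
        ``threshold_percent/100 * max`` are kept.
    min_size : int
        Minimum connected-component size in pixels.
    pixel_size_nm : float
        Lateral pixel size; used to express centroids in nm.
    voxel_size_nm : tuple, optional
        Per-axis (x, y, z) sizes for anisotropic 3D data; overrides
        ``pixel_size_nm``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim not in (2, 3):
        raise ValueError("detect_puncta expects a 2D or 3D single-channel image")
    flat = img.ravel()
    if flat.max() == flat.min():
        raise ValueError("constant image: threshold undefined")

    if mode == "area":
        k = max(1, int(round(threshold_percent / 100.0 * flat.size)))
        thr = np.partition(flat, flat.size - k)[flat.size - k]
        if thr <= flat.min():
            raise ValueError("degenerate percentile threshold (too many tied pixels)")
        mask = img >= thr
    elif mode == "intensity":
        mask = img >= threshold_percent / 100.0 * flat.max()
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")

    labels, n = ndimage.label(mask)
    if voxel_size_nm is None:
        voxel_size_nm = (pixel_size_nm,) * img.ndim
    # voxel_size given as (x, y[, z]); array axes are reversed (z, y, x)
    scale = np.asarray(voxel_size_nm[::-1], dtype=float)

    centroids, footprints, intensities = [], [], []
    for lab in range(1, n + 1):
        idx = np.flatnonzero(labels.ravel() == lab)
        if idx.size < min_size:
            continue
        coords = np.column_stack(np.unravel_index(idx, img.shape)).astype(float)
        w = flat[idx]
        cm = (coords * w[:, None]).sum(axis=0) / w.sum()
        # pixel-center convention, axes reordered to (x, y[, z])
        phys = ((cm + 0.5) * scale)[::-1]
        centroids.append(phys)
        footprints.append(idx)
        intensities.append(w.sum())

    if centroids:
        cents = np.vstack(centroids)
    else:
        cents = np.zeros((0, img.ndim))
    return PunctaSet(
        centroids=cents, footprints=footprints,
        intensities=np.asarray(intensities), channel=channel,
        pixel_size_nm=float(voxel_size_nm[0]), image_shape=img.shape,
    )
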