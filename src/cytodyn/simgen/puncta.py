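"""Planted two-channel puncta and engulfment phantoms.

Ground truth (true centroids, footprints, labels) is emitted alongside
the rendered images so downstream tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from ..synapse.puncta import PunctaSet

__all__ = ["PlantedPunctaSpec", "plant_puncta", "plant_engulfment"]

_MAX_TRIES = 20000


@dataclass(frozen=True)
class PlantedPunctaSpec:
    """Ground truth layout for a two-channel colocalization phantom.

    ``n_pairs`` cross-channel pairs are planted exactly
    ``pair_distance`` nm apart; singles are kept at least
    4 × ``pair_distance`` away from every opposite-channel punctum so
    matching is unambiguous.
    """

    n_pairs: int
    pair_distance: float            # nm
    n_singles_a: int = 0
    n_singles_b: int = 0
    field_size: float = 10.0        # µm
    pixel_size: float = 40.0        # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair_distance < 0:
            raise ValueError(f"pair_distance must be >= 0, got {self.pair_distance}")
        for name in ("n_pairs", "n_singles_a", "n_singles_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.field_size <= 0 or self.pixel_size <= 0:
            raise ValueError("field_size and pixel_size must be > 0")


def _render_spots(centers_nm: np.ndarray, shape: Tuple[int, int],
                  pixel_size: float, sigma_px: float = 1.5,
                  amplitude: float = 1000.0) -> np.ndarray:
    img = np.zeros(shape)
    ny, nx = shape
    yy = (np.arange(ny) + 0.5) * pixel_size
    xx = (np.arange(nx) + 0.5) * pixel_size
    s2 = (sigma_px * pixel_size) ** 2
    for cx, cy in centers_nm:
        gy = np.exp(-((yy - cy) ** 2) / (2 * s2))
        gx = np.exp(-((xx - cx) ** 2) / (2 * s2))
        img += amplitude * np.outer(gy, gx)
    return img


def _footprint(center_nm: np.ndarray, shape: Tuple[int, int],
               pixel_size: float, radius_px: float = 4.0) -> np.ndarray:
    ny, nx = shape
    cy, cx = center_nm[1] / pixel_size - 0.5, center_nm[0] / pixel_size - 0.5
    y0, y1 = int(max(0, cy - radius_px - 1)), int(min(ny, cy + radius_px + 2))
    x0, x1 = int(max(0, cx - radius_px - 1)), int(min(nx, cx + radius_px + 2))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (ys - cy) ** 2 + (xs - cx) ** 2 <= radius_px ** 2
    return np.ravel_multi_index((ys[inside], xs[inside]), shape)


def plant_puncta(spec: PlantedPunctaSpec) -> Tuple[PunctaSet, PunctaSet, np.ndarray]:
    """Plant paired and single puncta; return (set_a, set_b, image).

    The image has shape (2, ny, nx) with channel A first.  Centroids in
    the returned sets are the exact planted positions (nm).
    """
    field_nm = spec.field_size * 1000.0
    npx = int(round(field_nm / spec.pixel_size))
    shape = (npx, npx)
    rng = np.random.default_rng(spec.seed)

    # spots must be far enough apart that detection footprints stay disjoint
    spacing = max(4.0 * spec.pair_distance, 20.0 * spec.pixel_size)
    margin = 8.0 * spec.pixel_size
    lo, hi = margin, field_nm - margin
    if hi <= lo:
        raise ValueError("field too small for the requested pixel size")

    anchors: List[np.ndarray] = []

    def place() -> np.ndarray:
        for _ in range(_MAX_TRIES):
            p = rng.uniform(lo, hi, size=2)
            if all(np.linalg.norm(p - q) >= spacing for q in anchors):
                anchors.append(p)
                return p
        raise ValueError("infeasible packing: cannot place puncta at required spacing")

    a_centers: List[np.ndarray] = []
    b_centers: List[np.ndarray] = []
    for _ in range(spec.n_pairs):
        c = place()
        phi = rng.uniform(0, 2 * np.pi)
        off = spec.pair_distance * np.array([np.cos(phi), np.sin(phi)])
        a_centers.append(c)
        b_centers.append(c + off)
    for _ in range(spec.n_singles_a):
        a_centers.append(place())
    for _ in range(spec.n_singles_b):
        b_centers.append(place())

    a_arr = np.asarray(a_centers).reshape(-1, 2)
    b_arr = np.asarray(b_centers).reshape(-1, 2)
    img = np.stack([
        _render_spots(a_arr, shape, spec.pixel_size),
        _render_spots(b_arr, shape, spec.pixel_size),
    ])

    def as_set(cents: np.ndarray, channel: str) -> PunctaSet:
        return PunctaSet(
            centroids=cents,
            footprints=[_footprint(c, shape, spec.pixel_size) for c in cents],
            intensities=np.full(len(cents), 1000.0),
            channel=channel, pixel_size_nm=spec.pixel_size, image_shape=shape,
        )

    return as_set(a_arr, "A"), as_set(b_arr, "B"), img


def plant_engulfment(
    cell_mask: np.ndarray,
    n_inside: int,
    n_partial: int,
    n_outside: int,
    seed: int = 0,
    radius_px: float = 2.0,
    pixel_size_nm: float = 40.0,
) -> Tuple[np.ndarray, PunctaSet, np.ndarray]:
    """Plant puncta fully inside, straddling, and outside a cell mask.

    Returns (image, puncta, truth_labels) where ``truth_labels`` holds
    "inside" / "partial" / "outside" per punctum, in planting order.
    """
    from scipy import ndimage

    mask = np.asarray(cell_mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("cell_mask must be a non-empty 2D mask")
    rng = np.random.default_rng(seed)
    shape = mask.shape
    r_int = int(np.ceil(radius_px)) + 1
    struct = np.ones((2 * r_int + 1, 2 * r_int + 1), dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    exterior = ndimage.binary_erosion(~mask, structure=struct, border_value=1)
    boundary = ~interior & ~exterior

    placed: List[Tuple[float, float]] = []
    spacing = 6.0 * radius_px

    def sample_from(region: np.ndarray, kind: str) -> Tuple[float, float]:
        ys, xs = np.nonzero(region)
        if len(ys) == 0:
            raise ValueError(f"infeasible: no room to place a {kind} punctum")
        for _ in range(_MAX_TRIES):
            i = rng.integers(len(ys))
            cy, cx = float(ys[i]), float(xs[i])
            if all((cy - py) ** 2 + (cx - px) ** 2 >= spacing ** 2 for py, px in placed):
                fp = _disk_indices(cy, cx, radius_px, shape)
                in_frac = mask.ravel()[fp].mean()
                if kind == "inside" and in_frac < 1.0:
                    continue
                if kind == "outside" and in_frac > 0.0:
                    continue
                if kind == "partial" and not 0.0 < in_frac < 1.0:
                    continue
                placed.append((cy, cx))
                return cy, cx
        raise ValueError(f"infeasible: could not place a {kind} punctum")

    centers: List[Tuple[float, float]] = []
    labels: List[str] = []
    for kind, region, count in (
        ("inside", interior, n_inside),
        ("partial", boundary, n_partial),
        ("outside", exterior, n_outside),
    ):
        for _ in range(count):
            centers.append(sample_from(region, kind))
            labels.append(kind)

    cents_nm = np.array([[ (cx + 0.5) * pixel_size_nm, (cy + 0.5) * pixel_size_nm]
                         for cy, cx in centers]).reshape(-1, 2)
    img = _render_spots(cents_nm, shape, pixel_size_nm, sigma_px=1.0)
    footprints = [_disk_indices(cy, cx, radius_px, shape) for cy, cx in centers]
    puncta = PunctaSet(
        centroids=cents_nm, footprints=footprints,
        intensities=np.full(len(centers), 1000.0),
        channel="engulfed", pixel_size_nm=pixel_size_nm, image_shape=shape,
    )
    return img, puncta, np.asarray(labels)


def _disk_indices(cy: float, cx: float, radius_px: float,
                  shape: Tuple[int, int]) -> np.ndarray:
    ny, nx = shape
    r = int(np.ceil(radius_px))
    y0, y1 = max(0, int(cy) - r), min(ny, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(nx, int(cx) + r + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (ys - cy) ** 2 + (xs - cx) ** 2 <= radius_px ** 2
    return np.ravel_multi_index((ys[inside], xs[inside]), shape)
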