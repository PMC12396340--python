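"""Cross-channel colocalization and engulfment scoring.

Colocalization: one-to-one greedy matching of puncta centroids in
increasing distance order, admitting pairs strictly below the distance
threshold (default 50 nm).  Engulfment: a punctum counts for a cell iff
its entire pixel footprint lies inside that cell's mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .puncta import PunctaSet

__all__ = ["ColocResult", "colocalize", "engulfment"]


@dataclass
class ColocResult:
    """Matched cross-channel puncta pairs below the distance threshold."""

    pairs: List[Tuple[int, int]]
    distances_nm: np.ndarray
    count: int
    density_per_um2: float | None = None


def colocalize(
    a: PunctaSet,
    b: PunctaSet,
    max_distance_nm: float = 50.0,
    area_um2: float | None = None,
) -> ColocResult:
    """Greedy one-to-one nearest-pair matching between two channels.

    Candidate pairs are sorted by centroid distance and admitted while
    the distance is strictly below ``max_distance_nm``; each punctum can
    participate in at most one pair.  Ties are broken toward lower
    punctum indices.
    """
    if len(a) == 0 or len(b) == 0:
        return ColocResult(pairs=[], distances_nm=np.zeros(0), count=0,
                           density_per_um2=0.0 if area_um2 else None)
    if a.centroids.shape[1] != b.centroids.shape[1]:
        raise ValueError("channel centroid dimensionalities differ")
    d = cdist(a.centroids, b.centroids)
    ii, jj = np.nonzero(d < max_distance_nm)
    order = np.lexsort((jj, ii, d[ii, jj]))   # distance, then index tie-break
    used_a: set = set()
    used_b: set = set()
    pairs: List[Tuple[int, int]] = []
    dists: List[float] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
        dists.append(float(d[i, j]))
    density = len(pairs) / area_um2 if area_um2 else None
    return ColocResult(pairs=pairs, distances_nm=np.asarray(dists),
                       count=len(pairs), density_per_um2=density)


def engulfment(puncta: PunctaSet, cell_body_mask: np.ndarray) -> Dict[int, int]:
    """Count puncta entirely within each labeled cell body.

    ``cell_body_mask`` is an integer label image (0 = background) or a
    boolean mask (treated as one cell with label 1).  A punctum counts
    for a cell only when every pixel of its footprint carries that
    cell's label — strict containment, so boundary-straddling puncta
    are excluded.
    """
    labels = np.asarray(cell_body_mask)
    if labels.dtype == bool:
        labels = labels.astype(np.int32)
    flat = labels.ravel()
    cell_ids = [int(c) for c in np.unique(labels) if c != 0]
    counts = {c: 0 for c in cell_ids}
    for fp in puncta.footprints:
        vals = np.unique(flat[fp])
        if len(vals) == 1 and vals[0] != 0:
            counts[int(vals[0])] += 1
    return counts
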