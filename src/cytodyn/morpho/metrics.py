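"""Skeleton morphometrics: total branch length and Sholl profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import Skeleton

__all__ = ["ShollProfile", "total_branch_length", "sholl"]


def total_branch_length(skel: Skeleton) -> float:
    """Sum of Euclidean edge lengths, in µm."""
    return float(skel.edge_lengths().sum())


@dataclass
class ShollProfile:
    """Crossing counts of concentric spheres centered on the soma."""

    radii: np.ndarray          # µm, fixed step
    intersections: np.ndarray  # counts >= 0

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=int)
        if self.radii.shape != self.intersections.shape:
            raise ValueError("radii and intersections must align")


def _segment_sphere_crossings(p0: np.ndarray, p1: np.ndarray, r: float) -> np.ndarray:
    """Number of intersections of segments p0→p1 with the sphere |p| = r.

    Solves |p0 + t·(p1−p0)|² = r² and counts real roots with t ∈ [0, 1),
    so a crossing shared by two adjacent segments is counted once.  A
    segment whose closest approach dips inside the sphere while both
    endpoints are outside contributes two crossings.
    """
    d = p1 - p0
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", p0, d)
    c = np.einsum("ij,ij->i", p0, p0) - r * r
    counts = np.zeros(len(p0), dtype=int)

    degenerate = a == 0
    disc = b * b - 4 * a * c
    ok = (~degenerate) & (disc > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-b - sq) / (2 * a)
        t2 = (-b + sq) / (2 * a)
    for t in (t1, t2):
        counts += (ok & (t >= 0) & (t < 1)).astype(int)
    # tangent grazing (disc == 0) touches but does not cross; not counted
    return counts


def sholl(skel: Skeleton, step: float = 1.0, max_radius: float | None = None) -> ShollProfile:
    """Sholl profile by exact segment–sphere intersection.

    Radii run from ``step`` upward in increments of ``step`` (the soma
    radius 0 is not sampled).  Every geometric crossing is counted with
    multiplicity.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    center = skel.nodes[skel.soma]
    pts = skel.nodes - center
    if max_radius is None:
        reach = float(np.linalg.norm(pts, axis=1).max()) if len(pts) else 0.0
        max_radius = max(reach + step, step)
    radii = np.arange(step, max_radius + step * 1e-9, step)

    e = np.asarray(skel.edges, dtype=int)
    if e.size == 0:
        return ShollProfile(radii=radii, intersections=np.zeros(len(radii), dtype=int))
    p0 = pts[e[:, 0]]
    p1 = pts[e[:, 1]]
    counts = np.array([_segment_sphere_crossings(p0, p1, r).sum() for r in radii])
    return ShollProfile(radii=radii, intersections=counts)
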