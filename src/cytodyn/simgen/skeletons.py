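"""Parametric star skeletons with analytic morphometrics."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from ..morpho.skeleton import Skeleton

__all__ = ["make_star_skeleton"]


def make_star_skeleton(
    k: int,
    length: float,
    soma: Sequence[float] = (0.0, 0.0, 0.0),
    bifurcate_at: Optional[float] = None,
) -> Skeleton:
    """Build k straight radial branches of ``length`` µm at equal angles.

    With ``bifurcate_at`` set, each branch splits into two daughters at
    that radius; the daughters run to radius ``length`` at small angular
    offsets, so sphere crossings double beyond the split radius.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if length <= 0:
        raise ValueError(f"length must be > 0, got {length}")
    if bifurcate_at is not None and not 0 < bifurcate_at < length:
        raise ValueError(
            f"bifurcate_at must lie strictly between 0 and length, got {bifurcate_at}"
        )
    soma = np.asarray(soma, dtype=float)
    if soma.shape != (3,):
        raise ValueError("soma must be a 3D point")

    thetas = 2.0 * np.pi * np.arange(k) / k
    nodes = [soma]
    edges: list[Tuple[int, int]] = []
    for theta in thetas:
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        if bifurcate_at is None:
            nodes.append(soma + length * u)
            edges.append((0, len(nodes) - 1))
        else:
            split = soma + bifurcate_at * u
            nodes.append(split)
            split_id = len(nodes) - 1
            edges.append((0, split_id))
            dphi = np.pi / (6 * k)     # small split angle keeps daughters radial
            for sign in (+1, -1):
                phi = theta + sign * dphi
                tip = soma + length * np.array([np.cos(phi), np.sin(phi), 0.0])
                nodes.append(tip)
                edges.append((split_id, len(nodes) - 1))
    return Skeleton(nodes=np.asarray(nodes), edges=edges, soma=0)
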