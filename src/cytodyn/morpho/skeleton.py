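"""3D cell skeletons: graph representation, SWC I/O, mask thinning.

A :class:`Skeleton` is a node/edge graph in physical µm coordinates
with a designated soma node.  Skeletons may come from SWC files, from
the synthetic generators, or from a binary mask via 3D thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize

__all__ = ["Skeleton", "read_swc", "write_swc", "skeleton_from_mask"]


@dataclass
class Skeleton:
    """Node/edge graph with a soma node; coordinates in µm (x, y, z)."""

    nodes: np.ndarray                    # (n, 3) float
    edges: List[Tuple[int, int]]
    soma: int = 0
    units: str = "um"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be an (n, 3) array")
        n = len(self.nodes)
        for a, b in self.edges:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a}, {b}) references a missing node")
        if not 0 <= self.soma < n:
            raise ValueError(f"soma id {self.soma} out of range")

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(self.edges)
        return g

    @property
    def is_tree(self) -> bool:
        g = self.graph
        return nx.is_connected(g) and g.number_of_edges() == g.number_of_nodes() - 1

    def edge_lengths(self) -> np.ndarray:
        e = np.asarray(self.edges, dtype=int)
        if e.size == 0:
            return np.zeros(0)
        return np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] = (0, 0, 0)) -> "Skeleton":
        """Rigidly transform the node coordinates (for invariance tests)."""
        pts = self.nodes
        if rotation is not None:
            pts = pts @ np.asarray(rotation).T
        pts = pts + np.asarray(translation, dtype=float)
        return Skeleton(nodes=pts, edges=list(self.edges), soma=self.soma,
                        units=self.units)


# ---------------------------------------------------------------- SWC I/O

def write_swc(skel: Skeleton, path: str | Path) -> None:
    """Write a skeleton as SWC (soma rooted; graph must be a tree)."""
    g = skel.graph
    if not nx.is_connected(g):
        raise ValueError("cannot serialise a disconnected skeleton to SWC")
    parent = {skel.soma: -1}
    order = [skel.soma]
    for u, v in nx.bfs_edges(g, skel.soma):
        parent[v] = u
        order.append(v)
    remap = {node: i + 1 for i, node in enumerate(order)}
    lines = ["# index type x y z radius parent"]
    for node in order:
        x, y, z = skel.nodes[node]
        t = 1 if node == skel.soma else 3
        p = -1 if parent[node] == -1 else remap[parent[node]]
        lines.append(f"{remap[node]} {t} {x:.17g} {y:.17g} {z:.17g} 1.0 {p}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> Skeleton:
    """Read an SWC file into a :class:`Skeleton` (coordinates taken as µm)."""
    ids: List[int] = []
    rows: List[Tuple[float, float, float]] = []
    parents: List[int] = []
    types: List[int] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        ids.append(int(parts[0]))
        types.append(int(parts[1]))
        rows.append((float(parts[2]), float(parts[3]), float(parts[4])))
        parents.append(int(parts[6]))
    if not ids:
        raise ValueError(f"no SWC records in {path}")
    index = {swc_id: i for i, swc_id in enumerate(ids)}
    edges = [(index[p], index[i]) for i, p in zip(ids, parents) if p != -1]
    roots = [index[i] for i, p in zip(ids, parents) if p == -1]
    soma_candidates = [index[i] for i, t in zip(ids, types) if t == 1]
    soma = soma_candidates[0] if soma_candidates else roots[0]
    return Skeleton(nodes=np.array(rows), edges=edges, soma=soma)


# ------------------------------------------------------- mask → skeleton

_NEIGHBOR_OFFSETS = np.array(
    [(dz, dy, dx)
     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)]
)


def skeleton_from_mask(
    mask: np.ndarray,
    soma_seed: Tuple[float, float, float],
    voxel_size_um: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    prune_px: float = 2.0,
) -> Skeleton:
    """Thin a binary 3D mask to a centerline graph.

    The mask is reduced to a 1-voxel-wide centerline, 26-connected
    voxels become graph edges, and terminal spurs shorter than
    ``prune_px`` voxels are removed.  ``soma_seed`` is given as (x, y, z)
    voxel indices; the nearest centerline voxel becomes the soma node.
    Coordinates are converted to µm with ``voxel_size_um`` (x, y, z).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (z, y, x)")
    if not mask.any():
        raise ValueError("mask is empty")
    from scipy import ndimage as ndi

    labels, n_comp = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    sx, sy, sz = (int(round(c)) for c in soma_seed)
    if not (0 <= sz < mask.shape[0] and 0 <= sy < mask.shape[1] and 0 <= sx < mask.shape[2]):
        raise ValueError("soma_seed outside the volume")
    seed_label = labels[sz, sy, sx]
    if seed_label == 0:
        raise ValueError("soma_seed does not lie in the mask")
    if n_comp > 1:
        mask = labels == seed_label

    centerline = skeletonize(mask)
    voxels = np.argwhere(centerline)          # (n, 3) z,y,x
    if len(voxels) == 0:
        voxels = np.array([[sz, sy, sx]])
    vox_index = {tuple(v): i for i, v in enumerate(voxels)}

    g = nx.Graph()
    g.add_nodes_from(range(len(voxels)))
    for i, v in enumerate(voxels):
        for off in _NEIGHBOR_OFFSETS:
            nb = tuple(v + off)
            j = vox_index.get(nb)
            if j is not None and j > i:
                g.add_edge(i, j, weight=float(np.linalg.norm(off)))

    dists = np.linalg.norm(voxels - np.array([sz, sy, sx]), axis=1)
    soma = int(np.argmin(dists))

    # iterative spur pruning: drop terminal branches shorter than prune_px
    changed = True
    while changed and g.number_of_nodes() > 1:
        changed = False
        for leaf in [n for n in g.nodes if g.degree(n) == 1 and n != soma]:
            path = [leaf]
            length = 0.0
            node = leaf
            while g.degree(path[-1]) <= 2:
                nbrs = [n for n in g.neighbors(path[-1]) if n not in path]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[path[-1], nxt]["weight"]
                if g.degree(nxt) > 2 or length > prune_px:
                    break
                path.append(nxt)
            if length <= prune_px and len(path) < g.number_of_nodes():
                ends_at_junction = any(g.degree(n) > 2 for p in path for n in g.neighbors(p))
                if ends_at_junction:
                    g.remove_nodes_from(path)
                    changed = True

    keep = sorted(g.nodes)
    remap = {old: new for new, old in enumerate(keep)}
    vz, vy, vx = voxels[keep].T
    ux, uy, uz = voxel_size_um
    nodes = np.column_stack([vx * ux, vy * uy, vz * uz]).astype(float)
    edges = [(remap[a], remap[b]) for a, b in g.edges]
    return Skeleton(nodes=nodes, edges=edges, soma=remap[soma])
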