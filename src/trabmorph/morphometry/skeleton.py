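"""Strut-network analysis of the trabecular skeleton.

The bone phase is reduced to a one-voxel-wide medial skeleton by 3D
topology-preserving thinning. Skeleton voxels are classified by their number
of 26-connected skeleton neighbors: 1 neighbor marks a terminus (a free
trabecular end), 3 or more a junction between trabeculae, and voxels lying
on the volume/VOI boundary are flagged as cortical attachments. Adjacent
junction voxels are collapsed into a single node at their centroid.

A branch is a maximal skeleton path between two nodes (or a closed loop with
no node). The branch count b yields the connectivity density Conn.D = b/TV,
and the summed polyline arc length (anisotropic spacing honored) is the
total strut length TSL. The conventional Euler-characteristic connectivity
estimate (1 - chi)/TV is exposed separately and never silently substituted
for b/TV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.measure import euler_number
from skimage.morphology import skeletonize

from ..volumes import BinaryVolume

__all__ = [
    "SkeletonNode",
    "SkeletonBranch",
    "SkeletonGraph",
    "skeleton_analysis",
    "connectivity_density",
    "total_strut_length",
    "euler_connectivity_density",
]

NodeKind = Literal["junction", "terminus", "cortical_attachment", "isolated"]

_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


@dataclass
class SkeletonNode:
    position: tuple[float, float, float]  # mm
    kind: NodeKind


@dataclass
class SkeletonBranch:
    polyline: np.ndarray  # (n, 3) voxel indices along the branch
    length: float  # mm


@dataclass
class SkeletonGraph:
    nodes: list[SkeletonNode] = field(default_factory=list)
    branches: list[SkeletonBranch] = field(default_factory=list)

    @property
    def b(self) -> int:
        """Branch count."""
        return len(self.branches)

    @property
    def total_length(self) -> float:
        return float(sum(br.length for br in self.branches))


def _polyline_length(poly: np.ndarray, spacing) -> float:
    if len(poly) < 2:
        return 0.0
    steps = np.diff(poly, axis=0) * np.asarray(spacing)
    return float(np.linalg.norm(steps, axis=1).sum())


def _thin(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning with an even-width rescue.

    The parallel deletion pass of Lee-style 3D thinning can erase an entire
    component whose cross-section is even-width in every axis (all of its
    voxels are simultaneously simple). Any component left without a single
    skeleton voxel is re-thinned after a one-voxel one-sided dilation, which
    flips the width parity without moving the medial axis by more than one
    voxel.
    """
    skel = skeletonize(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n:
        covered = np.unique(labels[skel])
        for cid in range(1, n + 1):
            if cid in covered:
                continue
            comp = labels == cid
            grown = ndimage.binary_dilation(comp, structure=np.ones((2, 2, 2), dtype=bool))
            skel |= skeletonize(grown)
    return skel


def skeleton_analysis(mask: BinaryVolume) -> SkeletonGraph:
    """Thin the bone phase and extract the classified strut graph."""
    if not mask.mask.any():
        return SkeletonGraph()
    skel = _thin(mask.mask)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return SkeletonGraph()
    spacing = np.asarray(mask.spacing)
    shape = np.asarray(mask.shape)
    index_of = {tuple(c): i for i, c in enumerate(coords)}

    neighbors: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _OFFSETS:
            j = index_of.get(tuple(c + off))
            if j is not None and j > i:
                neighbors[i].append(j)
                neighbors[j].append(i)
    degree = np.array([len(n) for n in neighbors])

    is_node = degree != 2
    # Thinning retracts skeleton ends from the volume face by up to the local
    # strut radius, so "touches the boundary" is judged within that radius
    # (plus one voxel) rather than by exact face membership.
    radius_mm = ndimage.distance_transform_edt(mask.mask, sampling=spacing)
    dist_to_face = np.minimum(coords, shape - 1 - coords) * spacing
    on_boundary = (
        dist_to_face.min(axis=1)
        <= radius_mm[coords[:, 0], coords[:, 1], coords[:, 2]] + spacing.max()
    )

    # collapse adjacent junction voxels into clusters
    cluster = -np.ones(len(coords), dtype=int)
    n_clusters = 0
    for i in np.flatnonzero(is_node):
        if cluster[i] >= 0:
            continue
        stack = [i]
        cluster[i] = n_clusters
        while stack:
            u = stack.pop()
            if degree[u] < 3:
                continue  # only junction voxels merge; termini stay singletons
            for v in neighbors[u]:
                if is_node[v] and degree[v] >= 3 and cluster[v] < 0:
                    cluster[v] = n_clusters
                    stack.append(v)
        n_clusters += 1

    nodes: list[SkeletonNode] = []
    for cid in range(n_clusters):
        members = np.flatnonzero(cluster == cid)
        centroid = tuple((coords[members].mean(axis=0) * spacing).tolist())
        if np.any(on_boundary[members]):
            kind: NodeKind = "cortical_attachment"
        elif np.any(degree[members] >= 3):
            kind = "junction"
        elif degree[members[0]] == 1:
            kind = "terminus"
        else:
            kind = "isolated"
        nodes.append(SkeletonNode(position=centroid, kind=kind))

    # trace branches: maximal chains between node voxels, each edge used once
    visited_edges: set[tuple[int, int]] = set()

    def edge_key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    branches: list[SkeletonBranch] = []
    for start in np.flatnonzero(is_node):
        for nxt in neighbors[start]:
            if edge_key(start, nxt) in visited_edges:
                continue
            if is_node[nxt] and cluster[start] == cluster[nxt]:
                visited_edges.add(edge_key(start, nxt))
                continue  # intra-cluster junction edge, not a strut
            path = [start, nxt]
            visited_edges.add(edge_key(start, nxt))
            prev, cur = start, nxt
            while not is_node[cur]:
                nexts = [v for v in neighbors[cur] if v != prev]
                if not nexts:
                    break
                nxt2 = nexts[0]
                visited_edges.add(edge_key(cur, nxt2))
                path.append(nxt2)
                prev, cur = cur, nxt2
            branches.append(
                SkeletonBranch(
                    polyline=coords[path], length=_polyline_length(coords[path], spacing)
                )
            )
    # closed loops containing no node voxel
    for i in np.flatnonzero(degree == 2):
        for j in neighbors[i]:
            if edge_key(i, j) in visited_edges:
                continue
            path = [i, j]
            visited_edges.add(edge_key(i, j))
            prev, cur = i, j
            while cur != i:
                nexts = [v for v in neighbors[cur] if v != prev]
                if not nexts:
                    break
                nxt2 = nexts[0]
                visited_edges.add(edge_key(cur, nxt2))
                path.append(nxt2)
                prev, cur = cur, nxt2
            branches.append(
                SkeletonBranch(
                    polyline=coords[path], length=_polyline_length(coords[path], spacing)
                )
            )
    return SkeletonGraph(nodes=nodes, branches=branches)


def connectivity_density(graph: SkeletonGraph, tv: float) -> float:
    """Conn.D = b / TV (branch count per tissue volume, 1/mm^3)."""
    if tv <= 0:
        raise ValueError("TV must be positive")
    return graph.b / tv


def total_strut_length(graph: SkeletonGraph) -> float:
    """TSL: summed branch arc length in mm."""
    return graph.total_length


def euler_connectivity_density(mask: BinaryVolume, tv: float) -> float:
    """Alternative Conn.D estimate (1 - chi)/TV from the Euler characteristic.

    Labeled alternative to the branch-count definition; reported separately.
    """
    if tv <= 0:
        raise ValueError("TV must be positive")
    if not mask.mask.any():
        return 0.0
    chi = euler_number(mask.mask, connectivity=3)
    return (1 - chi) / tv
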