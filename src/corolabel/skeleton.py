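"""Topology-preserving 3D thinning and skeleton-to-graph conversion.

A binary lumen mask is reduced to a one-voxel-wide skeleton by iterative
border-point erosion that deletes only simple points (26-connected
foreground over 6-connected background), then converted into a vessel
graph: voxels with a number of skeleton neighbours different from two
become nodes (endpoints, junctions), maximal chains of two-neighbour
voxels become polyline edges in world millimetres.

Thinning operates on the voxel lattice; metric correctness is restored
when voxel indices are mapped to world coordinates through the volume's
spacing and origin (voxel-centre convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .geometry import Centerline, arc_length

__all__ = [
    "BinaryVolume",
    "VesselGraph",
    "thin_volume",
    "skeleton_to_graph",
    "root_paths",
    "prune_spurs",
]

# 26-connectivity structuring element
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_NEIGHBOR_OFFSETS = np.array(
    [off for off in product((-1, 0, 1), repeat=3) if off != (0, 0, 0)], dtype=int
)


@dataclass
class BinaryVolume:
    """Binary 3D voxel grid with world-space metadata.

    ``origin`` is the world position (mm) of the centre of voxel (0, 0, 0);
    axes are index order (i, j, k) → world (x, y, z).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("voxel grid must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    def world(self, idx) -> np.ndarray:
        """Map voxel indices (n, 3) to world mm coordinates."""
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def count_components(self, connectivity: int = 26) -> int:
        struct = _STRUCT26 if connectivity == 26 else ndimage.generate_binary_structure(3, 1)
        _, n = ndimage.label(self.voxels, structure=struct)
        return int(n)


class VesselGraph:
    """Skeleton-derived graph: junction/endpoint nodes, polyline edges.

    Thin wrapper over a ``networkx.MultiGraph``. Node attributes: ``pos``
    (world mm centroid of the merged junction cluster), ``voxel_count``.
    Edge attribute ``points``: the full polyline from one node position
    through the chain interior to the other node position, in world mm.
    """

    def __init__(self):
        self.g = nx.MultiGraph()
        self.warnings: list[str] = []

    # -- construction -------------------------------------------------
    def add_node(self, nid: int, pos, voxel_count: int = 1):
        self.g.add_node(nid, pos=np.asarray(pos, dtype=float), voxel_count=voxel_count)

    def add_edge(self, u: int, v: int, points: np.ndarray, n_interior: int):
        self.g.add_edge(u, v, points=np.asarray(points, dtype=float), n_interior=n_interior)

    # -- queries ------------------------------------------------------
    def node_pos(self, nid: int) -> np.ndarray:
        return self.g.nodes[nid]["pos"]

    def degree(self, nid: int) -> int:
        return self.g.degree(nid)

    def endpoints(self) -> list[int]:
        return [n for n in self.g.nodes if self.g.degree(n) == 1]

    def junctions(self) -> list[int]:
        return [n for n in self.g.nodes if self.g.degree(n) >= 3]

    def nearest_node(self, p, tol: float | None = None) -> int:
        """Node nearest to world point ``p``; error if farther than ``tol``."""
        if self.g.number_of_nodes() == 0:
            raise ValueError("graph has no nodes")
        p = np.asarray(p, dtype=float)
        nodes = list(self.g.nodes)
        pos = np.array([self.g.nodes[n]["pos"] for n in nodes])
        d = np.linalg.norm(pos - p, axis=1)
        i = int(np.argmin(d))
        if tol is not None and d[i] > tol:
            raise ValueError(f"no graph node within {tol} mm of {p} (nearest {d[i]:.2f} mm)")
        return nodes[i]

    def edge_polyline(self, u: int, v: int, key: int) -> Centerline:
        return Centerline(self.g.edges[u, v, key]["points"])

    def total_length(self) -> float:
        return sum(arc_length(Centerline(d["points"])) for _, _, d in self.g.edges(data=True))

    def subgraph_component(self, nid: int) -> "VesselGraph":
        comp = nx.node_connected_component(self.g, nid)
        out = VesselGraph()
        out.g = self.g.subgraph(comp).copy()
        out.warnings = list(self.warnings)
        return out


def thin_volume(v: BinaryVolume) -> BinaryVolume:
    """Thin a binary volume to a one-voxel-wide, topology-preserving skeleton.

    Erosion-style border-point deletion with simple-point tests
    (26-connected foreground / 6-connected background). The skeleton is a
    subset of the input foreground, preserves the 26-connected component
    count, and is a fixed point of the operation.
    """
    if not v.voxels.any():
        raise ValueError("cannot skeletonize an empty volume")
    skel = _skimage_skeletonize(v.voxels, method="lee").astype(bool)
    # border-point deletion can erase a small isolated component entirely;
    # restore its innermost voxel so the component count is preserved
    labels, n = ndimage.label(v.voxels, structure=_STRUCT26)
    if n > 1 or not skel.any():
        surviving = set(np.unique(labels[skel])) - {0}
        for cid in range(1, n + 1):
            if cid in surviving:
                continue
            comp = labels == cid
            depth = ndimage.distance_transform_edt(comp)
            skel[np.unravel_index(int(np.argmax(depth)), depth.shape)] = True
    meta = dict(v.meta)
    if not np.allclose(v.spacing, v.spacing[0]):
        # lattice thinning ignores anisotropy; flag so downstream users know
        meta["anisotropic_thinning"] = True
    return BinaryVolume(skel, v.spacing, v.origin, meta)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    padded = np.pad(skel.astype(np.uint8), 1)
    counts = np.zeros_like(padded, dtype=np.uint8)
    for off in _NEIGHBOR_OFFSETS:
        counts += np.roll(padded, -off, axis=(0, 1, 2))
    return counts[1:-1, 1:-1, 1:-1]


def skeleton_to_graph(skel: BinaryVolume) -> VesselGraph:
    """Convert a skeleton volume into a vessel graph of polyline edges.

    Voxels with ≠ 2 skeleton neighbours (26-connectivity) are node voxels;
    26-adjacent node voxels are merged into one node at their world
    centroid. Maximal chains of 2-neighbour voxels become edges. Every
    skeleton voxel is assigned exactly once: to a node cluster or to one
    edge interior. Pure cycles (no node voxel) are anchored at an arbitrary
    chain voxel and reported as a warning.
    """
    graph = VesselGraph()
    mask = skel.voxels
    if not mask.any():
        return graph

    counts = _neighbor_counts(mask)
    node_mask = mask & (counts != 2)
    chain_mask = mask & (counts == 2)

    # merge adjacent node voxels into clusters
    labels, n_clusters = ndimage.label(node_mask, structure=_STRUCT26)
    cluster_of: dict[tuple, int] = {}
    for cid in range(1, n_clusters + 1):
        vox = np.argwhere(labels == cid)
        graph.add_node(cid, skel.world(vox).mean(axis=0), voxel_count=len(vox))
        for t in map(tuple, vox):
            cluster_of[t] = cid

    chain_set = set(map(tuple, np.argwhere(chain_mask)))

    def neighbors(t):
        for off in _NEIGHBOR_OFFSETS:
            u = (t[0] + off[0], t[1] + off[1], t[2] + off[2])
            if u in chain_set or u in cluster_of:
                yield u

    visited_chain: set[tuple] = set()

    def walk(start_node_vox, first_chain_vox):
        """Follow a chain from a node voxel until the next node voxel."""
        path = [first_chain_vox]
        prev, cur = start_node_vox, first_chain_vox
        while True:
            nxts = [u for u in neighbors(cur) if u != prev]
            # a chain voxel has exactly 2 neighbours; the one that is not
            # `prev` continues the chain (or terminates at a node voxel)
            if not nxts:
                return path, None  # dangling (should not happen on valid skeletons)
            nxt = nxts[0]
            if nxt in cluster_of:
                return path, nxt
            prev, cur = cur, nxt
            path.append(cur)

    def add_edge_from_chain(u_cid, v_cid, interior):
        pts = [graph.node_pos(u_cid)]
        pts.extend(skel.world(np.array(interior)))
        pts.append(graph.node_pos(v_cid))
        pts = np.asarray(pts)
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12]
        )
        pts = pts[keep]
        if len(pts) < 2:
            return
        graph.add_edge(u_cid, v_cid, pts, n_interior=len(interior))

    # edges with chain interiors
    for nv, cid in list(cluster_of.items()):
        for nb in neighbors(nv):
            if nb in chain_set and nb not in visited_chain:
                interior, end_vox = walk(nv, nb)
                if end_vox is None:
                    continue
                visited_chain.update(interior)
                add_edge_from_chain(cid, cluster_of[end_vox], interior)

    # direct node-to-node adjacencies between different clusters
    seen_pairs: set[tuple] = set()
    for nv, cid in cluster_of.items():
        for nb in neighbors(nv):
            if nb in cluster_of and cluster_of[nb] != cid:
                pair = tuple(sorted((cid, cluster_of[nb])))
                if pair in seen_pairs or graph.g.has_edge(*pair):
                    continue
                seen_pairs.add(pair)
                add_edge_from_chain(cid, cluster_of[nb], [])

    # leftover chains are pure cycles: anchor each at one voxel
    remaining = chain_set - visited_chain
    next_id = n_clusters + 1
    while remaining:
        anchor = min(remaining)  # deterministic pick
        graph.add_node(next_id, skel.world(np.array(anchor)), voxel_count=1)
        cluster_of[anchor] = next_id
        chain_set.discard(anchor)
        nbs = [u for u in neighbors(anchor) if u in chain_set and u not in visited_chain]
        if nbs:
            interior, end_vox = walk(anchor, nbs[0])
            visited_chain.update(interior)
            if end_vox is not None:
                add_edge_from_chain(next_id, cluster_of[end_vox], interior)
        graph.warnings.append("cycle detected in skeleton (segmentation artifact?)")
        remaining = chain_set - visited_chain - set(cluster_of)
        next_id += 1

    return graph


def prune_spurs(graph: VesselGraph, min_length: float = 3.0) -> VesselGraph:
    """Remove terminal edges shorter than ``min_length`` mm.

    Skeletonization of finite-radius tubes leaves short spurs near
    junctions that would otherwise be mistaken for side branches. After
    pruning, pass-through nodes of degree 2 are spliced so each anatomical
    branch is again a single edge.
    """
    g = graph.g
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if not g.has_edge(u, v, k):
                continue
            length = arc_length(Centerline(d["points"]))
            if length >= min_length:
                continue
            # a spur has an endpoint of degree 1 that is not a lone branch
            for tip, other in ((u, v), (v, u)):
                if g.degree(tip) == 1 and g.degree(other) >= 3:
                    g.remove_edge(u, v, k)
                    g.remove_node(tip)
                    changed = True
                    break
    _splice_degree2(graph)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return graph


def _splice_degree2(graph: VesselGraph):
    g = graph.g
    for n in list(g.nodes):
        if n not in g or g.degree(n) != 2:
            continue
        inc = list(g.edges(n, keys=True, data=True))
        if len(inc) != 2:
            continue  # self-loop
        (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
        a = v1 if u1 == n else u1
        b = v2 if u2 == n else u2
        if a == n or b == n:
            continue
        p1 = d1["points"] if np.allclose(d1["points"][-1], graph.node_pos(n)) else d1["points"][::-1]
        p2 = d2["points"] if np.allclose(d2["points"][0], graph.node_pos(n)) else d2["points"][::-1]
        merged = np.vstack([p1, p2[1:]])
        keep = np.concatenate([[True], np.linalg.norm(np.diff(merged, axis=0), axis=1) > 1e-12])
        merged = merged[keep]
        g.remove_edge(u1, v1, k1)
        g.remove_edge(u2, v2, k2)
        g.remove_node(n)
        graph.add_edge(a, b, merged, n_interior=d1["n_interior"] + d2["n_interior"] + 1)


def _oriented_points(graph: VesselGraph, u: int, v: int, key: int) -> np.ndarray:
    """Edge polyline oriented to run from node u to node v."""
    pts = graph.g.edges[u, v, key]["points"]
    du = np.linalg.norm(pts[0] - graph.node_pos(u))
    dv = np.linalg.norm(pts[-1] - graph.node_pos(u))
    return pts if du <= dv else pts[::-1]


def _best_key(graph: VesselGraph, u: int, v: int) -> int:
    keys = list(graph.g[u][v].keys())
    return keys[0]


def path_polyline(graph: VesselGraph, node_path: list[int], keys: list[int] | None = None) -> Centerline:
    """Concatenate the edges along a node path into one centerline."""
    pts = [graph.node_pos(node_path[0])[None, :]]
    for i, (u, v) in enumerate(zip(node_path[:-1], node_path[1:])):
        key = keys[i] if keys is not None else _best_key(graph, u, v)
        seg = _oriented_points(graph, u, v, key)
        pts.append(seg[1:])
    all_pts = np.vstack(pts)
    keep = np.concatenate([[True], np.linalg.norm(np.diff(all_pts, axis=0), axis=1) > 1e-12])
    return Centerline(all_pts[keep])


def root_paths(graph: VesselGraph, root, tol: float = 2.0) -> list[Centerline]:
    """Every simple path from the root node to each endpoint, root outward.

    ``root`` is a world point; it must lie within ``tol`` mm of a graph
    node. If the graph contains cycles the paths still never revisit a
    node and a warning is recorded on the graph.
    """
    rid = graph.nearest_node(root, tol=tol)
    return [path_polyline(graph, p) for p in root_node_paths(graph, rid)]


def root_node_paths(graph: VesselGraph, rid: int) -> list[list[int]]:
    """Node sequences of every simple path from node ``rid`` to an endpoint."""
    g = graph.g
    if g.number_of_edges() > g.number_of_nodes() - 1:
        graph.warnings.append("graph contains cycles; enumerating simple paths only")
    targets = [n for n in graph.endpoints() if n != rid]
    paths: list[list[int]] = []
    if g.degree(rid) == 0:
        return paths
    for t in sorted(targets):
        for p in nx.all_simple_paths(g, rid, t):
            paths.append(p)
    # deterministic order: by endpoint id, then path length
    paths.sort(key=lambda p: (p[-1], len(p), p))
    return paths
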