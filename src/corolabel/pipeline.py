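"""End-to-end pipeline: mask or centerlines in, segment labels out."""

from __future__ import annotations

import logging

import numpy as np

from .geometry import PointCloud
from .labeler import LabeledTree, label_tree
from .io import PipelineConfig
from .skeleton import BinaryVolume, VesselGraph, prune_spurs, skeleton_to_graph, thin_volume

__all__ = ["graph_from_mask", "graph_from_centerlines", "run_pipeline"]

log = logging.getLogger("corolabel")


def graph_from_mask(mask: BinaryVolume, spur_min_mm: float = 3.0) -> VesselGraph:
    """Skeletonize a binary lumen mask and extract the vessel graph."""
    skel = thin_volume(mask)
    log.info("skeleton: %d voxels from %d foreground", skel.voxels.sum(), mask.voxels.sum())
    graph = skeleton_to_graph(skel)
    graph = prune_spurs(graph, min_length=spur_min_mm)
    log.info(
        "graph: %d nodes, %d edges, %d endpoints",
        graph.g.number_of_nodes(), graph.g.number_of_edges(), len(graph.endpoints()),
    )
    return graph


def graph_from_centerlines(centerlines) -> VesselGraph:
    """Build a vessel graph from polyline centerlines (no skeletonization).

    Polyline endpoints within 1 mm of each other (or of an interior point
    of another polyline) are fused into shared nodes, so per-branch files
    reconnect into a tree.
    """
    graph = VesselGraph()
    tol = 1.0
    node_pos: list[np.ndarray] = []

    def node_for(p):
        for nid, q in enumerate(node_pos):
            if np.linalg.norm(p - q) <= tol:
                return nid
        node_pos.append(np.asarray(p, float))
        nid = len(node_pos) - 1
        graph.add_node(nid, p)
        return nid

    # First pass: branch start points may attach to the interior of a parent
    # branch; split parent polylines at such attachment points.
    lines = [np.asarray(c.points, float) for c in centerlines]
    attach_points = [line[0] for line in lines] + [line[-1] for line in lines]
    split_lines = []
    for line in lines:
        cuts = [0, len(line) - 1]
        for p in attach_points:
            d = np.linalg.norm(line - p, axis=1)
            j = int(np.argmin(d))
            if d[j] <= tol and 0 < j < len(line) - 1:
                cuts.append(j)
        cuts = sorted(set(cuts))
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b > a:
                split_lines.append(line[a : b + 1])
    for seg in split_lines:
        if len(seg) < 2:
            continue
        u = node_for(seg[0])
        v = node_for(seg[-1])
        if u == v:
            continue
        graph.add_edge(u, v, seg, n_interior=max(len(seg) - 2, 0))
    return graph


def run_pipeline(
    *,
    mask: BinaryVolume | None = None,
    centerlines=None,
    la: PointCloud,
    lv: PointCloud,
    ostia: dict,
    cfg: PipelineConfig | None = None,
) -> LabeledTree:
    """Execute skeletonize (if mask input) → graph → label.

    Exactly one of ``mask`` or ``centerlines`` must be given. The
    structured log records per-stage counts and the LCx candidate table
    ends up in the returned tree's provenance.
    """
    cfg = cfg or PipelineConfig()
    if (mask is None) == (centerlines is None):
        raise ValueError("provide exactly one of mask= or centerlines=")
    try:
        if mask is not None:
            graph = graph_from_mask(mask, spur_min_mm=cfg.spur_min_mm)
        else:
            graph = graph_from_centerlines(centerlines)
    except Exception as e:
        raise RuntimeError(f"graph extraction failed: {e}") from e
    try:
        tree = label_tree(graph, la, lv, ostia, cfg.labeler)
    except Exception as e:
        raise RuntimeError(f"labeling failed: {e}") from e
    for w in tree.warnings:
        log.warning("%s", w)
    if "lcx_selected" in tree.provenance:
        log.info("LCx selected: %s", tree.provenance["lcx_selected"])
    return tree
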