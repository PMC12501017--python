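"""Lumen segmentation and centerline-graph extraction.

Lumens are isolated by adaptive thresholding: a voxel is kept when its
value exceeds the local Gaussian-weighted mean (physical window) plus a
fixed fraction of the global value range. The binary mask is cleaned by
morphological closing and small-component removal, thinned to a one-voxel
skeleton on an isotropically resampled grid, and converted into a graph
whose nodes are junctions/endpoints and whose edges are centerline
polylines with physical arc lengths.

The full-pipeline entry point :func:`segment_lumens` thresholds the flow
(decorrelation) volume — which carries the lumen boundary — and gates the
result with the support of the Hessian tubularity response, so that only
flow voxels backed by tubular evidence survive. Thresholding the
vesselness response alone would shrink lumens toward their axes and bias
cross-sectional areas low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import morphology

from .reconstruction import OCTAVolume
from .vesselness import VesselnessVolume

__all__ = [
    "LumenMask",
    "CenterlineGraph",
    "adaptive_threshold",
    "clean_mask",
    "extract_centerlines",
    "segment_lumens",
]


@dataclass
class LumenMask:
    """Binary segmented lumens with voxel spacing and parameter provenance."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


@dataclass
class CenterlineGraph:
    """Vessel centerlines as a graph of polylines in physical micrometers.

    ``graph`` is a networkx MultiGraph whose nodes carry a ``coord_um``
    attribute and whose edges carry ``points_um`` (the polyline, one row
    per point, (z, y, x) um) and ``length_um`` (its arc length).
    """

    graph: nx.MultiGraph
    voxel_size: tuple[float, float, float]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edge_polylines(self) -> list[np.ndarray]:
        return [d["points_um"] for *_, d in self.graph.edges(data=True)]

    def edge_lengths(self) -> list[float]:
        return [d["length_um"] for *_, d in self.graph.edges(data=True)]

    @property
    def total_length_um(self) -> float:
        return float(sum(self.edge_lengths()))


def _arc_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def adaptive_threshold(
    volume: np.ndarray,
    voxel_size: tuple[float, float, float],
    window_um: float = 120.0,
    offset: float = 0.05,
) -> LumenMask:
    """Keep voxels above their local Gaussian mean plus a global-range offset.

    A voxel is set iff ``value > local_mean + offset * (max - min)`` where
    the local mean is Gaussian-weighted with physical standard deviation
    ``window_um / 2`` per axis. The window must be at least three times
    the largest voxel dimension.
    """
    volume = np.asarray(volume, dtype=np.float64)
    spacing = np.asarray(voxel_size, dtype=float)
    if window_um < 3.0 * spacing.max():
        raise ValueError("window must be >= 3x the largest voxel dimension")
    sig_vox = (window_um / 2.0) / spacing
    local_mean = ndimage.gaussian_filter(volume, sigma=sig_vox, mode="nearest")
    vrange = float(volume.max() - volume.min())
    mask = volume > local_mean + offset * vrange
    return LumenMask(
        mask=mask,
        voxel_size=tuple(spacing),
        provenance={"window_um": window_um, "offset": offset},
    )


def _ellipsoid_structure(radius_um: float, voxel_size) -> np.ndarray:
    """Binary ellipsoid of the given physical radius on an anisotropic grid."""
    spacing = np.asarray(voxel_size, dtype=float)
    half = np.maximum(np.floor(radius_um / spacing).astype(int), 0)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    dist2 = sum(g * g for g in grids)
    return dist2 <= radius_um * radius_um


def clean_mask(
    lumen: LumenMask,
    min_component_volume_um3: float = 1e4,
    closing_radius_um: float = 8.0,
) -> LumenMask:
    """Morphological closing then removal of small 26-connected components.

    The closing structuring element is an ellipsoid of the given physical
    radius; components smaller than ``min_component_volume_um3`` (in
    physical volume) are dropped.
    """
    mask = lumen.mask
    spacing = lumen.voxel_size
    if closing_radius_um > 0:
        structure = _ellipsoid_structure(closing_radius_um, spacing)
        if structure.sum() > 1:
            mask = ndimage.binary_closing(mask, structure=structure)
    voxel_vol = float(np.prod(spacing))
    min_voxels = int(np.ceil(min_component_volume_um3 / voxel_vol))
    if min_voxels > 1 and mask.any():
        mask = morphology.remove_small_objects(mask, max_size=min_voxels - 1, connectivity=3)
    prov = dict(lumen.provenance)
    prov.update(
        {
            "closing_radius_um": closing_radius_um,
            "min_component_volume_um3": min_component_volume_um3,
        }
    )
    return LumenMask(mask=mask, voxel_size=spacing, provenance=prov)


# --- skeleton graph -------------------------------------------------------

_NEIGH_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


def _skeleton_neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    return ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")


def _build_graph_from_skeleton(skel: np.ndarray, iso_um: float) -> nx.MultiGraph:
    """Graph from a 1-voxel skeleton on an isotropic grid (spacing iso_um)."""
    g = nx.MultiGraph()
    if not skel.any():
        return g
    counts = _skeleton_neighbor_counts(skel)
    node_vox = skel & (counts != 2)
    # a pure cycle has no natural node; seed one voxel per such component
    chain_only = skel & ~node_vox
    lbl, n_lbl = ndimage.label(chain_only, structure=np.ones((3, 3, 3)))
    if n_lbl:
        has_node_neighbor = ndimage.binary_dilation(
            node_vox, structure=np.ones((3, 3, 3))
        )
        for comp in range(1, n_lbl + 1):
            comp_mask = lbl == comp
            if not np.any(comp_mask & has_node_neighbor):
                seed = tuple(np.argwhere(comp_mask)[0])
                node_vox[seed] = True

    # merge adjacent node voxels into single nodes at their centroid
    node_lbl, n_nodes = ndimage.label(node_vox, structure=np.ones((3, 3, 3)))
    centroids = ndimage.center_of_mass(node_vox, node_lbl, range(1, n_nodes + 1))
    for i, cen in enumerate(centroids, start=1):
        g.add_node(i, coord_um=np.asarray(cen, dtype=float) * iso_um)

    skel_set = {tuple(p) for p in np.argwhere(skel)}
    node_of = {tuple(p): int(node_lbl[tuple(p)]) for p in np.argwhere(node_vox)}
    visited_chain: set[tuple[int, int, int]] = set()
    seen_edges: set[tuple] = set()

    def neighbors(p):
        for off in _NEIGH_OFFSETS:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if q in skel_set:
                yield q

    for start in node_of:
        for nb in neighbors(start):
            if nb in node_of:
                # direct node-to-node contact between different clusters
                a, b = node_of[start], node_of[nb]
                if a != b:
                    key = (min(a, b), max(a, b), min(start, nb), max(start, nb))
                    if key not in seen_edges:
                        seen_edges.add(key)
                        pts = np.array([start, nb], dtype=float) * iso_um
                        g.add_edge(a, b, points_um=pts, length_um=_arc_length(pts))
                continue
            if nb in visited_chain:
                continue
            # walk the degree-2 chain until the next node voxel; every
            # chain voxel has exactly two 26-neighbors, so the step is
            # the unique neighbor other than the previous voxel
            path = [start, nb]
            visited_chain.add(nb)
            prev, cur = start, nb
            while cur not in node_of:
                candidates = [q for q in neighbors(cur) if q != prev]
                if not candidates:
                    break
                nxt = candidates[0]
                path.append(nxt)
                if nxt not in node_of:
                    visited_chain.add(nxt)
                prev, cur = cur, nxt
            end = path[-1]
            if end in node_of:
                a, b = node_of[start], node_of[end]
                pts = np.asarray(path, dtype=float) * iso_um
                g.add_edge(a, b, points_um=pts, length_um=_arc_length(pts))
    return g


def _prune_and_merge(g: nx.MultiGraph, min_branch_length_um: float) -> nx.MultiGraph:
    """Remove short terminal spurs, then merge pass-through (degree-2) nodes."""
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            deg_u, deg_v = g.degree(u), g.degree(v)
            is_spur = (deg_u == 1 or deg_v == 1) and d["length_um"] < min_branch_length_um
            # keep isolated edges (both ends degree 1): they are whole vessels,
            # not spurs off a larger vessel
            if is_spur and not (deg_u == 1 and deg_v == 1):
                g.remove_edge(u, v, key=k)
                changed = True
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])

    # merge chains through degree-2 nodes into single edges
    merged = True
    while merged:
        merged = False
        for n in list(g.nodes):
            if g.degree(n) != 2 or n not in g:
                continue
            inc = list(g.edges(n, keys=True, data=True))
            if len(inc) != 2:
                continue  # self-loop or multi-edge; leave as-is
            (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
            o1 = v1 if u1 == n else u1
            o2 = v2 if u2 == n else u2
            if o1 == n or o2 == n:
                continue
            pts1 = _orient_polyline(d1["points_um"], toward_end=_node_xyz(g, n))
            pts2 = _orient_polyline(d2["points_um"], toward_start=_node_xyz(g, n))
            pts = np.vstack([pts1, pts2[1:]])
            g.remove_edge(u1, v1, key=k1)
            g.remove_edge(u2, v2, key=k2)
            g.remove_node(n)
            g.add_edge(o1, o2, points_um=pts, length_um=_arc_length(pts))
            merged = True
    return g


def _node_xyz(g: nx.MultiGraph, n) -> np.ndarray:
    return np.asarray(g.nodes[n]["coord_um"], dtype=float)


def _orient_polyline(pts: np.ndarray, toward_end=None, toward_start=None) -> np.ndarray:
    """Flip a polyline so its end (or start) is nearest the given point."""
    ref = toward_end if toward_end is not None else toward_start
    d_start = np.linalg.norm(pts[0] - ref)
    d_end = np.linalg.norm(pts[-1] - ref)
    if toward_end is not None:
        return pts if d_end <= d_start else pts[::-1]
    return pts if d_start <= d_end else pts[::-1]


def extract_centerlines(
    lumen: LumenMask, min_branch_length_um: float = 40.0
) -> CenterlineGraph:
    """Thin the mask to a skeleton and build the centerline graph.

    The mask is resampled to isotropic voxels (nearest neighbor, spacing =
    the smallest voxel dimension) before 3D topological thinning, because
    thinning on an anisotropic grid distorts the medial axis; skeleton
    coordinates are mapped back to physical micrometers. Skeleton voxels
    with a 26-neighbor count different from 2 become nodes (adjacent node
    voxels merged at their centroid); maximal degree-2 chains become
    edges; terminal spurs shorter than ``min_branch_length_um`` are
    pruned (whole isolated vessels are never treated as spurs).
    """
    spacing = np.asarray(lumen.voxel_size, dtype=float)
    iso = float(spacing.min())
    if not lumen.mask.any():
        return CenterlineGraph(graph=nx.MultiGraph(), voxel_size=lumen.voxel_size)
    zoom = spacing / iso
    if np.allclose(zoom, 1.0):
        iso_mask = lumen.mask
    else:
        iso_mask = ndimage.zoom(lumen.mask.astype(np.uint8), zoom, order=0).astype(bool)
    skel = morphology.skeletonize(iso_mask)
    skel = _rescue_vanished_components(iso_mask, skel)
    g = _build_graph_from_skeleton(skel, iso)
    g = _prune_and_merge(g, min_branch_length_um)
    return CenterlineGraph(graph=g, voxel_size=lumen.voxel_size)


def _rescue_vanished_components(mask: np.ndarray, skel: np.ndarray) -> np.ndarray:
    """Re-thin components that 3D thinning erased completely.

    Lee-style thinning annihilates structures only one or two voxels
    thick (they contain no unremovable center voxel). Such a component
    is re-skeletonized from its one-voxel dilation — thick enough to
    survive — and the result is clipped back to the component.
    """
    lbl, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n == 0:
        return skel
    have = set(np.unique(lbl[skel])) - {0}
    missing = set(range(1, n + 1)) - have
    if not missing:
        return skel
    skel = skel.copy()
    for comp in missing:
        comp_mask = lbl == comp
        skel |= _principal_axis_chain(comp_mask)
    return skel


def _principal_axis_chain(comp_mask: np.ndarray) -> np.ndarray:
    """One-voxel chain through a thin component, ordered along its long axis.

    Only used when topological thinning erased the component outright;
    such components are line- or bar-like, so per-bin centroids along
    the leading principal direction trace their medial line well.
    """
    pts = np.argwhere(comp_mask)
    out = np.zeros_like(comp_mask)
    if len(pts) == 1:
        out[tuple(pts[0])] = True
        return out
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered.astype(float), full_matrices=False)
    t = centered @ vt[0]
    order = np.argsort(t)
    bins = np.round(t[order]).astype(int)
    chain = []
    for b in np.unique(bins):
        sel = pts[order][bins == b]
        chain.append(np.round(sel.mean(axis=0)).astype(int))
    # fill any gaps so consecutive chain voxels stay 26-adjacent
    filled = [chain[0]]
    for p in chain[1:]:
        prev = filled[-1]
        steps = int(np.max(np.abs(p - prev)))
        for s in range(1, steps + 1):
            filled.append(np.round(prev + (p - prev) * s / steps).astype(int))
    for p in filled:
        out[tuple(p)] = True
    return out


def segment_lumens(
    octa: OCTAVolume,
    vesselness: VesselnessVolume,
    window_um: float = 120.0,
    offset: float = 0.05,
    min_decorrelation: float = 0.05,
    vesselness_gate: float = 0.01,
    gate_dilation_um: float = 8.0,
    min_component_volume_um3: float = 1e4,
    closing_radius_um: float = 8.0,
) -> LumenMask:
    """Flow-thresholded lumens gated by tubular (vesselness) support.

    Adaptive thresholding runs on the decorrelation volume; the result is
    intersected with an absolute flow-significance floor
    (``decorrelation > min_decorrelation``) and with the dilated support
    of the vesselness response (``response > vesselness_gate``), then
    closed and filtered by component size.

    The absolute floor exists because both the adaptive threshold (via
    the global value range) and the data-adaptive vesselness
    normalization are relative: on a volume containing no flow at all
    they would amplify residual sensor-noise decorrelation (order 1e-3
    in static tissue) into spurious lumens. Perfused voxels decorrelate
    at order 0.1-0.4, so a floor of 0.05 separates the two regimes
    without touching genuine vessels.
    """
    flow = adaptive_threshold(
        octa.decorrelation, octa.voxel_size, window_um=window_um, offset=offset
    )
    flow.mask &= octa.decorrelation > min_decorrelation
    flow.provenance["min_decorrelation"] = min_decorrelation
    support = vesselness.response > vesselness_gate
    if gate_dilation_um > 0 and support.any():
        structure = _ellipsoid_structure(gate_dilation_um, octa.voxel_size)
        if structure.sum() > 1:
            support = ndimage.binary_dilation(support, structure=structure)
    gated = LumenMask(
        mask=flow.mask & support,
        voxel_size=octa.voxel_size,
        provenance={
            **flow.provenance,
            "vesselness_gate": vesselness_gate,
            "gate_dilation_um": gate_dilation_um,
        },
    )
    return clean_mask(
        gated,
        min_component_volume_um3=min_component_volume_um3,
        closing_radius_um=closing_radius_um,
    )
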