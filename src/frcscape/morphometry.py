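"""Reticular-network morphometry: skeleton graphs, gaps, fiber shapes.

The FRC network mask is thinned to a 1-pixel skeleton; junction and
endpoint pixels become graph nodes and the degree-2 pixel runs between
them become edges with geodesic lengths (diagonal step = sqrt(2) px).
Gap analysis tiles the background with greedy maximal inscribed circles
(field border treated as an obstacle).  Fiber shape features feed the
morphology clusters (c15-c18), ordered from elongated-simple to
compact-complex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

log = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)
_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonGraph:
    """Graph of a 1-px skeleton: nodes (endpoint/junction) and edges."""

    nodes: list[dict]  # {id, row, col, kind}
    edges: list[dict]  # {node_a, node_b, geodesic_length_um, pixel_path}
    pixel_size_um: float

    @property
    def n_junctions(self) -> int:
        return sum(1 for n in self.nodes if n["kind"] == "junction")

    @property
    def n_endpoints(self) -> int:
        return sum(1 for n in self.nodes if n["kind"] == "endpoint")

    @property
    def n_branches(self) -> int:
        return len(self.edges)

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "nodes": self.nodes,
            "edges": [
                {k: (v if k != "pixel_path" else [list(map(int, p)) for p in v])
                 for k, v in e.items()}
                for e in self.edges
            ],
        }


@dataclass
class GapSet:
    """Maximal inscribed background circles, largest first."""

    circles: list[dict]  # {center_row, center_col, radius_um}
    min_radius_um: float

    @property
    def radii_um(self) -> np.ndarray:
        return np.array([c["radius_um"] for c in self.circles])

    def summary(self) -> dict:
        r = self.radii_um
        return {
            "n_gaps": len(r),
            "mean_radius_um": float(r.mean()) if len(r) else float("nan"),
            "median_radius_um": float(np.median(r)) if len(r) else float("nan"),
        }


# --------------------------------------------------------------------------
# skeleton graph construction
# --------------------------------------------------------------------------


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def _trace_edges(skel: np.ndarray, pixel_size_um: float) -> tuple[list[dict], list[dict]]:
    """Build node clusters and trace degree-2 runs between them."""
    h, w = skel.shape
    counts = _neighbor_counts(skel)
    node_px = skel & (counts != 2)  # endpoints (1) and junctions (>=3)
    # isolated single pixels (count 0) are their own nodes with no edges
    node_labels, n_nodes = cc_label(node_px, connectivity=2, return_num=True)

    nodes: list[dict] = []
    node_kind = {}
    for lab in range(1, n_nodes + 1):
        px = np.argwhere(node_labels == lab)
        r, c = px.mean(axis=0)
        # kind from max pixel degree within cluster
        degs = [counts[tuple(p)] for p in px]
        kind = "junction" if max(degs) >= 3 else "endpoint"
        nodes.append({"id": lab - 1, "row": float(r), "col": float(c), "kind": kind})
        node_kind[lab] = kind

    skel_set = skel
    visited = np.zeros_like(skel, dtype=bool)
    edges: list[dict] = []

    def neighbors(r, c):
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel_set[rr, cc]:
                yield rr, cc

    # trace from every node pixel into each adjacent non-node run
    node_pixels = np.argwhere(node_px)
    direct_seen: set[tuple[int, int]] = set()
    for start in node_pixels:
        sr, sc = map(int, start)
        start_lab = node_labels[sr, sc]
        for nr, nc in neighbors(sr, sc):
            if node_px[nr, nc]:
                # two adjacent node clusters -> direct short edge (deduped)
                other = node_labels[nr, nc]
                key = (min(start_lab, other), max(start_lab, other))
                if other != start_lab and key not in direct_seen:
                    direct_seen.add(key)
                    step = _SQRT2 if (nr != sr and nc != sc) else 1.0
                    edges.append(
                        {
                            "node_a": int(key[0] - 1),
                            "node_b": int(key[1] - 1),
                            "geodesic_length_um": step * pixel_size_um,
                            "pixel_path": [(sr, sc), (nr, nc)],
                        }
                    )
                continue
            if visited[nr, nc]:
                continue
            # walk the degree-2 run
            path = [(sr, sc), (nr, nc)]
            length = (_SQRT2 if (nr != sr and nc != sc) else 1.0)
            visited[nr, nc] = True
            pr, pc, cr, cc_ = sr, sc, nr, nc
            while True:
                nxt = [p for p in neighbors(cr, cc_) if p != (pr, pc)]
                # stop at a node pixel, but don't fall straight back into the
                # start cluster from the first run pixel
                stop = [
                    p
                    for p in nxt
                    if node_px[p]
                    and not (len(path) == 2 and node_labels[p] == start_lab)
                ]
                cont = [p for p in nxt if not node_px[p] and not visited[p]]
                if stop:
                    er, ec = stop[0]
                    step = _SQRT2 if (er != cr and ec != cc_) else 1.0
                    length += step
                    path.append((er, ec))
                    end_lab = node_labels[er, ec]
                    edges.append(
                        {
                            "node_a": int(start_lab - 1),
                            "node_b": int(end_lab - 1),
                            "geodesic_length_um": length * pixel_size_um,
                            "pixel_path": path,
                        }
                    )
                    break
                if not cont:
                    # dead end without a node pixel (shouldn't happen) or cycle
                    edges.append(
                        {
                            "node_a": int(start_lab - 1),
                            "node_b": int(start_lab - 1),
                            "geodesic_length_um": length * pixel_size_um,
                            "pixel_path": path,
                        }
                    )
                    break
                er, ec = cont[0]
                step = _SQRT2 if (er != cr and ec != cc_) else 1.0
                length += step
                visited[er, ec] = True
                path.append((er, ec))
                pr, pc, cr, cc_ = cr, cc_, er, ec

    # pure cycles with no node pixel: each unvisited degree-2 component
    remaining = skel & ~visited & ~node_px
    if remaining.any():
        cyc_labels, n_cyc = cc_label(remaining, connectivity=2, return_num=True)
        for lab in range(1, n_cyc + 1):
            px = np.argwhere(cyc_labels == lab)
            r0, c0 = map(int, px[0])
            nid = len(nodes)
            nodes.append({"id": nid, "row": float(r0), "col": float(c0), "kind": "junction"})
            n_px = len(px)
            edges.append(
                {
                    "node_a": nid,
                    "node_b": nid,
                    "geodesic_length_um": n_px * pixel_size_um,
                    "pixel_path": [tuple(map(int, p)) for p in px],
                }
            )
    return nodes, edges


def _prune_spurs(skel: np.ndarray, prune_px: float) -> np.ndarray:
    """Iteratively delete endpoint-terminated runs shorter than prune_px."""
    skel = skel.copy()
    h, w = skel.shape
    changed = True
    while changed:
        changed = False
        counts = _neighbor_counts(skel)
        endpoints = np.argwhere(skel & (counts == 1))
        for er, ec in endpoints:
            if not skel[er, ec]:
                continue
            # walk from endpoint until junction (neighbors != 2) or length cap
            path = [(int(er), int(ec))]
            length = 0.0
            pr, pc = -1, -1
            cr, cc_ = int(er), int(ec)
            while True:
                counts_local = 0
                nxt = None
                for dr, dc in _NEIGH:
                    rr, cc2 = cr + dr, cc_ + dc
                    if 0 <= rr < h and 0 <= cc2 < w and skel[rr, cc2] and (rr, cc2) != (pr, pc):
                        counts_local += 1
                        nxt = (rr, cc2)
                if counts_local != 1:
                    # reached a junction (or dead end); junction pixel kept
                    reached_junction = counts_local >= 2
                    if reached_junction and length < prune_px:
                        for p in path:
                            skel[p] = False
                        changed = True
                    break
                step = _SQRT2 if (nxt[0] != cr and nxt[1] != cc_) else 1.0
                length += step
                if length >= prune_px:
                    break
                pr, pc, (cr, cc_) = cr, cc_, nxt
                path.append((cr, cc_))
    return skel


def skeletonize_network(
    binary: np.ndarray, pixel_size_um: float = 1.0, prune_spur_um: float = 3.0
) -> SkeletonGraph:
    """Thin a binary fiber mask and build its skeleton graph.

    Spurs (endpoint-terminated branches) shorter than prune_spur_um are
    removed as rasterization artifacts.  An empty mask yields an empty
    graph.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return SkeletonGraph([], [], pixel_size_um)
    skel = skeletonize(binary)
    if prune_spur_um > 0:
        skel = _prune_spurs(skel, prune_spur_um / pixel_size_um)
        skel = skeletonize(skel)  # re-thin after deletions
    if not skel.any():
        return SkeletonGraph([], [], pixel_size_um)
    nodes, edges = _trace_edges(skel, pixel_size_um)
    return SkeletonGraph(nodes, edges, pixel_size_um)


def branch_statistics(graph: SkeletonGraph) -> dict:
    """Branch count, mean branch length (um) and junction count per field."""
    n = graph.n_branches
    lengths = np.array([e["geodesic_length_um"] for e in graph.edges])
    return {
        "n_branches": n,
        "mean_branch_length_um": float(lengths.mean()) if n else float("nan"),
        "total_length_um": float(lengths.sum()) if n else 0.0,
        "n_junctions": graph.n_junctions,
    }


# --------------------------------------------------------------------------
# gap analysis
# --------------------------------------------------------------------------


def gap_analysis(
    binary: np.ndarray,
    pixel_size_um: float = 1.0,
    min_radius_um: float = 5.0,
    max_circles: int = 200,
) -> GapSet:
    """Greedy maximal-inscribed-circle tiling of the network background.

    Obstacles are fiber pixels and the field border.  Circles are
    extracted largest-first; each extracted disk becomes an obstacle so
    circles never overlap.
    """
    fg = np.asarray(binary, dtype=bool)
    h, w = fg.shape
    # pad with a 1-px foreground ring so the border is an obstacle
    obstacle = np.ones((h + 2, w + 2), dtype=bool)
    obstacle[1:-1, 1:-1] = fg
    circles: list[dict] = []
    min_r_px = min_radius_um / pixel_size_um
    yy, xx = np.mgrid[0 : h + 2, 0 : w + 2]
    while len(circles) < max_circles:
        edt = ndimage.distance_transform_edt(~obstacle)
        idx = np.unravel_index(np.argmax(edt), edt.shape)
        r_px = edt[idx]
        if r_px < min_r_px:
            break
        circles.append(
            {
                "center_row": float(idx[0] - 1),
                "center_col": float(idx[1] - 1),
                "radius_um": float(r_px * pixel_size_um),
                "radius_px": float(r_px),
            }
        )
        obstacle |= (yy - idx[0]) ** 2 + (xx - idx[1]) ** 2 <= r_px**2
    return GapSet(circles, min_radius_um)


# --------------------------------------------------------------------------
# fiber shape features and morphology clusters
# --------------------------------------------------------------------------

SHAPE_FEATURE_COLUMNS = (
    "area_um2",
    "major_axis_um",
    "minor_axis_um",
    "elongation",
    "branchpoint_count",
    "endpoint_count",
    "skeleton_length_um",
)


def fiber_shape_features(
    binary: np.ndarray, pixel_size_um: float = 1.0, min_area_px: int = 9
) -> "pd.DataFrame":
    """Per-connected-component shape features of a fiber mask.

    elongation = minor/major axis length, in (0, 1]; branch/endpoint
    counts come from each component's skeleton graph.
    """
    import pandas as pd

    labels, n = cc_label(np.asarray(binary, dtype=bool), connectivity=2, return_num=True)
    rows = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        major = prop.axis_major_length
        minor = prop.axis_minor_length
        if major <= 0:
            elong = 1.0
        else:
            elong = float(np.clip(minor / major, 1e-6, 1.0))
        comp = labels[prop.slice] == prop.label
        g = skeletonize_network(comp, pixel_size_um, prune_spur_um=2 * pixel_size_um)
        stats = branch_statistics(g)
        rows.append(
            {
                "component_id": prop.label,
                "area_um2": prop.area * pixel_size_um**2,
                "major_axis_um": major * pixel_size_um,
                "minor_axis_um": minor * pixel_size_um,
                "elongation": elong,
                "branchpoint_count": g.n_junctions,
                "endpoint_count": g.n_endpoints,
                "skeleton_length_um": stats["total_length_um"],
            }
        )
    return pd.DataFrame(rows, columns=["component_id", *SHAPE_FEATURE_COLUMNS])


def classify_fiber_shapes(features: "pd.DataFrame", k: int = 4, seed: int = 0) -> np.ndarray:
    """Cluster fiber components into shape classes c15..c(14+k).

    K-means on standardized features; clusters are relabeled by ascending
    mean elongation so c15 is the most elongated-simple and the last class
    the most compact-complex, stable across runs.  With fewer components
    than k, falls back to quantile binning on elongation.
    """
    import pandas as pd

    n = len(features)
    feats = features[list(SHAPE_FEATURE_COLUMNS)].to_numpy(dtype=float)
    if n == 0:
        return np.array([], dtype=object)
    if n < k:
        log.warning("only %d components for k=%d: falling back to elongation bins", n, k)
        order = features["elongation"].rank(method="first").to_numpy()
        bins = np.ceil(order / max(1, n) * k).astype(int)
        labels = bins - 1
    else:
        X = StandardScaler().fit_transform(feats)
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        raw = km.fit_predict(X)
        mean_elong = [features["elongation"][raw == c].mean() for c in range(k)]
        order = np.argsort(mean_elong)  # ascending elongation = most elongated first
        remap = {int(c): i for i, c in enumerate(order)}
        labels = np.array([remap[int(c)] for c in raw])
    return np.array([f"c{15 + int(l)}" for l in labels], dtype=object)
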