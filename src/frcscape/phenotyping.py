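"""Single-cell quantification and CD8+ TIL phenotype clustering.

Cells are quantified from a label mask (mean marker intensity, area,
perimeter, circularity = 4*pi*A/P^2).  CD8+ cells are clustered on
arcsinh-normalized checkpoint/granzyme-B intensities with a Jaccard-
weighted k-nearest-neighbour graph and Leiden modularity communities
(PhenoGraph-style); cluster ids c1..cK are renumbered by descending size.
Each cluster then receives a phenotype identity (nonactivated, progenitor
exhausted, cytotoxic, terminally exhausted) from its normalized median
checkpoint vs granzyme-B expression.
"""

from __future__ import annotations

import logging

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from skimage.measure import find_contours, perimeter_crofton, regionprops
from sklearn.neighbors import NearestNeighbors

from .exceptions import (
    DegenerateInputError,
    FormatError,
    PanelError,
    ParameterError,
)
from .io import CHECKPOINT_MARKERS, FUNCTIONAL_MARKERS, MultiplexImage

log = logging.getLogger(__name__)

IDENTITY_NAMES = (
    "nonactivated",
    "progenitor_exhausted",
    "cytotoxic",
    "terminally_exhausted",
    "indeterminate",
)


def estimate_perimeter(mask: np.ndarray) -> float:
    """Boundary length of a binary object in pixels.

    Mean of the 4-direction Crofton estimate (biased low on polygonal
    shapes) and the marching-squares contour length (biased high), so the
    two biases largely cancel for both smooth and rectilinear objects.
    """
    mask = np.pad(np.asarray(mask, dtype=bool), 1)
    p_crofton = perimeter_crofton(mask, directions=4)
    contours = find_contours(mask.astype(float), 0.5)
    p_contour = sum(
        float(np.sqrt((np.diff(c, axis=0) ** 2).sum(axis=1)).sum()) for c in contours
    )
    return 0.5 * (p_crofton + p_contour)


def quantify_cells(
    image: MultiplexImage,
    label_mask: np.ndarray,
    cd8_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-cell morphology and mean marker intensities from a label mask.

    class is 'CD8' when the mean CD8-channel intensity reaches
    cd8_threshold, else 'other'.  Circularity is 4*pi*A/P^2 with the
    perimeter from :func:`estimate_perimeter`.
    """
    label_mask = np.asarray(label_mask)
    if label_mask.shape != image.shape:
        raise FormatError(
            f"label mask shape {label_mask.shape} != image shape {image.shape}"
        )
    px = image.panel.pixel_size_um
    rows = []
    marker_stack = image.channels
    for prop in regionprops(label_mask.astype(np.int64)):
        area_px = prop.area
        perim_px = estimate_perimeter(label_mask[prop.slice] == prop.label)
        area = area_px * px**2
        perim = perim_px * px
        circ = float(4 * np.pi * area / perim**2) if perim > 0 else float("nan")
        mask = label_mask[prop.slice] == prop.label
        means = marker_stack[:, prop.slice[0], prop.slice[1]][:, mask].mean(axis=1)
        row = {
            "cell_id": int(prop.label),
            "sample_id": image.sample_id,
            "core_id": image.core_id,
            "centroid_row": float(prop.centroid[0]),
            "centroid_col": float(prop.centroid[1]),
            "area_um2": float(area),
            "perimeter_um": float(perim),
            "circularity": circ,
        }
        for name, v in zip(image.panel.markers, means):
            row[name] = float(v)
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["class"] = np.where(table["CD8"] >= cd8_threshold, "CD8", "other")
    else:
        table["class"] = pd.Series(dtype=object)
    return table


def cell_density(table: pd.DataFrame, tissue_area_mm2: float, klass: str = "CD8") -> float:
    """Cells of a class per mm^2 of tissue."""
    if not (tissue_area_mm2 > 0):
        raise DegenerateInputError("tissue area must be positive")
    n = int((table["class"] == klass).sum()) if "class" in table else len(table)
    return n / tissue_area_mm2


def normalize_markers(
    table: pd.DataFrame,
    markers: tuple[str, ...] = FUNCTIONAL_MARKERS,
    cofactor: float = 5.0,
    pmin: float = 1.0,
    pmax: float = 99.0,
) -> pd.DataFrame:
    """arcsinh(x/cofactor) then per-marker percentile rescale to [0, 1].

    The pmin percentile maps to 0 and pmax to 1 (clipped); zero-variance
    markers map to 0.  Monotone, so rank order is preserved.
    """
    if pmin >= pmax:
        raise ParameterError("pmin must be < pmax")
    out = table.copy()
    for m in markers:
        x = np.arcsinh(table[m].to_numpy(dtype=float) / cofactor)
        lo, hi = np.percentile(x, [pmin, pmax])
        if hi > lo:
            out[m] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        else:
            out[m] = 0.0
    return out


def cluster_phenotypes(
    table: pd.DataFrame,
    markers: tuple[str, ...] = FUNCTIONAL_MARKERS,
    k_nn: int = 30,
    seed: int = 0,
    max_clusters: int | None = 10,
) -> np.ndarray:
    """PhenoGraph-style community detection on normalized marker space.

    Builds a k-NN graph (Euclidean), reweights edges by neighbourhood
    Jaccard overlap, and runs Leiden modularity optimisation with a fixed
    seed.  Returns labels 'c1'..'cK' renumbered by descending cluster
    size; ties broken by first occurrence.  When more than max_clusters
    communities are found, the smallest are merged into the nearest
    remaining community by centroid distance, keeping the label space at
    c1..c{max_clusters}.
    """
    X_orig = table[list(markers)].to_numpy(dtype=float)
    n = len(X_orig)
    if n < k_nn + 1:
        raise DegenerateInputError(f"need at least k_nn+1={k_nn + 1} cells, got {n}")
    if np.allclose(X_orig, X_orig[0]):
        return np.array(["c1"] * n, dtype=object)
    # canonical cell order so the partition is invariant to input order
    order = np.lexsort(tuple(X_orig[:, i] for i in range(X_orig.shape[1] - 1, -1, -1)))
    X = X_orig[order]
    nn = NearestNeighbors(n_neighbors=k_nn + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row[1:]) for row in idx]
    edges = {}
    for i in range(n):
        for j in idx[i][1:]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in edges:
                continue
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            wt = inter / union if union else 0.0
            if wt > 0:
                edges[(a, b)] = wt
    g = ig.Graph(n=n, edges=list(edges.keys()))
    g.es["weight"] = list(edges.values())
    part = leidenalg.find_partition(
        g,
        leidenalg.ModularityVertexPartition,
        weights="weight",
        seed=seed,
        n_iterations=2,
    )
    raw = np.array(part.membership)
    if max_clusters is not None:
        raw = _merge_small_communities(X, raw, max_clusters)
    # renumber by descending size, first-found tiebreak
    sizes = pd.Series(raw).value_counts(sort=False)
    rank = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {int(c): i + 1 for i, c in enumerate(rank)}
    labels_sorted = np.array([f"c{remap[int(c)]}" for c in raw], dtype=object)
    labels = np.empty(n, dtype=object)
    labels[order] = labels_sorted
    return labels


def _merge_small_communities(X: np.ndarray, labels: np.ndarray, max_k: int) -> np.ndarray:
    """Merge the smallest communities into the nearest surviving one
    (centroid Euclidean distance) until at most max_k remain."""
    labels = labels.copy()
    while len(np.unique(labels)) > max_k:
        uniq, counts = np.unique(labels, return_counts=True)
        smallest = uniq[np.argmin(counts)]
        centroids = {c: X[labels == c].mean(axis=0) for c in uniq}
        src = centroids[smallest]
        best = min(
            (c for c in uniq if c != smallest),
            key=lambda c: float(np.sum((centroids[c] - src) ** 2)),
        )
        labels[labels == smallest] = best
    return labels


def median_expression_matrix(
    table: pd.DataFrame,
    labels: np.ndarray,
    markers: tuple[str, ...] = FUNCTIONAL_MARKERS,
) -> pd.DataFrame:
    """Per-cluster marker medians, min-max rescaled per marker across
    clusters (the heatmap matrix).  Rows are cluster labels; a
    'n_cells' column carries the per-cluster count."""
    df = table[list(markers)].copy()
    df["_cluster"] = labels
    med = df.groupby("_cluster", sort=False).median()
    counts = df.groupby("_cluster", sort=False).size()
    empty = counts[counts == 0]
    if len(empty):
        log.warning("excluding empty clusters: %s", list(empty.index))
        med = med.drop(index=empty.index)
    norm = med.copy()
    for m in markers:
        lo, hi = med[m].min(), med[m].max()
        norm[m] = (med[m] - lo) / (hi - lo) if hi > lo else 0.0
    norm["n_cells"] = counts.reindex(norm.index)
    # sort rows c1, c2, ... numerically when labels follow that pattern
    try:
        norm = norm.loc[sorted(norm.index, key=lambda s: int(str(s).lstrip("c")))]
    except ValueError:
        pass
    return norm


def assign_phenotype_identity(
    matrix: pd.DataFrame,
    low_thr: float = 0.35,
    high_thr: float = 0.65,
    margin: float = 0.10,
) -> pd.Series:
    """Map each cluster to a phenotype identity from the heatmap matrix.

    ckpt is the mean of the five checkpoint medians.  Precedence:
    both ckpt and GrB high -> terminally_exhausted; both low ->
    nonactivated; ckpt exceeding GrB by the margin -> progenitor_exhausted;
    GrB exceeding ckpt -> cytotoxic; otherwise indeterminate (flagged).
    """
    missing = [m for m in FUNCTIONAL_MARKERS if m not in matrix.columns]
    if missing:
        raise PanelError(f"expression matrix missing marker(s) {missing}")
    ckpt = matrix[list(CHECKPOINT_MARKERS)].mean(axis=1)
    grb = matrix["GrB"]
    out = {}
    for cluster in matrix.index:
        c, g = float(ckpt[cluster]), float(grb[cluster])
        if c >= high_thr and g >= high_thr:
            ident = "terminally_exhausted"
        elif c < low_thr and g < low_thr:
            ident = "nonactivated"
        elif c >= g + margin:
            ident = "progenitor_exhausted"
        elif g >= c + margin:
            ident = "cytotoxic"
        else:
            ident = "indeterminate"
            log.warning("cluster %s identity indeterminate (ckpt=%.2f GrB=%.2f)", cluster, c, g)
        out[cluster] = ident
    return pd.Series(out, name="identity")


def frc_ligand_clusters(
    frc_table: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> np.ndarray:
    """Gate FRC records into c11..c14 by PD-L1/PD-L2 double positivity.

    Gate order: -/- -> c11, +/- -> c12, -/+ -> c13, +/+ -> c14.
    Thresholds default to per-marker Otsu over the provided records.
    """
    from skimage.filters import threshold_otsu

    if len(frc_table) == 0:
        raise DegenerateInputError("no FRC records to gate")
    thr = {}
    for m in ("PD-L1", "PD-L2"):
        vals = frc_table[m].to_numpy(dtype=float)
        if thresholds and m in thresholds:
            thr[m] = float(thresholds[m])
        elif np.ptp(vals) > 0:
            thr[m] = float(threshold_otsu(vals))
        else:
            thr[m] = float("inf")
    p1 = frc_table["PD-L1"].to_numpy(dtype=float) >= thr["PD-L1"]
    p2 = frc_table["PD-L2"].to_numpy(dtype=float) >= thr["PD-L2"]
    gate = np.select(
        [~p1 & ~p2, p1 & ~p2, ~p1 & p2, p1 & p2],
        ["c11", "c12", "c13", "c14"],
        default="c11",
    )
    return gate.astype(object)
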