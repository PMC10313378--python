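"""TIL-FRC environment (TFE) discovery.

Per-sample frequency vectors over the CD8 phenotype clusters (c1..c10),
FRC PD-1-ligand gates (c11..c14) and fiber shape classes (c15..c18) are
z-scored per column and hierarchically clustered (Ward linkage, Euclidean
distance).  The number of environments k is chosen by maximum mean
silhouette over a candidate range unless fixed.  TFE ids are renumbered
so TFE1 is the most exhausted-enriched group, giving stable ids across
runs and the expected survival ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .exceptions import DegenerateInputError, ValidationError

log = logging.getLogger(__name__)

CD8_BLOCK = "cd8"
LIGAND_BLOCK = "ligand"
SHAPE_BLOCK = "shape"


@dataclass
class TFEAssignment:
    labels: pd.Series  # sample_id -> 'TFE1'..'TFEk'
    k: int
    linkage_matrix: np.ndarray
    silhouette_scores: dict[int, float]

    def group(self, sample_id: str) -> str:
        return self.labels[sample_id]


_BLOCK_RANGES = {CD8_BLOCK: (1, 10), LIGAND_BLOCK: (11, 14), SHAPE_BLOCK: (15, 18)}


def _validate_block_label(column: str, block: str) -> None:
    lo, hi = _BLOCK_RANGES[block]
    try:
        idx = int(str(column).lstrip("c"))
    except ValueError:
        raise ValidationError(f"unknown cluster column {column!r}") from None
    if not (lo <= idx <= hi):
        raise ValidationError(
            f"cluster label {column!r} outside the {block} block range c{lo}-c{hi}"
        )


def _core_fractions(labels: pd.Series, columns: list[str]) -> pd.Series:
    counts = labels.value_counts()
    total = counts.sum()
    if total == 0:
        return pd.Series(np.nan, index=columns)
    unknown = set(counts.index) - set(columns)
    if unknown:
        raise ValidationError(f"unknown cluster label(s) {sorted(unknown)}")
    return pd.Series(
        {c: counts.get(c, 0) / total for c in columns}, index=columns, dtype=float
    )


def build_frequency_matrix(
    cd8_labels: pd.DataFrame,
    ligand_labels: pd.DataFrame,
    shape_labels: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample cluster frequency matrix, averaged over cores.

    Each input is a long table with columns (sample_id, core_id, cluster).
    Within each core the fractions of each block sum to 1; per-sample
    values are the unweighted mean across that sample's cores.  Samples
    with an empty block are imputed with the uniform distribution and
    flagged via the '<block>_imputed' column.
    """
    blocks = {
        CD8_BLOCK: (cd8_labels, [f"c{i}" for i in range(1, 11)]),
        LIGAND_BLOCK: (ligand_labels, [f"c{i}" for i in range(11, 15)]),
        SHAPE_BLOCK: (shape_labels, [f"c{i}" for i in range(15, 19)]),
    }
    # column set may be smaller than the nominal c1-c10 if fewer CD8
    # communities were found; use observed labels within the block range
    sample_ids = sorted(
        set().union(*[set(df["sample_id"]) for df, _ in blocks.values() if len(df)])
    )
    pieces = []
    flags = {}
    for block, (df, nominal) in blocks.items():
        observed = sorted(
            set(df["cluster"]), key=lambda s: int(str(s).lstrip("c"))
        ) if len(df) else []
        columns = observed if observed else nominal
        for c in columns:
            _validate_block_label(c, block)
        per_sample = {}
        imputed = {}
        for sid in sample_ids:
            sub = df[df["sample_id"] == sid] if len(df) else df
            core_rows = []
            for cid, core_df in sub.groupby("core_id"):
                core_rows.append(_core_fractions(core_df["cluster"], columns))
            if core_rows:
                per_sample[sid] = pd.concat(core_rows, axis=1).mean(axis=1)
                imputed[sid] = False
            else:
                per_sample[sid] = pd.Series(1.0 / len(columns), index=columns)
                imputed[sid] = True
                log.warning("sample %s has no %s objects: uniform-imputed", sid, block)
        pieces.append(pd.DataFrame(per_sample).T)
        flags[f"{block}_imputed"] = pd.Series(imputed)
    out = pd.concat(pieces, axis=1)
    for name, flag in flags.items():
        out[name] = flag
    out.index.name = "sample_id"
    return out


def frequency_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if str(c).startswith("c") and str(c)[1:].isdigit()]


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column (x - mean)/sd over samples; zero-variance columns -> 0."""
    cols = frequency_columns(matrix)
    if len(matrix) < 2:
        raise DegenerateInputError("z-scoring requires at least 2 samples")
    out = matrix[cols].copy().astype(float)
    for c in cols:
        sd = out[c].std(ddof=0)
        if sd > 0:
            out[c] = (out[c] - out[c].mean()) / sd
        else:
            out[c] = 0.0
            log.warning("column %s has zero variance: set to 0", c)
    return out


def cluster_samples(
    zmatrix: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    k_fixed: int | None = None,
    exhausted_columns: list[str] | None = None,
    order_scores: pd.Series | None = None,
) -> TFEAssignment:
    """Ward-linkage hierarchical clustering of samples into TFE groups.

    k is chosen by maximum mean silhouette over k_range unless k_fixed is
    given.  Groups are renumbered by exhausted-cluster enrichment so TFE1
    is the most exhausted-enriched: by descending group mean of
    order_scores when given (typically the per-sample total frequency of
    the exhausted CD8 clusters), else by mean z-score over
    exhausted_columns, else by group mean over all columns.
    """
    X = zmatrix.to_numpy(dtype=float)
    n = len(X)
    if n < 2:
        raise DegenerateInputError("need at least 2 samples")
    Z = linkage(X, method="ward", metric="euclidean")
    lo, hi = k_range
    hi_eff = min(hi, n - 1)
    if hi_eff < hi:
        log.warning("k_range clipped to (%d, %d) for n=%d samples", lo, hi_eff, n)
    scores: dict[int, float] = {}
    if k_fixed is None:
        for k in range(lo, hi_eff + 1):
            lab = fcluster(Z, k, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            scores[k] = float(silhouette_score(X, lab))
        k = max(scores, key=lambda kk: scores[kk])
    else:
        k = k_fixed
    raw = fcluster(Z, k, criterion="maxclust")

    if order_scores is not None:
        score_basis = order_scores.reindex(zmatrix.index)
    elif exhausted_columns:
        present = [c for c in exhausted_columns if c in zmatrix.columns]
        score_basis = zmatrix[present].mean(axis=1) if present else zmatrix.mean(axis=1)
    else:
        score_basis = zmatrix.mean(axis=1)
    group_scores = {
        g: float(score_basis[raw == g].mean()) for g in np.unique(raw)
    }
    order = sorted(group_scores, key=lambda g: -group_scores[g])
    remap = {g: i + 1 for i, g in enumerate(order)}
    labels = pd.Series(
        [f"TFE{remap[g]}" for g in raw], index=zmatrix.index, name="tfe"
    )
    return TFEAssignment(labels, int(k), Z, scores)


def characterize_tfe(
    assignment: TFEAssignment, zmatrix: pd.DataFrame, top_n: int = 3
) -> pd.DataFrame:
    """Per-TFE mean z-score per cluster column plus enrichment summaries."""
    df = zmatrix.copy()
    df["_tfe"] = assignment.labels
    means = df.groupby("_tfe").mean()
    means.index.name = "tfe"
    summaries = {}
    for tfe, row in means.iterrows():
        top = row.sort_values(ascending=False)
        summaries[tfe] = (
            f"enriched: {', '.join(top.index[:top_n])}; "
            f"depleted: {', '.join(top.index[-top_n:][::-1])}"
        )
    means["summary"] = pd.Series(summaries)
    return means
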