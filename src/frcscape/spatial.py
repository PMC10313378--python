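"""Cell-to-network spatial distance analysis.

Distances are measured from each CD8 centroid to the nearest FRC-mask
pixel via the Euclidean distance transform of the mask complement, in um.
Profiles aggregate mean distances per (CD8 cluster, TFE group); a TFE is
flagged "uncoupled" when its cell-weighted mean distance exceeds a cutoff
(10 um by default, the bound used for the poor-outcome group).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DegenerateInputError


def distance_to_network(
    frc_mask: np.ndarray,
    centroids: np.ndarray,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Per-cell Euclidean distance (um) to the nearest FRC-mask pixel."""
    frc_mask = np.asarray(frc_mask, dtype=bool)
    if not frc_mask.any():
        raise DegenerateInputError("FRC mask is empty")
    centroids = np.asarray(centroids, dtype=float)
    if centroids.size == 0:
        return np.zeros(0)
    edt = ndimage.distance_transform_edt(~frc_mask)
    r = np.clip(np.round(centroids[:, 0]).astype(int), 0, frc_mask.shape[0] - 1)
    c = np.clip(np.round(centroids[:, 1]).astype(int), 0, frc_mask.shape[1] - 1)
    return edt[r, c] * pixel_size_um


def cluster_distance_profile(
    distances: pd.DataFrame,
    tfe_labels: pd.Series,
) -> pd.DataFrame:
    """Mean distance per (CD8 cluster, TFE).

    distances: long table with columns (sample_id, cluster, distance_um).
    Cells from samples without a TFE assignment are dropped.  Empty
    (cluster, TFE) combinations are left as NaN, not zero-filled.
    """
    df = distances.copy()
    df["tfe"] = df["sample_id"].map(tfe_labels)
    df = df.dropna(subset=["tfe"])
    profile = df.pivot_table(
        index="cluster", columns="tfe", values="distance_um", aggfunc="mean"
    )
    try:
        profile = profile.loc[
            sorted(profile.index, key=lambda s: int(str(s).lstrip("c")))
        ]
    except ValueError:
        pass
    return profile


def contact_fraction(distances_um: np.ndarray, contact_threshold_um: float = 5.0) -> dict:
    """Fraction of cells within the contact threshold of the network."""
    d = np.asarray(distances_um, dtype=float)
    return {
        "fraction": float((d <= contact_threshold_um).mean()) if d.size else float("nan"),
        "threshold_um": float(contact_threshold_um),
        "n_cells": int(d.size),
    }


def uncoupling_flag(
    distances: pd.DataFrame,
    tfe_labels: pd.Series,
    cutoff_um: float = 10.0,
) -> pd.Series:
    """Per-TFE flag: cell-weighted mean CD8-to-network distance > cutoff."""
    df = distances.copy()
    df["tfe"] = df["sample_id"].map(tfe_labels)
    df = df.dropna(subset=["tfe"])
    means = df.groupby("tfe")["distance_um"].mean()
    return (means > cutoff_um).rename("uncoupled")
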