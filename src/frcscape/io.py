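"""Readers/writers for the formats the pipeline touches.

Images are multipage TIFF stacks (one page per marker channel), label masks
are 16/32-bit integer TIFFs with 0 reserved for background, tables are CSV,
and run configuration is versioned YAML.  All rasters are row-major with the
origin at the top-left and 0-based pixel indexing; physical distances are
derived from the panel's ``pixel_size_um``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import (
    FormatError,
    PanelError,
    ParameterError,
    SchemaError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Markers every default panel carries, in channel order.
DEFAULT_MARKERS: tuple[str, ...] = (
    "PDPN",
    "CD31",
    "CD20",
    "CD8",
    "FAP",
    "PD-1",
    "LAG-3",
    "TIM-3",
    "PD-L1",
    "PD-L2",
    "GrB",
)

#: Inhibitory checkpoint receptors/ligands measured on CD8+ TILs.
CHECKPOINT_MARKERS: tuple[str, ...] = ("PD-1", "LAG-3", "TIM-3", "PD-L1", "PD-L2")

#: Markers used for CD8 phenotype clustering (checkpoints + granzyme B).
FUNCTIONAL_MARKERS: tuple[str, ...] = CHECKPOINT_MARKERS + ("GrB",)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered channel → marker mapping plus the physical pixel size.

    Channel index is the position in ``markers`` (contiguous from 0).
    """

    markers: tuple[str, ...]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ParameterError("panel must contain at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError("marker names must be unique")
        if not (self.pixel_size_um > 0):
            raise ParameterError("pixel_size_um must be positive")
        object.__setattr__(self, "markers", tuple(self.markers))

    def __len__(self) -> int:
        return len(self.markers)

    def index_of(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise PanelError(f"marker {marker!r} not in panel {self.markers}") from None

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "channel": np.arange(len(self.markers)),
                "marker": list(self.markers),
                "pixel_size_um": self.pixel_size_um,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path)
        for col in ("channel", "marker", "pixel_size_um"):
            if col not in df.columns:
                raise SchemaError(f"panel CSV missing required column {col!r}")
        df = df.sort_values("channel")
        channels = df["channel"].to_numpy()
        if not np.array_equal(channels, np.arange(len(channels))):
            raise ValidationError("panel channel indices must be contiguous from 0")
        return cls(tuple(df["marker"]), float(df["pixel_size_um"].iloc[0]))


def default_panel(pixel_size_um: float = 1.0) -> MarkerPanel:
    return MarkerPanel(DEFAULT_MARKERS, pixel_size_um)


@dataclass
class MultiplexImage:
    """A multichannel image: ``channels`` is (channel, row, col) float."""

    channels: np.ndarray
    panel: MarkerPanel
    sample_id: str = ""
    core_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3:
            raise FormatError("channels must be a (channel, row, col) stack")
        if self.channels.shape[0] != len(self.panel):
            raise FormatError(
                f"image has {self.channels.shape[0]} channels but panel lists "
                f"{len(self.panel)} markers"
            )
        if not np.all(np.isfinite(self.channels)) or self.channels.min() < 0:
            raise ValidationError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, marker: str) -> np.ndarray:
        return self.channels[self.panel.index_of(marker)]


def write_multiplex_image(path: str | Path, image: MultiplexImage) -> None:
    tifffile.imwrite(path, image.channels.astype(np.float32))


def read_multiplex_image(
    path: str | Path, panel: MarkerPanel, sample_id: str = "", core_id: str = ""
) -> MultiplexImage:
    """Read a multipage TIFF as a MultiplexImage, channel order per panel.

    Intensities are widened to float32 without rescaling.
    """
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(panel):
        raise FormatError(
            f"{path}: {stack.shape[0]} pages but panel lists {len(panel)} markers"
        )
    return MultiplexImage(stack.astype(np.float32), panel, sample_id, core_id)


def write_label_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    dtype = np.uint16 if mask.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(path, mask.astype(dtype))


def read_label_mask(path: str | Path) -> np.ndarray:
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise FormatError(f"{path}: label mask must be 2D")
    if not np.issubdtype(mask.dtype, np.integer) or mask.min() < 0:
        raise ValidationError("label mask must be a non-negative integer raster")
    return mask.astype(np.int64)


def label_ids(mask: np.ndarray) -> np.ndarray:
    """Distinct nonzero labels present in a mask (cells need not be contiguous)."""
    ids = np.unique(mask)
    return ids[ids > 0]


# required columns for a minimal cell table
CELL_TABLE_REQUIRED = ("cell_id", "sample_id", "core_id", "centroid_row", "centroid_col")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing required column(s) {missing}")
    return df


def write_cell_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical table: sample_id, overall-survival time (months), event flag."""
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "os_time", "event") if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample_id(s): {dupes}")
    times = df["os_time"].to_numpy(dtype=float)
    if not np.all(np.isfinite(times)) or (times < 0).any():
        raise ValidationError("os_time must be finite and non-negative")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event flag must be 0 or 1")
    return df


CONFIG_SCHEMA_VERSION = 1


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    version = cfg.get("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise FormatError(
            f"config schema_version {version} unsupported (expected {CONFIG_SCHEMA_VERSION})"
        )
    cfg["schema_version"] = version
    return cfg


def save_config(path: str | Path, cfg: dict) -> None:
    cfg = dict(cfg)
    cfg.setdefault("schema_version", CONFIG_SCHEMA_VERSION)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
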