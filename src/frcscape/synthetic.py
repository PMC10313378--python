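"""Seeded synthetic IMC-like data: reticular networks, cells, and cohorts.

The generator emulates the statistical structure of a lymph-node tissue
microarray: a fibroblastic reticular cell (FRC) fiber network grown as a
random-walk tree with branching (so the true skeleton graph is known before
rasterization), lymphatic/blood endothelial structures, CD8+ T cells drawn
from phenotype archetypes with distinct checkpoint/granzyme-B intensity
profiles, placement either coupled to the network or held at a minimum
clearance from it, and per-patient survival times with archetype-specific
exponential hazards.

All outputs are fully determined by the seeds carried in the parameter
objects: the same parameters yield bit-identical rasters and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as disk_coords
from skimage.draw import line as line_coords
from skimage.morphology import disk as disk_footprint

from .exceptions import DegenerateInputError, ParameterError, PlacementError
from .io import (
    CHECKPOINT_MARKERS,
    FUNCTIONAL_MARKERS,
    MarkerPanel,
    MultiplexImage,
    default_panel,
)

PHENOTYPE_NAMES: tuple[str, ...] = (
    "nonactivated",
    "progenitor_exhausted",
    "cytotoxic",
    "terminally_exhausted",
)

#: Stroma class codes shared with the mapping stage.
STROMA_NONE, STROMA_FRC, STROMA_LEC, STROMA_BEC = 0, 1, 2, 3


# --------------------------------------------------------------------------
# parameter objects
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the random-walk fiber-network generator.

    fiber_density is the expected number of fiber trees per 100x100 um of
    field; branch_length_scale_um sets the total walk budget per tree.
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    fiber_density: float = 2.0
    branch_length_scale_um: float = 60.0
    fiber_width_px: int = 3
    branching_prob: float = 0.05
    direction_jitter: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 32 or w < 32:
            raise ParameterError("field_size_px must be at least 32x32")
        if not (self.pixel_size_um > 0):
            raise ParameterError("pixel_size_um must be positive")
        if self.fiber_density < 0:
            raise ParameterError("fiber_density must be >= 0")
        if not (self.branch_length_scale_um > 0):
            raise ParameterError("branch_length_scale_um must be positive")
        if self.fiber_width_px < 1:
            raise ParameterError("fiber_width_px must be a positive integer")


@dataclass(frozen=True)
class PhenotypeArchetype:
    """A CD8 phenotype with lognormal marker intensity profile."""

    name: str
    marker_means: dict[str, float]
    marker_sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.name not in PHENOTYPE_NAMES:
            raise ParameterError(f"unknown phenotype {self.name!r}")
        expected = set(FUNCTIONAL_MARKERS)
        if set(self.marker_means) != expected or set(self.marker_sds) != expected:
            raise ParameterError(f"marker maps must cover exactly {sorted(expected)}")
        for m in FUNCTIONAL_MARKERS:
            if not (self.marker_means[m] > 0 and self.marker_sds[m] > 0):
                raise ParameterError("marker means/sds must be positive")


# Invented fixture constants mirroring the qualitative lo/hi pattern of the
# four CD8 phenotype states; arbitrary intensity units.
_ARCHETYPE_INTENSITY = {
    "nonactivated": {"ckpt": 1.0, "GrB": 1.0},
    "progenitor_exhausted": {"ckpt": 8.0, "GrB": 1.5},
    "cytotoxic": {"ckpt": 1.5, "GrB": 9.0},
    "terminally_exhausted": {"ckpt": 9.0, "GrB": 8.0},
}


def default_phenotype_archetypes() -> dict[str, PhenotypeArchetype]:
    out = {}
    for name, levels in _ARCHETYPE_INTENSITY.items():
        means = {m: levels["ckpt"] for m in CHECKPOINT_MARKERS}
        means["GrB"] = levels["GrB"]
        sds = {m: 0.30 * v for m, v in means.items()}
        out[name] = PhenotypeArchetype(name, means, sds)
    return out


@dataclass(frozen=True)
class TFEArchetype:
    """A TIL-FRC environment archetype.

    cd8_cluster_weights is a simplex over the four phenotype archetypes;
    frc_ligand_level is the propensity of FRC objects/fibers to be PD-1
    ligand positive; placement_mode couples CD8 cells to the network or
    keeps them at >= clearance_um from it; hazard_rate is the exponential
    overall-survival hazard (1/month).
    """

    name: str
    cd8_cluster_weights: dict[str, float]
    frc_ligand_level: float
    frc_shape_bias: str
    placement_mode: str
    clearance_um: float
    hazard_rate: float

    def __post_init__(self) -> None:
        if set(self.cd8_cluster_weights) != set(PHENOTYPE_NAMES):
            raise ParameterError("cd8_cluster_weights must cover all phenotype names")
        total = sum(self.cd8_cluster_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"cd8_cluster_weights must sum to 1 (got {total})")
        if self.frc_shape_bias not in ("elongated", "circular"):
            raise ParameterError("frc_shape_bias must be 'elongated' or 'circular'")
        if self.placement_mode not in ("coupled", "uncoupled"):
            raise ParameterError("placement_mode must be 'coupled' or 'uncoupled'")
        if self.placement_mode == "uncoupled" and not (self.clearance_um > 0):
            raise ParameterError("uncoupled placement requires clearance_um > 0")
        if not (0 <= self.frc_ligand_level <= 1):
            raise ParameterError("frc_ligand_level must be in [0, 1]")
        if not (self.hazard_rate > 0):
            raise ParameterError("hazard_rate must be positive")

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.cd8_cluster_weights[n] for n in PHENOTYPE_NAMES])


def default_tfe_archetypes() -> list[TFEArchetype]:
    """The four default environments.

    Compositions follow the qualitative descriptions of the four
    microenvironment groups (TFE1 exhausted-enriched and spatially
    uncoupled, TFE2 ligand-high/progenitor-exhausted, TFE3 nonactivated
    with circular ligand-low FRCs, TFE4 cytotoxic-enriched); the numeric
    weights, ligand levels and hazards are fixture constants, with the
    TFE1:TFE4 hazard ratio set to 4 and TFE2/TFE3 intermediate.
    """
    w = lambda a, b, c, d: dict(zip(PHENOTYPE_NAMES, (a, b, c, d)))
    return [
        TFEArchetype("TFE1", w(0.05, 0.35, 0.10, 0.50), 0.30, "elongated", "uncoupled", 12.0, 0.12),
        TFEArchetype("TFE2", w(0.15, 0.60, 0.05, 0.20), 0.80, "elongated", "coupled", 0.0, 0.06),
        TFEArchetype("TFE3", w(0.65, 0.15, 0.12, 0.08), 0.10, "circular", "coupled", 0.0, 0.05),
        TFEArchetype("TFE4", w(0.20, 0.08, 0.65, 0.07), 0.40, "elongated", "coupled", 0.0, 0.03),
    ]


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 40
    cores_per_sample: int = 2
    n_cd8_per_core: int = 150
    n_frc_objects_per_core: int = 40
    core_field_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    mixing_noise_sd: float = 0.05
    censor_fraction: float = 0.2
    seed: int = 0
    archetype_library: tuple[TFEArchetype, ...] = field(
        default_factory=lambda: tuple(default_tfe_archetypes())
    )

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.cores_per_sample < 1:
            raise ParameterError("n_samples and cores_per_sample must be positive")
        if self.mixing_noise_sd < 0:
            raise ParameterError("mixing_noise_sd must be >= 0")
        if not (0 <= self.censor_fraction <= 1):
            raise ParameterError("censor_fraction must be in [0, 1]")
        if len(self.archetype_library) == 0:
            raise ParameterError("archetype_library must not be empty")
        object.__setattr__(self, "archetype_library", tuple(self.archetype_library))


# --------------------------------------------------------------------------
# fiber network generation
# --------------------------------------------------------------------------


@dataclass
class NetworkGroundTruth:
    """Skeleton statistics of the generative graph, recorded pre-raster."""

    n_branches: int
    n_junctions: int
    total_length_um: float
    branch_lengths_um: list[float]
    segments: list[np.ndarray]  # polylines, (n, 2) float pixel coords


def _grow_network(rng: np.random.Generator, params: NetworkParams):
    """Grow fiber trees by random-walk with branching; return segments."""
    h, w = params.field_size_px
    px = params.pixel_size_um
    area_um2 = h * w * px * px
    n_fibers = int(round(params.fiber_density * area_um2 / 1e4))
    step_px = 2.0
    step_um = step_px * px
    min_branch_steps = max(4, int(8 / step_um))  # keep segments above spur length
    segments: list[np.ndarray] = []
    lengths: list[float] = []
    n_junctions = 0

    for _ in range(n_fibers):
        start = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        theta = rng.uniform(0, 2 * math.pi)
        budget_um = params.branch_length_scale_um * rng.uniform(0.7, 1.3)
        budget_steps = max(min_branch_steps + 1, int(budget_um / step_um))
        # stack of pending walks: (position, direction, remaining steps)
        stack = [(start, theta, budget_steps)]
        while stack:
            pos, ang, steps = stack.pop()
            pts = [pos.copy()]
            seg_len = 0.0
            for _ in range(steps):
                ang += rng.normal(0.0, params.direction_jitter)
                nxt = pos + step_px * np.array([math.sin(ang), math.cos(ang)])
                if not (0 <= nxt[0] < h and 0 <= nxt[1] < w):
                    break
                pos = nxt
                pts.append(pos.copy())
                seg_len += step_um
                steps -= 1
                if steps > min_branch_steps and rng.random() < params.branching_prob:
                    # branch point: close this segment, continue two children
                    child_ang = ang + rng.choice([-1, 1]) * rng.uniform(0.6, 1.3)
                    child_steps = max(min_branch_steps, int(steps * rng.uniform(0.5, 0.9)))
                    stack.append((pos.copy(), child_ang, child_steps))
                    stack.append((pos.copy(), ang, steps))
                    n_junctions += 1
                    break
            if len(pts) >= 2:
                segments.append(np.array(pts))
                lengths.append(seg_len)
    return segments, lengths, n_junctions


def _rasterize_segments(
    segments: list[np.ndarray], shape: tuple[int, int], width_px: int
) -> np.ndarray:
    raster = np.zeros(shape, dtype=bool)
    for seg in segments:
        pix = np.round(seg).astype(int)
        pix[:, 0] = np.clip(pix[:, 0], 0, shape[0] - 1)
        pix[:, 1] = np.clip(pix[:, 1], 0, shape[1] - 1)
        for a, b in zip(pix[:-1], pix[1:]):
            rr, cc = line_coords(a[0], a[1], b[0], b[1])
            raster[rr, cc] = True
    if width_px > 1:
        raster = ndimage.binary_dilation(raster, disk_footprint(width_px // 2))
    return raster


def generate_frc_network(params: NetworkParams) -> tuple[np.ndarray, NetworkGroundTruth]:
    """Render an FRC fiber network raster with its generative skeleton truth.

    Returns (binary raster, ground truth).  fiber_density = 0 yields an
    all-background raster with zero branches.  Deterministic under seed.
    """
    rng = np.random.default_rng(params.seed)
    segments, lengths, n_junctions = _grow_network(rng, params)
    raster = _rasterize_segments(segments, tuple(params.field_size_px), params.fiber_width_px)
    truth = NetworkGroundTruth(
        n_branches=len(segments),
        n_junctions=n_junctions,
        total_length_um=float(sum(lengths)),
        branch_lengths_um=list(lengths),
        segments=segments,
    )
    return raster, truth


def _network_params_for_archetype(
    base: NetworkParams, archetype: TFEArchetype
) -> NetworkParams:
    """Circular shape bias shortens walks; blobs are added at render time."""
    if archetype.frc_shape_bias == "circular":
        return replace(base, branch_length_scale_um=0.45 * base.branch_length_scale_um)
    return base


def _render_circular_frc_blobs(
    rng: np.random.Generator, shape: tuple[int, int], n_blobs: int
) -> np.ndarray:
    blobs = np.zeros(shape, dtype=bool)
    h, w = shape
    for _ in range(n_blobs):
        r = rng.uniform(4, 8)
        cy, cx = rng.uniform(r, h - r), rng.uniform(r, w - r)
        rr, cc = disk_coords((cy, cx), r, shape=shape)
        blobs[rr, cc] = True
    return blobs


def _render_vessels(rng: np.random.Generator, shape: tuple[int, int], pixel_size_um: float):
    """LEC: larger elongated ellipses; BEC: small disks.  Returns two masks."""
    h, w = shape
    area_scale = (h * w) / (512 * 512)
    lec = np.zeros(shape, dtype=bool)
    bec = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(max(1, int(round(3 * area_scale)))):
        cy, cx = rng.uniform(10, h - 10), rng.uniform(10, w - 10)
        a, b = rng.uniform(8, 16), rng.uniform(3, 6)
        th = rng.uniform(0, math.pi)
        u = (yy - cy) * math.cos(th) + (xx - cx) * math.sin(th)
        v = -(yy - cy) * math.sin(th) + (xx - cx) * math.cos(th)
        lec |= (u / a) ** 2 + (v / b) ** 2 <= 1
    for _ in range(max(2, int(round(6 * area_scale)))):
        cy, cx = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
        rr, cc = disk_coords((cy, cx), rng.uniform(3, 6), shape=shape)
        bec[rr, cc] = True
    return lec, bec


# --------------------------------------------------------------------------
# cell placement and sample rendering
# --------------------------------------------------------------------------


def place_cells(
    rng: np.random.Generator,
    network: np.ndarray,
    n_cells: int,
    mode: str,
    clearance_um: float,
    pixel_size_um: float,
    min_separation_px: float = 5.0,
    max_retries_factor: int = 400,
) -> np.ndarray:
    """Sample cell centroids coupled to or cleared from the network.

    Coupled: most centroids land within a few um of a network pixel
    (a small uniform background fraction is retained).  Uncoupled: every
    centroid's EDT distance to the network is >= clearance_um, enforced
    exactly; raises PlacementError if the constraint cannot be met within
    the retry budget.
    """
    h, w = network.shape
    if n_cells == 0:
        return np.zeros((0, 2), dtype=float)
    edt = ndimage.distance_transform_edt(~network) * pixel_size_um
    net_idx = np.argwhere(network)
    if mode == "uncoupled" and not network.any():
        # no obstacles: any placement satisfies clearance trivially
        pass
    centroids: list[np.ndarray] = []
    attempts = 0
    budget = max_retries_factor * n_cells
    while len(centroids) < n_cells:
        attempts += 1
        if attempts > budget:
            raise PlacementError(
                f"could not place {n_cells} cells (mode={mode}, "
                f"clearance={clearance_um} um) within {budget} attempts"
            )
        if mode == "coupled" and len(net_idx) > 0 and rng.random() > 0.10:
            base = net_idx[rng.integers(len(net_idx))]
            cand = base + rng.normal(0, 1.5, size=2)
        else:
            cand = np.array([rng.uniform(3, h - 3), rng.uniform(3, w - 3)])
        r, c = int(round(cand[0])), int(round(cand[1]))
        if not (3 <= r < h - 3 and 3 <= c < w - 3):
            continue
        if mode == "uncoupled" and edt[r, c] < clearance_um:
            continue
        if centroids and min_separation_px > 0:
            d2 = np.sum((np.array(centroids) - [r, c]) ** 2, axis=1)
            if d2.min() < min_separation_px**2:
                continue
        centroids.append(np.array([r, c], dtype=float))
    return np.array(centroids)


def _draw_cell_marker_values(
    rng: np.random.Generator,
    archetypes: np.ndarray,
    library: dict[str, PhenotypeArchetype],
) -> pd.DataFrame:
    """Per-cell functional-marker intensities, lognormal around the archetype
    profile (Gaussian on the log scale, positive by construction)."""
    cols = {}
    for m in FUNCTIONAL_MARKERS:
        mu = np.array([library[a].marker_means[m] for a in archetypes])
        sd = np.array([library[a].marker_sds[m] for a in archetypes])
        sigma = np.sqrt(np.log1p((sd / mu) ** 2))
        cols[m] = mu * np.exp(rng.normal(0, 1, size=len(archetypes)) * sigma - sigma**2 / 2)
    return pd.DataFrame(cols)


def generate_sample_image(
    network: NetworkParams,
    tfe: TFEArchetype,
    n_cd8: int,
    seed: int,
    sample_id: str = "S1",
    core_id: str = "c1",
    panel: MarkerPanel | None = None,
    phenotype_library: dict[str, PhenotypeArchetype] | None = None,
) -> dict:
    """Render one synthetic IMC core.

    Returns a dict with the MultiplexImage, the ground-truth cell table
    (centroid, archetype, true marker means), the ground-truth stroma class
    raster, the 16-bit cell label mask, and the network skeleton truth.
    """
    if n_cd8 < 0:
        raise ParameterError("n_cd8 must be >= 0")
    panel = panel or default_panel(network.pixel_size_um)
    library = phenotype_library or default_phenotype_archetypes()
    rng = np.random.default_rng(seed)
    h, w = network.field_size_px
    px = network.pixel_size_um

    net_params = _network_params_for_archetype(network, tfe)
    fiber_raster, net_truth = generate_frc_network(net_params)
    frc_mask = fiber_raster.copy()
    if tfe.frc_shape_bias == "circular":
        n_blobs = max(3, int(round(len(net_truth.segments) * 0.6)))
        frc_mask |= _render_circular_frc_blobs(rng, (h, w), n_blobs)
    lec, bec = _render_vessels(rng, (h, w), px)

    stroma_truth = np.zeros((h, w), dtype=np.uint8)
    stroma_truth[frc_mask] = STROMA_FRC
    stroma_truth[lec] = STROMA_LEC
    stroma_truth[bec] = STROMA_BEC
    frc_class = stroma_truth == STROMA_FRC  # FRC pixels not claimed by vessels

    # per-fiber PD-1 ligand positivity (propensity = frc_ligand_level)
    ligand_pos = np.zeros((h, w), dtype=bool)
    for seg in net_truth.segments:
        if rng.random() < tfe.frc_ligand_level:
            m = _rasterize_segments([seg], (h, w), net_params.fiber_width_px)
            ligand_pos |= m
    ligand_pos &= frc_class

    # cells
    centroids = place_cells(
        rng, frc_mask, n_cd8, tfe.placement_mode, tfe.clearance_um, px
    )
    archetype_names = np.array(PHENOTYPE_NAMES)
    weights = tfe.weight_vector
    cell_arch = (
        archetype_names[rng.choice(len(archetype_names), size=n_cd8, p=weights)]
        if n_cd8
        else np.array([], dtype=object)
    )
    cell_values = _draw_cell_marker_values(rng, cell_arch, library)
    radii = rng.uniform(3.0, 5.0, size=n_cd8)

    label_mask = np.zeros((h, w), dtype=np.uint16)
    for i, (cen, rad) in enumerate(zip(centroids, radii), start=1):
        rr, cc = disk_coords(tuple(cen), rad, shape=(h, w))
        label_mask[rr, cc] = i

    # channel stack: low lognormal background everywhere
    chans = np.empty((len(panel), h, w), dtype=np.float32)
    for k in range(len(panel)):
        chans[k] = 0.2 * np.exp(rng.normal(0, 0.3, size=(h, w)))

    def paint(marker: str, mask: np.ndarray, level: float, jitter: float = 0.25) -> None:
        k = panel.index_of(marker)
        vals = level * np.exp(rng.normal(0, jitter, size=int(mask.sum())))
        chans[k][mask] = np.maximum(chans[k][mask], vals)

    paint("PDPN", frc_class | lec, 10.0)
    paint("CD31", lec | bec, 10.0)
    paint("CD20", ~(frc_mask | lec | bec), 2.0, 0.4)  # diffuse tumor B-cell field
    paint("FAP", frc_class, 4.0, 0.5)
    paint("PD-L1", ligand_pos, 8.0)
    paint("PD-L2", ligand_pos, 8.0)
    cell_fp = label_mask > 0
    paint("CD8", cell_fp, 8.0)
    for m in FUNCTIONAL_MARKERS:
        k = panel.index_of(m)
        for i in range(n_cd8):
            fp = label_mask == (i + 1)
            v = cell_values[m].iloc[i]
            chans[k][fp] = np.maximum(
                chans[k][fp], v * np.exp(rng.normal(0, 0.1, size=int(fp.sum())))
            )

    cell_table = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cd8 + 1),
            "sample_id": sample_id,
            "core_id": core_id,
            "centroid_row": centroids[:, 0] if n_cd8 else np.array([]),
            "centroid_col": centroids[:, 1] if n_cd8 else np.array([]),
            "radius_px": radii,
            "archetype": cell_arch,
        }
    )
    for m in FUNCTIONAL_MARKERS:
        cell_table[m] = cell_values[m].to_numpy()

    image = MultiplexImage(chans, panel, sample_id, core_id)
    return {
        "image": image,
        "cell_table": cell_table,
        "stroma_truth": stroma_truth,
        "label_mask": label_mask,
        "network_truth": net_truth,
        "frc_mask": frc_mask,
        "ligand_mask": ligand_pos,
    }


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


@dataclass
class CoreData:
    core_id: str
    network_raster: np.ndarray
    cd8_table: pd.DataFrame
    frc_table: pd.DataFrame


@dataclass
class SampleRecord:
    sample_id: str
    archetype_name: str
    cores: list[CoreData]


@dataclass
class CohortBundle:
    """A synthetic cohort: per-sample cores, clinical table, ground truth."""

    samples: list[SampleRecord]
    clinical: pd.DataFrame
    config: CohortConfig

    @property
    def truth_archetypes(self) -> pd.Series:
        return pd.Series(
            {s.sample_id: s.archetype_name for s in self.samples}, name="archetype"
        )

    def pooled_cd8(self) -> pd.DataFrame:
        return pd.concat([c.cd8_table for s in self.samples for c in s.cores], ignore_index=True)

    def pooled_frc(self) -> pd.DataFrame:
        return pd.concat([c.frc_table for s in self.samples for c in s.cores], ignore_index=True)


def draw_survival(
    rng: np.random.Generator, hazard: float, n: int, censor_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with uniform censoring.

    Censored subjects (probability censor_fraction) get an observation time
    uniform on (0, T) and event flag 0.
    """
    t = rng.exponential(1.0 / hazard, size=n)
    censored = rng.random(n) < censor_fraction
    obs = np.where(censored, rng.uniform(0, 1, size=n) * t, t)
    events = (~censored).astype(int)
    return obs, events


def _jitter_weights(rng: np.random.Generator, weights: np.ndarray, sd: float) -> np.ndarray:
    w = np.clip(weights + rng.normal(0, sd, size=len(weights)), 1e-6, None)
    return w / w.sum()


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a cohort of samples in table mode.

    Samples are assigned archetypes round-robin; each sample draws jittered
    phenotype weights shared by its cores; each core gets a rendered fiber
    raster, a CD8 cell table with archetype-specific marker intensities and
    distances placed per the archetype's coupling mode, and an FRC object
    table whose PD-L1/PD-L2 positivity follows frc_ligand_level.
    """
    rng = np.random.default_rng(config.seed)
    library = default_phenotype_archetypes()
    n_arch = len(config.archetype_library)
    samples: list[SampleRecord] = []
    clin_rows = []
    archetype_names = np.array(PHENOTYPE_NAMES)

    for i in range(config.n_samples):
        arch = config.archetype_library[i % n_arch]
        sid = f"S{i + 1:03d}"
        weights = _jitter_weights(rng, arch.weight_vector, config.mixing_noise_sd)
        cores = []
        for j in range(config.cores_per_sample):
            cid = f"{sid}_core{j + 1}"
            net_params = _network_params_for_archetype(
                NetworkParams(
                    field_size_px=config.core_field_px,
                    pixel_size_um=config.pixel_size_um,
                    seed=int(rng.integers(2**31 - 1)),
                ),
                arch,
            )
            raster, _ = generate_frc_network(net_params)
            if arch.frc_shape_bias == "circular":
                raster = raster | _render_circular_frc_blobs(
                    rng, tuple(config.core_field_px), 8
                )
            n_cd8 = config.n_cd8_per_core
            centroids = place_cells(
                rng, raster, n_cd8, arch.placement_mode, arch.clearance_um,
                config.pixel_size_um, min_separation_px=0.0,
            )
            cell_arch = archetype_names[
                rng.choice(len(archetype_names), size=n_cd8, p=weights)
            ]
            values = _draw_cell_marker_values(rng, cell_arch, library)
            cd8 = pd.DataFrame(
                {
                    "cell_id": np.arange(1, n_cd8 + 1),
                    "sample_id": sid,
                    "core_id": cid,
                    "centroid_row": centroids[:, 0] if n_cd8 else np.array([]),
                    "centroid_col": centroids[:, 1] if n_cd8 else np.array([]),
                    "archetype": cell_arch,
                }
            )
            for m in FUNCTIONAL_MARKERS:
                cd8[m] = values[m].to_numpy()
            n_frc = config.n_frc_objects_per_core
            pos = rng.random(n_frc) < arch.frc_ligand_level
            frc = pd.DataFrame(
                {
                    "object_id": np.arange(1, n_frc + 1),
                    "sample_id": sid,
                    "core_id": cid,
                    "PD-L1": np.where(pos, 8.0, 0.8)
                    * np.exp(rng.normal(0, 0.3, n_frc)),
                    "PD-L2": np.where(pos, 8.0, 0.8)
                    * np.exp(rng.normal(0, 0.3, n_frc)),
                }
            )
            cores.append(CoreData(cid, raster, cd8, frc))
        samples.append(SampleRecord(sid, arch.name, cores))
        t, e = draw_survival(rng, arch.hazard_rate, 1, config.censor_fraction)
        clin_rows.append(
            {"sample_id": sid, "os_time": float(t[0]), "event": int(e[0]),
             "archetype": arch.name}
        )

    clinical = pd.DataFrame(clin_rows)
    return CohortBundle(samples, clinical, config)
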