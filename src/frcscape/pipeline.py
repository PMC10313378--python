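"""End-to-end orchestration.

Two entry points:

* :func:`analyze_cohort` — in-memory analysis of a synthetic cohort bundle
  (tables mode): CD8 phenotype clustering, identity assignment, FRC ligand
  gates, fiber shape classes, the per-sample frequency matrix, TFE
  discovery, distance profiles and survival stratification.

* :func:`run_all` — disk-based pipeline from a YAML config: simulate
  synthetic cores to TIFF/CSV, then run stroma mapping, morphometry,
  phenotyping, TFE classification, spatial and survival stages in
  dependency order, with content-hash-based stage skipping and a run
  manifest.  All randomness flows from one root seed expanded per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import FrcscapeError
from .io import (
    FUNCTIONAL_MARKERS,
    MultiplexImage,
    default_panel,
    read_label_mask,
    read_multiplex_image,
    write_label_mask,
    write_multiplex_image,
)
from .morphometry import (
    branch_statistics,
    classify_fiber_shapes,
    fiber_shape_features,
    gap_analysis,
    skeletonize_network,
)
from .phenotyping import (
    assign_phenotype_identity,
    cluster_phenotypes,
    frc_ligand_clusters,
    median_expression_matrix,
    normalize_markers,
    quantify_cells,
)
from .spatial import cluster_distance_profile, distance_to_network, uncoupling_flag
from .stats import survival_fit
from .stroma import area_occupied, classify_stroma_pixels
from .synthetic import (
    CohortBundle,
    CohortConfig,
    NetworkParams,
    default_tfe_archetypes,
    generate_cohort,
    generate_sample_image,
)
from .tfe import (
    build_frequency_matrix,
    cluster_samples,
    characterize_tfe,
    zscore_columns,
)

log = logging.getLogger(__name__)


def derive_seed(root_seed: int, stage: str) -> int:
    """Expand one root seed into a per-stage seed, stable across runs."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# --------------------------------------------------------------------------
# in-memory cohort analysis (tables mode)
# --------------------------------------------------------------------------


@dataclass
class CohortAnalysis:
    cd8_cells: pd.DataFrame  # pooled, with cluster + identity + distance_um
    expression_matrix: pd.DataFrame
    cluster_identities: pd.Series
    frequency_matrix: pd.DataFrame
    zmatrix: pd.DataFrame
    assignment: "object"
    tfe_profile: pd.DataFrame
    distance_profile: pd.DataFrame
    uncoupled: pd.Series
    survival: "object | None"


def analyze_cohort(
    bundle: CohortBundle,
    k_nn: int = 30,
    seed: int = 0,
    k_fixed: int | None = None,
    k_range: tuple[int, int] = (2, 8),
) -> CohortAnalysis:
    """Run the full tables-mode analysis on a synthetic cohort bundle."""
    cd8 = bundle.pooled_cd8().reset_index(drop=True)
    norm = normalize_markers(cd8)
    labels = cluster_phenotypes(norm, k_nn=k_nn, seed=seed)
    cd8 = cd8.copy()
    cd8["cluster"] = labels
    matrix = median_expression_matrix(norm, labels)
    identities = assign_phenotype_identity(matrix)
    cd8["identity"] = cd8["cluster"].map(identities)

    frc = bundle.pooled_frc().reset_index(drop=True)
    frc = frc.copy()
    frc["cluster"] = frc_ligand_clusters(frc)

    shape_rows = []
    for s in bundle.samples:
        for core in s.cores:
            feats = fiber_shape_features(
                core.network_raster, bundle.config.pixel_size_um
            )
            feats["sample_id"] = s.sample_id
            feats["core_id"] = core.core_id
            shape_rows.append(feats)
    shapes = pd.concat(shape_rows, ignore_index=True)
    shapes["cluster"] = classify_fiber_shapes(shapes, k=4, seed=seed)

    freq = build_frequency_matrix(
        cd8[["sample_id", "core_id", "cluster"]],
        frc[["sample_id", "core_id", "cluster"]],
        shapes[["sample_id", "core_id", "cluster"]],
    )
    zmat = zscore_columns(freq)
    exhausted_cols = [
        c for c, ident in identities.items()
        if ident in ("progenitor_exhausted", "terminally_exhausted")
    ]
    order_scores = (
        freq[[c for c in exhausted_cols if c in freq.columns]].sum(axis=1)
        if exhausted_cols
        else None
    )
    assignment = cluster_samples(
        zmat,
        k_range=k_range,
        k_fixed=k_fixed,
        exhausted_columns=exhausted_cols,
        order_scores=order_scores,
    )
    profile_means = characterize_tfe(assignment, zmat)

    # distances per core
    dist_parts = []
    for s in bundle.samples:
        for core in s.cores:
            sub = cd8[cd8["core_id"] == core.core_id]
            if len(sub) == 0 or not core.network_raster.any():
                continue
            d = distance_to_network(
                core.network_raster,
                sub[["centroid_row", "centroid_col"]].to_numpy(),
                bundle.config.pixel_size_um,
            )
            dist_parts.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "core_id": core.core_id,
                        "cell_id": sub["cell_id"].to_numpy(),
                        "cluster": sub["cluster"].to_numpy(),
                        "distance_um": d,
                    }
                )
            )
    distances = pd.concat(dist_parts, ignore_index=True)
    cd8 = cd8.merge(
        distances[["core_id", "cell_id", "distance_um"]],
        on=["core_id", "cell_id"],
        how="left",
    )
    dprofile = cluster_distance_profile(distances, assignment.labels)
    uncoupled = uncoupling_flag(distances, assignment.labels)

    surv = None
    if len(bundle.clinical):
        surv = survival_fit(bundle.clinical, assignment.labels)

    return CohortAnalysis(
        cd8_cells=cd8,
        expression_matrix=matrix,
        cluster_identities=identities,
        frequency_matrix=freq,
        zmatrix=zmat,
        assignment=assignment,
        tfe_profile=profile_means,
        distance_profile=dprofile,
        uncoupled=uncoupled,
        survival=surv,
    )


# --------------------------------------------------------------------------
# disk-based pipeline with manifest and stage skipping
# --------------------------------------------------------------------------

STAGES = ("simulate", "stroma", "morphometry", "phenotype", "tfe", "spatial", "survival")


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=str))


def _core_paths(images_dir: Path) -> list[tuple[str, str, Path, Path]]:
    """(sample_id, core_id, image path, labels path) per simulated core."""
    out = []
    for img in sorted(images_dir.glob("*_image.tiff")):
        core_id = img.name[: -len("_image.tiff")]
        sample_id = core_id.split("_core")[0]
        out.append((sample_id, core_id, img, img.with_name(f"{core_id}_labels.tiff")))
    return out


def run_all(
    config: dict,
    out_dir: str | Path,
    force: bool = False,
    stop_after: str | None = None,
) -> dict:
    """Run every stage on a synthetic cohort described by the config.

    Stages are skipped when their parameter/input hash is unchanged and
    their outputs exist; deleting a stage's outputs recomputes it and its
    descendants.  stop_after ends the run after the named stage (e.g.
    'simulate').  Returns the run manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    )
    manifest = {
        "version": __version__,
        "config_hash": _hash_obj(config),
        "seed": config.get("seed", 0),
        "stages": {},
    }
    root_seed = int(config.get("seed", 0))
    ccfg = config.get("cohort", {})
    acfg = config.get("analysis", {})
    pixel_size = float(ccfg.get("pixel_size_um", 1.0))
    panel = default_panel(pixel_size)

    upstream_ran = False

    def stage_should_run(name: str, params_hash: str, outputs: list[Path]) -> bool:
        if force or upstream_ran:
            return True
        prev = previous.get("stages", {}).get(name)
        if prev is None or prev.get("hash") != params_hash:
            return True
        return not all(p.exists() for p in outputs)

    def record(name: str, params_hash: str, outputs: list[Path], ran: bool, t0: float):
        manifest["stages"][name] = {
            "hash": params_hash,
            "outputs": [str(p.relative_to(out)) for p in outputs],
            "ran": ran,
            "elapsed_s": round(time.monotonic() - t0, 3),
        }
        log.info("stage %-12s %s (%.2fs)", name, "ran" if ran else "skipped",
                 time.monotonic() - t0)

    # ---- simulate ----------------------------------------------------
    t0 = time.monotonic()
    images_dir = out / "images"
    sim_hash = _hash_obj({"cohort": ccfg, "seed": root_seed})
    clinical_path = out / "clinical.csv"
    field_px = tuple(ccfg.get("field_px", (256, 256)))
    n_samples = int(ccfg.get("n_samples", 8))
    cores_per_sample = int(ccfg.get("cores_per_sample", 1))
    n_cd8 = int(ccfg.get("n_cd8_per_core", 80))
    sim_outputs = [clinical_path, images_dir / "done.json"]
    if stage_should_run("simulate", sim_hash, sim_outputs):
        upstream_ran = True
        images_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(derive_seed(root_seed, "simulate"))
        archetypes = default_tfe_archetypes()
        clin_rows = []
        truth = {}
        from .synthetic import draw_survival

        for i in range(n_samples):
            arch = archetypes[i % len(archetypes)]
            sid = f"S{i + 1:03d}"
            truth[sid] = arch.name
            for j in range(cores_per_sample):
                cid = f"{sid}_core{j + 1}"
                net = NetworkParams(
                    field_size_px=field_px,
                    pixel_size_um=pixel_size,
                    seed=int(rng.integers(2**31 - 1)),
                )
                sample = generate_sample_image(
                    net, arch, n_cd8, seed=int(rng.integers(2**31 - 1)),
                    sample_id=sid, core_id=cid, panel=panel,
                )
                write_multiplex_image(images_dir / f"{cid}_image.tiff", sample["image"])
                write_label_mask(images_dir / f"{cid}_labels.tiff", sample["label_mask"])
                sample["cell_table"].to_csv(
                    images_dir / f"{cid}_truth_cells.csv", index=False
                )
            t, e = draw_survival(
                rng, arch.hazard_rate, 1, float(ccfg.get("censor_fraction", 0.2))
            )
            clin_rows.append(
                {"sample_id": sid, "os_time": float(t[0]), "event": int(e[0])}
            )
        pd.DataFrame(clin_rows).to_csv(clinical_path, index=False)
        panel.to_csv(out / "panel.csv")
        _dump_json(images_dir / "done.json", {"n_samples": n_samples, "truth": truth})
        record("simulate", sim_hash, sim_outputs, True, t0)
    else:
        record("simulate", sim_hash, sim_outputs, False, t0)

    def finalize() -> dict:
        manifest["manifest_hash"] = _hash_obj(
            {k: v["hash"] for k, v in manifest["stages"].items()}
        )
        _dump_json(manifest_path, manifest)
        return manifest

    if stop_after == "simulate":
        return finalize()

    cores = _core_paths(images_dir)

    # ---- stroma ------------------------------------------------------
    t0 = time.monotonic()
    stroma_dir = out / "stroma"
    stroma_hash = _hash_obj({"sim": sim_hash, "params": acfg.get("stroma", {})})
    stroma_outputs = [stroma_dir / "area_stats.json"] + [
        stroma_dir / f"{cid}_frc_mask.tiff" for _, cid, _, _ in cores
    ]
    if stage_should_run("stroma", stroma_hash, stroma_outputs):
        upstream_ran = True
        stroma_dir.mkdir(exist_ok=True)
        area_stats = {}
        for sid, cid, img_path, _ in cores:
            image = read_multiplex_image(img_path, panel, sid, cid)
            smap = classify_stroma_pixels(image)
            write_label_mask(
                stroma_dir / f"{cid}_frc_mask.tiff", smap.frc_mask.astype(np.uint16)
            )
            area_stats[cid] = area_occupied(smap)
        _dump_json(stroma_dir / "area_stats.json", area_stats)
        record("stroma", stroma_hash, stroma_outputs, True, t0)
    else:
        record("stroma", stroma_hash, stroma_outputs, False, t0)

    # ---- morphometry -------------------------------------------------
    t0 = time.monotonic()
    morph_dir = out / "morphometry"
    morph_hash = _hash_obj({"stroma": stroma_hash, "params": acfg.get("morphometry", {})})
    shapes_path = morph_dir / "fiber_shapes.csv"
    morph_outputs = [morph_dir / "morphometry.json", shapes_path]
    if stage_should_run("morphometry", morph_hash, morph_outputs):
        upstream_ran = True
        morph_dir.mkdir(exist_ok=True)
        min_gap = float(acfg.get("morphometry", {}).get("min_gap_radius_um", 5.0))
        results = {}
        shape_rows = []
        for sid, cid, _, _ in cores:
            frc_mask = read_label_mask(stroma_dir / f"{cid}_frc_mask.tiff") > 0
            graph = skeletonize_network(frc_mask, pixel_size_um=pixel_size)
            gaps = gap_analysis(frc_mask, pixel_size_um=pixel_size, min_radius_um=min_gap)
            results[cid] = {
                "branches": branch_statistics(graph),
                "gaps": gaps.summary(),
            }
            feats = fiber_shape_features(frc_mask, pixel_size_um=pixel_size)
            feats["sample_id"] = sid
            feats["core_id"] = cid
            shape_rows.append(feats)
        shapes = pd.concat(shape_rows, ignore_index=True)
        shapes["cluster"] = classify_fiber_shapes(
            shapes, k=4, seed=derive_seed(root_seed, "shapes")
        )
        shapes.to_csv(shapes_path, index=False)
        _dump_json(morph_dir / "morphometry.json", results)
        record("morphometry", morph_hash, morph_outputs, True, t0)
    else:
        record("morphometry", morph_hash, morph_outputs, False, t0)

    # ---- phenotype ---------------------------------------------------
    t0 = time.monotonic()
    pheno_dir = out / "phenotype"
    pheno_hash = _hash_obj({"stroma": stroma_hash, "params": acfg.get("phenotype", {})})
    cells_path = pheno_dir / "cells.csv"
    frc_objects_path = pheno_dir / "frc_objects.csv"
    heatmap_path = pheno_dir / "heatmap.csv"
    pheno_outputs = [cells_path, frc_objects_path, heatmap_path]
    if stage_should_run("phenotype", pheno_hash, pheno_outputs):
        upstream_ran = True
        pheno_dir.mkdir(exist_ok=True)
        k_nn = int(acfg.get("phenotype", {}).get("k_nn", 15))
        all_cells = []
        frc_rows = []
        from skimage.measure import label as cc_label, regionprops

        for sid, cid, img_path, lab_path in cores:
            image = read_multiplex_image(img_path, panel, sid, cid)
            mask = read_label_mask(lab_path)
            table = quantify_cells(image, mask)
            all_cells.append(table)
            # FRC objects: connected components of the FRC mask with mean
            # PD-1 ligand intensities, for the c11-c14 gates
            frc_mask = read_label_mask(stroma_dir / f"{cid}_frc_mask.tiff") > 0
            comp = cc_label(frc_mask, connectivity=2)
            pl1 = image.channel("PD-L1")
            pl2 = image.channel("PD-L2")
            for prop in regionprops(comp):
                if prop.area < 9:
                    continue
                m = comp == prop.label
                frc_rows.append(
                    {
                        "sample_id": sid,
                        "core_id": cid,
                        "object_id": int(prop.label),
                        "PD-L1": float(pl1[m].mean()),
                        "PD-L2": float(pl2[m].mean()),
                    }
                )
        cells = pd.concat(all_cells, ignore_index=True)
        cd8 = cells[cells["class"] == "CD8"].reset_index(drop=True)
        norm = normalize_markers(cd8)
        labels = cluster_phenotypes(
            norm, k_nn=k_nn, seed=derive_seed(root_seed, "phenotype")
        )
        cd8["cluster"] = labels
        matrix = median_expression_matrix(norm, labels)
        identities = assign_phenotype_identity(matrix)
        cd8["identity"] = cd8["cluster"].map(identities)
        matrix.assign(identity=identities).to_csv(heatmap_path)
        cd8.to_csv(cells_path, index=False)
        frc_objects = pd.DataFrame(frc_rows)
        frc_objects["cluster"] = frc_ligand_clusters(frc_objects)
        frc_objects.to_csv(frc_objects_path, index=False)
        record("phenotype", pheno_hash, pheno_outputs, True, t0)
    else:
        record("phenotype", pheno_hash, pheno_outputs, False, t0)

    # ---- tfe ---------------------------------------------------------
    t0 = time.monotonic()
    tfe_dir = out / "tfe"
    tfe_hash = _hash_obj({"pheno": pheno_hash, "morph": morph_hash,
                          "params": acfg.get("tfe", {})})
    freq_path = tfe_dir / "frequencies.csv"
    tfe_path = tfe_dir / "tfe.csv"
    tfe_outputs = [freq_path, tfe_path, tfe_dir / "tfe_summary.json"]
    if stage_should_run("tfe", tfe_hash, tfe_outputs):
        upstream_ran = True
        tfe_dir.mkdir(exist_ok=True)
        cd8 = pd.read_csv(cells_path)
        frc_objects = pd.read_csv(frc_objects_path)
        shapes = pd.read_csv(shapes_path)
        heat = pd.read_csv(heatmap_path, index_col=0)
        freq = build_frequency_matrix(
            cd8[["sample_id", "core_id", "cluster"]],
            frc_objects[["sample_id", "core_id", "cluster"]],
            shapes[["sample_id", "core_id", "cluster"]],
        )
        zmat = zscore_columns(freq)
        exhausted = [
            c for c, ident in heat["identity"].items()
            if ident in ("progenitor_exhausted", "terminally_exhausted")
        ]
        k_fixed = acfg.get("tfe", {}).get("k_fixed")
        order_scores = (
            freq[[c for c in exhausted if c in freq.columns]].sum(axis=1)
            if exhausted
            else None
        )
        assignment = cluster_samples(
            zmat, k_fixed=k_fixed, exhausted_columns=exhausted,
            order_scores=order_scores,
        )
        freq.to_csv(freq_path)
        assignment.labels.to_frame().to_csv(tfe_path)
        _dump_json(
            tfe_dir / "tfe_summary.json",
            {
                "k": assignment.k,
                "silhouette_scores": assignment.silhouette_scores,
                "group_sizes": assignment.labels.value_counts().to_dict(),
            },
        )
        record("tfe", tfe_hash, tfe_outputs, True, t0)
    else:
        record("tfe", tfe_hash, tfe_outputs, False, t0)

    # ---- spatial -----------------------------------------------------
    t0 = time.monotonic()
    spatial_dir = out / "spatial"
    spatial_hash = _hash_obj({"tfe": tfe_hash, "params": acfg.get("spatial", {})})
    dist_path = spatial_dir / "distances.csv"
    spatial_outputs = [dist_path, spatial_dir / "profile.csv", spatial_dir / "uncoupling.json"]
    if stage_should_run("spatial", spatial_hash, spatial_outputs):
        upstream_ran = True
        spatial_dir.mkdir(exist_ok=True)
        cd8 = pd.read_csv(cells_path)
        tfe_labels = pd.read_csv(tfe_path, index_col=0)["tfe"]
        parts = []
        for sid, cid, _, _ in cores:
            sub = cd8[cd8["core_id"] == cid]
            frc_mask = read_label_mask(stroma_dir / f"{cid}_frc_mask.tiff") > 0
            if len(sub) == 0 or not frc_mask.any():
                continue
            d = distance_to_network(
                frc_mask, sub[["centroid_row", "centroid_col"]].to_numpy(), pixel_size
            )
            parts.append(
                pd.DataFrame(
                    {"sample_id": sid, "core_id": cid,
                     "cluster": sub["cluster"].to_numpy(), "distance_um": d}
                )
            )
        distances = pd.concat(parts, ignore_index=True)
        distances.to_csv(dist_path, index=False)
        cluster_distance_profile(distances, tfe_labels).to_csv(
            spatial_dir / "profile.csv"
        )
        flags = uncoupling_flag(distances, tfe_labels)
        _dump_json(
            spatial_dir / "uncoupling.json",
            {k: bool(v) for k, v in flags.items()},
        )
        record("spatial", spatial_hash, spatial_outputs, True, t0)
    else:
        record("spatial", spatial_hash, spatial_outputs, False, t0)

    # ---- survival ----------------------------------------------------
    t0 = time.monotonic()
    surv_dir = out / "survival"
    surv_hash = _hash_obj({"tfe": tfe_hash})
    surv_outputs = [surv_dir / "km.json"]
    if stage_should_run("survival", surv_hash, surv_outputs):
        upstream_ran = True
        surv_dir.mkdir(exist_ok=True)
        clinical = pd.read_csv(clinical_path)
        tfe_labels = pd.read_csv(tfe_path, index_col=0)["tfe"]
        fit = survival_fit(clinical, tfe_labels)
        _dump_json(
            surv_dir / "km.json",
            {
                "groups": fit.groups,
                "logrank_statistic": fit.statistic,
                "df": fit.df,
                "p_value": fit.p_value,
            },
        )
        record("survival", surv_hash, surv_outputs, True, t0)
    else:
        record("survival", surv_hash, surv_outputs, False, t0)

    return finalize()
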