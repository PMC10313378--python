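# frcscape

Quantitative analysis of the fibroblastic reticular cell (FRC) network and
CD8⁺ tumor-infiltrating lymphocyte (TIL) microenvironments in lymph-node
imaging mass cytometry (IMC) data.

In diffuse large B-cell lymphoma (DLBCL), the lymph-node stroma is
extensively remodeled: the PDPN⁺CD31⁻ FRC network stretches and loosens,
FRCs aberrantly express PD-1 ligands, and CD8⁺ TILs span a spectrum from
nonactivated to terminally exhausted states. `frcscape` provides a
reproducible pipeline for the image-derived readouts of that biology, for
computational pathologists and tumor-immunology groups working with
multiplexed tissue imaging:

1. **Stroma mapping** — per-pixel classification into FRC (PDPN⁺CD31⁻),
   LEC (PDPN⁺CD31⁺), BEC (PDPN⁻CD31⁺) and background; compartment area
   fractions; FRC-restricted marker statistics (e.g. FAP⁺ FRC fraction,
   PD-L1/PD-L2 pixel intensity).
2. **Network morphometry** — skeletonization of the FRC mask into a
   branch/junction graph; greedy maximal-inscribed-circle gap analysis;
   per-fiber shape features and k-means morphology classes (c15–c18).
3. **CD8⁺ TIL phenotyping** — per-cell quantification from label masks
   (circularity = 4πA/P², cells/mm²), arcsinh normalization, PhenoGraph-style
   kNN/Leiden clustering on PD-1, LAG-3, TIM-3, PD-L1, PD-L2 and GrB
   (clusters c1–c10), and rule-based identity assignment (nonactivated,
   progenitor exhausted, cytotoxic, terminally exhausted).
4. **TIL–FRC environments (TFEs)** — per-sample frequency matrix over
   clusters c1–c18 (CD8 phenotypes, FRC PD-1-ligand gates c11–c14, fiber
   shapes c15–c18), column z-scoring, Ward hierarchical clustering with
   silhouette-based selection of the group count; TFE1 is always the most
   exhausted-enriched group.
5. **Spatial statistics** — Euclidean-distance-transform distances from
   each CD8 centroid to the FRC mask, per-(cluster × TFE) distance
   profiles, contact fractions, and the >10 μm "uncoupling" flag.
6. **Survival** — Kaplan–Meier estimation per TFE with the log-rank
   (Mantel–Cox) test; Mann–Whitney *U* (exact for small samples) and
   one-way ANOVA + Tukey HSD for group comparisons.

A first-class **synthetic-data generator** (`frcscape.synthetic`) emulates a
TMA-like cohort — a random-walk fiber network with a known ground-truth
skeleton graph, endothelial structures, CD8 cells drawn from phenotype
archetypes, coupled/uncoupled cell placement, four environment archetypes,
and per-environment exponential survival — so the entire pipeline is
testable end-to-end without any imaging data.

## Worked example

```python
from frcscape.synthetic import CohortConfig, generate_cohort
from frcscape.pipeline import analyze_cohort

cfg = CohortConfig(n_samples=80, seed=7)      # 2 cores per sample
bundle = generate_cohort(cfg)
res = analyze_cohort(bundle, seed=7)

print("selected k:", res.assignment.k)
print("group sizes:", res.assignment.labels.value_counts().to_dict())
print("uncoupled (>10 um):", {k: bool(v) for k, v in res.uncoupled.items()})
print("KM medians (months):",
      {g: round(v["median"], 1) for g, v in res.survival.groups.items()})
print(f"log-rank: chi2={res.survival.statistic:.1f}, df={res.survival.df}, "
      f"p={res.survival.p_value:.2e}")
```

Output:

```
selected k: 4
group sizes: {'TFE1': 20, 'TFE2': 20, 'TFE3': 20, 'TFE4': 20}
uncoupled (>10 um): {'TFE1': True, 'TFE2': False, 'TFE3': False, 'TFE4': False}
KM medians (months): {'TFE1': 7.0, 'TFE2': 17.2, 'TFE3': 20.0, 'TFE4': 16.5}
log-rank: chi2=12.7, df=3, p=5.35e-03
```

Silhouette selection recovers the four planted environments with 20 samples
each. Only TFE1 — the exhausted-enriched environment generated in uncoupled
placement mode — exceeds the 10 μm mean CD8-to-network distance, and it has
the shortest median overall survival; the log-rank test separates the four
survival curves. (At 20 patients per group the medians of the intermediate
groups are noisy; the ordering sharpens with cohort size.)

The same analysis runs from the shell on rendered TIFF cores:

```bash
frcscape run-all --config config.yaml --out results/ --seed 7
```

with subcommands `simulate`, `stroma`, `morphometry`, `phenotype`, `tfe`,
`spatial`, `survival` for the individual stages. Re-running skips stages
whose inputs are unchanged (content-hash manifest); deleting a stage output
recomputes it and its descendants.

## Layout

```
src/frcscape/
  synthetic.py     seeded generators (networks, cores, cohorts)
  io.py            TIFF/CSV/YAML readers and writers, panels
  stroma.py        pixel classification and area/intensity stats
  morphometry.py   skeleton graph, gap circles, fiber shapes
  phenotyping.py   cell quantification, clustering, identities
  tfe.py           frequency matrix, z-scores, TFE clustering
  spatial.py       distance-to-network analysis
  stats.py         KM/log-rank, Mann-Whitney, ANOVA/Tukey
  pipeline.py      cohort analysis and the staged disk pipeline
  cli.py           `frcscape` command-line interface
docs/methods.md    model and parameter documentation
tests/             pytest suite (unit, property, end-to-end)
```
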