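# Methods

This note documents the models, algorithms, defaults and known limitations
of `frcscape`. It covers what each stage computes, why the defaults are
what they are, and what the synthetic-data generator does and does not
emulate.

## Stromal pixel classification

Pixels are gated on two channels after Gaussian smoothing at σ = 0.7 px
(about a 1-pixel FWHM window): PDPN⁺CD31⁻ → FRC, PDPN⁺CD31⁺ → LEC,
PDPN⁻CD31⁺ → BEC, else background. Thresholds default to per-channel Otsu;
fixed thresholds can be supplied through the config for gating consistency
across cohorts. Pixels exactly at a threshold count as positive, so the
rule is deterministic. σ = 0.7 px was chosen because heavier smoothing
(σ = 1 px) visibly halos 3-px-wide fibers and drops FRC precision below
0.9 against the synthetic ground truth, while σ = 0.7 keeps both recall
and precision above 0.97. The classification depends only on marker names,
never on channel order.

Area fractions are reported over the full field by default (per-core
denominators are the convention for TMA dot plots) or over a supplied
tissue mask. "FAP⁺ FRC frequency" and the PD-1-ligand statistics are
computed over FRC-class pixels; requesting them on a map with no FRC
pixels is an error rather than a silent zero.

## Network morphometry

**Skeleton graph.** The FRC mask is thinned to a 1-px skeleton
(8-connected morphological skeletonization). Endpoint pixels (1 neighbor)
and junction pixels (≥3 neighbors) become graph nodes — adjacent node
pixels are merged into one node — and the degree-2 runs between them
become edges with geodesic length (diagonal step = √2 px, scaled by the
pixel size). Spurs shorter than 3 μm terminating at an endpoint are pruned
iteratively and the raster re-thinned; such spurs are rasterization
artifacts of fiber-width rendering, not biology. Isolated cycles with no
node pixel are represented as a single self-edge. A branch is an edge of
this graph; branch count, mean branch length and junction count are the
per-field statistics.

**Gap analysis.** The background distance transform (fibers *and* the
field border as obstacles, implemented by padding with a foreground ring)
is maximized greedily: the largest inscribed circle is extracted, its disk
becomes an obstacle, and the transform is recomputed until the radius
falls below `min_radius_um` (default 5 μm) or `max_circles` (default 200)
is reached. Circles therefore never overlap and radii are non-increasing.
Because greedy packing subdivides leftover space down to the minimum
radius, summary medians compress toward that minimum; comparisons across
conditions are most sensitive in the large-radius tail (the tests average
medians over seeds when sweeping generator density).

**Fiber shapes.** Per connected component: area, major/minor axis lengths
from second moments, elongation = minor/major ∈ (0, 1], and
branch/endpoint counts and skeleton length of the component's own
skeleton. Components under 9 px are ignored as speckle. Shape classes
c15–c18 come from k-means (k = 4, fixed seed, standardized features),
relabeled by ascending mean elongation so c15 is always the most
elongated-simple class; with fewer components than k the classes fall
back to elongation quantile bins with a logged warning.

## Cell quantification and CD8 phenotyping

Cells are read from 16-bit label masks (0 = background, labels need not be
contiguous). Per cell: mean intensity per channel, area (pixel count ×
pixel size²), perimeter, and circularity 4πA/P². The perimeter estimator
is the mean of the 4-direction Crofton estimate and the marching-squares
contour length: Crofton is biased low on rectilinear shapes and the
contour length is biased high, and their mean is accurate for both disks
(circularity ≈ 0.95–1.0) and squares (within 0.07 of the analytic π/4).
A cell is classed CD8 when its mean CD8-channel intensity reaches the
class threshold (default 2.0, between the synthetic background ≈0.2 and
cell signal ≈8).

Marker normalization is the cytometry convention: arcsinh(x/5) followed by
a per-marker 1st–99th percentile rescale to [0, 1] (zero-variance markers
map to 0; the transform is monotone).

Clustering is PhenoGraph-style: a k-nearest-neighbour graph (Euclidean,
k = 30 by default) with edges reweighted by neighbourhood Jaccard overlap,
then Leiden modularity optimisation with a fixed seed. Cells are first
sorted into a canonical (lexicographic) order so the partition is
invariant to input row order; labels c1…cK are renumbered by descending
cluster size. Communities beyond 10 are merged into their nearest
neighbour by centroid distance so the label space stays within the c1–c10
block of the frequency matrix; on data with four planted archetypes this
merging only rejoins fragments of the same archetype.

Identity assignment operates on the heatmap matrix (per-cluster marker
medians, min–max rescaled per marker across clusters). With ckpt = mean of
the five checkpoint medians and GrB the granzyme-B median, rules apply in
precedence order: both ≥ 0.65 → terminally exhausted; both < 0.35 →
nonactivated; ckpt ≥ GrB + 0.1 → progenitor exhausted; GrB ≥ ckpt + 0.1 →
cytotoxic; else indeterminate (logged). The thresholds are declared
constants on the normalized scale chosen to split it into clear low/high
bands with a tie margin; identities are scale-free because the
normalization chain absorbs any global intensity factor.

FRC PD-1-ligand classes c11–c14 are the 2×2 PD-L1/PD-L2 positivity gates
(−/−, +/−, −/+, +/+), with per-marker Otsu thresholds by default. From
images, the gated units are connected components of the FRC mask; in the
cohort tables mode they are the generator's FRC object records.

## TFE discovery

The per-sample frequency matrix concatenates three blocks — CD8 cluster
fractions (c1–c10), ligand-gate fractions (c11–c14), shape-class fractions
(c15–c18) — computed per core and averaged across a sample's cores
(equal weight per core). Samples with an empty block are imputed with the
uniform distribution and flagged. Columns are z-scored across samples
(zero-variance columns set to 0), and samples are clustered with Ward
linkage on Euclidean distances. The number of environments k is selected
by maximum mean silhouette over k = 2…8 unless fixed. Group ids are
renumbered by descending group mean of the per-sample *total*
exhausted-cluster frequency (the summed frequencies of clusters whose
identity is progenitor- or terminally-exhausted), so TFE1 is always the
most exhausted-enriched group. The scalar ordering statistic is used
rather than the mean of per-column z-scores because the latter overweights
whichever identity happens to split into more clusters.

## Spatial analysis

Distances are measured from each CD8 centroid to the nearest FRC-mask
pixel via the Euclidean distance transform of the mask complement, scaled
to μm — the full mask, not the skeleton, since interaction distance is to
the fiber surface as rendered. The (cluster × TFE) profile is the mean
per-cell distance per combination; empty combinations stay NaN. The
contact fraction uses a 5 μm default threshold, and a TFE is flagged
"uncoupled" when its cell-weighted mean distance exceeds 10 μm. The
centroid-to-nearest-pixel metric slightly overstates boundary-to-boundary
distances by the cell radius (3–5 px in the generator); the 10 μm cutoff
applies to the centroid metric.

## Statistics

Kaplan–Meier curves and the k-group log-rank (Mantel–Cox) test come from
lifelines. Mann–Whitney *U* is exact by full enumeration of group splits
when both samples have ≤ 8 observations (the two-sided p counts splits at
least as extreme in |U − nm/2|), otherwise the normal approximation with
midrank tie correction. One-way ANOVA uses the pooled-variance F test with
Tukey HSD pairwise comparisons. Under the null, all three tests hold a
5% type-I error within [0.03, 0.07] over 2,000 seeded repetitions (tested).

## The synthetic-data generator

The generator's defaults define the study conditions the tests and the
acceptance script run under.

**Fiber network.** Fiber trees are seeded uniformly at a density of 2
trees per 100×100 μm and grown as random walks (step 2 px, heading jitter
σ = 0.18 rad) with a per-step branching probability of 0.05 and a total
length budget of ~60 μm per tree; polylines are rasterized at 3 px width.
The pre-raster polyline graph is the ground truth (branch = segment
between branch points/ends). Crossings between independently grown fibers
create junctions in the raster that the generative graph does not know
about; the defaults keep generative branches dominant so measured branch
counts stay within ±15% of truth. A "circular" shape bias shortens walks
to 45% and adds compact blobs, emulating less-stretched FRC morphology.

**Cells.** CD8 cells are disks (radius 3–5 px) with per-cell functional
marker intensities drawn lognormally around one of four archetype profiles
(arbitrary units): nonactivated = checkpoints 1.0 / GrB 1.0; progenitor
exhausted = 8.0 / 1.5; cytotoxic = 1.5 / 9.0; terminally exhausted =
9.0 / 8.0, all with 30% coefficient of variation. These are invented
fixture constants reproducing the qualitative lo/hi heatmap pattern of the
four states — no numeric intensities are reported for the real cohort.
Coupled placement samples a network pixel plus N(0, 1.5 px) jitter (10%
uniform background); uncoupled placement rejection-samples until the EDT
distance is ≥ the clearance, enforcing the constraint exactly or raising
an error.

**Environments.** Four archetypes with phenotype weight vectors
(nonactivated, progenitor, cytotoxic, terminal):
TFE1 (0.05, 0.35, 0.10, 0.50), uncoupled at 12 μm clearance, ligand level
0.30; TFE2 (0.15, 0.60, 0.05, 0.20), ligand 0.80; TFE3
(0.65, 0.15, 0.12, 0.08), circular fibers, ligand 0.10; TFE4
(0.20, 0.08, 0.65, 0.07), ligand 0.40. Only the qualitative contrasts are
reported for the real cohort; the numeric weights are fixture constants
chosen so between-archetype separation exceeds four times the default
mixing noise (sd 0.05), the regime in which silhouette selection is
expected to recover the planted group count. Per-sample weights are the
archetype weights plus Gaussian jitter (renormalized), shared by the
sample's cores (default 2), which are otherwise independent draws.

**Survival.** Overall-survival times are exponential with per-archetype
hazards 0.12, 0.06, 0.05, 0.03 /month (TFE1:TFE4 hazard ratio 4, TFE2/3
intermediate — only the ordering is a reported fact). Censoring is
uniform: with probability `censor_fraction` (default 0.2) a subject is
censored at a Uniform(0, T) fraction of its event time. These hazards give
the TFE1 < {TFE2, TFE3} < TFE4 median ordering in ≥ 90% of seeds at 50
patients per group.

**What the generator does not emulate.** No IMC noise physics (channel
spillover, isotope impurity, hot pixels), no 3D tissue structure, no
B-cell/tumor compartment beyond a diffuse background channel, no
cell-shape diversity beyond disks, and no correlation between a sample's
stromal morphology and its survival other than through the archetype. A
pipeline that passes these tests is validated for its algorithmic
contracts (recovery of planted structure, oracle equivalence, calibration),
not for robustness to real IMC artifacts.

## Problem sizes

The test suite and acceptance script use desk-scale cohorts chosen as the
smallest sizes at which the statistical claims are stable: 80 samples
(2 cores, 150 CD8 cells/core, 256² px) for environment-count recovery;
a single 512² px core with 300 cells for the uncoupling bound; 50 patients
per environment for survival separation; 16-sample cohorts across 50 seeds
for the recovery-ARI average; 2,000 cells for identity recovery; 2,000
repetitions for test calibration.

## Known limitations

* Skeleton-graph branch statistics depend on rasterization width; very
  short inter-junction runs (< spur length) are merged.
* Greedy gap packing is deterministic but not the unique maximal packing;
  radii near ties can reorder under 90° rotation (tests allow 1 px).
* Leiden modularity on large homogeneous populations can split one
  archetype into several communities; identity assignment reunifies them
  at the phenotype level, and the c1–c10 cap merges fragments for the
  frequency matrix.
* The exact Mann–Whitney enumeration is O(C(n+m, n)) and limited to
  n, m ≤ 8; beyond that the tie-corrected normal approximation applies.
* k selection by silhouette assumes compact, comparably sized groups; for
  strongly nested structure a fixed k (as the config allows) is the safer
  choice.
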