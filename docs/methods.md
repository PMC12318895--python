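# Methods

This note documents the models and procedures implemented in `gcspatial`,
the assumptions behind them, the parameters that matter, and what the
synthetic test-bench does and does not establish about real imaging data.

## The cell table

All analyses operate on a table of segmented cells: 2D centroids in μm
(3D surfaces projected to the imaging plane — every downstream statistic
uses only Euclidean distances and areas, so the origin and axis orientation
are irrelevant), volume (μm³), sphericity (0–1], and per-marker mean voxel
intensities in arbitrary fluorescence units, with optional per-marker
medians. Population labels are a *set* per cell because gates are
hierarchical: a follicular helper T cell is simultaneously `CD3hi`, `TFH`
and, say, `TFH_CD57hi`.

## Filtering

**Uniform-staining artefacts.** Debris, tissue folds and edge artefacts
stain uniformly across a segmented surface, so their mean and median voxel
intensities coincide; genuine cells stain heterogeneously (membranous,
punctate or nuclear patterns) and mean > median for right-skewed intensity
distributions. A cell is removed when, in at least `m_channels` (default 4)
markers with mean intensity ≥ `min_level` (default 10), the relative
mean–median difference is ≤ `epsilon` (default 0.05). The exact rule any
given imaging lab applies is a judgement call made per dataset; this
implementation is one consistent, configurable reading of mean/median-based
filtering. Both thresholds should be tuned on the negative controls of the
actual assay.

**Geometry.** Events outside a plausible cell volume window
(default 50–4000 μm³) or below a sphericity floor (default 0.3) are removed
as non-cell events — the same logic used to clean in-situ-hybridisation
channels before counting cytokine-positive cells.

Both filters partition their input and are idempotent.

## Threshold derivation and gating

Fluorescence intensities are right-skewed, so hi/lo cut-offs are derived on
log1p intensities. The default method fits a two-component Gaussian mixture
(scikit-learn, fixed seed, 3 initialisations) and places the threshold at
the equal-responsibility point between the component means; a `valley`
alternative takes the KDE minimum between the two largest modes. A
threshold is flagged *unreliable* (and parked at the 99th percentile) when
either (a) the component means are closer than half the pooled component
standard deviation, or (b) the mixture density at the proposed cut rivals
(> 0.8×) the smaller component peak — the latter check catches unimodal
distributions that a 2-component fit happily splits into two overlapping
halves. Derived thresholds are suggestions: thresholds set explicitly in a
gate tree always win, mirroring inspection-driven manual gating.

Gating walks a tree of hi/lo splits (`hi` is ≥ threshold, closed; `lo` is <,
open — a fixed tie-break). A cell receives the population name of every
node whose root-to-node conditions all hold, so child labels imply parent
labels and raising a hi-threshold can only shrink a population.

`CD20^hi/dim` B cells are treated as one gate with the threshold at the
dim/negative boundary, because the dim shoulder largely reflects spillover
of B-cell signal into T cells conjugated to B cells and belongs with the
B/T-interaction biology rather than with the negative population.

## Follicle ROI detection

Follicles are the regions where B cells pack densely. The implementation
histograms B-cell coordinates on a grid of step = bandwidth/2, smooths with
a Gaussian of sd `kde_bandwidth_um`, thresholds at `density_threshold_frac`
× the density maximum, polygonises the outer contour of each connected
super-threshold component, merges overlapping polygons, and keeps
components containing ≥ `min_b_cells` B cells (default 20). IDs F0, F1, …
follow decreasing area.

Defaults (bandwidth 30 μm, threshold fraction 0.2) were calibrated once on
the generator's planted-disc scenario: this pairing recovers disc areas
within ±25% while keeping the dense follicle rim inside the contour
(cell-level compartment assignment ≥ 95%). A higher threshold shrinks the
contour into the rim; a wider bandwidth inflates the area. Both are exposed
in the config and should be re-examined for follicles much smaller than
~150 μm radius. Zonated follicles (B density higher in the GC than the
mantle) bias the max-referenced threshold upward; detection there is still
reliable but the contour can clip the outermost mantle zone.

Compartment assignment is boundary-inclusive point-in-polygon; relative
radial position is ρ = |cell − centroid| / |boundary∩ray − centroid| along
the centroid→cell ray (0 at the centroid, 1 on the boundary; for
non-convex, star-shaped boundaries the farthest ray crossing is used).

## Nearest-neighbour spatial statistics

For a subset with n cells in a follicle ROI of area A, the intensity is
λ = n/A and the CSR reference for nearest-neighbour distances is
G(d) = 1 − exp(−λπd²). The empirical G is the NN-distance CDF; the
**dispersion score** is the trapezoidal ∫(G_theo − G_emp) dd over a grid of
`distance_grid_n` (default 200) points from 0 to d_max (default: the
distance at which both curves pass 0.999, capped at the ROI diameter).
Sign convention: theoretical minus empirical, so clustered patterns
(short NN distances) score negative and regular/hard-core patterns positive.
The score has units of μm and scales linearly under uniform spatial
rescaling.

For two subsets, the per-source-cell minima over targets give the
cross-distance profile; its **cross-G** is compared with the independence
null 1 − exp(−λ_target πd²). Two scalars are reported: the signed area
(negative = attraction, positive = avoidance) and the absolute deviation
∫|emp − theo| dd, a non-directional distance from complete spatial
randomness. Which of the two a given "randomness" axis in a downstream plot
should use is a presentation choice; both are always computed.

Edge correction (reduced-sample/border method: at grid distance d only
cells ≥ d from the ROI boundary contribute) is available for both curves
and is what makes the CSR null unbiased; it is OFF by default to match the
naive estimator commonly used in practice, and ON in every null-calibration
analysis here. Follicles contribute only when every subset involved has at
least `min_cells_per_subset` (default 20) cells; under-populated follicles
are skipped with a logged reason, not an error.

λ is estimated from the follicle polygon area, not from a convex hull of
the subset, because the follicle is the biological analysis unit.

## Batch clustering

Per-tissue z-scoring ((x − mean)/sd, population sd) removes affine
per-tissue batch effects (gain and offset) on each marker exactly, which is
the stated purpose of the batch step; a global mode exists because scaling
once on the concatenated matrix is an equally defensible reading and the
two differ only when tissues truly differ in composition. Coordinates,
volume and sphericity are never normalised. Equal-n downsampling (uniform,
without replacement, seeded; tissues below n are excluded with a logged
reason) gives every tissue the same weight in the clustering.

The SOM is a full-batch implementation: the codebook initialises on the
plane of the first two principal components (SVD with a deterministic sign
convention), and each of `epochs` (default 20) iterations reassigns cells
to best-matching nodes and recomputes each node as the Gaussian-
neighbourhood-weighted mean, the neighbourhood radius decaying linearly
from max(grid)/2 to 0.5. This differs from the classical online SOM with
random initialisation on purpose: it is deterministic given (data, seed),
and at this scale (10×10 nodes, thousands of cells) batch training with PCA
initialisation has the same recovery power. Metaclustering is plain
average-linkage agglomerative clustering of the 100 codebook vectors cut at
k (default 8) — again a deterministic simplification of consensus
hierarchical metaclustering. Metaclusters are renumbered P0..P(k−1) by
decreasing assigned-cell count, and the tissues × metaclusters count matrix
(rows summing to the per-tissue n) is the final output, log1p-transformed
for heatmap display on request. t-SNE-style embeddings are deliberately out
of scope; the normalised concatenated matrix is exposed for any external
embedding tool.

## Inference

All tests are two-sided at α = 0.05. Mann–Whitney U uses the exact
permutation distribution when the combined sample has ≤ 12 observations
without ties, Wilcoxon signed-rank when ≤ 15 nonzero differences without
tied magnitudes (zeros dropped, W = smaller signed-rank sum); larger or
tied samples use the normal approximation with tie and continuity
corrections. The cutoffs keep enumeration sub-second and are configurable —
note the continuity-corrected approximation is conservative (empirical
type-I ≈ 0.037 at n = 8 vs 8, against 0.0499 for the exact test), so
calibration studies at that size should pass `exact_max_n=16`. Pearson's r
takes its p from the t distribution on n − 2 df. No multiple-testing
correction is applied by default (per-comparison reporting); a
Benjamini–Hochberg helper exists.

## The synthetic tissue generator

`TissueSpec` describes a rectangular section with circular follicles.
Geometry is deliberately minimal but testable: follicle = mantle-zone
annulus around a GC disc (radius `gc_radius_frac`·R, default 0.6); a chord
splits the GC into dark and light zones with the DZ holding `dz_fraction`
of its area; the GC-boundary band is the annulus from 0.8·GC-radius to the
GC edge; "DZ-core" (the DZ half within 0.75·GC-radius) realises a
DZ-adjacent GC core for planting CD57^hi T_FH. Subsets are placed per zone
under CSR, Thomas (Gaussian offspring around CSR parents) or hard-core
(dart-throwing with a minimum distance, failing loudly when the packing
bound makes placement infeasible) processes, with exact per-follicle counts
by default so count assertions are exact.

Marker intensities are log-normal: hi ~ exp(N(μ_hi, σ)), lo ~ exp(N(μ_lo,
σ)) with defaults μ_hi = 3, μ_lo = 1, σ = 0.4 (a 5σ separation in log
space — comfortably beyond the 2σ needed for < 5% mixture-threshold
misclassification). Medians are planted at 0.55–0.80 of the mean for real
cells (right-skewed staining) and within ±2% for artefact cells, which also
stain high in all channels; debris events get sub-cellular volumes and low
sphericity. Per-tissue batch effects are affine (I → g·I + b, gains 0.7–1.4,
offsets 0–5 in the cohort scenarios). Everything is a pure function of
(spec, seed).

The clustering scenarios plant 8 phenotype clusters as one-hot hi codes
over 8 markers on a shared CD3/CD4/PD1-hi base, with σ = 0.2 so cluster
centres sit ≥ ~6 within-cluster sd apart on the raw intensity scale — the
separation regime assumed by the recovery analyses; enrichment cohorts
raise one cluster's proportion 3× in half the tissues.

**What the generator does not emulate:** optical spillover between
channels, spatially varying background, irregular (non-circular,
non-simply-connected) follicle shapes, 3D distance structure, cell-size-
dependent intensity, and segmentation errors other than the two planted
artefact classes. Passing tests therefore establish the correctness and
calibration of the *algorithms* under their stated models, not the
robustness of any particular biological conclusion to real-world imaging
pathology.

## Simulation sizes

The test suite runs the study conditions at full size: 100 random instances
(≤ 500 points) for brute-force oracle equivalence; 200 CSR simulations
(n = 300 in a 300 μm-radius disc, border-corrected) for the dispersion and
cross-G null calibrations; 100 replicates per process for the
Thomas < CSR < hard-core ordering (rank test p < 0.01 per adjacent pair);
50 single-follicle tissues for the DZ-B→T_FH distance comparison; 50 seeds
for follicle detection; 4 tissues × 2200 cells for metacluster recovery;
100 pipeline replicates (8 tissues, 1000 cells downsampled each) for
enrichment-detection power; 10 000 null replicates for the Mann–Whitney
type-I error. `scripts/acceptance.py` recomputes the same metrics with 20
detection seeds, 100 spatial replicates, 30 distance follicles, 30 power
replicates and 3000 type-I replicates, which keeps a full run around half a
minute on one CPU.

## Known limitations

- ROI detection assumes simply-connected follicles; a follicle with a
  density hole is returned by its outer contour.
- The max-referenced density threshold couples detection to the brightest
  follicle in the field; fields mixing very dense and very sparse follicles
  may need a lower `density_threshold_frac`.
- The cross-G independence null conditions on the observed target count;
  it does not model inhomogeneous target intensity within the follicle.
- Exact inference switches to approximations in the presence of ties;
  heavily tied count data at small n get conservative p-values.
- Relative radial position is well-defined only for boundaries star-shaped
  around their centroid.
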