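# gcspatial

Histocytometry-style analysis of segmented-cell tables from multiplex
immunofluorescence (mIF) imaging of human lymphoid tissue: tonsils and
reactive lymph nodes, their B-cell follicles and germinal centres (GC), and
the follicular T-cell subsets that organise them.

After 3D surface segmentation, an mIF experiment reduces to a table — one
row per cell with centroid coordinates (μm), volume, sphericity and mean
(plus median) voxel intensity per marker. `gcspatial` takes it from there:

1. **Filtering** — removes uniform-staining artefacts (events whose mean and
   median intensities agree across several channels) and non-cell debris
   (volume/sphericity bounds).
2. **Gating** — derives hi/lo intensity cut-offs from two-component Gaussian
   mixtures on log intensity (or a KDE valley), then applies a hierarchical
   gate tree to label populations such as `CD20^hi/dim` B cells,
   `CD3^hi PD1^hi` T_FH cells and their CD57^hi / CXCR3^hi subsets, or
   Ki67/Bcl6-defined mantle-zone, dark-zone (DZ) and light-zone (LZ) B cells.
3. **Follicle geometry** — detects follicular regions of interest from the
   kernel density of B-cell coordinates, assigns every cell to the
   follicular (F) or extrafollicular (EF) compartment, and computes relative
   radial positions within a follicle.
4. **Spatial statistics** — per follicle:
   - Ripley's G function (the CDF of nearest-neighbour distances) against
     the theoretical Poisson curve G(d) = 1 − exp(−λπd²); the signed area
     ∫(G_theo − G_emp) dd is a *dispersion score*: negative = clustered,
     positive = dispersed/regular relative to complete spatial randomness;
   - per-source-cell minimum Euclidean distances to a second subset (e.g.
     GC B cell → T_FH), their exact median, and the cross-G function of
     those minima against the independence null, summarised as a signed
     area (attraction < 0 < avoidance) and an absolute deviation
     (distance-profile randomness);
   - follicles enter an analysis only with ≥ 20 cells of each subset.
5. **Batch clustering** — per-tissue z-score normalisation, equal-n random
   downsampling and concatenation (e.g. 2200 T_FH cells per tissue), a
   deterministic 10×10 batch SOM with PCA-plane initialisation, and
   average-linkage metaclustering of the codebook into k = 8 phenotype
   metaclusters P0..P7 (numbered by decreasing prevalence), with per-tissue
   count matrices (optionally log1p-transformed for heatmaps).
6. **Inference** — two-sided Mann–Whitney, Wilcoxon signed-rank (exact by
   enumeration for small samples) and Pearson correlation.

A first-class synthetic-tissue generator (`gcspatial.synthetic`,
`gcspatial.scenarios`) plants follicles with MZ/DZ/LZ zonation, subsets
under CSR / Thomas-clustered / hard-core point processes, log-normal hi/lo
marker mixtures, per-tissue affine batch effects, artefacts and debris —
with full ground truth — so every stage of the pipeline is testable without
any imaging data.

## Worked example

```python
from gcspatial.scenarios import basic_tissue_spec, default_gate_tree, GATE_MARKERS
from gcspatial.synthetic import simulate_tissue
from gcspatial.gating import filter_artefacts, derive_thresholds, apply_gates
from gcspatial.config import ArtefactFilterParams, SpatialParams
from gcspatial.follicles import detect_follicles, assign_compartment
from gcspatial.spatial import follicle_spatial_analysis

table, truth = simulate_tissue(basic_tissue_spec(seed=1, artefact_fraction=0.1))
kept, removed = filter_artefacts(table, ArtefactFilterParams())
tree = default_gate_tree()
tree.fill_thresholds(derive_thresholds(kept, GATE_MARKERS, seed=0))
labelled = apply_gates(kept, tree)
rois = detect_follicles(labelled.subset("B"))
labelled = assign_compartment(labelled, rois)
res = follicle_spatial_analysis(
    labelled, rois,
    pairs=[("B_DZ", "TFH_CD57hi"), ("B_DZ", "TFH_CXCR3hi")],
    subsets_for_dispersion=["B_DZ"],
    params=SpatialParams(edge_correction=True))
print(res.to_string(index=False))
```

This simulates one tonsil-like tissue (1375 cells, 14 markers), removes the
125 planted uniform-staining artefacts, gates 785 B cells and 156 T_FH
cells, detects the 2 planted follicles (≈ 118 000 and 116 000 μm²), and
prints, per follicle:

```
follicle_id              analysis subset      target   n  value_um
         F0            dispersion   B_DZ             119 -7.383174
         F0   median_min_distance   B_DZ  TFH_CD57hi 119 18.030717
         F0   cross_g_signed_area   B_DZ  TFH_CD57hi 119 -7.284842
         F0 cross_g_abs_deviation   B_DZ  TFH_CD57hi 119  7.286818
         F0   median_min_distance   B_DZ TFH_CXCR3hi 119 28.948508
         F0   cross_g_signed_area   B_DZ TFH_CXCR3hi 119  6.666704
         F0 cross_g_abs_deviation   B_DZ TFH_CXCR3hi 119 10.546115
         ...
```

Reading the numbers: DZ B cells are clustered within the follicle
(dispersion −7.4 μm, i.e. nearest neighbours closer than a Poisson pattern
of the same intensity); they sit a median of 18 μm from the CD57^hi T_FH
subset planted in the GC core near the DZ but 29 μm from the CXCR3^hi
subset planted in the GC boundary band; the cross-G signed areas show
attraction to the former (−7.3 μm) and avoidance of the latter (+6.7 μm).

The same pipeline is scriptable from the shell:

```sh
gcspatial validate tissue.csv --config cfg.yaml
gcspatial gate tissue.csv --config cfg.yaml --out labelled.csv
gcspatial follicles labelled.csv --b-label B --out follicles.geojson --assign assigned.csv
gcspatial spatial assigned.csv --follicles follicles.geojson \
    --pairs "B_DZ:TFH_CD57hi,B_DZ:TFH_CXCR3hi" --out spatial.csv
gcspatial cluster assigned.csv --population TFH --n 2200 --grid 10x10 --k 8 \
    --seed 7 --out clusters.csv --prevalence prevalence.csv
gcspatial compare spatial.csv --test mann-whitney --group-col organ --value-col value_um
```

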