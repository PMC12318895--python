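"""Canonical synthetic study conditions.

Builders for the tissue configurations the test-bench exercises end to end:
a gateable B/T-cell tissue with MZ/DZ/LZ zonation, the single-follicle
geometry with CD57hi T_FH in the DZ-adjacent GC core versus CXCR3hi T_FH in
the GC boundary band, and batch-effect-laden multi-tissue cohorts with
planted T_FH phenotype clusters for SOM metaclustering.
"""

from __future__ import annotations

import numpy as np

from .synthetic import (CSR, FollicleSpec, MarkerModel, SubsetSpec, TissueSpec)

PANEL_MARKERS = ["CD20", "CD3", "CD4", "CD8", "PD1", "CD57", "CXCR3",
                 "TIGIT", "Bcl6", "Ki67", "TCF1", "GrzB", "CD25", "FOXP3"]

#: markers carrying the one-hot phenotype codes in the clustering scenarios
PHENOTYPE_CODE_MARKERS = ["CD57", "CXCR3", "TIGIT", "Bcl6", "Ki67", "TCF1", "GrzB", "CD25"]


def default_panel(mu_hi: float = 3.0, mu_lo: float = 1.0, sigma: float = 0.4):
    """Log-normal hi/lo models for the full marker panel (separation 5σ)."""
    return {m: MarkerModel(mu_hi=mu_hi, mu_lo=mu_lo, sigma=sigma) for m in PANEL_MARKERS}


def _levels(hi_markers: list[str]) -> dict[str, str]:
    return {m: ("hi" if m in hi_markers else "lo") for m in PANEL_MARKERS}


# population -> markers expressed hi
POPULATION_PROFILES = {
    "B_MZ": ["CD20"],
    "B_DZ": ["CD20", "Ki67", "Bcl6"],
    "B_LZ": ["CD20", "Bcl6"],
    "TFH_CD57hi": ["CD3", "CD4", "PD1", "CD57", "Bcl6"],
    "TFH_CXCR3hi": ["CD3", "CD4", "PD1", "CXCR3", "TIGIT"],
    "CD8T": ["CD3", "CD8", "GrzB"],
    "EF_T": ["CD3", "CD4"],
}


def default_gate_tree():
    """Gate tree matching :data:`POPULATION_PROFILES`: B cells split by
    Ki67/Bcl6 into MZ/DZ/LZ; CD3hi cells into PD1hi T_FH (CD57hi vs CXCR3hi)
    and CD8 T cells.  Thresholds are left open for
    :func:`gcspatial.gating.derive_thresholds` / manual override."""
    from .gating import GateTree

    return GateTree.from_dict([
        {"marker": "CD20", "direction": "hi", "population": "B", "children": [
            {"marker": "CD3", "direction": "lo", "children": [
                {"marker": "Ki67", "direction": "hi", "children": [
                    {"marker": "Bcl6", "direction": "hi", "population": "B_DZ"}]},
                {"marker": "Ki67", "direction": "lo", "children": [
                    {"marker": "Bcl6", "direction": "hi", "population": "B_LZ"},
                    {"marker": "Bcl6", "direction": "lo", "population": "B_MZ"}]}]}]},
        {"marker": "CD3", "direction": "hi", "population": "CD3hi", "children": [
            {"marker": "PD1", "direction": "hi", "children": [
                {"marker": "CD20", "direction": "lo", "population": "TFH", "children": [
                    {"marker": "CD57", "direction": "hi", "population": "TFH_CD57hi"},
                    {"marker": "CD57", "direction": "lo", "children": [
                        {"marker": "CXCR3", "direction": "hi",
                         "population": "TFH_CXCR3hi"}]}]}]},
            {"marker": "CD8", "direction": "hi", "children": [
                {"marker": "CD4", "direction": "lo", "population": "CD8T"}]}]},
    ])


GATE_MARKERS = ["CD20", "CD3", "CD4", "CD8", "PD1", "CD57", "CXCR3", "Ki67", "Bcl6"]


def basic_tissue_spec(tissue_id: str = "T0", seed: int = 0, *,
                      n_follicles: int = 2,
                      artefact_fraction: float = 0.0,
                      debris_fraction: float = 0.0,
                      cells_scale: float = 1.0) -> TissueSpec:
    """A gateable tissue: zonated B subsets, two T_FH subsets, follicular CD8
    T cells and extrafollicular CD4 T cells, in well-separated follicles."""
    centres = [(400.0, 400.0), (1100.0, 1100.0), (400.0, 1100.0), (1100.0, 400.0)]
    follicles = [FollicleSpec(centres[i], radius_um=220.0) for i in range(n_follicles)]

    def n(x):
        return max(1, int(round(x * cells_scale)))

    subsets = [
        SubsetSpec("B_MZ", n=n(150), zone="MZ", marker_model=_levels(POPULATION_PROFILES["B_MZ"])),
        SubsetSpec("B_DZ", n=n(120), zone="DZ", marker_model=_levels(POPULATION_PROFILES["B_DZ"])),
        SubsetSpec("B_LZ", n=n(120), zone="LZ", marker_model=_levels(POPULATION_PROFILES["B_LZ"])),
        SubsetSpec("TFH_CD57hi", n=n(40), zone="GC",
                   marker_model=_levels(POPULATION_PROFILES["TFH_CD57hi"])),
        SubsetSpec("TFH_CXCR3hi", n=n(40), zone="GC-boundary-band",
                   marker_model=_levels(POPULATION_PROFILES["TFH_CXCR3hi"])),
        SubsetSpec("CD8T", n=n(30), zone="whole-follicle",
                   marker_model=_levels(POPULATION_PROFILES["CD8T"])),
        SubsetSpec("EF_T", n=n(250), zone="extrafollicular",
                   marker_model=_levels(POPULATION_PROFILES["EF_T"])),
    ]
    return TissueSpec(tissue_id=tissue_id, width_um=1500.0, height_um=1500.0,
                      follicles=follicles, subsets=subsets, panel=default_panel(),
                      artefact_fraction=artefact_fraction,
                      debris_fraction=debris_fraction, seed=seed)


def uniform_follicle_spec(tissue_id: str = "T0", seed: int = 0, *,
                          n_follicles: int = 2, n_b_per_follicle: int = 220,
                          n_background: int = 60,
                          radius_um: float = 180.0) -> TissueSpec:
    """Well-separated follicle discs with uniform B-cell density plus sparse
    extrafollicular T cells — the geometry used to score follicle detection
    and compartment assignment against the planted discs."""
    centres = [(400.0, 400.0), (1100.0, 1100.0), (400.0, 1100.0), (1100.0, 400.0)]
    follicles = [FollicleSpec(centres[i], radius_um=radius_um) for i in range(n_follicles)]
    subsets = [
        SubsetSpec("B", n=n_b_per_follicle, zone="whole-follicle",
                   marker_model=_levels(POPULATION_PROFILES["B_MZ"])),
        SubsetSpec("EF_T", n=n_background, zone="extrafollicular",
                   marker_model=_levels(POPULATION_PROFILES["EF_T"])),
    ]
    return TissueSpec(tissue_id=tissue_id, width_um=1500.0, height_um=1500.0,
                      follicles=follicles, subsets=subsets, panel=default_panel(),
                      seed=seed)


def follicle_distance_spec(tissue_id: str = "T0", seed: int = 0, *,
                           n_dz_b: int = 80, n_lz_b: int = 80,
                           n_tfh: int = 25) -> TissueSpec:
    """Single follicle with CD57hi T_FH planted in the DZ-adjacent GC core and
    CXCR3hi T_FH in the GC boundary band — the geometry behind the
    DZ-B-to-T_FH minimum-distance comparison."""
    follicle = FollicleSpec((500.0, 500.0), radius_um=300.0, gc_radius_frac=0.65)
    subsets = [
        SubsetSpec("B_DZ", n=n_dz_b, zone="DZ", marker_model=_levels(POPULATION_PROFILES["B_DZ"])),
        SubsetSpec("B_LZ", n=n_lz_b, zone="LZ", marker_model=_levels(POPULATION_PROFILES["B_LZ"])),
        SubsetSpec("TFH_CD57hi", n=n_tfh, zone="DZ-core",
                   marker_model=_levels(POPULATION_PROFILES["TFH_CD57hi"])),
        SubsetSpec("TFH_CXCR3hi", n=n_tfh, zone="GC-boundary-band",
                   marker_model=_levels(POPULATION_PROFILES["TFH_CXCR3hi"])),
    ]
    return TissueSpec(tissue_id=tissue_id, width_um=1000.0, height_um=1000.0,
                      follicles=[follicle], subsets=subsets, panel=default_panel(),
                      seed=seed)


def phenotype_cluster_spec(tissue_id: str, seed: int, *,
                           proportions: list[float] | None = None,
                           n_cells: int = 2600,
                           sigma: float = 0.2,
                           batch_gain_range: tuple[float, float] = (0.7, 1.4),
                           batch_offset_range: tuple[float, float] = (0.0, 5.0)) -> TissueSpec:
    """One tissue of T_FH cells carrying 8 planted phenotype clusters.

    Cluster ``k`` is hi in the k-th phenotype-code marker (one-hot over
    :data:`PHENOTYPE_CODE_MARKERS`) on top of a shared CD3/CD4/PD1-hi T_FH
    base.  Per-tissue affine batch effects (gain, offset) are drawn from the
    given ranges, reproducing the between-tissue intensity shifts that the
    per-tissue z-score step is meant to remove.

    The default intensity spread (``sigma`` 0.2 in log space) places cluster
    centres at least ~6 within-cluster standard deviations apart on the raw
    intensity scale, the separation regime the clustering recovery analyses
    assume for well-resolved phenotypes.
    """
    k = len(PHENOTYPE_CODE_MARKERS)
    if proportions is None:
        proportions = [1.0 / k] * k
    if len(proportions) != k:
        raise ValueError(f"need {k} proportions")
    total = sum(proportions)
    rng = np.random.default_rng(seed)
    follicle = FollicleSpec((750.0, 750.0), radius_um=450.0)
    panel = default_panel(sigma=sigma)
    subsets = []
    for i, code_marker in enumerate(PHENOTYPE_CODE_MARKERS):
        hi = ["CD3", "CD4", "PD1", code_marker]
        subsets.append(SubsetSpec(f"P{i}_pheno", n=int(round(n_cells * proportions[i] / total)),
                                  zone="whole-follicle", process=CSR(),
                                  marker_model=_levels(hi)))
    gains = {m: float(rng.uniform(*batch_gain_range)) for m in PANEL_MARKERS}
    offsets = {m: float(rng.uniform(*batch_offset_range)) for m in PANEL_MARKERS}
    return TissueSpec(tissue_id=tissue_id, width_um=1500.0, height_um=1500.0,
                      follicles=[follicle], subsets=subsets, panel=panel,
                      batch_gain=gains, batch_offset=offsets, seed=seed)


def cohort_specs(n_tissues: int, seed: int, *, enriched: list[int] | None = None,
                 enriched_cluster: int = 1, enrichment: float = 3.0,
                 n_cells: int = 2600) -> list[TissueSpec]:
    """A cohort of phenotype-cluster tissues; tissues whose index appears in
    ``enriched`` carry ``enrichment``-fold the baseline proportion of
    ``enriched_cluster`` (others renormalised)."""
    k = len(PHENOTYPE_CODE_MARKERS)
    base = [1.0 / k] * k
    specs = []
    for t in range(n_tissues):
        props = list(base)
        if enriched and t in enriched:
            props[enriched_cluster] *= enrichment
        specs.append(phenotype_cluster_spec(f"T{t}", seed * 1000 + t,
                                            proportions=props, n_cells=n_cells))
    return specs
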