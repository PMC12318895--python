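"""Batch phenotype clustering across tissues.

The batch pipeline mirrors cytometry practice for comparing marker
phenotypes across samples with different staining intensities: per-tissue
z-score normalisation of marker intensities (coordinates and geometry are
left untouched), equal-n random downsampling and concatenation so every
tissue contributes the same weight, a self-organizing map (SOM) quantising
cells onto a node grid (default 10×10), and average-linkage agglomerative
metaclustering of the codebook into k phenotype metaclusters (default 8),
named P0..P(k-1) in decreasing cell count.  Per-tissue metacluster
prevalence (absolute counts, optional log1p transform) is the heatmap-ready
output.

The SOM is a deterministic full-batch implementation with PCA-plane
initialisation: given a seed, the whole pipeline reproduces identical
metacluster assignments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .celltable import CellTable, concat_tables
from .errors import ConfigurationError, InsufficientDataError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalisation and downsampling
# ---------------------------------------------------------------------------


def zscore_normalize(table: CellTable, per_tissue: bool = True,
                     markers: list[str] | None = None) -> CellTable:
    """Scale each marker to mean 0 / sd 1 (population sd), within each tissue
    when ``per_tissue`` else globally.  Coordinates, volume and sphericity
    are untouched; constant markers become 0 with a warning."""
    markers = list(markers or table.markers)
    out = table.copy()
    groups = out.df.groupby("tissue_id").groups if per_tissue else {"all": out.df.index}
    for gname, idx in groups.items():
        if len(idx) < 2:
            raise InsufficientDataError(
                f"tissue {gname!r} has {len(idx)} cell(s); need >= 2 to normalise")
        block = out.df.loc[idx, markers].to_numpy(dtype=float)
        mean = block.mean(axis=0)
        sd = block.std(axis=0)  # population sd, ddof=0
        zero = sd == 0
        if zero.any():
            warnings.warn(f"constant marker(s) in {gname!r}: "
                          + ", ".join(np.asarray(markers)[zero]))
            sd = np.where(zero, 1.0, sd)
        out.df.loc[idx, markers] = (block - mean) / sd
    return out


def downsample_concatenate(tables: list[CellTable], n: int,
                           seed: int = 0) -> CellTable:
    """Sample exactly ``n`` cells without replacement from every tissue and
    concatenate; tissues with fewer than ``n`` cells are excluded with a
    logged reason."""
    rng = np.random.default_rng(seed)
    kept = []
    for t in tables:
        tissue = t.df["tissue_id"].iloc[0] if len(t) else "?"
        if len(t) < n:
            log.warning("tissue %s excluded from batch: %d cells < %d", tissue, len(t), n)
            continue
        idx = np.sort(rng.choice(len(t), size=n, replace=False))
        kept.append(CellTable(t.df.iloc[idx].reset_index(drop=True).copy(), list(t.markers)))
    if not kept:
        raise InsufficientDataError(f"no tissue has >= {n} cells")
    return concat_tables(kept)


# ---------------------------------------------------------------------------
# SOM
# ---------------------------------------------------------------------------


@dataclass
class SOMModel:
    grid: tuple[int, int]
    codebook: np.ndarray                 # (n_nodes, n_markers)
    markers: list[str]
    metacluster_of_node: np.ndarray | None = None   # node -> 0..k-1 (P-number)
    node_cell_counts: np.ndarray | None = None      # training BMU histogram
    quantisation_errors: list[float] = field(default_factory=list)
    epochs: int = 20
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def predict_nodes(self, data: np.ndarray) -> np.ndarray:
        return np.argmin(cdist(np.asarray(data, dtype=float), self.codebook), axis=1)

    def predict_metaclusters(self, data: np.ndarray) -> np.ndarray:
        if self.metacluster_of_node is None:
            raise ConfigurationError("run metacluster() before predicting metaclusters")
        return self.metacluster_of_node[self.predict_nodes(data)]


def _node_grid_coords(grid: tuple[int, int]) -> np.ndarray:
    w, h = grid
    gx, gy = np.meshgrid(np.arange(w), np.arange(h), indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()]).astype(float)


def train_som(data: np.ndarray, grid: tuple[int, int] = (10, 10), epochs: int = 20,
              seed: int = 0, markers: list[str] | None = None) -> SOMModel:
    """Train a full-batch SOM on a (cells × markers) matrix.

    The codebook initialises on the plane of the first two principal
    directions (sign-fixed, so the fit is deterministic); each epoch assigns
    every cell to its best-matching node and recomputes the codebook as the
    neighbourhood-weighted mean, with a Gaussian neighbourhood whose radius
    decays linearly from max(grid)/2 to 0.5.
    """
    X = np.asarray(data, dtype=float)
    n_nodes = grid[0] * grid[1]
    if len(X) < n_nodes:
        raise InsufficientDataError(
            f"{len(X)} observations < {n_nodes} SOM nodes; use a smaller grid")

    # deterministic PCA-plane initialisation
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:2]
    for i in range(2):                      # fix sign: largest |loading| positive
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    sd = s[:2] / np.sqrt(len(X))
    coords = _node_grid_coords(grid)
    span = np.column_stack([
        np.linspace(-2, 2, grid[0])[coords[:, 0].astype(int)] * sd[0],
        np.linspace(-2, 2, grid[1])[coords[:, 1].astype(int)] * sd[1],
    ])
    codebook = mean + span @ comps

    node_d2 = cdist(coords, coords, "sqeuclidean")
    r0, r1 = max(grid) / 2.0, 0.5
    qerrs: list[float] = []
    for epoch in range(epochs):
        radius = r0 + (r1 - r0) * (epoch / max(epochs - 1, 1))
        d2 = cdist(X, codebook, "sqeuclidean")
        bmu = np.argmin(d2, axis=1)
        qerrs.append(float(np.sqrt(d2[np.arange(len(X)), bmu]).mean()))
        h = np.exp(-node_d2 / (2.0 * radius * radius))        # (nodes, nodes)
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, X)
        denom = h @ counts
        codebook = (h @ sums) / denom[:, None]

    d2 = cdist(X, codebook, "sqeuclidean")
    bmu = np.argmin(d2, axis=1)
    qerrs.append(float(np.sqrt(d2[np.arange(len(X)), bmu]).mean()))
    model = SOMModel(grid=tuple(grid), codebook=codebook,
                     markers=list(markers or [f"m{i}" for i in range(X.shape[1])]),
                     node_cell_counts=np.bincount(bmu, minlength=n_nodes),
                     quantisation_errors=qerrs, epochs=epochs, seed=seed)
    return model


def metacluster(model: SOMModel, k: int = 8) -> SOMModel:
    """Average-linkage agglomerative clustering of the codebook into k
    metaclusters, renumbered P0..P(k-1) by decreasing training cell count."""
    if k < 1 or k > model.n_nodes:
        raise ConfigurationError(f"k must be in [1, {model.n_nodes}]")
    if k == model.n_nodes:
        raw = np.arange(model.n_nodes)
    else:
        Z = linkage(model.codebook, method="average", metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust") - 1
    counts = model.node_cell_counts if model.node_cell_counts is not None \
        else np.ones(model.n_nodes)
    totals = np.bincount(raw, weights=counts, minlength=raw.max() + 1)
    order = np.argsort(-totals, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    model.metacluster_of_node = rank[raw]
    return model


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


def prevalence_matrix(metacluster_labels: np.ndarray, tissue_ids,
                      transform: str = "none", k: int | None = None) -> pd.DataFrame:
    """Tissues × metaclusters absolute-count matrix (optionally log1p for
    heatmap display).  Untransformed rows sum to each tissue's cell count."""
    labels = np.asarray(metacluster_labels)
    tissues = pd.Series(tissue_ids, name="tissue_id").astype(str)
    if len(labels) != len(tissues):
        raise ValueError("labels and tissue_ids must align")
    k = k if k is not None else (int(labels.max()) + 1 if len(labels) else 0)
    mat = pd.crosstab(tissues, pd.Series(labels, name="metacluster"))
    mat = mat.reindex(columns=range(k), fill_value=0)
    mat.columns = [f"P{j}" for j in range(k)]
    if transform == "log1p":
        return np.log1p(mat.astype(float))
    if transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return mat


# ---------------------------------------------------------------------------
# end-to-end batch pipeline
# ---------------------------------------------------------------------------


@dataclass
class BatchClusteringResult:
    table: CellTable                 # normalised, downsampled, concatenated
    model: SOMModel
    cell_metaclusters: np.ndarray
    prevalence: pd.DataFrame


def batch_cluster(tables: list[CellTable], markers: list[str], n_downsample: int,
                  grid: tuple[int, int] = (10, 10), k: int = 8, epochs: int = 20,
                  seed: int = 0, per_tissue: bool = True) -> BatchClusteringResult:
    """Normalise → downsample/concatenate → SOM → metacluster → prevalence."""
    normed = [zscore_normalize(t, per_tissue=per_tissue, markers=markers) for t in tables]
    merged = downsample_concatenate(normed, n_downsample, seed=seed)
    X = merged.intensity_matrix(markers)
    model = metacluster(train_som(X, grid=grid, epochs=epochs, seed=seed, markers=markers), k)
    cells = model.predict_metaclusters(X)
    prev = prevalence_matrix(cells, merged.df["tissue_id"], k=k)
    return BatchClusteringResult(table=merged, model=model,
                                 cell_metaclusters=cells, prevalence=prev)
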