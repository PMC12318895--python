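"""Synthetic lymphoid-tissue generator with planted ground truth.

Emulates what the real pipeline sees after 3D segmentation of multiplex
immunofluorescence: a table of cell centroids (projected to x/y, μm),
geometry (volume, sphericity) and per-marker mean (and median) voxel
intensities.  Tissues carry multiple follicles with concentric zonation —
a mantle-zone (MZ) annulus around a germinal-centre (GC) disc that a chord
splits into dark (DZ) and light (LZ) zones — plus extrafollicular space.
Cell subsets are planted per zone under complete spatial randomness (CSR),
Thomas-clustered or hard-core point processes, with hi/lo log-normal marker
intensity mixtures, per-tissue affine batch effects, and optional
uniform-staining artefact cells and sub-cellular debris.

Every generated cell is recorded in a :class:`GroundTruth` so each pipeline
stage (artefact filtering, threshold derivation, gating, follicle detection,
spatial statistics, clustering) can be scored against the planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon, box

from .celltable import CellTable, median_column
from .errors import InfeasibleError

# ---------------------------------------------------------------------------
# point processes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CSR:
    """Homogeneous Poisson (binomial at fixed n) placement."""


@dataclass(frozen=True)
class Thomas:
    """Parent-offspring clustering: offspring are Gaussian displacements
    (sd ``offspring_sd_um``) around CSR parents."""

    parent_intensity: float | None = None  # parents per μm²; or derive from n
    offspring_sd_um: float = 10.0
    mean_offspring: float = 10.0


@dataclass(frozen=True)
class HardCore:
    """Dart-throwing with a minimum pairwise distance ``min_dist_um``."""

    min_dist_um: float = 10.0


ProcessSpec = CSR | Thomas | HardCore


def _sample_in_polygon(rng: np.random.Generator, region: Polygon, n: int,
                       max_tries: int = 10_000) -> np.ndarray:
    """Rejection-sample exactly n uniform points inside ``region``."""
    minx, miny, maxx, maxy = region.bounds
    out = np.empty((0, 2))
    tries = 0
    while len(out) < n and tries < max_tries:
        m = max(4 * (n - len(out)), 64)
        pts = np.column_stack([rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)])
        keep = shapely.intersects_xy(region, pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[keep]])
        tries += 1
    if len(out) < n:
        raise InfeasibleError(f"could not place {n} points in region after {max_tries} batches")
    return out[:n]


def simulate_point_pattern(process: ProcessSpec | str, region: Polygon, n: int,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """Place exactly ``n`` points inside ``region`` under the given process.

    Returns an (n, 2) float array of (x_um, y_um).  Deterministic given the
    seed.  Hard-core placement raises :class:`InfeasibleError` when the
    packing constraint cannot be met after bounded retries.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if region.is_empty or region.area <= 0:
        raise ValueError("region is degenerate")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty((0, 2))
    if isinstance(process, str):
        process = {"CSR": CSR(), "csr": CSR()}.get(process) or _parse_process(process)

    if isinstance(process, CSR):
        return _sample_in_polygon(rng, region, n)

    if isinstance(process, Thomas):
        if process.parent_intensity is not None:
            n_parents = max(1, int(round(process.parent_intensity * region.area)))
        else:
            n_parents = max(1, int(round(n / process.mean_offspring)))
        parents = _sample_in_polygon(rng, region, n_parents)
        out = np.empty((0, 2))
        for _ in range(10_000):
            m = max(2 * (n - len(out)), 64)
            idx = rng.integers(0, n_parents, m)
            pts = parents[idx] + rng.normal(0.0, process.offspring_sd_um, (m, 2))
            keep = shapely.intersects_xy(region, pts[:, 0], pts[:, 1])
            out = np.vstack([out, pts[keep]])
            if len(out) >= n:
                return out[:n]
        raise InfeasibleError("Thomas offspring placement did not converge")

    if isinstance(process, HardCore):
        delta = process.min_dist_um
        accepted: list[np.ndarray] = []
        attempts = 0
        max_attempts = 2000 * n + 10_000
        minx, miny, maxx, maxy = region.bounds
        while len(accepted) < n and attempts < max_attempts:
            attempts += 1
            p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
            if not shapely.intersects_xy(region, p[0], p[1]):
                continue
            if accepted:
                d2 = np.sum((np.asarray(accepted) - p) ** 2, axis=1)
                if d2.min() < delta * delta:
                    continue
            accepted.append(p)
        if len(accepted) < n:
            raise InfeasibleError(
                f"hard-core packing infeasible: placed {len(accepted)}/{n} "
                f"points at min distance {delta} μm")
        return np.asarray(accepted)

    raise TypeError(f"unknown process spec: {process!r}")


def _parse_process(s: str) -> ProcessSpec:
    s = s.strip()
    if s.lower().startswith("thomas"):
        return Thomas()
    if s.lower().startswith("hardcore"):
        return HardCore()
    raise ValueError(f"unknown process string {s!r}")


# ---------------------------------------------------------------------------
# tissue specification
# ---------------------------------------------------------------------------


@dataclass
class MarkerModel:
    """Log-normal hi/lo intensity mixture for one marker.

    ``mu_hi``/``mu_lo`` are means of the underlying normal (natural-log
    intensity); separation ``mu_hi - mu_lo >= 2 * sigma`` makes the marker
    gateable with < 5% overlap.
    """

    mu_hi: float = 3.0
    mu_lo: float = 1.0
    sigma: float = 0.4

    def __post_init__(self):
        if self.mu_hi <= self.mu_lo:
            raise ValueError("marker model requires mu_hi > mu_lo")


@dataclass
class FollicleSpec:
    """A circular follicle: MZ annulus around a GC disc, GC split into DZ/LZ
    by a chord chosen so the DZ holds ``dz_fraction`` of the GC area."""

    centre: tuple[float, float]
    radius_um: float
    gc_radius_frac: float = 0.6
    dz_fraction: float = 0.5

    def __post_init__(self):
        if not 0 < self.gc_radius_frac < 1:
            raise ValueError("gc_radius_frac must be in (0, 1)")
        if not 0 < self.dz_fraction < 1:
            raise ValueError("dz_fraction must be in (0, 1)")

    @property
    def gc_radius_um(self) -> float:
        return self.gc_radius_frac * self.radius_um

    def disc(self) -> Polygon:
        return Point(*self.centre).buffer(self.radius_um, quad_segs=90)

    def _chord_offset(self) -> float:
        """x-offset (relative to centre) of the DZ/LZ chord."""
        r = self.gc_radius_um

        def area_left(a):
            return r * r * (math.asin(a / r) + math.pi / 2) + a * math.sqrt(max(r * r - a * a, 0.0))

        target = self.dz_fraction * math.pi * r * r
        return brentq(lambda a: area_left(a) - target, -r, r)

    def zone_polygon(self, zone: str) -> Polygon:
        cx, cy = self.centre
        r, gr = self.radius_um, self.gc_radius_um
        disc = self.disc()
        gc = Point(cx, cy).buffer(gr, quad_segs=90)
        if zone in ("whole-follicle", "follicle"):
            return disc
        if zone == "GC":
            return gc
        if zone == "MZ":
            return disc.difference(gc)
        if zone in ("DZ", "LZ", "DZ-core"):
            a = self._chord_offset()
            left = box(cx - r - 1, cy - r - 1, cx + a, cy + r + 1)
            dz = gc.intersection(left)
            if zone == "DZ":
                return dz
            if zone == "LZ":
                return gc.difference(left)
            # DZ-core: DZ-adjacent inner GC core (inside 0.75 of the GC radius)
            return dz.intersection(Point(cx, cy).buffer(0.75 * gr, quad_segs=90))
        if zone == "GC-boundary-band":
            return gc.difference(Point(cx, cy).buffer(0.8 * gr, quad_segs=90))
        raise ValueError(f"unknown zone {zone!r}")


FOLLICULAR_ZONES = ("MZ", "DZ", "LZ", "GC", "whole-follicle", "GC-boundary-band", "DZ-core")


@dataclass
class SubsetSpec:
    """One planted cell population.

    ``n`` is the count per follicle for follicular zones and the total count
    for the extrafollicular zone; alternatively ``density`` (cells per μm²)
    is converted through the zone area.  ``marker_model`` maps every panel
    marker to ``"hi"`` or ``"lo"``.
    """

    name: str
    n: int | None = None
    density: float | None = None
    zone: str = "whole-follicle"
    process: ProcessSpec = field(default_factory=CSR)
    marker_model: dict[str, str] = field(default_factory=dict)

    def count_for(self, region: Polygon) -> int:
        if self.n is not None:
            return int(self.n)
        if self.density is not None:
            return int(round(self.density * region.area))
        raise ValueError(f"subset {self.name!r}: provide n or density")


@dataclass
class TissueSpec:
    tissue_id: str
    width_um: float = 1500.0
    height_um: float = 1500.0
    follicles: list[FollicleSpec] = field(default_factory=list)
    subsets: list[SubsetSpec] = field(default_factory=list)
    panel: dict[str, MarkerModel] = field(default_factory=dict)
    batch_gain: dict[str, float] = field(default_factory=dict)    # g_m > 0
    batch_offset: dict[str, float] = field(default_factory=dict)  # b_m >= 0
    artefact_fraction: float = 0.0
    debris_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.artefact_fraction < 1:
            raise ValueError("artefact_fraction must be in [0, 1)")
        for f in self.follicles:
            cx, cy = f.centre
            if (cx - f.radius_um < 0 or cx + f.radius_um > self.width_um
                    or cy - f.radius_um < 0 or cy + f.radius_um > self.height_um):
                raise ValueError(f"follicle at {f.centre} exceeds the section")
        for m, g in self.batch_gain.items():
            if g <= 0:
                raise ValueError(f"batch gain for {m} must be > 0")

    @property
    def markers(self) -> list[str]:
        return list(self.panel)

    def section(self) -> Polygon:
        return box(0, 0, self.width_um, self.height_um)

    def extrafollicular_region(self) -> Polygon:
        region = self.section()
        for f in self.follicles:
            region = region.difference(f.disc())
        return region


@dataclass
class GroundTruth:
    """Planted truth for every generated cell, plus the true follicle discs."""

    df: pd.DataFrame          # cell_id, population, follicle_id, zone, is_artefact, is_debris
    follicle_polys: dict[str, Polygon]
    spec: TissueSpec

    def population_mask(self, table: CellTable, population: str) -> np.ndarray:
        truth = self.df.set_index("cell_id")["population"]
        return truth.reindex(table.df["cell_id"]).to_numpy() == population


# ---------------------------------------------------------------------------
# tissue simulation
# ---------------------------------------------------------------------------

_MEDIAN_RATIO_RANGE = (0.55, 0.80)   # right-skewed staining: median < mean
_ARTEFACT_MEDIAN_JITTER = 0.02       # uniform staining: median ≈ mean


def _draw_intensities(rng, panel: dict[str, MarkerModel], levels: dict[str, str],
                      n: int) -> dict[str, np.ndarray]:
    out = {}
    for marker, model in panel.items():
        level = levels.get(marker, "lo")
        mu = model.mu_hi if level == "hi" else model.mu_lo
        out[marker] = np.exp(rng.normal(mu, model.sigma, n))
    return out


def simulate_tissue(spec: TissueSpec) -> tuple[CellTable, GroundTruth]:
    """Generate one tissue and its ground truth.

    Output is a pure function of the spec (including ``spec.seed``): the same
    spec yields a byte-identical table.  Artefact cells (uniform staining
    across channels, mean ≈ median) and sub-volume debris are appended after
    the planted subsets; their counts are ``floor(fraction * n_planted)``.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    follicle_polys = {f"F{i}": f.disc() for i, f in enumerate(spec.follicles)}

    def emit(points, subset_name, zone, follicle_id, levels, *, artefact=False, debris=False):
        n = len(points)
        if n == 0:
            return
        if artefact:
            # uniform high staining in every channel, mean ≈ median
            inten = {m: np.exp(rng.normal(model.mu_hi + 0.5, 0.2, n))
                     for m, model in spec.panel.items()}
            med_ratio = {m: 1.0 + rng.uniform(-_ARTEFACT_MEDIAN_JITTER,
                                              _ARTEFACT_MEDIAN_JITTER, n)
                         for m in spec.panel}
            volume = np.exp(rng.normal(math.log(300.0), 0.3, n))
            spher = rng.uniform(0.6, 0.95, n)
        elif debris:
            inten = _draw_intensities(rng, spec.panel, {}, n)
            med_ratio = {m: rng.uniform(*_MEDIAN_RATIO_RANGE, n) for m in spec.panel}
            volume = np.exp(rng.normal(math.log(12.0), 0.35, n))   # sub-cellular
            spher = rng.uniform(0.05, 0.25, n)
        else:
            inten = _draw_intensities(rng, spec.panel, levels, n)
            med_ratio = {m: rng.uniform(*_MEDIAN_RATIO_RANGE, n) for m in spec.panel}
            volume = np.exp(rng.normal(math.log(300.0), 0.3, n))
            spher = rng.uniform(0.6, 0.95, n)

        for i in range(n):
            row = {
                "cell_id": f"{spec.tissue_id}-c{len(rows):06d}",
                "tissue_id": spec.tissue_id,
                "x_um": float(points[i, 0]),
                "y_um": float(points[i, 1]),
                "volume_um3": float(volume[i]),
                "sphericity": float(spher[i]),
            }
            for m in spec.panel:
                g = spec.batch_gain.get(m, 1.0)
                b = spec.batch_offset.get(m, 0.0)
                mean_i = g * inten[m][i] + b
                row[m] = mean_i
                row[median_column(m)] = g * (inten[m][i] * med_ratio[m][i]) + b
            rows.append(row)
            truth_rows.append({
                "cell_id": row["cell_id"], "tissue_id": spec.tissue_id,
                "population": subset_name, "follicle_id": follicle_id,
                "zone": zone, "is_artefact": artefact, "is_debris": debris,
            })

    for subset in spec.subsets:
        if subset.zone == "extrafollicular":
            region = spec.extrafollicular_region()
            pts = simulate_point_pattern(subset.process, region, subset.count_for(region), rng)
            emit(pts, subset.name, "extrafollicular", "", subset.marker_model)
        elif subset.zone in FOLLICULAR_ZONES:
            for fid, follicle in zip(follicle_polys, spec.follicles):
                region = follicle.zone_polygon(subset.zone)
                pts = simulate_point_pattern(subset.process, region, subset.count_for(region), rng)
                emit(pts, subset.name, subset.zone, fid, subset.marker_model)
        else:
            raise ValueError(f"unknown zone {subset.zone!r} for subset {subset.name!r}")

    n_planted = len(rows)
    n_artefact = int(spec.artefact_fraction * n_planted)
    if n_artefact:
        pts = _sample_in_polygon(rng, spec.section(), n_artefact)
        emit(pts, "artefact", "", "", {}, artefact=True)
    n_debris = int(spec.debris_fraction * n_planted)
    if n_debris:
        pts = _sample_in_polygon(rng, spec.section(), n_debris)
        emit(pts, "debris", "", "", {}, debris=True)

    df = pd.DataFrame(rows)
    table = CellTable(df, spec.markers)
    truth = GroundTruth(pd.DataFrame(truth_rows), follicle_polys, spec)
    return table, truth
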