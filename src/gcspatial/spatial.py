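"""Nearest-neighbour spatial statistics for cells inside a follicle ROI.

Implements the G-function toolkit used to quantify how cell subsets are
arranged within follicles:

* ``empirical_G`` — the CDF of nearest-neighbour (NN) distances of one
  subset, optionally border-corrected;
* ``theoretical_poisson_G`` — the CSR reference ``G(d) = 1 - exp(-λπd²)``;
* ``dispersion_score`` — the signed area between the theoretical and
  empirical curves: positive means NN distances are stochastically larger
  than CSR (dispersed/regular), negative means clustered;
* ``min_cross_distances`` — per-source-cell minimum Euclidean distance to a
  second subset, with its exact sample median;
* ``cross_G_randomness`` — the cross-G CDF of those minimum distances
  against the independence null ``1 - exp(-λ_target πd²)``.

Follicles contribute only when the subsets involved have at least
``min_cells_per_subset`` cells (default 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .config import SpatialParams
from .errors import InsufficientDataError
from .follicles import FollicleROI

log = logging.getLogger(__name__)


@dataclass
class GCurve:
    """A monotone CDF-like curve over a distance grid."""

    d: np.ndarray               # increasing distances (μm), starting at 0
    g: np.ndarray               # values in [0, 1], non-decreasing
    kind: str                   # empirical | theoretical | cross-empirical | cross-theoretical
    n_points: int = 0
    lambda_per_um2: float = float("nan")

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.g = np.asarray(self.g, dtype=float)


@dataclass
class DispersionResult:
    score_um: float             # ∫ (G_theo - G_emp) dd
    g_emp: GCurve
    g_theo: GCurve
    n: int
    roi_area_um2: float
    lambda_per_um2: float


@dataclass
class CrossDistanceResult:
    source_subset: str
    target_subset: str
    min_dists_um: np.ndarray    # one per source cell
    median_um: float
    cross_g_emp: GCurve | None = None
    cross_g_theo: GCurve | None = None
    signed_area_um: float = float("nan")   # ∫ (theo - emp) dd
    abs_deviation_um: float = float("nan")  # ∫ |emp - theo| dd


# ---------------------------------------------------------------------------


def _border_distances(points: np.ndarray, roi: Polygon) -> np.ndarray:
    return shapely.distance(shapely.points(points), roi.exterior)


def _border_corrected_cdf(values: np.ndarray, d_border: np.ndarray,
                          grid: np.ndarray) -> np.ndarray:
    """Reduced-sample (border method) CDF estimate: at each grid distance d,
    only points at least d from the window boundary contribute."""
    g = np.empty_like(grid)
    for i, d in enumerate(grid):
        ok = d_border >= d
        g[i] = np.mean(values[ok] <= d) if ok.any() else np.nan
    # keep the curve CDF-valid where the border set empties out
    return np.fmax.accumulate(np.nan_to_num(g, nan=1.0))


def nearest_neighbour_distances(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise InsufficientDataError("need >= 2 points for nearest-neighbour distances")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return d[:, 1]


def empirical_G(points: np.ndarray, grid: np.ndarray, edge_correction: bool = False,
                roi: Polygon | None = None) -> GCurve:
    """Empirical G: for each grid distance d, the fraction of points whose NN
    distance is <= d.

    With ``edge_correction`` (border method) only points lying at least d
    from the ROI boundary contribute at that d, removing the bias from
    unobserved neighbours outside the window; ``roi`` is then required.
    """
    points = np.asarray(points, dtype=float)
    grid = np.asarray(grid, dtype=float)
    nn = nearest_neighbour_distances(points)
    if edge_correction:
        if roi is None:
            raise ValueError("edge correction requires the ROI polygon")
        g = _border_corrected_cdf(nn, _border_distances(points, roi), grid)
    else:
        g = np.searchsorted(np.sort(nn), grid, side="right") / len(nn)
    return GCurve(grid, g, kind="empirical", n_points=len(points))


def theoretical_poisson_G(lambda_per_um2: float, grid: np.ndarray,
                          kind: str = "theoretical") -> GCurve:
    """CSR nearest-neighbour CDF: G(d) = 1 - exp(-λ π d²)."""
    if lambda_per_um2 <= 0:
        raise ValueError("intensity lambda must be > 0")
    grid = np.asarray(grid, dtype=float)
    g = 1.0 - np.exp(-lambda_per_um2 * np.pi * grid ** 2)
    return GCurve(grid, g, kind=kind, lambda_per_um2=lambda_per_um2)


def _default_grid(lam: float, nn_max: float, roi: FollicleROI,
                  params: SpatialParams) -> np.ndarray:
    if params.d_max_um is not None:
        d_max = params.d_max_um
    else:
        # distance at which both curves have effectively saturated
        d_theo = np.sqrt(np.log(1000.0) / (lam * np.pi))
        minx, miny, maxx, maxy = roi.boundary.bounds
        diameter = float(np.hypot(maxx - minx, maxy - miny))
        d_max = min(max(d_theo, nn_max), diameter)
    return np.linspace(0.0, d_max, params.distance_grid_n)


def dispersion_score(points: np.ndarray, roi: FollicleROI,
                     params: SpatialParams | None = None) -> DispersionResult | None:
    """Signed area between the CSR reference and the empirical G-curve.

    λ comes from the subset count over the follicle ROI area.  Follicles with
    fewer than ``params.min_cells_per_subset`` cells are skipped (returns
    None) with a logged reason.
    """
    params = params or SpatialParams()
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < params.min_cells_per_subset:
        log.info("skipping follicle %s: %d cells < %d required",
                 roi.follicle_id, n, params.min_cells_per_subset)
        return None
    lam = n / roi.area_um2
    nn_max = float(nearest_neighbour_distances(points).max())
    grid = _default_grid(lam, nn_max, roi, params)
    g_emp = empirical_G(points, grid, edge_correction=params.edge_correction,
                        roi=roi.boundary if params.edge_correction else None)
    g_theo = theoretical_poisson_G(lam, grid)
    score = float(np.trapezoid(g_theo.g - g_emp.g, grid))
    return DispersionResult(score_um=score, g_emp=g_emp, g_theo=g_theo, n=n,
                            roi_area_um2=roi.area_um2, lambda_per_um2=lam)


def min_cross_distances(source_points: np.ndarray, target_points: np.ndarray,
                        source_subset: str = "source",
                        target_subset: str = "target") -> CrossDistanceResult:
    """Per-source-cell minimum Euclidean distance to the target subset, plus
    the exact sample median of those distances."""
    source_points = np.asarray(source_points, dtype=float)
    target_points = np.asarray(target_points, dtype=float)
    if len(source_points) == 0 or len(target_points) == 0:
        raise InsufficientDataError("both source and target subsets must be non-empty")
    tree = cKDTree(target_points)
    d, _ = tree.query(source_points, k=1)
    d = np.asarray(d, dtype=float)
    return CrossDistanceResult(source_subset=source_subset, target_subset=target_subset,
                               min_dists_um=d, median_um=float(np.median(d)))


def cross_G_randomness(source_points: np.ndarray, target_points: np.ndarray,
                       roi: FollicleROI, params: SpatialParams | None = None,
                       source_subset: str = "source",
                       target_subset: str = "target") -> CrossDistanceResult | None:
    """Cross-G of source→target minimum distances against the independence
    null (CSR targets at λ_target = n_target / ROI area).

    Reports the signed area ∫(theo − emp) dd (positive: targets farther from
    sources than independence predicts, i.e. avoidance; negative:
    attraction) and the absolute deviation ∫|emp − theo| dd (small: the
    distance profile is close to complete spatial randomness).
    """
    params = params or SpatialParams()
    source_points = np.asarray(source_points, dtype=float)
    target_points = np.asarray(target_points, dtype=float)
    if min(len(source_points), len(target_points)) < params.min_cells_per_subset:
        log.info("skipping follicle %s: subsets below %d cells",
                 roi.follicle_id, params.min_cells_per_subset)
        return None
    base = min_cross_distances(source_points, target_points, source_subset, target_subset)
    lam_t = len(target_points) / roi.area_um2
    grid = _default_grid(lam_t, float(base.min_dists_um.max()), roi, params)
    if params.edge_correction:
        g_vals = _border_corrected_cdf(base.min_dists_um,
                                       _border_distances(source_points, roi.boundary), grid)
    else:
        g_vals = np.searchsorted(np.sort(base.min_dists_um), grid,
                                 side="right") / len(base.min_dists_um)
    g_emp = GCurve(grid, g_vals, kind="cross-empirical", n_points=len(source_points))
    g_theo = theoretical_poisson_G(lam_t, grid, kind="cross-theoretical")
    base.cross_g_emp = g_emp
    base.cross_g_theo = g_theo
    base.signed_area_um = float(np.trapezoid(g_theo.g - g_emp.g, grid))
    base.abs_deviation_um = float(np.trapezoid(np.abs(g_emp.g - g_theo.g), grid))
    return base


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------


def follicle_spatial_analysis(table, follicles: list[FollicleROI],
                              pairs: list[tuple[str, str]],
                              subsets_for_dispersion: list[str] | None = None,
                              params: SpatialParams | None = None):
    """Run dispersion and cross-G analyses per follicle on a labelled table.

    ``pairs`` are (source_label, target_label) population pairs; sources are
    typically GC B-cell subsets.  Returns a tidy DataFrame, one row per
    follicle × analysis, skipping under-populated follicles.
    """
    import pandas as pd

    params = params or SpatialParams()
    rows = []
    for roi in follicles:
        in_f = table.has_label(f"F:{roi.follicle_id}")
        for name in (subsets_for_dispersion or []):
            pts = table.coordinates[in_f & table.has_label(name)]
            res = dispersion_score(pts, roi, params)
            if res is not None:
                rows.append({"follicle_id": roi.follicle_id, "analysis": "dispersion",
                             "subset": name, "target": "", "n": res.n,
                             "value_um": res.score_um})
        for src, tgt in pairs:
            sp = table.coordinates[in_f & table.has_label(src)]
            tp = table.coordinates[in_f & table.has_label(tgt)]
            if min(len(sp), len(tp)) < params.min_cells_per_subset:
                log.info("follicle %s: pair (%s, %s) below %d cells, skipped",
                         roi.follicle_id, src, tgt, params.min_cells_per_subset)
                continue
            res = cross_G_randomness(sp, tp, roi, params, src, tgt)
            rows.append({"follicle_id": roi.follicle_id, "analysis": "median_min_distance",
                         "subset": src, "target": tgt, "n": len(sp),
                         "value_um": res.median_um})
            rows.append({"follicle_id": roi.follicle_id, "analysis": "cross_g_signed_area",
                         "subset": src, "target": tgt, "n": len(sp),
                         "value_um": res.signed_area_um})
            rows.append({"follicle_id": roi.follicle_id, "analysis": "cross_g_abs_deviation",
                         "subset": src, "target": tgt, "n": len(sp),
                         "value_um": res.abs_deviation_um})
    return pd.DataFrame(rows, columns=["follicle_id", "analysis", "subset", "target",
                                       "n", "value_um"])
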