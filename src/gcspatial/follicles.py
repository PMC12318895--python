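"""Follicle ROI detection from B-cell density and compartment assignment.

Follicular areas are the regions where CD20 B cells pack densely.  A
Gaussian kernel density estimate of the B-cell coordinates is thresholded at
a fraction of its maximum; each connected super-threshold component whose
outer contour contains enough B cells becomes a :class:`FollicleROI`.
Cells inside any ROI are follicular ("F"), everything else extrafollicular
("EF").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union
from skimage import measure

from .celltable import CellTable
from .config import FollicleParams
from .errors import InsufficientDataError

log = logging.getLogger(__name__)


@dataclass
class FollicleROI:
    """A follicular region: simple closed boundary polygon (μm), area,
    centroid and the number of member B cells."""

    follicle_id: str
    boundary: Polygon
    area_um2: float
    centroid: tuple[float, float]
    b_cell_count: int


def detect_follicles(b_cells: CellTable, kde_bandwidth_um: float = 30.0,
                     density_threshold_frac: float = 0.2,
                     min_b_cells: int = 20) -> list[FollicleROI]:
    """Detect follicle ROIs from a table of (already gated) B cells.

    The density surface is a 2D histogram smoothed with a Gaussian of sd
    ``kde_bandwidth_um`` on a grid no coarser than half the bandwidth.  The
    super-threshold region (``density_threshold_frac`` × max density) is
    split into connected components; components with fewer than
    ``min_b_cells`` member B cells are dropped; overlapping contours are
    merged.  IDs ``F0, F1, ...`` follow decreasing area.
    """
    if len(b_cells) < min_b_cells:
        log.info("only %d B cells (< %d): no follicle can qualify", len(b_cells), min_b_cells)
        return []
    xy = b_cells.coordinates
    step = kde_bandwidth_um / 2.0
    pad = 3.0 * kde_bandwidth_um
    x0, y0 = xy.min(axis=0) - pad
    x1, y1 = xy.max(axis=0) + pad
    nx = max(int(math.ceil((x1 - x0) / step)), 8)
    ny = max(int(math.ceil((y1 - y0) / step)), 8)

    hist, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1],
                                  bins=[nx, ny], range=[[x0, x1], [y0, y1]])
    density = gaussian_filter(hist, sigma=kde_bandwidth_um / step, mode="constant")
    if density.max() <= 0:
        return []
    level = density_threshold_frac * density.max()
    mask = density >= level
    labelled = measure.label(mask)
    n_comp = int(labelled.max())

    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    polys = []
    for comp in range(1, n_comp + 1):
        comp_mask = labelled == comp
        # contour of the smoothed density restricted to this component
        comp_density = np.where(comp_mask, density, 0.0)
        contours = measure.find_contours(comp_density, level)
        if not contours:
            continue
        contour = max(contours, key=len)
        # grid indices -> μm (axis 0 of the histogram is x)
        px = np.interp(contour[:, 0], np.arange(nx), xc)
        py = np.interp(contour[:, 1], np.arange(ny), yc)
        poly = Polygon(np.column_stack([px, py]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty or poly.area <= 0:
            continue
        polys.append(poly)

    if not polys:
        return []
    merged = unary_union(polys)
    geoms = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]

    rois = []
    for poly in geoms:
        if poly.area <= 0:
            continue
        inside = shapely.intersects_xy(poly, xy[:, 0], xy[:, 1])
        count = int(inside.sum())
        if count < min_b_cells:
            log.info("dropping candidate follicle with %d B cells (< %d)", count, min_b_cells)
            continue
        poly = shapely.geometry.polygon.orient(poly, sign=1.0)  # counter-clockwise
        rois.append((poly, count))

    rois.sort(key=lambda pc: pc[0].area, reverse=True)
    return [FollicleROI(follicle_id=f"F{i}", boundary=poly, area_um2=poly.area,
                        centroid=(poly.centroid.x, poly.centroid.y), b_cell_count=count)
            for i, (poly, count) in enumerate(rois)]


def assign_compartment(table: CellTable, follicles: list[FollicleROI]) -> CellTable:
    """Label every cell follicular ("F", plus "F:<id>") or extrafollicular
    ("EF"); point-in-polygon is boundary-inclusive."""
    out = table.copy()
    xy = out.coordinates
    any_f = np.zeros(len(out), dtype=bool)
    for roi in follicles:
        inside = shapely.intersects_xy(roi.boundary, xy[:, 0], xy[:, 1])
        inside &= ~any_f  # first (largest) follicle wins where merged ROIs touch
        out.add_labels(inside, f"F:{roi.follicle_id}")
        any_f |= inside
    out.add_labels(any_f, "F")
    out.add_labels(~any_f, "EF")
    return out


def relative_radial_position(cell_xy: tuple[float, float], follicle: FollicleROI) -> float:
    """Relative radial position ρ of a cell within its follicle.

    ρ = distance(cell, centroid) / distance(boundary ∩ ray, centroid), where
    the ray runs from the centroid through the cell: 0 at the centroid, 1 on
    the boundary; interior cells of a star-shaped follicle get ρ in [0, 1].
    """
    cx, cy = follicle.centroid
    px, py = float(cell_xy[0]), float(cell_xy[1])
    d = math.hypot(px - cx, py - cy)
    if d < 1e-12:
        return 0.0
    # extend the ray well past the boundary and take the farthest crossing
    minx, miny, maxx, maxy = follicle.boundary.bounds
    reach = 2.0 * math.hypot(maxx - minx, maxy - miny)
    far = (cx + (px - cx) / d * reach, cy + (py - cy) / d * reach)
    ray = LineString([(cx, cy), far])
    hits = ray.intersection(follicle.boundary.exterior)
    if hits.is_empty:
        return float("nan")
    pts = []
    for geom in getattr(hits, "geoms", [hits]):
        if geom.geom_type == "Point":
            pts.append(geom)
        else:
            pts.extend(Point(c) for c in geom.coords)
    r_boundary = max(math.hypot(p.x - cx, p.y - cy) for p in pts)
    return d / r_boundary


def radial_positions(table: CellTable, follicles: list[FollicleROI]) -> np.ndarray:
    """ρ for every cell labelled F:<id>; NaN for extrafollicular cells."""
    by_id = {f.follicle_id: f for f in follicles}
    out = np.full(len(table), np.nan)
    for i, labels in enumerate(table.df["labels"]):
        fids = [l.split(":", 1)[1] for l in labels if l.startswith("F:")]
        if fids and fids[0] in by_id:
            out[i] = relative_radial_position(
                (table.df["x_um"].iat[i], table.df["y_um"].iat[i]), by_id[fids[0]])
    return out
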