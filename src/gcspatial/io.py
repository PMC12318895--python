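"""CSV / GeoJSON input-output for cell tables and follicle ROIs.

Cell tables are plain CSV (RFC 4180, UTF-8, '.' decimal) — the portable
equivalent of the spreadsheet export produced by 3D surface segmentation.
Follicle boundaries travel as GeoJSON Polygon features with coordinates in
micrometres.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .celltable import LABEL_SEP, REQUIRED_COLUMNS, CellTable, median_column
from .errors import SchemaError, ValidationError


def read_cell_table(path, panel: list[str]) -> CellTable:
    """Read and validate a segmented-cell CSV.

    Parameters
    ----------
    path : str or Path
        CSV with columns ``cell_id, tissue_id, x_um, y_um, volume_um3,
        sphericity`` plus one mean-intensity column per marker in ``panel``.
        Optional ``<marker>_median`` columns are kept if present, as is an
        optional ``label`` column of ';'-joined population names.
    panel : list of str
        Ordered marker names expected in the header.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "tissue_id": str})
    missing = [c for c in (*REQUIRED_COLUMNS, *panel) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")

    for col in ["x_um", "y_um", "volume_um3", "sphericity", *panel]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad][:10])
            raise ValidationError(f"{path}: non-numeric value(s) in {col!r} at row(s) {rows}",
                                  [(int(i), col) for i in df.index[bad]])
        df[col] = coerced

    if "label" in df.columns:
        df["labels"] = [
            frozenset(s.split(LABEL_SEP)) if isinstance(s, str) and s else frozenset()
            for s in df["label"]
        ]
        df = df.drop(columns=["label"])

    keep = [c for c in df.columns if c in (*REQUIRED_COLUMNS, *panel, "labels")
            or c in {median_column(m) for m in panel}]
    table = CellTable(df[keep], list(panel))
    return table.validate()


def write_cell_table(table: CellTable, path) -> None:
    """Write a cell table to CSV without labels (raw-export shape)."""
    cols = [*REQUIRED_COLUMNS, *table.markers]
    cols += [median_column(m) for m in table.markers if median_column(m) in table.df.columns]
    table.df[cols].to_csv(path, index=False)


def write_labelled_table(table: CellTable, path) -> None:
    """Write a table with a ``label`` column of ';'-joined population names.

    The output keeps coordinates alongside labels so gated populations can be
    re-imported as spots over the source image (back-gating validation).
    """
    cols = [*REQUIRED_COLUMNS, *table.markers]
    cols += [median_column(m) for m in table.markers if median_column(m) in table.df.columns]
    out = table.df[cols].copy()
    out["label"] = [LABEL_SEP.join(sorted(s)) for s in table.df["labels"]]
    out.to_csv(path, index=False)


def follicles_to_geojson(follicles, path=None) -> dict:
    """Serialise follicle ROIs as a GeoJSON FeatureCollection (μm coordinates)."""
    features = []
    for roi in follicles:
        coords = [list(map(float, xy)) for xy in roi.boundary.exterior.coords]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [coords]},
            "properties": {
                "follicle_id": roi.follicle_id,
                "area_um2": float(roi.area_um2),
                "centroid": [float(roi.centroid[0]), float(roi.centroid[1])],
                "b_cell_count": int(roi.b_cell_count),
            },
        })
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection, indent=1))
    return collection


def follicles_from_geojson(path):
    """Read follicle ROIs back from GeoJSON written by :func:`follicles_to_geojson`."""
    from shapely.geometry import Polygon

    from .follicles import FollicleROI

    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        poly = Polygon(feat["geometry"]["coordinates"][0])
        props = feat["properties"]
        out.append(FollicleROI(
            follicle_id=props["follicle_id"],
            boundary=poly,
            area_um2=props.get("area_um2", poly.area),
            centroid=tuple(props.get("centroid", (poly.centroid.x, poly.centroid.y))),
            b_cell_count=props.get("b_cell_count", 0),
        ))
    return out
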