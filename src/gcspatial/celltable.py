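"""The segmented-cell table: the universal currency of the pipeline.

A :class:`CellTable` wraps a pandas DataFrame with one row per segmented
cell.  Required columns are ``cell_id``, ``tissue_id``, ``x_um``, ``y_um``
(projected centroid in micrometres), ``volume_um3`` and ``sphericity``, plus
one column of mean fluorescence intensity per panel marker.  Optional
``<marker>_median`` columns carry per-channel median voxel intensities and
are needed only by the uniform-staining artefact filter.

Population labels are hierarchical and a cell may carry several (e.g. a
follicular T cell is both ``CD3hi`` and ``TFH``), so labels live in a
``labels`` column of frozensets rather than a single categorical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

REQUIRED_COLUMNS = ("cell_id", "tissue_id", "x_um", "y_um", "volume_um3", "sphericity")
LABEL_SEP = ";"


def median_column(marker: str) -> str:
    return f"{marker}_median"


@dataclass
class CellTable:
    """One row per segmented cell; ``markers`` fixes the panel order."""

    df: pd.DataFrame
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "labels" not in self.df.columns:
            self.df = self.df.copy()
            self.df["labels"] = [frozenset()] * len(self.df)

    # -- basic introspection -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) array of x/y centroids in μm."""
        return self.df[["x_um", "y_um"]].to_numpy(dtype=float)

    def intensity_matrix(self, markers: list[str] | None = None) -> np.ndarray:
        return self.df[list(markers or self.markers)].to_numpy(dtype=float)

    def has_median_columns(self, markers: list[str] | None = None) -> bool:
        return all(median_column(m) in self.df.columns for m in (markers or self.markers))

    # -- labels --------------------------------------------------------------
    def has_label(self, label: str) -> np.ndarray:
        return np.fromiter((label in s for s in self.df["labels"]), dtype=bool, count=len(self.df))

    def add_labels(self, mask: np.ndarray, label: str) -> None:
        mask = np.asarray(mask, dtype=bool)
        col = self.df["labels"].tolist()
        self.df["labels"] = [s | {label} if m else s for s, m in zip(col, mask)]

    def clear_labels(self) -> None:
        self.df["labels"] = [frozenset()] * len(self.df)

    def subset(self, mask_or_label) -> "CellTable":
        if isinstance(mask_or_label, str):
            mask = self.has_label(mask_or_label)
        else:
            mask = np.asarray(mask_or_label, dtype=bool)
        return CellTable(self.df.loc[mask].reset_index(drop=True).copy(), list(self.markers))

    def copy(self) -> "CellTable":
        return CellTable(self.df.copy(), list(self.markers))

    # -- validation ----------------------------------------------------------
    def validate(self) -> "CellTable":
        """Check every table invariant, reporting *all* offending rows."""
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        missing += [m for m in self.markers if m not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

        offenders: list[tuple[int, str]] = []
        dup = self.df["cell_id"].duplicated(keep=False)
        for i in self.df.index[dup]:
            offenders.append((int(i), f"duplicate cell_id {self.df.at[i, 'cell_id']!r}"))

        numeric_cols = ["x_um", "y_um", "volume_um3", "sphericity"] + list(self.markers)
        for col in numeric_cols:
            vals = pd.to_numeric(self.df[col], errors="coerce")
            for i in self.df.index[vals.isna()]:
                offenders.append((int(i), f"non-numeric value in {col!r}"))
        if offenders:
            raise ValidationError(
                f"{len(offenders)} invalid value(s): "
                + "; ".join(f"row {i}: {msg}" for i, msg in offenders[:20]),
                offenders,
            )

        bad = ~np.isfinite(self.df["x_um"].astype(float)) | ~np.isfinite(self.df["y_um"].astype(float))
        for i in self.df.index[bad]:
            offenders.append((int(i), "non-finite coordinate"))
        for i in self.df.index[self.df["volume_um3"].astype(float) <= 0]:
            offenders.append((int(i), "volume_um3 must be > 0"))
        sph = self.df["sphericity"].astype(float)
        for i in self.df.index[(sph <= 0) | (sph > 1)]:
            offenders.append((int(i), "sphericity must be in (0, 1]"))
        neg = self.df[list(self.markers)].astype(float) < 0
        for col in self.markers:
            for i in self.df.index[neg[col]]:
                offenders.append((int(i), f"negative intensity in {col!r}"))
        if offenders:
            raise ValidationError(
                f"{len(offenders)} invalid value(s): "
                + "; ".join(f"row {i}: {msg}" for i, msg in offenders[:20]),
                offenders,
            )
        return self


def concat_tables(tables: list[CellTable]) -> CellTable:
    if not tables:
        raise ValueError("need at least one table")
    markers = tables[0].markers
    for t in tables[1:]:
        if t.markers != markers:
            raise SchemaError("cannot concatenate tables with different panels")
    return CellTable(pd.concat([t.df for t in tables], ignore_index=True), list(markers))
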