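"""Histocytometry gating: artefact/geometry filtering, automatic intensity
thresholds, hierarchical population labelling and population counting.

This is the in-silico counterpart of flow-style hand gating on segmented-cell
intensity tables.  Thresholds derived here are suggestions: a configured
manual threshold always wins, mirroring inspection-driven cut-offs on the
raw image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from .celltable import CellTable, median_column
from .config import ArtefactFilterParams, GeometryFilterParams
from .errors import ConfigurationError, InsufficientDataError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_artefacts(table: CellTable, params: ArtefactFilterParams,
                     markers: list[str] | None = None) -> tuple[CellTable, CellTable]:
    """Remove uniform-staining artefacts.

    A segmented event is called an artefact when, in at least
    ``params.m_channels`` of the tested markers, its mean intensity is at
    least ``params.min_level`` *and* mean and median voxel intensity agree to
    within ``params.epsilon`` (relative): genuine cells stain non-uniformly
    across their volume, so mean and median diverge.

    Returns ``(kept, removed)``; together they partition the input.
    """
    markers = list(markers or table.markers)
    missing = [m for m in markers if median_column(m) not in table.df.columns]
    if missing:
        raise ConfigurationError(
            "artefact filter needs per-marker median intensity columns; missing: "
            + ", ".join(median_column(m) for m in missing)
            + " — export medians or disable this filter")
    mean = table.df[markers].to_numpy(dtype=float)
    med = table.df[[median_column(m) for m in markers]].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        rel = np.abs(mean - med) / np.where(mean > 0, mean, np.nan)
    uniform = (mean >= params.min_level) & (rel <= params.epsilon)
    removed_mask = uniform.sum(axis=1) >= params.m_channels
    return table.subset(~removed_mask), table.subset(removed_mask)


def filter_geometry(table: CellTable, min_volume_um3: float, max_volume_um3: float,
                    min_sphericity: float) -> tuple[CellTable, CellTable]:
    """Remove events whose 3D-surface geometry is incompatible with an intact
    cell (debris, fragments, fused surfaces)."""
    if min_volume_um3 >= max_volume_um3:
        raise ConfigurationError("min_volume must be < max_volume")
    vol = table.df["volume_um3"].to_numpy(dtype=float)
    sph = table.df["sphericity"].to_numpy(dtype=float)
    removed = (vol < min_volume_um3) | (vol > max_volume_um3) | (sph < min_sphericity)
    return table.subset(~removed), table.subset(removed)


def filter_geometry_params(table: CellTable,
                           params: GeometryFilterParams) -> tuple[CellTable, CellTable]:
    return filter_geometry(table, params.min_volume_um3, params.max_volume_um3,
                           params.min_sphericity)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


@dataclass
class Threshold:
    value: float
    reliable: bool = True
    method: str = "mixture"


def derive_threshold(values, method: str = "mixture", seed: int = 0) -> Threshold:
    """Derive a hi/lo intensity cut-off from a bimodal intensity distribution.

    ``mixture``: two-component Gaussian mixture on log1p intensities; the
    threshold is the point between the component means where the posterior
    responsibilities are equal.  ``valley``: minimum of a kernel density
    estimate between the two largest modes.  When the data look unimodal
    (component means closer than half the pooled sigma) the threshold is
    flagged unreliable and set at the 99th percentile.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 50:
        raise InsufficientDataError(f"need >= 50 values to derive a threshold, got {values.size}")
    if np.any(values < 0):
        raise ValueError("intensities must be nonnegative")
    x = np.log1p(values)

    if np.ptp(x) < 1e-12:
        warnings.warn("constant intensities: threshold unreliable")
        return Threshold(float(np.expm1(np.percentile(x, 99))), reliable=False, method=method)

    if method == "mixture":
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
        gm.fit(x.reshape(-1, 1))
        mu = gm.means_.ravel()
        sd = np.sqrt(gm.covariances_.ravel())
        w = gm.weights_
        order = np.argsort(mu)
        mu, sd, w = mu[order], sd[order], w[order]
        pooled = np.sqrt(w @ (sd ** 2))
        if abs(mu[1] - mu[0]) < 0.5 * pooled:
            warnings.warn("intensity distribution looks unimodal: threshold unreliable")
            return Threshold(float(np.expm1(np.percentile(x, 99))), reliable=False, method=method)
        grid = np.linspace(mu[0], mu[1], 2001)
        resp = gm.predict_proba(grid.reshape(-1, 1))
        lo_comp = int(np.argmin(gm.means_.ravel()))
        diff = resp[:, lo_comp] - resp[:, 1 - lo_comp]
        sign = np.signbit(diff)
        crossings = np.nonzero(sign[1:] != sign[:-1])[0]
        t_log = grid[crossings[0]] if crossings.size else 0.5 * (mu[0] + mu[1])
        # a genuine hi/lo split shows a density valley at the cut; if the
        # mixture density there rivals the component peaks the data are
        # effectively unimodal and the cut is arbitrary
        def mix_pdf(v):
            return float(np.exp(gm.score_samples(np.array([[v]])))[0])
        if mix_pdf(t_log) > 0.8 * min(mix_pdf(mu[0]), mix_pdf(mu[1])):
            warnings.warn("no density valley between modes: threshold unreliable")
            return Threshold(float(np.expm1(np.percentile(x, 99))), reliable=False, method=method)
        return Threshold(float(np.expm1(t_log)), reliable=True, method="mixture")

    if method == "valley":
        kde = gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 1024)
        dens = kde(grid)
        # local maxima
        peaks = np.nonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:]))[0] + 1
        if peaks.size < 2:
            warnings.warn("fewer than two density modes: threshold unreliable")
            return Threshold(float(np.expm1(np.percentile(x, 99))), reliable=False, method=method)
        top2 = peaks[np.argsort(dens[peaks])[-2:]]
        lo_m, hi_m = np.sort(top2)
        valley = lo_m + int(np.argmin(dens[lo_m:hi_m + 1]))
        return Threshold(float(np.expm1(grid[valley])), reliable=True, method="valley")

    raise ValueError(f"unknown threshold method {method!r}")


def derive_thresholds(table: CellTable, markers: list[str], method: str = "mixture",
                      seed: int = 0) -> dict[str, Threshold]:
    return {m: derive_threshold(table.df[m].to_numpy(dtype=float), method=method, seed=seed)
            for m in markers}


# ---------------------------------------------------------------------------
# gate tree
# ---------------------------------------------------------------------------


@dataclass
class GateNode:
    """One hi/lo split on a marker; ``hi`` keeps intensity >= threshold
    (closed), ``lo`` keeps intensity < threshold."""

    marker: str
    direction: str = "hi"
    threshold: float | None = None
    population: str | None = None
    children: list["GateNode"] = field(default_factory=list)

    def mask(self, table: CellTable) -> np.ndarray:
        if self.marker not in table.df.columns:
            raise ConfigurationError(f"gate references marker {self.marker!r} absent from table")
        if self.threshold is None:
            raise ConfigurationError(f"no threshold set for gate on {self.marker!r}")
        v = table.df[self.marker].to_numpy(dtype=float)
        return v >= self.threshold if self.direction == "hi" else v < self.threshold


@dataclass
class GateTree:
    """Hierarchical gating scheme: all cells enter at the root; a cell earns
    the population name of every node on every root-to-node path whose
    conditions all hold, so child labels imply parent labels."""

    roots: list[GateNode] = field(default_factory=list)

    @classmethod
    def from_dict(cls, spec: list | dict) -> "GateTree":
        def build(node: dict) -> GateNode:
            return GateNode(
                marker=node["marker"],
                direction=node.get("direction", "hi"),
                threshold=node.get("threshold"),
                population=node.get("population"),
                children=[build(c) for c in node.get("children", [])],
            )
        nodes = spec if isinstance(spec, list) else [spec]
        tree = cls([build(n) for n in nodes])
        names = [p for p in tree.populations()]
        if len(names) != len(set(names)):
            raise ConfigurationError("population names in the gate tree must be unique")
        return tree

    def populations(self) -> list[str]:
        out = []

        def walk(node):
            if node.population:
                out.append(node.population)
            for c in node.children:
                walk(c)
        for r in self.roots:
            walk(r)
        return out

    def fill_thresholds(self, thresholds: dict[str, "Threshold | float"],
                        overwrite: bool = False) -> "GateTree":
        """Set node thresholds from a marker->threshold map; manually set
        node thresholds are kept unless ``overwrite``."""
        def walk(node):
            if (node.threshold is None or overwrite) and node.marker in thresholds:
                t = thresholds[node.marker]
                node.threshold = float(t.value if isinstance(t, Threshold) else t)
            for c in node.children:
                walk(c)
        for r in self.roots:
            walk(r)
        return self


def apply_gates(table: CellTable, tree: GateTree) -> CellTable:
    """Assign hierarchical population labels; returns a labelled copy."""
    out = table.copy()

    def walk(node: GateNode, parent_mask: np.ndarray):
        m = parent_mask & node.mask(out)
        if node.population:
            out.add_labels(m, node.population)
        for c in node.children:
            walk(c, m)

    everyone = np.ones(len(out), dtype=bool)
    for root in tree.roots:
        walk(root, everyone)
    return out


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def _combo_mask(table: CellTable, combo: dict[str, bool]) -> np.ndarray:
    mask = np.ones(len(table), dtype=bool)
    for label, required in combo.items():
        has = table.has_label(label)
        mask &= has if required else ~has
    return mask


def parse_combo(s: str) -> dict[str, bool]:
    """Parse ``"IL21+IL4-"`` into ``{"IL21": True, "IL4": False}``."""
    out, token = {}, ""
    for ch in s:
        if ch in "+-":
            if not token:
                raise ValueError(f"malformed combination {s!r}")
            out[token] = (ch == "+")
            token = ""
        else:
            token += ch
    if token:
        raise ValueError(f"combination {s!r} must end with + or -")
    return out


def combo_name(combo: dict[str, bool]) -> str:
    return "".join(f"{k}{'+' if v else '-'}" for k, v in combo.items())


def count_populations(table: CellTable, by: str = "tissue",
                      populations: list[str] | None = None,
                      combos: list[dict[str, bool] | str] | None = None,
                      parent: str | None = None):
    """Count labelled populations (or label combinations) per group.

    ``by`` groups by ``tissue`` (tissue_id), ``follicle`` (F:<id> labels) or
    ``compartment`` (F/EF labels).  ``combos`` are conjunctions over labels,
    e.g. ``"IL21+IL4-"``; when they partition ``parent``, frequencies sum to
    100% within each group.  Frequencies are relative to ``parent`` when
    given, else to the group size.
    """
    import pandas as pd

    known = set()
    for s in table.df["labels"]:
        known |= set(s)

    if combos is not None:
        combos = [parse_combo(c) if isinstance(c, str) else c for c in combos]
        for c in combos:
            unknown = [k for k in c if k not in known]
            if unknown:
                raise ValueError(
                    f"unknown label(s) {unknown} in combination; known labels: "
                    + ", ".join(sorted(known)))
        targets = [(combo_name(c), _combo_mask(table, c)) for c in combos]
    else:
        populations = populations if populations is not None else sorted(known)
        targets = [(p, table.has_label(p)) for p in populations]

    if by == "tissue":
        groups = table.df["tissue_id"].astype(str)
    elif by == "compartment":
        groups = np.where(table.has_label("F"), "F", np.where(table.has_label("EF"), "EF", ""))
        groups = pd.Series(groups, index=table.df.index)
    elif by == "follicle":
        def fol(s):
            ids = [l.split(":", 1)[1] for l in s if l.startswith("F:")]
            return ids[0] if ids else ""
        groups = pd.Series([fol(s) for s in table.df["labels"]], index=table.df.index)
    else:
        raise ValueError(f"unknown grouping {by!r}")

    parent_mask = table.has_label(parent) if parent else np.ones(len(table), dtype=bool)
    rows = []
    for g in (sorted(groups.unique()) if len(table) else []):
        in_group = (groups == g).to_numpy()
        denom = int((in_group & parent_mask).sum())
        for name, mask in targets:
            count = int((in_group & mask).sum())
            rows.append({
                by: g, "population": name, "count": count,
                "frequency_pct": 100.0 * count / denom if denom else np.nan,
            })
    if not rows:
        rows = [{by: "", "population": name, "count": 0, "frequency_pct": np.nan}
                for name, _ in targets]
    return pd.DataFrame(rows)
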