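"""Analysis configuration: panel roles, gates, filters, follicle/spatial/cluster
parameters.  Mirrors a YAML file field-for-field; every module takes the piece
it needs so a single config drives the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class ArtefactFilterParams:
    """Uniform-staining artefact rule: a cell is an artefact when, in at least
    ``m_channels`` channels above ``min_level``, mean and median voxel
    intensity agree to within ``epsilon`` (relative)."""

    epsilon: float = 0.05
    m_channels: int = 4
    min_level: float = 10.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigurationError("artefact epsilon must be > 0")
        if self.m_channels < 2:
            raise ConfigurationError("artefact m_channels must be >= 2")


@dataclass
class GeometryFilterParams:
    min_volume_um3: float = 50.0
    max_volume_um3: float = 4000.0
    min_sphericity: float = 0.3

    def __post_init__(self):
        if self.min_volume_um3 >= self.max_volume_um3:
            raise ConfigurationError("geometry filter: min_volume must be < max_volume")


@dataclass
class FollicleParams:
    kde_bandwidth_um: float = 30.0
    density_threshold_frac: float = 0.2
    min_b_cells: int = 20

    def __post_init__(self):
        if not 0 < self.density_threshold_frac < 1:
            raise ConfigurationError("density_threshold_frac must be in (0, 1)")
        if self.min_b_cells < 1:
            raise ConfigurationError("min_b_cells must be >= 1")


@dataclass
class SpatialParams:
    distance_grid_n: int = 200
    d_max_um: float | None = None
    edge_correction: bool = False
    min_cells_per_subset: int = 20

    def __post_init__(self):
        if self.min_cells_per_subset < 1:
            raise ConfigurationError("min_cells_per_subset must be >= 1")


@dataclass
class ClusterParams:
    n_downsample: int = 2200
    som_grid: tuple[int, int] = (10, 10)
    n_metaclusters: int = 8
    epochs: int = 20
    seed: int = 0

    def __post_init__(self):
        self.som_grid = tuple(self.som_grid)
        if self.n_downsample < 1:
            raise ConfigurationError("n_downsample must be >= 1")
        if min(self.som_grid) < 2:
            raise ConfigurationError("SOM grid dimensions must be >= 2")


@dataclass
class AnalysisConfig:
    """Full pipeline configuration.

    ``panel`` maps marker name -> role, one of ``phenotype`` (used in gates and
    clustering), ``registration`` (alignment channels, ignored by analysis) or
    ``exclude_norm`` (kept in tables but excluded from normalisation).
    ``gates`` holds the nested gate-tree specification consumed by
    :class:`gcspatial.gating.GateTree`.
    """

    panel: dict[str, str] = field(default_factory=dict)
    gates: dict | None = None
    artefact: ArtefactFilterParams = field(default_factory=ArtefactFilterParams)
    geometry_filter: GeometryFilterParams = field(default_factory=GeometryFilterParams)
    follicles: FollicleParams = field(default_factory=FollicleParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    alpha: float = 0.05

    @property
    def phenotype_markers(self) -> list[str]:
        return [m for m, role in self.panel.items() if role == "phenotype"]

    @property
    def markers(self) -> list[str]:
        return [m for m, role in self.panel.items() if role != "registration"]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = dict(d)
        for key, sub in [("artefact", ArtefactFilterParams),
                         ("geometry_filter", GeometryFilterParams),
                         ("follicles", FollicleParams),
                         ("spatial", SpatialParams),
                         ("cluster", ClusterParams)]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
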