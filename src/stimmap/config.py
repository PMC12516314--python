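"""Run configuration: every tunable of the pipeline in one serializable object."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grid import VoxelGrid
from .synth import DEFAULT_GRID, SOURSPOT_MM, SWEETSPOT_MM, CohortConfig, EffectField, plant_effect_field
from .vta import VTAParams

__all__ = ["MappingParams", "ReviewGrid", "RunConfig"]


@dataclass(frozen=True)
class MappingParams:
    """Voxelwise mapping and histogram-model settings."""

    alpha: float = 0.05  # significance threshold for sweet/sour voxels
    min_cluster: int = 50  # cluster size must strictly exceed this
    min_coverage: int = 2  # subjects required on each side of the voxel split
    connectivity: int = 6  # 6 | 18 | 26 neighbourhood for clustering
    n_bins: int = 15  # interference-histogram bins over [-1, +1]
    smoothing_kernel: int = 3  # display-only box kernel, voxels


@dataclass(frozen=True)
class ReviewGrid:
    """Enumeration grid of the in-silico monopolar review."""

    amplitudes: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)  # mA
    pulse_width_us: float = 60.0
    mcid: float = 5.0  # minimal clinically important difference, % points


@dataclass(frozen=True)
class GridSpec:
    """Shape/spacing/origin of the shared analysis lattice."""

    shape: tuple[int, int, int] = DEFAULT_GRID.shape
    spacing: tuple[float, float, float] = DEFAULT_GRID.spacing
    origin: tuple[float, float, float] = DEFAULT_GRID.origin

    def build(self) -> VoxelGrid:
        return VoxelGrid(self.shape, self.spacing, self.origin)


DEFAULT_BLOBS = (
    (SWEETSPOT_MM, 4.0, +0.9),
    (SOURSPOT_MM, 4.5, -0.71),
)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration; serializes losslessly to YAML/JSON."""

    grid: GridSpec = field(default_factory=GridSpec)
    blobs: tuple = DEFAULT_BLOBS  # planted effect blobs: (centre mm, scale mm, peak)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mapping: MappingParams = field(default_factory=MappingParams)
    vta: VTAParams = field(default_factory=VTAParams)
    review: ReviewGrid = field(default_factory=ReviewGrid)
    seed: int = 0

    def build_effect_field(self) -> EffectField:
        return plant_effect_field(self.grid.build(), self.blobs)

    def to_dict(self) -> dict:
        # json round-trip turns nested tuples into plain lists for YAML/JSON
        return json.loads(json.dumps(asdict(self)))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def _tuplify(d: dict, keys) -> dict:
            out = dict(d)
            for k in keys:
                if k in out and isinstance(out[k], list):
                    out[k] = tuple(out[k])
            return out

        grid = _tuplify(data.get("grid", {}), ["shape", "spacing", "origin"])
        cohort = _tuplify(data.get("cohort", {}), ["target_centre", "amplitude_range"])
        review = _tuplify(data.get("review", {}), ["amplitudes"])
        blobs = tuple(
            (tuple(centre), float(scale), float(peak))
            for centre, scale, peak in data.get("blobs", DEFAULT_BLOBS)
        )
        cohort_cfg = CohortConfig(**cohort)
        return cls(
            grid=GridSpec(**grid),
            blobs=blobs,
            cohort=cohort_cfg,
            mapping=MappingParams(**data.get("mapping", {})),
            vta=VTAParams(**data.get("vta", {})),
            review=ReviewGrid(**review),
            # the cohort stream is the pipeline's only randomness source, so
            # an unspecified top-level seed follows it
            seed=int(data.get("seed", cohort_cfg.seed)),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)
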