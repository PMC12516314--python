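"""Synthetic cohort generator.

Emulates the statistical structure the mapping analysis assumes: a bounded
pallidal target region in template space, bilateral quadripolar leads placed
near a target point with Gaussian jitter, spherical VTAs whose size grows
with amplitude and pulse width, and percentage motor outcomes that are a
noisy linear function of the VTA overlap with a planted spatial effect
field. Every quantity flows from one integer seed, split deterministically
per subject, so a generated cohort is byte-reproducible and growing the
cohort never perturbs earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import Cohort, Subject
from .grid import VoxelGrid
from .vta import (
    LeadGeometry,
    StimSetting,
    VTAParams,
    ensure_left,
    mirror_to_left,
    rasterize_vta,
    vta_radius,
)

__all__ = [
    "EffectField",
    "CohortConfig",
    "default_grid",
    "default_effect_field",
    "plant_effect_field",
    "place_leads",
    "simulate_cohort",
]

# Left-hemisphere analysis box, 1 mm isotropic, 40 x 50 x 40 mm around the
# posteroventral pallidum; the antiparkinsonian sweetspot reference point
# sits well inside.
DEFAULT_GRID = VoxelGrid(shape=(40, 50, 40), spacing=(1.0, 1.0, 1.0), origin=(-38.0, -32.0, -27.0))

# template coordinate of the planted beneficial blob: the ventromedial GPi
# sweetspot reported for off-period motor improvement
SWEETSPOT_MM = (-18.4, -7.3, -7.0)
# detrimental blob dorsal to it, along the lead trajectory towards GPe
SOURSPOT_MM = (-16.5, -5.5, -0.5)


def default_grid() -> VoxelGrid:
    return DEFAULT_GRID


@dataclass(frozen=True)
class EffectField:
    """Planted ground-truth spatial effect: per-voxel values in [-1, +1].

    The field is a sum of Gaussian blobs (centre mm, spatial scale mm, peak
    in [-1, 1]), clipped to [-1, +1]. It stands in for the beneficial /
    detrimental structure a probabilistic map should recover.
    """

    grid: VoxelGrid
    values: np.ndarray
    blob_specs: tuple = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise ValueError(f"field shape {vals.shape} does not match grid {self.grid.shape}")
        if np.any(vals < -1) or np.any(vals > 1):
            raise ValueError("effect-field values must lie in [-1, +1]")
        object.__setattr__(self, "values", vals)

    def sample_flat(self, flat_indices: np.ndarray) -> np.ndarray:
        return self.values.ravel()[flat_indices]


def plant_effect_field(grid: VoxelGrid, blob_specs) -> EffectField:
    """Plant Gaussian blobs on the grid and clip the sum to [-1, +1].

    ``blob_specs``: iterable of (centre_mm, scale_mm, peak). Each blob
    contributes peak * exp(-d^2 / (2 scale^2)); an empty list yields the
    all-zero field.
    """
    values = np.zeros(grid.shape, dtype=float)
    specs = []
    for i, (centre, scale, peak) in enumerate(blob_specs):
        centre = tuple(float(c) for c in centre)
        if not grid.contains_world(centre):
            raise ValueError(f"blob {i} centre {centre} lies outside the grid")
        if not -1.0 <= peak <= 1.0:
            raise ValueError(f"blob {i} peak {peak} outside [-1, 1]")
        if scale <= 0:
            raise ValueError(f"blob {i} scale must be > 0 mm, got {scale}")
        d = grid.distance_to_point(centre)
        values += peak * np.exp(-(d**2) / (2.0 * scale**2))
        specs.append((centre, float(scale), float(peak)))
    return EffectField(grid=grid, values=np.clip(values, -1.0, 1.0), blob_specs=tuple(specs))


def default_effect_field(grid: VoxelGrid | None = None) -> EffectField:
    """One beneficial and one detrimental blob along the lead trajectory."""
    grid = grid or DEFAULT_GRID
    return plant_effect_field(
        grid,
        [
            (SWEETSPOT_MM, 4.0, +0.9),
            (SOURSPOT_MM, 4.5, -0.71),
        ],
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults define the emulated study conditions.

    ``outcome_scale`` maps the mean planted-field value under a subject's
    VTA pair to a percentage improvement, and ``noise_sd`` adds unexplained
    clinical variability (rater noise, disease progression) in percentage
    points. The defaults were calibrated once so the generated cohort's
    improvement distribution has mean/SD near 16/37 %.
    """

    n_subjects: int = 40
    target_centre: tuple[float, float, float] = SWEETSPOT_MM
    lead_jitter_sd: float = 1.5  # mm, isotropic placement error
    lead_tilt_deg: float = 20.0  # polar angle of the trajectory from vertical
    lead_azimuth_deg: float = 45.0
    contact_pitch: float = 2.0  # mm centre-to-centre
    amplitude_range: tuple[float, float] = (1.0, 4.0)  # mA, uniform
    pulse_width_us: float = 60.0
    frequency_hz: float = 130.0
    outcome_scale: float = 120.0  # % per unit mean field value
    noise_sd: float = 23.0  # percentage points
    baseline_mean: float = 53.0  # baseline motor score, points
    baseline_sd: float = 17.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError(f"need at least 4 subjects, got {self.n_subjects}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[1] < self.amplitude_range[0]:
            raise ValueError(f"invalid amplitude range {self.amplitude_range}")

    def to_dict(self) -> dict:
        return asdict(self)


def _trajectory_direction(tilt_deg: float, azimuth_deg: float, side: str) -> np.ndarray:
    """Ventral-to-dorsal unit vector of the lead trajectory.

    The polar tilt is taken from the +z axis; the azimuth rotates in the
    axial plane. The x component flips for the right hemisphere so the two
    implants are mirror images.
    """
    theta = np.deg2rad(tilt_deg)
    phi = np.deg2rad(azimuth_deg)
    d = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])
    if side == "right":
        d[0] = -d[0]
    return d


def place_leads(config: CohortConfig, side: str, rng: np.random.Generator) -> LeadGeometry:
    """Place one quadripolar lead near the (side-appropriate) target point.

    Contact 0 (most ventral) sits at the target centre, displaced by an
    isotropic Gaussian jitter; contacts 1-3 follow along the tilted
    trajectory at the configured pitch. With zero jitter, contact 0 lands
    exactly on the target.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    target = np.asarray(config.target_centre, dtype=float)
    if side == "right":
        target = mirror_to_left(target)  # involution: mirrors the left target to the right
    jitter = rng.normal(0.0, config.lead_jitter_sd, size=3) if config.lead_jitter_sd > 0 else np.zeros(3)
    direction = _trajectory_direction(config.lead_tilt_deg, config.lead_azimuth_deg, side)
    base = target + jitter
    centres = base[None, :] + np.arange(4)[:, None] * config.contact_pitch * direction[None, :]
    return LeadGeometry(contact_centres=centres, pitch=config.contact_pitch, side=side)


def _subject_outcome(field: EffectField, masks: dict, outcome_scale: float) -> float:
    """Noise-free percentage improvement: scaled mean field value under the
    VTA pair, pooling voxels with multiplicity across the two mirrored VTAs."""
    flat = np.concatenate([m.flat_indices for m in masks.values()])
    if flat.size == 0:
        raise ValueError("empty VTA pair: cannot attach an outcome")
    return float(outcome_scale * field.sample_flat(flat).mean())


def simulate_cohort(
    config: CohortConfig,
    effect_field: EffectField | None = None,
    vta_params: VTAParams | None = None,
) -> Cohort:
    """Generate a cohort whose outcomes are driven by the planted field.

    Per subject: bilateral leads with placement jitter, one uniformly chosen
    active contact per side, amplitude drawn uniformly from the configured
    range at the configured pulse width, spherical VTAs rasterized on the
    shared grid with the right side mirrored to the left, and

        improvement % = outcome_scale * mean(field under the VTA pair)
                        + Normal(0, noise_sd).

    Baseline scores are drawn from Normal(baseline_mean, baseline_sd)
    truncated to [10, 100]; the post score is back-filled so the percentage
    change reproduces the simulated improvement exactly.
    """
    field = effect_field if effect_field is not None else default_effect_field()
    grid = field.grid
    vta_params = vta_params or VTAParams()
    if not grid.contains_world(config.target_centre):
        raise ValueError(f"target centre {config.target_centre} outside the grid")

    # one spawned stream per subject: adding subject n+1 never changes 1..n
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    subjects = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        leads, settings, masks = {}, {}, {}
        for side in ("left", "right"):
            lead = place_leads(config, side, rng)
            contact = int(rng.integers(0, 4))
            amplitude = float(rng.uniform(*config.amplitude_range))
            setting = StimSetting(
                contact_index=contact,
                amplitude=amplitude,
                pulse_width_us=config.pulse_width_us,
                frequency_hz=config.frequency_hz,
            )
            if amplitude <= 0:
                raise ValueError(f"subject {i} side {side}: zero amplitude yields an empty VTA")
            radius = vta_radius(amplitude, setting.pulse_width_us, vta_params)
            centre = ensure_left(lead.contact_centres[contact], side)
            mask = rasterize_vta(
                grid, centre, radius, provenance={"subject": i, "side": side, "setting": setting}
            )
            leads[side], settings[side], masks[side] = lead, setting, mask

        improvement = _subject_outcome(field, masks, config.outcome_scale)
        if config.noise_sd > 0:
            improvement += float(rng.normal(0.0, config.noise_sd))

        pre = float(np.clip(rng.normal(config.baseline_mean, config.baseline_sd), 10.0, 100.0))
        post = pre * (1.0 - improvement / 100.0)
        subjects.append(
            Subject(
                subject_id=f"S{i:03d}",
                score_pre=pre,
                score_post=post,
                lead_geometry=leads,
                settings=settings,
                vta_masks=masks,
            )
        )
    return Cohort(grid=grid, subjects=subjects, provenance={"config": config.to_dict()})
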