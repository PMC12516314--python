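"""Parametric stimulation-field surrogate.

The field's finite-element axon-activation models are replaced here by a
documented parametric surrogate with the same interface: the volume of
tissue activated (VTA) around an active contact is a sphere whose radius
grows with the square root of the stimulation intensity and a power of the
pulse width, and the electric field magnitude is that of a point source in
a homogeneous medium. Constants are exposed so they can be recalibrated
against any activation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "LeadGeometry",
    "StimSetting",
    "VTAMask",
    "EFieldMap",
    "VTAParams",
    "vta_radius",
    "rasterize_vta",
    "mirror_to_left",
    "efield_magnitude",
]

N_CONTACTS = 4  # quadripolar, non-directional


@dataclass(frozen=True)
class LeadGeometry:
    """A quadripolar DBS lead: four collinear contact centres, ventral to dorsal."""

    contact_centres: np.ndarray  # (4, 3) world mm, contact 0 most ventral
    pitch: float  # centre-to-centre spacing, mm
    side: str  # "left" | "right"
    model_name: str = "generic-quadripolar"

    def __post_init__(self) -> None:
        centres = np.asarray(self.contact_centres, dtype=float)
        if centres.shape != (N_CONTACTS, 3):
            raise ValueError(f"expected {N_CONTACTS} contact centres, got shape {centres.shape}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        # collinearity: every contact must lie on the line through contacts 0 and 1
        d = centres[1] - centres[0]
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("contacts 0 and 1 coincide")
        u = d / norm
        resid = (centres - centres[0]) - np.outer((centres - centres[0]) @ u, u)
        if np.abs(resid).max() > 1e-9:
            raise ValueError("contact centres are not collinear")
        object.__setattr__(self, "contact_centres", centres)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from ventral (contact 0) to dorsal (contact 3)."""
        d = self.contact_centres[-1] - self.contact_centres[0]
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class StimSetting:
    """One monopolar (or collapsed-bipolar) stimulation setting."""

    contact_index: int
    amplitude: float  # stimulation intensity
    pulse_width_us: float = 60.0
    frequency_hz: float = 130.0
    amplitude_unit: str = "mA"  # "mA" | "V"
    polarity: str = "cathodic"  # "cathodic" | "bipolar"

    def __post_init__(self) -> None:
        if not 0 <= int(self.contact_index) < N_CONTACTS:
            raise ValueError(f"contact_index must be 0..{N_CONTACTS - 1}, got {self.contact_index}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.pulse_width_us <= 0:
            raise ValueError(f"pulse width must be > 0 us, got {self.pulse_width_us}")
        if self.frequency_hz <= 0:
            raise ValueError(f"frequency must be > 0 Hz, got {self.frequency_hz}")
        if self.amplitude_unit not in ("mA", "V"):
            raise ValueError(f"amplitude_unit must be 'mA' or 'V', got {self.amplitude_unit!r}")


@dataclass(frozen=True)
class VTAMask:
    """A set of activated voxels on a shared grid."""

    grid: VoxelGrid
    indices: np.ndarray  # (k, 3) int voxel indices
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int).reshape(-1, 3)
        if idx.size and not np.all(self.grid.contains_index(idx)):
            raise ValueError("VTA mask contains voxel indices outside the grid")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.shape[0])

    @property
    def flat_indices(self) -> np.ndarray:
        """Raveled (C-order) voxel indices; convenient for coverage bookkeeping."""
        return np.ravel_multi_index(self.indices.T, self.grid.shape)

    def to_array(self) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=np.uint8)
        if len(self):
            vol[tuple(self.indices.T)] = 1
        return vol

    def world_coordinates(self) -> np.ndarray:
        return self.grid.index_to_world(self.indices)


@dataclass(frozen=True)
class EFieldMap:
    """Point-source electric-field magnitude on the grid (V/mm)."""

    grid: VoxelGrid
    magnitude: np.ndarray  # full-shape array, V/mm
    source_centre: tuple[float, float, float]
    sigma: float  # conductivity, S/mm


@dataclass(frozen=True)
class VTAParams:
    """Constants of the parametric VTA-radius surrogate.

    ``radius_at_ref`` is the sphere radius produced by the reference
    intensity ``ref_amplitude`` at a 60 us pulse width; ``pulse_width_exp``
    controls how the radius grows with pulse width. The same calibration is
    applied to current-mode (mA) and voltage-mode (V) settings, with the
    unit recorded on each setting.
    """

    radius_at_ref: float = 2.5  # mm at the reference intensity, 60 us
    ref_amplitude: float = 3.0  # mA (or V for voltage-mode leads)
    pulse_width_exp: float = 0.3
    ref_pulse_width_us: float = 60.0


def vta_radius(amplitude: float, pulse_width_us: float, params: VTAParams | None = None) -> float:
    """Radius (mm) of the spherical VTA surrogate.

    r = radius_at_ref * sqrt(amplitude / ref_amplitude)
        * (pulse_width / ref_pulse_width) ** pulse_width_exp

    Square-root growth in intensity reflects the roughly quadratic fall-off
    of the activating field with distance; the pulse-width power captures
    the lower activation threshold of longer pulses.
    """
    params = params or VTAParams()
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    if pulse_width_us <= 0:
        raise ValueError(f"pulse width must be > 0 us, got {pulse_width_us}")
    if amplitude == 0:
        return 0.0
    return float(
        params.radius_at_ref
        * np.sqrt(amplitude / params.ref_amplitude)
        * (pulse_width_us / params.ref_pulse_width_us) ** params.pulse_width_exp
    )


def rasterize_vta(grid: VoxelGrid, centre, radius: float, provenance: dict | None = None) -> VTAMask:
    """Voxelize a spherical VTA: voxels whose centre lies within ``radius`` (inclusive).

    A zero radius yields an empty mask. If the radius is positive but smaller
    than the distance to any voxel centre, the nearest voxel is included so a
    nonzero stimulation never maps to an empty volume.
    """
    centre = np.asarray(centre, dtype=float)
    if not grid.contains_world(centre):
        raise ValueError(f"VTA centre {tuple(centre)} lies outside the grid")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return VTAMask(grid, np.empty((0, 3), dtype=int), provenance or {})

    # restrict to the bounding box of the sphere before the distance test
    lo = np.maximum(np.floor(grid.world_to_index(centre - radius)).astype(int), 0)
    hi = np.minimum(np.ceil(grid.world_to_index(centre + radius)).astype(int), np.asarray(grid.shape) - 1)
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    if idx.size == 0:
        idx = grid.nearest_index(centre).reshape(1, 3)
        return VTAMask(grid, idx, provenance or {})
    dist = np.linalg.norm(grid.index_to_world(idx) - centre, axis=1)
    inside = idx[dist <= radius + 1e-12]
    if inside.shape[0] == 0:
        inside = grid.nearest_index(centre).reshape(1, 3)
    return VTAMask(grid, inside, provenance or {})


def mirror_to_left(obj):
    """Mirror across the mid-sagittal plane (x = 0 mm): x -> -x.

    Accepts a world coordinate (or array of coordinates) or a :class:`VTAMask`.
    Coordinates already in the left hemisphere (x <= 0) are flipped like any
    other point when passed individually — use :func:`ensure_left` for the
    conditional convention. For masks the grid must be symmetric about x = 0
    so the mirrored voxel set lives on the same lattice.
    """
    if isinstance(obj, VTAMask):
        grid = obj.grid
        if not grid.is_symmetric_about_midsagittal():
            raise ValueError(
                "grid is not symmetric about the mid-sagittal plane x=0; "
                "mask mirroring would leave the lattice"
            )
        mirrored = obj.indices.copy()
        mirrored[:, 0] = (grid.shape[0] - 1) - mirrored[:, 0]
        return VTAMask(grid, mirrored, dict(obj.provenance, mirrored=True))
    coords = np.asarray(obj, dtype=float).copy()
    coords[..., 0] = -coords[..., 0]
    return coords


def ensure_left(obj, side: str):
    """Return ``obj`` mirrored to the left hemisphere if it is on the right."""
    if side == "right":
        return mirror_to_left(obj)
    return obj


def efield_magnitude(grid: VoxelGrid, centre, current: float, sigma: float) -> EFieldMap:
    """Point-source electric-field magnitude |E|(r) = I / (4 pi sigma r^2).

    With ``current`` in amperes and ``sigma`` in S/mm the magnitude comes out
    in V/mm; any consistent unit pair works, and all downstream use is
    rank-based so the overall scale never matters. The singularity at the
    source is capped at the magnitude attained half a voxel diagonal away.
    """
    if current < 0:
        raise ValueError(f"current must be >= 0, got {current}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    centre = np.asarray(centre, dtype=float)
    r = grid.distance_to_point(centre)
    r_min = grid.voxel_diagonal / 2.0
    r_eff = np.maximum(r, r_min)
    mag = current / (4.0 * np.pi * sigma * r_eff**2)
    return EFieldMap(grid=grid, magnitude=mag, source_centre=tuple(centre), sigma=sigma)
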