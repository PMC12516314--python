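"""Subject and cohort containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .vta import LeadGeometry, StimSetting, VTAMask

__all__ = ["Subject", "Cohort"]

SIDES = ("left", "right")


@dataclass
class Subject:
    """One patient: motor scores, stimulation settings, lead geometry, VTAs.

    ``vta_masks`` hold the *mirrored* pair — both hemispheres expressed in
    left-hemisphere coordinates so the whole cohort shares one target model.
    """

    subject_id: str
    score_pre: float
    score_post: float
    centre: str = "synthetic"
    scale: str = "MDS-UPDRS-III"
    state: str = "MED-OFF"
    lead_geometry: dict[str, LeadGeometry] = field(default_factory=dict)
    settings: dict[str, StimSetting] = field(default_factory=dict)
    vta_masks: dict[str, VTAMask] = field(default_factory=dict)
    led_pre: float | None = None
    led_post: float | None = None
    cdrs_pre: float | None = None
    cdrs_post: float | None = None

    def __post_init__(self) -> None:
        if self.score_pre <= 0:
            raise ValueError(
                f"subject {self.subject_id}: score_pre must be > 0, got {self.score_pre}"
            )

    @property
    def pct_improvement(self) -> float:
        """Percentage reduction of the motor score; positive = improvement."""
        return 100.0 * (self.score_pre - self.score_post) / self.score_pre

    def vta_pair(self) -> tuple[VTAMask, VTAMask]:
        return self.vta_masks["left"], self.vta_masks["right"]

    def covered_flat_indices(self) -> np.ndarray:
        """Unique raveled voxel indices covered by either VTA of the pair."""
        parts = [m.flat_indices for m in self.vta_masks.values() if len(m)]
        if not parts:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate(parts))


@dataclass
class Cohort:
    """All subjects on one shared grid, with generation provenance."""

    grid: VoxelGrid
    subjects: list[Subject]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids are not unique")
        for s in self.subjects:
            for mask in s.vta_masks.values():
                if mask.grid.shape != self.grid.shape or mask.grid.origin != self.grid.origin:
                    raise ValueError(f"subject {s.subject_id}: VTA grid differs from cohort grid")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def outcomes(self, outcome_column: str = "pct_improvement") -> np.ndarray:
        """Outcome vector; any per-subject attribute or derived % change."""
        if outcome_column == "pct_improvement":
            return np.array([s.pct_improvement for s in self.subjects], dtype=float)
        if outcome_column == "led_pct_change":
            return np.array(
                [100.0 * (s.led_pre - s.led_post) / s.led_pre for s in self.subjects],
                dtype=float,
            )
        if outcome_column == "cdrs_pct_change":
            return np.array(
                [100.0 * (s.cdrs_pre - s.cdrs_post) / s.cdrs_pre for s in self.subjects],
                dtype=float,
            )
        return np.array([getattr(s, outcome_column) for s in self.subjects], dtype=float)

    def to_table(self) -> pd.DataFrame:
        """Flat per-subject table (one row per subject, both sides as columns)."""
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "centre": s.centre,
                "scale": s.scale,
                "state": s.state,
                "score_pre": s.score_pre,
                "score_post": s.score_post,
                "pct_improvement": s.pct_improvement,
            }
            for side in SIDES:
                st = s.settings.get(side)
                if st is not None:
                    row[f"contact_{side}"] = st.contact_index
                    row[f"amplitude_{side}"] = st.amplitude
                    row[f"pulse_width_us_{side}"] = st.pulse_width_us
                    row[f"frequency_hz_{side}"] = st.frequency_hz
                    row[f"amplitude_unit_{side}"] = st.amplitude_unit
            for attr in ("led_pre", "led_post", "cdrs_pre", "cdrs_post"):
                val = getattr(s, attr)
                if val is not None:
                    row[attr] = val
            rows.append(row)
        return pd.DataFrame(rows)
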