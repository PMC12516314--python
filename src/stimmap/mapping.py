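"""Voxelwise probabilistic mapping.

Each voxel covered by enough stimulation volumes gets a two-sample t-test
of the outcomes of covering subjects against all remaining outcomes. The
signed p-map ("heatmap") is (1 - p) * sign(t), running from -1 at the most
detrimental voxels to +1 at the most beneficial. Contiguous clusters of
significant voxels form sweetspots (beneficial) and sourspots
(detrimental). A rank-based R-map over electric-field magnitudes and a
map-to-map spatial Pearson correlation provide an independent check of the
spatial structure.

No voxel-level multiple-comparison correction is applied by design: the
aggregate map is validated predictively (leave-one-out histogram
regression) instead of voxel by voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .cohort import Cohort
from .grid import VoxelGrid

__all__ = [
    "SignedPMap",
    "ClusterSpot",
    "RMap",
    "DEFAULT_MCP_MM",
    "voxelwise_heatmap",
    "heatmap_from_coverage",
    "extract_spots",
    "cog_to_mcp",
    "smooth_map",
    "rmap_spearman",
    "spatial_correlation",
]

# midcommissural point of the template, mm; spot coordinates are also
# reported relative to this stereotactic reference
DEFAULT_MCP_MM = (0.0, -11.8, -3.3)


@dataclass(frozen=True)
class SignedPMap:
    """Voxelwise t, p, and signed-p = (1 - p) * sign(t) on a shared grid.

    ``defined_mask`` marks voxels with enough coverage on both sides of the
    split; everywhere else t, p and signed_p are 0/1/0 placeholders.
    ``degenerate_mask`` marks defined voxels where all outcomes were equal.
    """

    grid: VoxelGrid
    t_value: np.ndarray
    p_value: np.ndarray
    signed_p: np.ndarray
    coverage_count: np.ndarray
    defined_mask: np.ndarray
    degenerate_mask: np.ndarray
    n_subjects: int

    def sample_flat(self, flat_indices: np.ndarray) -> np.ndarray:
        """Signed-p values at raveled voxel indices; undefined voxels read 0."""
        return self.signed_p.ravel()[flat_indices]


def heatmap_from_coverage(
    grid: VoxelGrid,
    covered_flat: list[np.ndarray],
    outcomes: np.ndarray,
    min_coverage: int = 2,
) -> SignedPMap:
    """Signed p-map from per-subject covered-voxel index sets.

    ``covered_flat[i]`` holds the unique raveled voxel indices covered by
    either VTA of subject i, so group membership at a voxel is per subject.
    At each voxel with at least ``min_coverage`` subjects in *both* groups,
    a pooled-variance (Student) two-sample t-test compares the covering
    subjects' outcomes with all remaining outcomes; p is two-sided.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    n = outcomes.size
    if n < 4:
        raise ValueError(f"need at least 4 subjects for voxelwise mapping, got {n}")
    if len(covered_flat) != n:
        raise ValueError("one covered-voxel set per subject is required")

    nv = grid.n_voxels
    coverage = np.zeros(nv, dtype=np.int32)
    sum_in = np.zeros(nv, dtype=float)
    sumsq_in = np.zeros(nv, dtype=float)
    for idx, y in zip(covered_flat, outcomes):
        coverage[idx] += 1
        sum_in[idx] += y
        sumsq_in[idx] += y * y

    n1 = coverage.astype(float)
    n2 = n - n1
    defined = (n1 >= min_coverage) & (n2 >= min_coverage)

    t = np.zeros(nv)
    p = np.ones(nv)
    degenerate = np.zeros(nv, dtype=bool)
    if defined.any():
        d = defined
        total_sum = outcomes.sum()
        total_sumsq = float(np.dot(outcomes, outcomes))
        m1 = sum_in[d] / n1[d]
        m2 = (total_sum - sum_in[d]) / n2[d]
        ss1 = sumsq_in[d] - n1[d] * m1**2
        ss2 = (total_sumsq - sumsq_in[d]) - n2[d] * m2**2
        df = n - 2
        sp2 = np.maximum(ss1 + ss2, 0.0) / df
        se = np.sqrt(sp2 * (1.0 / n1[d] + 1.0 / n2[d]))
        diff = m1 - m2
        with np.errstate(divide="ignore", invalid="ignore"):
            t_d = diff / se
        zero_spread = se == 0
        # all covering and non-covering outcomes identical: no effect, flagged
        t_d[zero_spread & (np.abs(diff) < 1e-12)] = 0.0
        # zero pooled variance but distinct means: maximally significant
        t_d[zero_spread & (np.abs(diff) >= 1e-12)] = np.sign(diff[zero_spread & (np.abs(diff) >= 1e-12)]) * np.inf
        p_d = 2.0 * stats.t.sf(np.abs(t_d), df)
        deg = zero_spread & (np.abs(diff) < 1e-12)
        p_d[deg] = 1.0
        t[d], p[d] = t_d, p_d
        degenerate[d] = deg

    signed_p = np.where(defined, (1.0 - p) * np.sign(t), 0.0)
    shape = grid.shape
    return SignedPMap(
        grid=grid,
        t_value=t.reshape(shape),
        p_value=p.reshape(shape),
        signed_p=signed_p.reshape(shape),
        coverage_count=coverage.reshape(shape),
        defined_mask=defined.reshape(shape),
        degenerate_mask=degenerate.reshape(shape),
        n_subjects=n,
    )


def voxelwise_heatmap(
    cohort: Cohort,
    outcome_column: str = "pct_improvement",
    min_coverage: int = 2,
    exclude: set[str] | None = None,
) -> SignedPMap:
    """Signed p-map of a cohort; a subject covers a voxel if either VTA of
    its mirrored pair contains it (counted once per subject).

    ``exclude`` drops subjects by id (used for leave-one-out folds).
    """
    subjects = [s for s in cohort.subjects if not exclude or s.subject_id not in exclude]
    if len(subjects) < 4:
        raise ValueError(f"need at least 4 subjects, got {len(subjects)}")
    # canonical accumulation order: the map is bit-identical under any
    # permutation of the input subjects
    subjects = sorted(subjects, key=lambda s: s.subject_id)
    sub_cohort = Cohort(grid=cohort.grid, subjects=subjects)
    outcomes = sub_cohort.outcomes(outcome_column)
    if not np.all(np.isfinite(outcomes)):
        raise ValueError(f"outcome column {outcome_column!r} contains non-finite values")
    covered = [s.covered_flat_indices() for s in subjects]
    return heatmap_from_coverage(cohort.grid, covered, outcomes, min_coverage=min_coverage)


@dataclass(frozen=True)
class ClusterSpot:
    """A sweetspot (+1) or sourspot (-1): connected significant voxels."""

    indices: np.ndarray  # (k, 3) voxel indices
    sign: int
    size: int
    cog: tuple[float, float, float]  # mm, unweighted mean of member voxel centres
    cog_mcp: tuple[float, float, float]  # mm relative to the midcommissural point

    @property
    def kind(self) -> str:
        return "sweetspot" if self.sign > 0 else "sourspot"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "sign": self.sign,
            "size": self.size,
            "cog": list(self.cog),
            "cog_mcp": list(self.cog_mcp),
        }


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


def extract_spots(
    pmap: SignedPMap,
    alpha: float = 0.05,
    min_cluster: int = 50,
    connectivity: int = 6,
    mcp=DEFAULT_MCP_MM,
) -> list[ClusterSpot]:
    """Sweetspots and sourspots: clusters (> ``min_cluster`` voxels, strict)
    of significant (p < alpha) defined voxels, split by t sign before
    labelling, sorted by size descending."""
    if not pmap.defined_mask.any():
        raise ValueError("signed p-map has no defined voxels")
    spots: list[ClusterSpot] = []
    structure = _structure(connectivity)
    significant = pmap.defined_mask & (pmap.p_value < alpha) & ~pmap.degenerate_mask
    for sign in (+1, -1):
        mask = significant & (np.sign(pmap.t_value) == sign)
        labels, n_labels = ndimage.label(mask, structure=structure)
        for lab in range(1, n_labels + 1):
            member = np.argwhere(labels == lab)
            if member.shape[0] <= min_cluster:
                continue
            cog = pmap.grid.index_to_world(member).mean(axis=0)
            spots.append(
                ClusterSpot(
                    indices=member,
                    sign=sign,
                    size=int(member.shape[0]),
                    cog=tuple(cog),
                    cog_mcp=tuple(cog_to_mcp(cog, mcp)),
                )
            )
    return sorted(spots, key=lambda s: -s.size)


def cog_to_mcp(cog, mcp=DEFAULT_MCP_MM) -> np.ndarray:
    """Component-wise offset of a centre of gravity from the midcommissural point."""
    return np.asarray(cog, dtype=float) - np.asarray(mcp, dtype=float)


def smooth_map(volume: np.ndarray, kernel_voxels: int = 3) -> np.ndarray:
    """Box-mean smoothing for display/export copies only.

    A ``kernel_voxels``-wide cubic mean filter with edge replication;
    statistics and cluster extraction always run on the unsmoothed map.
    """
    if kernel_voxels < 1 or kernel_voxels % 2 == 0:
        raise ValueError(f"kernel size must be an odd positive integer, got {kernel_voxels}")
    if kernel_voxels == 1:
        return np.asarray(volume, dtype=float).copy()
    return ndimage.uniform_filter(np.asarray(volume, dtype=float), size=kernel_voxels, mode="nearest")


@dataclass(frozen=True)
class RMap:
    """Voxelwise Spearman correlation of field magnitudes with outcomes."""

    grid: VoxelGrid
    values: np.ndarray
    defined_mask: np.ndarray

    def sample_flat(self, flat_indices: np.ndarray) -> np.ndarray:
        return self.values.ravel()[flat_indices]


def rmap_spearman(efield_magnitudes: np.ndarray, outcomes, grid: VoxelGrid) -> RMap:
    """R-map: per-voxel Spearman rank correlation (average-rank ties) between
    subjects' electric-field magnitudes and their outcomes.

    ``efield_magnitudes`` is (n_subjects, *grid.shape). Voxels where all
    magnitudes tie — and the everywhere-undefined case of constant
    outcomes — are flagged undefined and set to 0.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    n = outcomes.size
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    mags = np.asarray(efield_magnitudes, dtype=float).reshape(n, -1)
    rank_y = stats.rankdata(outcomes)
    ry = rank_y - rank_y.mean()
    denom_y = np.sqrt(np.sum(ry**2))
    rank_m = stats.rankdata(mags, axis=0)
    rm = rank_m - rank_m.mean(axis=0, keepdims=True)
    denom_m = np.sqrt(np.sum(rm**2, axis=0))
    defined = (denom_m > 0) & (denom_y > 0)
    values = np.zeros(mags.shape[1])
    if denom_y > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = (ry @ rm) / (denom_m * denom_y)
        values[defined] = rho[defined]
    return RMap(grid=grid, values=values.reshape(grid.shape), defined_mask=defined.reshape(grid.shape))


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None):
    """Pearson spatial correlation between two volumes over a shared mask.

    Default mask: voxels finite in both maps. Returns (R, p, n_voxels); the
    p-value comes from the exact t transform with n - 2 degrees of freedom.
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    if mask is None:
        m = np.isfinite(a) & np.isfinite(b)
    else:
        m = np.asarray(mask, dtype=bool).ravel()
    a, b = a[m], b[m]
    if a.size < 3:
        raise ValueError(f"need at least 3 voxels in the mask, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map within the mask: correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), int(a.size)
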