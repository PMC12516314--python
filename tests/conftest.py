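"""Shared fixtures: small grids and cached synthetic cohorts.

The expensive objects (noise-free default cohort, its heatmap, LOO
histograms and model) are session-scoped so the recovery, prediction and
programming tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import stimmap as sm
from stimmap.grid import VoxelGrid


@pytest.fixture
def small_grid() -> VoxelGrid:
    """9^3 voxel, 1 mm grid symmetric about the mid-sagittal plane."""
    return VoxelGrid(shape=(9, 9, 9), spacing=(1.0, 1.0, 1.0), origin=(-4.0, -4.0, -4.0))


@pytest.fixture(scope="session")
def default_field() -> sm.EffectField:
    return sm.default_effect_field()


@pytest.fixture(scope="session")
def noise_free_cohort(default_field) -> sm.Cohort:
    """Default-size cohort (n=40) with the planted field and no outcome noise."""
    return sm.simulate_cohort(sm.CohortConfig(seed=1, noise_sd=0.0), default_field)


@pytest.fixture(scope="session")
def nf_heatmap(noise_free_cohort) -> sm.SignedPMap:
    return sm.voxelwise_heatmap(noise_free_cohort)


@pytest.fixture(scope="session")
def nf_histograms(noise_free_cohort):
    return sm.loo_histograms(noise_free_cohort)


@pytest.fixture(scope="session")
def nf_model(nf_histograms, noise_free_cohort) -> sm.OutcomeModel:
    return sm.fit_outcome_model(nf_histograms, noise_free_cohort.outcomes())


@pytest.fixture(scope="session")
def noisy_cohort(default_field) -> sm.Cohort:
    """Cohort at the default (calibrated) noise level."""
    return sm.simulate_cohort(sm.CohortConfig(seed=0), default_field)


def make_tiny_cohort(n=6, seed=0, noise_sd=0.0, **kwargs) -> sm.Cohort:
    """Small cohort on the default grid for cheap structural tests."""
    field = sm.default_effect_field()
    cfg = sm.CohortConfig(n_subjects=n, seed=seed, noise_sd=noise_sd, **kwargs)
    return sm.simulate_cohort(cfg, field)


@pytest.fixture
def tiny_cohort() -> sm.Cohort:
    return make_tiny_cohort()
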