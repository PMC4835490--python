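"""Shared fixtures: synthetic cohorts, prepared matrices, and LOO runs.

The planted and null end-to-end runs are session-scoped because several
acceptance criteria are measured on the same run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from perfcad.comparison import gm_prior
from perfcad.discriminant import LOOResult, loo_evaluate
from perfcad.preprocess import preprocess_volume
from perfcad.synth import SyntheticCohortSpec, generate_cohort
from perfcad.volume_io import (
    ClinicalTable,
    CohortMatrix,
    VoxelMask,
    build_cohort_matrix,
    coverage_mask,
)


@dataclass
class PreparedCohort:
    spec: SyntheticCohortSpec
    volumes: list
    gm_maps: list
    atlas: object
    table: ClinicalTable
    truth: object
    mask: VoxelMask
    cohort: CohortMatrix
    gm_priors: dict[str, np.ndarray]


def prepare_cohort(spec: SyntheticCohortSpec) -> PreparedCohort:
    volumes, gm_maps, atlas, table, truth = generate_cohort(spec)
    mask = coverage_mask(volumes)
    processed = [preprocess_volume(v, mask) for v in volumes]
    cohort = build_cohort_matrix(processed, table, mask)
    gm_priors = {
        g.subject_id: gm_prior(g, mask, subject_id=g.subject_id).values
        for g in gm_maps
    }
    return PreparedCohort(
        spec=spec,
        volumes=volumes,
        gm_maps=gm_maps,
        atlas=atlas,
        table=table,
        truth=truth,
        mask=mask,
        cohort=cohort,
        gm_priors=gm_priors,
    )


@pytest.fixture(scope="session")
def planted() -> PreparedCohort:
    """Default spec: lesion effect 0.70, n = 30 + 30, seed 42."""
    return prepare_cohort(SyntheticCohortSpec(seed=42, n_hc=30, n_ad=30))


@pytest.fixture(scope="session")
def planted_loo(planted: PreparedCohort) -> LOOResult:
    return loo_evaluate(planted.cohort, planted.table, planted.gm_priors)


@pytest.fixture(scope="session")
def null_cohort() -> PreparedCohort:
    """Same spec with lesion effect 1.0: groups exchangeable."""
    return prepare_cohort(
        SyntheticCohortSpec(seed=42, n_hc=30, n_ad=30, lesion_effect=1.0)
    )


@pytest.fixture(scope="session")
def null_loo(null_cohort: PreparedCohort) -> LOOResult:
    return loo_evaluate(null_cohort.cohort, null_cohort.table, null_cohort.gm_priors)


@pytest.fixture(scope="session")
def small_cohort() -> PreparedCohort:
    """A fast 8+8 cohort on a 16x16x8 grid for unit-level tests."""
    return prepare_cohort(
        SyntheticCohortSpec(grid_shape=(16, 16, 8), seed=7, n_hc=8, n_ad=8)
    )


def hc_cohort_matrix(
    n: int, j: int, mu: np.ndarray, sigma: np.ndarray, rng: np.random.Generator
) -> CohortMatrix:
    """Cohort of pure HC rows drawn voxel-wise from N(mu, sigma)."""
    gamma = rng.normal(mu, sigma, size=(n, j))
    return CohortMatrix(
        gamma=gamma,
        subject_ids=[f"hc{i:04d}" for i in range(n)],
        groups=["HC"] * n,
        mask=VoxelMask.full((j, 1, 1)),
    )
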