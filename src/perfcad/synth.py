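"""Synthetic cohort generator.

Builds cohorts with the statistical structure the pipeline assumes: a toy
box atlas with gray-matter-like and white-matter-like compartments, two
designated disease regions, region-structured baseline perfusion, additive
between-subject and voxel noise, multiplicative lesions in the disease
regions of AD subjects, matched gray-matter probability maps, and clinical
covariates whose MMSE is inversely coupled to lesion burden.  Everything is
driven by one seed; identical specs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .regional import AtlasVolume
from .volume_io import ClinicalTable, Volume3D

import pandas as pd

DISEASE_LABELS = (1, 2)
REGION_NAMES = {
    1: "parietal",
    2: "limbic",
    3: "frontal",
    4: "occipital",
    5: "deep_white",
}


@dataclass
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort generator."""

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    baseline_gm: float = 60.0  # ml/100g/min in gray-matter-like regions
    baseline_wm: float = 20.0
    subject_sd: float = 8.0  # between-subject global offset SD
    noise_sd: float = 6.0  # voxel-wise additive noise SD
    lesion_effect: float = 0.70  # multiplicative CBF factor in lesions
    lesion_extent: float | tuple[float, float] = 1.0  # fraction of disease
    # region voxels lesioned; a (lo, hi) pair samples per AD subject
    n_hc: int = 30
    n_ad: int = 30
    mmse_coupling: float = 0.0125  # MMSE points lost per unit lesion burden
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("SDs must be > 0")
        if not 0 < self.lesion_effect <= 1:
            raise ValueError("lesion_effect must be in (0, 1]")
        ext = self.lesion_extent
        lo, hi = (ext, ext) if np.isscalar(ext) else ext
        if not 0 < lo <= hi <= 1:
            raise ValueError("lesion_extent must lie in (0, 1]")
        if self.n_hc < 1 or self.n_ad < 0:
            raise ValueError("invalid group sizes")
        nx, ny, nz = self.grid_shape
        if nx < 12 or ny < 12 or nz < 6:
            raise ValueError("grid too small to contain the toy atlas")


@dataclass
class GroundTruth:
    """Per-subject lesion voxel indices (linear grid indices) and burden."""

    lesion_indices: dict[str, np.ndarray]
    burden: dict[str, float]
    disease_labels: tuple[int, ...] = DISEASE_LABELS
    atlas: AtlasVolume | None = field(default=None, repr=False)

    def lesion_grid_mask(self, subject_id: str, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m.ravel()[self.lesion_indices[subject_id]] = True
        return m


def toy_atlas(grid_shape: tuple[int, int, int]) -> AtlasVolume:
    """Box parcellation: four quadrant GM regions around a deep WM core.

    Labels 1 (parietal-like) and 2 (limbic-like) are the designated disease
    regions; label 5 is white-matter-like; 0 is out-of-brain background.
    """
    nx, ny, nz = grid_shape
    labels = np.zeros(grid_shape, dtype=np.int64)
    x0, x1 = 2, nx - 2
    y0, y1 = 2, ny - 2
    z0, z1 = 1, nz - 1
    xm, ym = (x0 + x1) // 2, (y0 + y1) // 2
    labels[x0:xm, y0:ym, z0:z1] = 1
    labels[xm:x1, y0:ym, z0:z1] = 2
    labels[x0:xm, ym:y1, z0:z1] = 3
    labels[xm:x1, ym:y1, z0:z1] = 4
    # deep white-matter core
    wx = (xm - 4, xm + 4)
    wy = (ym - 4, ym + 4)
    wz = ((z0 + z1) // 2 - 2, (z0 + z1) // 2 + 2)
    labels[wx[0] : wx[1], wy[0] : wy[1], wz[0] : wz[1]] = 5
    return AtlasVolume(labels=labels, name_map=dict(REGION_NAMES))


def region_baselines(spec: SyntheticCohortSpec) -> dict[int, float]:
    return {
        1: spec.baseline_gm,
        2: spec.baseline_gm,
        3: spec.baseline_gm,
        4: spec.baseline_gm,
        5: spec.baseline_wm,
    }


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[Volume3D], list[Volume3D], AtlasVolume, ClinicalTable, GroundTruth]:
    """Draw a full synthetic cohort.

    Returns (CBF volumes, GM probability maps, atlas, clinical table,
    ground truth).  Volumes are exactly zero outside the brain so the
    coverage mask excludes background.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = toy_atlas(spec.grid_shape)
    baselines = region_baselines(spec)
    brain = atlas.labels > 0
    base_vol = np.zeros(spec.grid_shape)
    for label, value in baselines.items():
        base_vol[atlas.labels == label] = value

    gm_template = np.zeros(spec.grid_shape)
    gm_template[np.isin(atlas.labels, [1, 2, 3, 4])] = 0.95
    gm_template[atlas.labels == 5] = 0.05

    disease_mask = np.isin(atlas.labels, DISEASE_LABELS)
    disease_idx = np.flatnonzero(disease_mask.ravel())

    ext = spec.lesion_extent
    ext_lo, ext_hi = (ext, ext) if np.isscalar(ext) else ext

    ids = [f"hc{i:03d}" for i in range(spec.n_hc)] + [
        f"ad{i:03d}" for i in range(spec.n_ad)
    ]
    groups = ["HC"] * spec.n_hc + [
        "AD_EA" if i % 3 == 0 else "AD_LA" for i in range(spec.n_ad)
    ]

    volumes: list[Volume3D] = []
    gm_maps: list[Volume3D] = []
    lesion_indices: dict[str, np.ndarray] = {}
    burden: dict[str, float] = {}
    clinical_rows = []

    for sid, group in zip(ids, groups):
        is_ad = group != "HC"
        offset = rng.normal(0.0, spec.subject_sd)
        noise = rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        data = np.where(brain, base_vol + offset + noise, 0.0)

        if is_ad:
            extent = rng.uniform(ext_lo, ext_hi)
            n_lesion = max(1, int(round(extent * len(disease_idx))))
            chosen = (
                disease_idx
                if n_lesion >= len(disease_idx)
                else rng.choice(disease_idx, size=n_lesion, replace=False)
            )
            chosen = np.sort(chosen)
            flat = data.ravel()
            flat[chosen] *= spec.lesion_effect
            lesion_indices[sid] = chosen
            burden[sid] = (1.0 - spec.lesion_effect) * len(chosen)
        else:
            lesion_indices[sid] = np.array([], dtype=np.int64)
            burden[sid] = 0.0

        volumes.append(Volume3D(data=data, subject_id=sid))
        gm = np.clip(gm_template + rng.normal(0.0, 0.02, size=spec.grid_shape), 0, 1)
        gm = np.where(brain, gm, 0.0)
        gm_maps.append(Volume3D(data=gm, subject_id=sid))

        age = rng.normal(71.0, 6.0) if is_ad else rng.normal(66.0, 6.0)
        mmse = 29.0 - spec.mmse_coupling * burden[sid] + rng.normal(0.0, 1.0)
        clinical_rows.append(
            {
                "id": sid,
                "group": group,
                "age": round(max(40.0, age), 1),
                "mmse": round(float(np.clip(mmse, 0.0, 30.0)), 1),
                "education": int(rng.integers(8, 20)),
                "gender": rng.choice(["F", "M"]),
            }
        )

    table = ClinicalTable(pd.DataFrame(clinical_rows))
    truth = GroundTruth(lesion_indices=lesion_indices, burden=burden, atlas=atlas)
    return volumes, gm_maps, atlas, table, truth


def generate_counts(
    n_hc: int,
    n_ad: int,
    hc_rate: float,
    ad_rate: float,
    dist: str = "poisson",
    nb_dispersion: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled hypo-voxel-count draws for threshold-recovery fixtures.

    Returns (counts, is_ad).  ``dist`` is ``poisson`` or ``negative_binomial``
    (gamma-mixed Poisson with shape ``nb_dispersion``).
    """
    if hc_rate < 0 or ad_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)

    def draw(rate: float, n: int) -> np.ndarray:
        if dist == "poisson":
            return rng.poisson(rate, size=n)
        if dist == "negative_binomial":
            lam = rng.gamma(nb_dispersion, rate / nb_dispersion, size=n)
            return rng.poisson(lam)
        raise ValueError(f"unknown distribution {dist!r}")

    counts = np.concatenate([draw(hc_rate, n_hc), draw(ad_rate, n_ad)])
    is_ad = np.concatenate(
        [np.zeros(n_hc, dtype=bool), np.ones(n_ad, dtype=bool)]
    )
    return counts, is_ad
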