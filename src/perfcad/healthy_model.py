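"""Voxel-wise Gaussian reference model of the healthy cohort and T-score maps."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .comparison import ScoreMap
from .volume_io import CohortMatrix, VoxelMask, delinearize, load_volume, save_volume

SIGMA_FLOOR_REL = 1e-6


@dataclass
class HealthyModel:
    """Per-voxel mean and standard deviation of the healthy reference cohort.

    ``sigma`` is floored at ``sigma_floor`` so that standardization is always
    defined; the floor is relative (1e-6 of the largest sigma) and only
    touches degenerate voxels.
    """

    mu: np.ndarray
    sigma: np.ndarray
    n_hc: int
    sigma_floor: float
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu/sigma length mismatch")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be strictly positive after flooring")

    @property
    def n_voxels(self) -> int:
        return len(self.mu)


def fit_healthy_model(
    cohort: CohortMatrix,
    hc_ids: Sequence[str] | None = None,
    exclude: Sequence[str] = (),
    ddof: int = 0,
) -> HealthyModel:
    """Element-wise Gaussian fit over healthy-control rows.

    ``exclude`` supports leave-one-out bookkeeping: excluded subjects take no
    part in the fit.  ``ddof=0`` uses the population (divisor N) standard
    deviation; set ``ddof=1`` for the sample estimator.
    """
    if hc_ids is None:
        hc_ids = cohort.hc_ids()
    groups = dict(zip(cohort.subject_ids, cohort.groups))
    bad = [s for s in hc_ids if groups.get(s) != "HC"]
    if bad:
        raise ValueError(f"non-HC subjects passed as hc_ids: {bad}")
    used = [s for s in hc_ids if s not in set(exclude)]
    if len(used) < 2:
        raise ValueError(f"need >= 2 healthy subjects to fit, got {len(used)}")
    rows = cohort.rows_for(used)
    mu = rows.mean(axis=0)
    sigma = rows.std(axis=0, ddof=ddof)
    smax = float(sigma.max())
    floor = SIGMA_FLOOR_REL * smax if smax > 0 else SIGMA_FLOOR_REL
    sigma = np.maximum(sigma, floor)
    return HealthyModel(
        mu=mu,
        sigma=sigma,
        n_hc=len(used),
        sigma_floor=floor,
        excluded_ids=[s for s in hc_ids if s in set(exclude)],
    )


def t_score_map(
    subject: np.ndarray, model: HealthyModel, subject_id: str = ""
) -> ScoreMap:
    """Standardized deviation (x - mu) / sigma per voxel."""
    subject = np.asarray(subject, dtype=np.float64)
    if subject.shape != model.mu.shape:
        raise ValueError("subject vector length does not match model")
    return ScoreMap(
        values=(subject - model.mu) / model.sigma,
        kind="tscore",
        subject_id=subject_id,
    )


def save_model(
    model: HealthyModel, directory: str | Path, mask: VoxelMask
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_volume(delinearize(model.mu, mask, subject_id="mu"), directory / "mu.nii.gz")
    save_volume(
        delinearize(model.sigma, mask, subject_id="sigma"), directory / "sigma.nii.gz"
    )
    sidecar = {
        "n_hc": model.n_hc,
        "sigma_floor": model.sigma_floor,
        "excluded_ids": model.excluded_ids,
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(directory: str | Path, mask: VoxelMask) -> HealthyModel:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    mu_vol = load_volume(directory / "mu.nii.gz")
    sigma_vol = load_volume(directory / "sigma.nii.gz")
    from .volume_io import linearize

    return HealthyModel(
        mu=linearize(mu_vol, mask),
        sigma=np.maximum(linearize(sigma_vol, mask), sidecar["sigma_floor"]),
        n_hc=sidecar["n_hc"],
        sigma_floor=sidecar["sigma_floor"],
        excluded_ids=sidecar["excluded_ids"],
    )
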