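"""Volume and table I/O, coverage masking, and (de)linearization.

All downstream stages operate on *linearized* vectors: a fixed, row-major
ordering of the voxels retained by the analysis :class:`VoxelMask`.  This
module owns that bijection and the round trip back to 3D volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("HC", "AD_EA", "AD_LA")
DEFAULT_COVERAGE_THRESHOLD = 0.95


class ShapeMismatchError(ValueError):
    """Raised when a volume does not match the expected grid."""


@dataclass
class Volume3D:
    """A 3D scalar volume (CBF in ml/100g/min, probability, or score).

    NaNs are replaced by zero on construction; the replacement count is
    logged and kept in :attr:`n_nan_replaced`.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    subject_id: str = ""
    n_nan_replaced: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume for {self.subject_id!r} must be 3D with positive "
                f"dimensions, got shape {self.data.shape}"
            )
        nan_mask = np.isnan(self.data)
        n_nan = int(nan_mask.sum())
        if n_nan:
            self.data = np.where(nan_mask, 0.0, self.data)
            self.n_nan_replaced += n_nan
            logger.info(
                "volume %s: replaced %d NaN voxels with 0", self.subject_id, n_nan
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VoxelMask:
    """Boolean analysis mask plus the ordered coordinate list defining the
    linearization index j = 1..J (row-major over the stored grid)."""

    keep: np.ndarray
    index_map: np.ndarray  # (J, 3) int coordinates, row-major order

    @classmethod
    def from_keep(cls, keep: np.ndarray) -> "VoxelMask":
        keep = np.asarray(keep, dtype=bool)
        if keep.ndim != 3:
            raise ValueError("mask must be 3D")
        index_map = np.argwhere(keep)  # argwhere is row-major (C order)
        if len(index_map) < 1:
            raise ValueError("empty mask: no voxel survives")
        return cls(keep=keep, index_map=index_map)

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "VoxelMask":
        return cls.from_keep(np.ones(shape, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return len(self.index_map)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.keep.shape


@dataclass
class ClinicalTable:
    """Per-subject covariates: id, group, age, mmse, education, gender."""

    frame: pd.DataFrame

    REQUIRED = ("id", "group", "age", "mmse", "education", "gender")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        df = self.frame
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown groups: {sorted(bad_group)}")
        if ((df["mmse"] < 0) | (df["mmse"] > 30)).any():
            raise ValueError("mmse outside [0, 30]")
        if (df["age"] <= 0).any():
            raise ValueError("non-positive age")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClinicalTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def ids(self) -> list[str]:
        return self.frame["id"].tolist()

    @property
    def groups(self) -> list[str]:
        return self.frame["group"].tolist()

    def is_ad(self, subject_id: str) -> bool:
        row = self.frame.loc[self.frame["id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        return str(row["group"].iloc[0]).startswith("AD")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CohortMatrix:
    """N x J matrix of linearized values plus bookkeeping."""

    gamma: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    mask: VoxelMask

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        n, j = self.gamma.shape
        if n < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if j != self.mask.n_voxels:
            raise ValueError("gamma columns do not match mask voxel count")
        if len(self.subject_ids) != n or len(self.groups) != n:
            raise ValueError("subject_ids/groups length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.gamma.shape[1]

    def rows_for(self, subject_ids: Sequence[str]) -> np.ndarray:
        idx = [self.subject_ids.index(s) for s in subject_ids]
        return self.gamma[idx]

    def hc_ids(self) -> list[str]:
        return [s for s, g in zip(self.subject_ids, self.groups) if g == "HC"]


def load_volume(path: str | Path, subject_id: str | None = None) -> Volume3D:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return Volume3D(
        data=np.asanyarray(img.dataobj, dtype=np.float64),
        voxel_size=zooms,
        subject_id=sid,
    )


def save_volume(volume: Volume3D, path: str | Path, dtype=np.float64) -> None:
    affine = np.diag(list(volume.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(dtype), affine), str(path))


def save_mask(mask: VoxelMask, path: str | Path, voxel_size=(2.0, 2.0, 2.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.keep.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path) -> VoxelMask:
    img = nib.load(str(path))
    return VoxelMask.from_keep(np.asanyarray(img.dataobj) > 0)


def load_cohort(
    paths: Sequence[str | Path], clinical: str | Path | ClinicalTable
) -> tuple[list[Volume3D], ClinicalTable]:
    """Load a cohort of volumes in clinical-table order.

    Volume files are matched to clinical rows by subject id (the file stem).
    Raises on grid-shape mismatch (naming the offender) or missing rows.
    """
    if len(paths) < 2:
        raise ValueError("need at least 2 volumes")
    table = clinical if isinstance(clinical, ClinicalTable) else ClinicalTable.from_csv(clinical)
    by_id = {}
    for p in paths:
        v = load_volume(p)
        by_id[v.subject_id] = v
    missing = [s for s in table.ids if s not in by_id]
    if missing:
        raise ValueError(f"no volume file for clinical subjects: {missing}")
    extra = [s for s in by_id if s not in set(table.ids)]
    if extra:
        raise ValueError(f"no clinical row for volumes: {extra}")
    volumes = [by_id[s] for s in table.ids]
    ref_shape = volumes[0].shape
    for v in volumes[1:]:
        if v.shape != ref_shape:
            raise ShapeMismatchError(
                f"volume {v.subject_id!r} has shape {v.shape}, expected {ref_shape}"
            )
    return volumes, table


def coverage_mask(
    volumes: Sequence[Volume3D], threshold: float = DEFAULT_COVERAGE_THRESHOLD
) -> VoxelMask:
    """Keep a voxel iff its nonzero-signal coverage across subjects is
    *strictly greater* than ``threshold`` (coverage <= threshold discarded)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not volumes:
        raise ValueError("no volumes given")
    stack = np.stack([v.data for v in volumes])
    coverage = (stack != 0).mean(axis=0)
    keep = coverage > threshold
    if not keep.any():
        raise ValueError(
            f"empty coverage mask: no voxel exceeds threshold {threshold}"
        )
    return VoxelMask.from_keep(keep)


def linearize(volume: Volume3D | np.ndarray, mask: VoxelMask) -> np.ndarray:
    """Extract masked voxels as a length-J vector in index_map order."""
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume)
    if data.shape != mask.shape:
        raise ShapeMismatchError(
            f"volume shape {data.shape} does not match mask grid {mask.shape}"
        )
    return data[mask.keep]  # boolean indexing is row-major, same as index_map


def delinearize(
    vec: np.ndarray,
    mask: VoxelMask,
    fill: float = 0.0,
    subject_id: str = "",
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> Volume3D:
    """Inverse of :func:`linearize`; unmasked voxels carry ``fill``."""
    vec = np.asarray(vec, dtype=np.float64)
    if vec.shape != (mask.n_voxels,):
        raise ValueError(
            f"vector length {vec.shape} does not match mask J={mask.n_voxels}"
        )
    out = np.full(mask.shape, float(fill), dtype=np.float64)
    out[mask.keep] = vec
    return Volume3D(data=out, subject_id=subject_id, voxel_size=voxel_size)


def build_cohort_matrix(
    volumes: Sequence[Volume3D], table: ClinicalTable, mask: VoxelMask
) -> CohortMatrix:
    gamma = np.stack([linearize(v, mask) for v in volumes])
    return CohortMatrix(
        gamma=gamma, subject_ids=table.ids, groups=table.groups, mask=mask
    )
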