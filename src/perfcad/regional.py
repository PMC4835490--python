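"""Atlas-based accumulation of hypoperfused voxels and clinical correlations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import ClinicalTable, VoxelMask, linearize


@dataclass
class AtlasVolume:
    """Integer-labeled parcellation on the analysis grid; 0 is background."""

    labels: np.ndarray
    name_map: dict[int, str]
    coverage_ok: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = self.present_labels()
        unnamed = [int(l) for l in present if l not in self.name_map]
        if unnamed:
            raise ValueError(f"atlas labels without names: {unnamed}")
        if not self.coverage_ok <= set(present):
            raise ValueError("coverage_ok contains absent labels")

    def present_labels(self) -> list[int]:
        return [int(l) for l in np.unique(self.labels) if l != 0]

    def flag_coverage(self, mask: VoxelMask) -> None:
        """Mark labels whose every voxel lies inside the coverage mask."""
        ok = set()
        for label in self.present_labels():
            region = self.labels == label
            if mask.keep[region].all():
                ok.add(label)
        self.coverage_ok = ok

    @classmethod
    def from_files(cls, nifti_path: str | Path, names_path: str | Path) -> "AtlasVolume":
        import nibabel as nib

        img = nib.load(str(nifti_path))
        labels = np.asanyarray(img.dataobj).astype(np.int64)
        names = pd.read_csv(names_path, sep="\t")
        name_map = dict(zip(names["label"].astype(int), names["name"]))
        return cls(labels=labels, name_map=name_map)


@dataclass
class RegionalReport:
    """Per subject x region hypo-voxel counts plus group summaries."""

    counts: pd.DataFrame  # index subject_id, columns region name + background
    fractions_pooled: pd.Series  # pooled voxel fraction per covered region
    fractions_mean: pd.Series  # mean over subjects of per-subject fractions
    p_values: pd.Series
    excluded_regions: list[str]


def regional_counts(
    hypo_mask: np.ndarray, atlas: AtlasVolume, mask: VoxelMask
) -> dict[int, int]:
    """Count hypo voxels per nonzero atlas label (key 0 = background count).

    ``hypo_mask`` is a boolean vector in mask order.
    """
    if atlas.labels.shape != mask.shape:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match mask {mask.shape}"
        )
    hypo_mask = np.asarray(hypo_mask, dtype=bool)
    if hypo_mask.shape != (mask.n_voxels,):
        raise ValueError("hypo mask length does not match mask voxel count")
    atlas_vec = linearize(atlas.labels, mask)
    hit = atlas_vec[hypo_mask]
    out = {label: 0 for label in [0] + atlas.present_labels()}
    for label, n in zip(*np.unique(hit, return_counts=True)):
        out[int(label)] = int(n)
    return out


def group_region_test(
    counts: pd.DataFrame,
    groups: Sequence[str],
    method: str = "mannwhitney",
) -> pd.Series:
    """Two-sided HC-vs-AD test of regional counts, one p-value per region.

    ``mannwhitney`` (default) is rank-based and monotone-invariant;
    ``welch`` runs an unequal-variance t-test instead.
    """
    is_ad = np.array([g.startswith("AD") for g in groups])
    if is_ad.sum() < 2 or (~is_ad).sum() < 2:
        raise ValueError("both groups need >= 2 subjects")
    pvals = {}
    for region in counts.columns:
        a = counts.loc[is_ad, region].to_numpy(dtype=float)
        h = counts.loc[~is_ad, region].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(h) == 0 and a[0] == h[0]:
            warnings.warn(
                f"region {region!r}: constant counts in both groups, p = 1",
                RuntimeWarning,
                stacklevel=2,
            )
            pvals[region] = 1.0
            continue
        if method == "mannwhitney":
            pvals[region] = float(
                stats.mannwhitneyu(a, h, alternative="two-sided").pvalue
            )
        elif method == "welch":
            pvals[region] = float(
                stats.ttest_ind(a, h, equal_var=False).pvalue
            )
        else:
            raise ValueError(f"unknown test method {method!r}")
    return pd.Series(pvals, name="p_value")


def bonferroni(p_values: pd.Series) -> pd.Series:
    return (p_values * len(p_values)).clip(upper=1.0)


def clinical_correlations(
    hypo_volume: dict[str, int],
    clinical: ClinicalTable,
    subjects: Sequence[str] | None = None,
    method: str = "spearman",
    covariates: Sequence[str] = ("mmse", "age", "education"),
) -> pd.DataFrame:
    """Correlate per-subject hypo-voxel counts with clinical covariates.

    ``subjects`` restricts the computation (e.g. to correctly classified
    patients).  Returns a frame with rho and p per covariate; constant
    covariates are reported as NaN.
    """
    ids = list(subjects) if subjects is not None else list(hypo_volume)
    if len(ids) < 3:
        raise ValueError("need >= 3 subjects for correlations")
    frame = clinical.frame.set_index("id").loc[ids]
    x = np.array([hypo_volume[s] for s in ids], dtype=float)
    rows = {}
    for cov in covariates:
        y = frame[cov].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            rows[cov] = {"rho": np.nan, "p_value": np.nan, "n": len(ids)}
            continue
        if method == "spearman":
            rho, p = stats.spearmanr(x, y)
        elif method == "pearson":
            rho, p = stats.pearsonr(x, y)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows[cov] = {"rho": float(rho), "p_value": float(p), "n": len(ids)}
    return pd.DataFrame(rows).T


def build_regional_report(
    hypo_masks: dict[str, np.ndarray],
    atlas: AtlasVolume,
    mask: VoxelMask,
    groups_by_id: dict[str, str],
    test_method: str = "mannwhitney",
) -> RegionalReport:
    """Accumulate per-subject regional counts and group statistics.

    Regions not fully inside the coverage mask are excluded from the
    fraction denominators and flagged in the report.
    """
    if not atlas.coverage_ok:
        atlas.flag_coverage(mask)
    label_names = {l: atlas.name_map[l] for l in atlas.present_labels()}
    records = {}
    for sid, hypo in hypo_masks.items():
        c = regional_counts(hypo, atlas, mask)
        records[sid] = {label_names[l]: c[l] for l in label_names} | {
            "background": c[0]
        }
    counts = pd.DataFrame.from_dict(records, orient="index")

    covered = [label_names[l] for l in sorted(atlas.coverage_ok)]
    excluded = [label_names[l] for l in label_names if l not in atlas.coverage_ok]
    covered_counts = counts[covered]
    total_pooled = covered_counts.to_numpy().sum()
    fractions_pooled = (
        covered_counts.sum(axis=0) / total_pooled
        if total_pooled > 0
        else covered_counts.sum(axis=0) * np.nan
    )
    row_tot = covered_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_subj = covered_counts.div(row_tot.replace(0, np.nan), axis=0)
    fractions_mean = per_subj.mean(axis=0, skipna=True)

    groups = [groups_by_id[s] for s in counts.index]
    p_values = group_region_test(covered_counts, groups, method=test_method)
    return RegionalReport(
        counts=counts,
        fractions_pooled=fractions_pooled,
        fractions_mean=fractions_mean,
        p_values=p_values,
        excluded_regions=excluded,
    )
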