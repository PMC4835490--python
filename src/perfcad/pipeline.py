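"""End-to-end orchestration with reproducible configuration.

A cohort directory is the on-disk interchange format::

    cohort/
      clinical.csv          id,group,age,mmse,education,gender
      volumes/<id>.nii.gz   CBF maps, common grid
      gm/<id>.nii.gz        gray-matter probability maps
      atlas.nii.gz          integer labels on the same grid
      atlas_labels.tsv      label<TAB>name
      ground_truth.json     optional (written by the simulator)

``run_pipeline`` consumes such a directory and writes a run directory with
the fitted model, priors, evaluation surfaces, and a deterministic JSON
report.  Stage failures are re-raised with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discriminant, regional, volume_io
from .comparison import gm_prior
from .healthy_model import fit_healthy_model, save_model
from .preprocess import SmoothingConfig, preprocess_volume
from .volume_io import ClinicalTable, VoxelMask


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


@dataclass
class PipelineConfig:
    """Resolved run configuration; defaults match the published settings."""

    input_dir: str = "."
    out_dir: str = "run"
    smoothing_sigma: float = 2.0
    smoothing_kernel_size: int = 6
    scaling_method: str = "minmax"
    coverage_threshold: float = 0.95
    n_components: int = 20
    tw_min: float = 0.50
    tw_max: float = 1.00
    tw_step: float = 0.01
    tb_min: int = 0
    tb_max: int = 5000
    tb_step: int = 50
    sd_divisor: str = "population"  # population (N) or sample (N-1)
    test_method: str = "mannwhitney"
    correlation_method: str = "spearman"
    svm_cost: float = 1.0
    seed: int = 0

    @property
    def ddof(self) -> int:
        return 0 if self.sd_divisor == "population" else 1

    def tw_grid(self) -> np.ndarray:
        n = int(round((self.tw_max - self.tw_min) / self.tw_step)) + 1
        return np.round(np.linspace(self.tw_min, self.tw_max, n), 10)

    def tb_grid(self) -> np.ndarray:
        return np.arange(self.tb_min, self.tb_max + 1, self.tb_step)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def hash_inputs(input_dir: str | Path) -> str:
    """SHA-256 over the sorted relative paths and contents of the inputs."""
    h = hashlib.sha256()
    root = Path(input_dir)
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def load_cohort_dir(
    input_dir: str | Path,
) -> tuple[list, list, "regional.AtlasVolume | None", ClinicalTable]:
    root = Path(input_dir)
    table = ClinicalTable.from_csv(root / "clinical.csv")
    vol_paths = [root / "volumes" / f"{sid}.nii.gz" for sid in table.ids]
    volumes, table = volume_io.load_cohort(vol_paths, table)
    gm_maps = [volume_io.load_volume(root / "gm" / f"{sid}.nii.gz") for sid in table.ids]
    atlas = None
    if (root / "atlas.nii.gz").exists():
        atlas = regional.AtlasVolume.from_files(
            root / "atlas.nii.gz", root / "atlas_labels.tsv"
        )
    return volumes, gm_maps, atlas, table


def save_cohort_dir(
    out_dir: str | Path,
    volumes,
    gm_maps,
    atlas,
    table: ClinicalTable,
    truth=None,
) -> Path:
    root = Path(out_dir)
    (root / "volumes").mkdir(parents=True, exist_ok=True)
    (root / "gm").mkdir(exist_ok=True)
    table.to_csv(root / "clinical.csv")
    for v in volumes:
        volume_io.save_volume(v, root / "volumes" / f"{v.subject_id}.nii.gz")
    for g in gm_maps:
        volume_io.save_volume(g, root / "gm" / f"{g.subject_id}.nii.gz")
    if atlas is not None:
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(atlas.labels.astype(np.int16), np.diag([2.0, 2.0, 2.0, 1.0])),
            str(root / "atlas.nii.gz"),
        )
        pd.DataFrame(
            {"label": list(atlas.name_map), "name": list(atlas.name_map.values())}
        ).to_csv(root / "atlas_labels.tsv", sep="\t", index=False)
    if truth is not None:
        gt = {
            "burden": truth.burden,
            "lesion_indices": {k: v.tolist() for k, v in truth.lesion_indices.items()},
            "disease_labels": list(truth.disease_labels),
        }
        (root / "ground_truth.json").write_text(json.dumps(gt, sort_keys=True))
    return root


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis on a cohort directory; returns the run dir.

    Deterministic given (inputs, config, seed): two runs produce
    byte-identical reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}

    with _stage("volume_io"):
        report["input_hash"] = hash_inputs(config.input_dir)
        volumes, gm_maps, atlas, table = load_cohort_dir(config.input_dir)
        mask = volume_io.coverage_mask(volumes, config.coverage_threshold)
        volume_io.save_mask(mask, out / "mask.nii.gz")
        report["n_subjects"] = len(table)
        report["n_voxels"] = mask.n_voxels

    with _stage("preprocess"):
        smoothing = SmoothingConfig(
            sigma=config.smoothing_sigma, kernel_size=config.smoothing_kernel_size
        )
        processed = [
            preprocess_volume(v, mask, smoothing, config.scaling_method)
            for v in volumes
        ]
        cohort = volume_io.build_cohort_matrix(processed, table, mask)
        gm_priors = {
            g.subject_id: gm_prior(g, mask, subject_id=g.subject_id).values
            for g in gm_maps
        }

    with _stage("healthy_model"):
        model = fit_healthy_model(cohort, ddof=config.ddof)
        save_model(model, out / "model", mask)

    with _stage("discriminant"):
        loo = discriminant.loo_evaluate(
            cohort,
            table,
            gm_priors,
            n_components=config.n_components,
            tw_grid=config.tw_grid(),
            tb_grid=config.tb_grid(),
            ddof=config.ddof,
        )
        surf = loo.training_surface
        surface_frame = pd.DataFrame(
            {
                "t_w": np.repeat(surf.tw_grid, len(surf.tb_grid)),
                "t_b": np.tile(surf.tb_grid, len(surf.tw_grid)),
                "sensitivity": surf.sensitivity.ravel(),
                "specificity": surf.specificity.ravel(),
                "misclassification": surf.misclassification.ravel(),
            }
        )
        surface_frame.to_csv(out / "surface.csv", index=False)
        report["loo"] = {
            "sensitivity": loo.sensitivity,
            "specificity": loo.specificity,
            "misclassification": loo.misclassification,
            "modal_t_w": loo.modal_thresholds.t_w,
            "modal_t_b": loo.modal_thresholds.t_b,
            "modal_fraction": loo.modal_fraction,
            "training_t_w": surf.chosen.t_w,
            "training_t_b": surf.chosen.t_b,
            "folds": [
                {
                    "subject_id": f.subject_id,
                    "true_group": f.true_group,
                    "predicted": f.predicted,
                    "count": f.count,
                    "t_w": f.thresholds.t_w,
                    "t_b": f.thresholds.t_b,
                }
                for f in loo.folds
            ],
        }
        is_ad = np.array([g.startswith("AD") for g in cohort.groups])
        acc, sens, spec = discriminant.svm_classify(
            loo.posteriors_matrix(), is_ad, cost=config.svm_cost
        )
        report["svm"] = {"accuracy": acc, "sensitivity": sens, "specificity": spec}

    with _stage("regional"):
        if atlas is not None:
            hypo_masks = {
                f.subject_id: f.posterior >= f.thresholds.t_w for f in loo.folds
            }
            groups_by_id = dict(zip(cohort.subject_ids, cohort.groups))
            reg = regional.build_regional_report(
                hypo_masks, atlas, mask, groups_by_id, config.test_method
            )
            reg.counts.to_csv(out / "regional_counts.csv")
            report["regional"] = {
                "fractions_pooled": reg.fractions_pooled.to_dict(),
                "fractions_mean": reg.fractions_mean.to_dict(),
                "p_values": reg.p_values.to_dict(),
                "excluded_regions": reg.excluded_regions,
            }
            hypo_volume = {
                f.subject_id: discriminant.count_hypoperfused(
                    f.posterior, f.thresholds.t_w
                )
                for f in loo.folds
            }
            correct_ad = [
                s
                for s in cohort.subject_ids
                if groups_by_id[s].startswith("AD") and loo.is_correct(s)
            ]
            if len(correct_ad) >= 3:
                corr = regional.clinical_correlations(
                    hypo_volume, table, correct_ad, config.correlation_method
                )
                report["correlations"] = {
                    cov: {
                        "rho": corr.loc[cov, "rho"],
                        "p_value": corr.loc[cov, "p_value"],
                        "n": int(corr.loc[cov, "n"]),
                    }
                    for cov in corr.index
                }

    text = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    (out / "report.json").write_text(text)
    return out
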