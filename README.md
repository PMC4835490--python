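# perfcad

Single-subject computer-aided detection of cerebral hypoperfusion from
arterial-spin-labeling (ASL) CBF maps.

Given spatially normalized CBF volumes, per-subject gray-matter probability
maps, a labeled brain atlas, and a clinical table, the pipeline:

1. **Coverage masking** — keeps voxels with nonzero signal in strictly more
   than 95% of subjects (`volume_io`).
2. **Post-processing** — truncated Gaussian smoothing (σ = 2 voxels, 7³
   window) and per-volume min–max feature scaling over the mask
   (`preprocess`).
3. **Healthy reference model** — voxel-wise Gaussian fit (population-SD
   divisor) over healthy controls, plus T-score maps (`healthy_model`).
4. **Likelihood of hypoperfusion** — Gaussian survival function
   `L = 1 − Φ((x − μ)/σ)`; values near 1 flag hypoperfusion (`comparison`).
5. **Priors and posterior** — gray-matter probability prior and a
   disease-predictive prior from PCA-reduced ordinary least squares on the
   stacked likelihoods (Gram-matrix eigen-trick, 20 components, min–max
   rescaled weights); posterior `P = mean_m(L · π_m)` (`predictive_prior`,
   `comparison`).
6. **Two-threshold classification** — count voxels with `P ≥ t_w`, call a
   subject diseased when the count exceeds `t_b`; both cutoffs picked by
   exhaustive grid search for minimum misclassification under leave-one-out
   folds (the healthy model and the predictive prior are refit in every
   fold), plus an RBF-SVM reference classifier (`discriminant`).
7. **Regional analysis** — atlas-based accumulation of hypoperfused voxels,
   rank-sum group tests, and Spearman correlations with MMSE / age /
   education (`regional`).

A synthetic cohort generator (`synth`) produces box-atlas phantoms with
planted multiplicative lesions, matched GM maps, and burden-coupled MMSE so
the whole pipeline is testable without clinical data.

## CLI

```sh
# generate a synthetic cohort directory
perfcad simulate --out cohort/ --seed 42 --n-hc 30 --n-ad 30 --effect 0.70

# fit and persist the healthy model
perfcad build-model --cohort cohort/ --out model/

# per-subject score maps (T-score, likelihood, posterior) as NIfTI
perfcad score --cohort cohort/ --subject ad000 --out scores/

# classify one subject at fixed thresholds (JSON report)
perfcad classify --cohort cohort/ --subject ad000 --tw 0.86 --tb 200

# leave-one-out evaluation: surfaces, thresholds, pooled rates
perfcad evaluate --cohort cohort/ --out run/

# regional accumulation at a fixed t_w
perfcad regional --cohort cohort/ --out regional/ --tw 0.86

# full pipeline from a YAML config
perfcad report --config config.yaml
```

A cohort directory contains `clinical.csv`, `volumes/<id>.nii.gz`,
`gm/<id>.nii.gz`, `atlas.nii.gz` + `atlas_labels.tsv`, and (for synthetic
cohorts) `ground_truth.json`. `PipelineConfig` (YAML) exposes smoothing,
scaling, coverage threshold, PCA components, threshold grids, the SD
divisor, and the seed; runs are deterministic given config + inputs.

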