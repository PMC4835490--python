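"""Two-threshold discriminant analysis with leave-one-out evaluation.

A subject's "hypoperfused volume" is the number of posterior voxels at or
above the within-subject cutoff t_w; the subject is called diseased when
that count strictly exceeds the between-subject cutoff t_b.  Both cutoffs
are picked by exhaustive grid search for minimum misclassification, under
leave-one-out folds in which the healthy model and the predictive prior are
refit without the held-out subject.  An RBF max-margin classifier on the
posterior vectors is provided as the reference alternative.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .comparison import PriorSet, ScoreMap, gm_prior, likelihood_map, posterior_map
from .healthy_model import fit_healthy_model
from .predictive_prior import (
    DEFAULT_N_COMPONENTS,
    RegressionDesign,
    build_predictive_prior,
)
from .volume_io import ClinicalTable, CohortMatrix

DEFAULT_TW = 0.86
DEFAULT_TB = 200


def default_tw_grid() -> np.ndarray:
    return np.round(np.arange(0.50, 1.0 + 1e-9, 0.01), 2)


def default_tb_grid() -> np.ndarray:
    return np.arange(0, 5001, 50)


@dataclass(frozen=True)
class DiscriminantThresholds:
    """Probability cutoff t_w in [0.5, 1] and voxel-count cutoff t_b >= 0."""

    t_w: float
    t_b: int

    def __post_init__(self) -> None:
        if not 0.5 <= self.t_w <= 1.0:
            raise ValueError("t_w must lie in [0.5, 1]")
        if self.t_b < 0 or int(self.t_b) != self.t_b:
            raise ValueError("t_b must be a non-negative integer")


@dataclass
class EvaluationSurface:
    """Sensitivity/specificity/misclassification over the (t_w, t_b) grid."""

    tw_grid: np.ndarray
    tb_grid: np.ndarray
    sensitivity: np.ndarray  # (n_tw, n_tb)
    specificity: np.ndarray
    misclassification: np.ndarray
    chosen: DiscriminantThresholds
    chosen_index: tuple[int, int]


def count_hypoperfused(P: ScoreMap | np.ndarray, t_w: float) -> int:
    """Voxels with posterior >= t_w (inclusive boundary)."""
    if isinstance(P, ScoreMap):
        if P.kind != "posterior":
            raise ValueError(f"expected a posterior map, got kind {P.kind!r}")
        values = P.values
    else:
        values = np.asarray(P)
    return int((values >= t_w).sum())


def classify_subject(count: int, t_b: int) -> str:
    """AD iff count strictly exceeds t_b."""
    return "AD" if count > t_b else "HC"


def counts_over_grid(posteriors: np.ndarray, tw_grid: np.ndarray) -> np.ndarray:
    """Per-subject hypoperfused-voxel counts for every t_w.

    posteriors: (N, J).  Returns (n_tw, N) integer counts.
    """
    posteriors = np.atleast_2d(np.asarray(posteriors))
    # sort once per subject, then binary-search every cutoff
    sorted_p = np.sort(posteriors, axis=1)
    j = posteriors.shape[1]
    tw_grid = np.asarray(tw_grid)
    counts = np.empty((len(tw_grid), posteriors.shape[0]), dtype=np.int64)
    for s, row in enumerate(sorted_p):
        counts[:, s] = j - np.searchsorted(row, tw_grid, side="left")
    return counts


def grid_search(
    counts_by_tw: np.ndarray,
    is_ad: np.ndarray,
    tw_grid: np.ndarray | None = None,
    tb_grid: np.ndarray | None = None,
) -> EvaluationSurface:
    """Exhaustive (t_w, t_b) evaluation, minimizing misclassification.

    counts_by_tw: (n_tw, N) hypoperfused-voxel counts per t_w per subject.
    Ties are broken by maximal sensitivity+specificity, then smallest t_w,
    then smallest t_b.  On separable data the zero-error region is a large
    plateau that always touches degenerate boundary cells (t_b = 0 with an
    extreme t_w keeping every control at zero count); preferring small t_b
    before t_w would select those cells and leave near-empty hypoperfusion
    masks, so the conservative cutoff is preferred instead.
    """
    tw_grid = default_tw_grid() if tw_grid is None else np.asarray(tw_grid)
    tb_grid = default_tb_grid() if tb_grid is None else np.asarray(tb_grid)
    counts_by_tw = np.asarray(counts_by_tw)
    is_ad = np.asarray(is_ad, dtype=bool)
    if counts_by_tw.shape != (len(tw_grid), len(is_ad)):
        raise ValueError("counts_by_tw shape does not match grid / labels")
    n_ad = int(is_ad.sum())
    n_hc = int((~is_ad).sum())
    if n_ad == 0 or n_hc == 0:
        raise ValueError("both classes must be present")
    n = n_ad + n_hc

    # predicted AD: count > t_b; broadcast to (n_tw, n_tb, N)
    pred_ad = counts_by_tw[:, None, :] > tb_grid[None, :, None]
    tp = (pred_ad & is_ad).sum(axis=2)
    fp = (pred_ad & ~is_ad).sum(axis=2)
    fn = n_ad - tp
    sens = tp / n_ad
    spec = (n_hc - fp) / n_hc
    misc = (fp + fn) / n

    # lexsort: last key is primary
    tw_mesh, tb_mesh = np.meshgrid(tw_grid, tb_grid, indexing="ij")
    order = np.lexsort(
        (
            tb_mesh.ravel(),  # 4th: smallest t_b
            tw_mesh.ravel(),  # 3rd: smallest t_w
            -(sens + spec).ravel(),  # 2nd: max sens+spec
            misc.ravel(),  # 1st: min misclassification
        )
    )
    flat = order[0]
    i_tw, i_tb = np.unravel_index(flat, misc.shape)
    chosen = DiscriminantThresholds(
        t_w=float(tw_grid[i_tw]), t_b=int(tb_grid[i_tb])
    )
    return EvaluationSurface(
        tw_grid=tw_grid,
        tb_grid=tb_grid,
        sensitivity=sens,
        specificity=spec,
        misclassification=misc,
        chosen=chosen,
        chosen_index=(int(i_tw), int(i_tb)),
    )


@dataclass
class FoldResult:
    subject_id: str
    true_group: str
    predicted: str
    count: int
    thresholds: DiscriminantThresholds
    posterior: np.ndarray = field(repr=False)


@dataclass
class LOOResult:
    folds: list[FoldResult]
    sensitivity: float
    specificity: float
    misclassification: float
    modal_thresholds: DiscriminantThresholds
    modal_fraction: float
    training_surface: EvaluationSurface  # surface on the full cohort, reported
    # alongside pooled LOO rates because the two can differ

    def posteriors_matrix(self) -> np.ndarray:
        return np.stack([f.posterior for f in self.folds])

    def is_correct(self, subject_id: str) -> bool:
        f = next(f for f in self.folds if f.subject_id == subject_id)
        truth = "AD" if f.true_group.startswith("AD") else "HC"
        return f.predicted == truth


def _pooled_rates(folds: Sequence[FoldResult]) -> tuple[float, float, float]:
    tp = sum(1 for f in folds if f.true_group.startswith("AD") and f.predicted == "AD")
    tn = sum(1 for f in folds if f.true_group == "HC" and f.predicted == "HC")
    n_ad = sum(1 for f in folds if f.true_group.startswith("AD"))
    n_hc = len(folds) - n_ad
    sens = tp / n_ad if n_ad else float("nan")
    spec = tn / n_hc if n_hc else float("nan")
    misc = 1.0 - (tp + tn) / len(folds)
    return sens, spec, misc


def loo_evaluate(
    cohort: CohortMatrix,
    clinical: ClinicalTable,
    gm_priors: dict[str, np.ndarray],
    n_components: int = DEFAULT_N_COMPONENTS,
    tw_grid: np.ndarray | None = None,
    tb_grid: np.ndarray | None = None,
    ddof: int = 0,
) -> LOOResult:
    """Leave-one-out evaluation of the two-threshold classifier.

    Per fold, with subject h held out: the healthy model is refit on the
    remaining HC subjects, the predictive prior on the remaining design rows,
    thresholds are picked by grid search over the training subjects only, and
    h is classified at those thresholds.
    """
    tw_grid = default_tw_grid() if tw_grid is None else np.asarray(tw_grid)
    tb_grid = default_tb_grid() if tb_grid is None else np.asarray(tb_grid)
    ids = cohort.subject_ids
    groups = cohort.groups
    is_ad_all = np.array([g.startswith("AD") for g in groups])
    if (~is_ad_all).sum() < 2 or is_ad_all.sum() < 2:
        raise ValueError("need >= 2 HC and >= 2 AD subjects")
    missing_gm = [s for s in ids if s not in gm_priors]
    if missing_gm:
        raise ValueError(f"missing gm priors for subjects: {missing_gm}")

    folds: list[FoldResult] = []
    for h, held_id in enumerate(ids):
        train_ids = [s for s in ids if s != held_id]
        train_is_ad = np.array([is_ad_all[ids.index(s)] for s in train_ids])
        if train_is_ad.all() or not train_is_ad.any():
            raise ValueError(f"fold {held_id!r}: single-class training set")
        model = fit_healthy_model(cohort, exclude=[held_id], ddof=ddof)
        likelihoods = {
            s: likelihood_map(cohort.gamma[ids.index(s)], model, subject_id=s)
            for s in ids
        }
        design = RegressionDesign.from_likelihoods(
            [likelihoods[s] for s in train_ids],
            [groups[ids.index(s)] for s in train_ids],
        )
        pi_pp = build_predictive_prior(design, K=n_components)

        def posterior_for(s: str) -> ScoreMap:
            priors = PriorSet(
                priors={
                    "gm": ScoreMap(gm_priors[s], kind="prior", subject_id=s),
                    "predictive": pi_pp,
                }
            )
            return posterior_map(likelihoods[s], priors)

        train_post = np.stack([posterior_for(s).values for s in train_ids])
        counts_by_tw = counts_over_grid(train_post, tw_grid)
        surface = grid_search(counts_by_tw, train_is_ad, tw_grid, tb_grid)
        held_post = posterior_for(held_id)
        count = count_hypoperfused(held_post, surface.chosen.t_w)
        predicted = classify_subject(count, surface.chosen.t_b)
        folds.append(
            FoldResult(
                subject_id=held_id,
                true_group=groups[h],
                predicted=predicted,
                count=count,
                thresholds=surface.chosen,
                posterior=held_post.values,
            )
        )

    sens, spec, misc = _pooled_rates(folds)
    pairs = collections.Counter((f.thresholds.t_w, f.thresholds.t_b) for f in folds)
    (modal_pair, modal_n) = pairs.most_common(1)[0]

    # training-set surface on the full cohort (no hold-out), for reporting
    model_all = fit_healthy_model(cohort, ddof=ddof)
    likelihoods_all = [
        likelihood_map(cohort.gamma[i], model_all, subject_id=s)
        for i, s in enumerate(ids)
    ]
    design_all = RegressionDesign.from_likelihoods(likelihoods_all, groups)
    pi_pp_all = build_predictive_prior(design_all, K=n_components)
    post_all = np.stack(
        [
            posterior_map(
                likelihoods_all[i],
                PriorSet(
                    priors={
                        "gm": ScoreMap(gm_priors[s], kind="prior", subject_id=s),
                        "predictive": pi_pp_all,
                    }
                ),
            ).values
            for i, s in enumerate(ids)
        ]
    )
    surface_all = grid_search(
        counts_over_grid(post_all, tw_grid), is_ad_all, tw_grid, tb_grid
    )

    return LOOResult(
        folds=folds,
        sensitivity=sens,
        specificity=spec,
        misclassification=misc,
        modal_thresholds=DiscriminantThresholds(t_w=modal_pair[0], t_b=modal_pair[1]),
        modal_fraction=modal_n / len(folds),
        training_surface=surface_all,
    )


def svm_classify(
    posteriors: np.ndarray,
    is_ad: np.ndarray,
    gamma: float | None = None,
    cost: float = 1.0,
) -> tuple[float, float, float]:
    """RBF max-margin classifier on posterior vectors under LOO folds.

    Returns (accuracy, sensitivity, specificity).  Kernel width defaults to
    1/J; hyperparameters are deliberately simple and config-exposed.
    """
    posteriors = np.asarray(posteriors)
    is_ad = np.asarray(is_ad, dtype=bool)
    n, j = posteriors.shape
    if gamma is None:
        gamma = 1.0 / j
    preds = np.zeros(n, dtype=bool)
    for h in range(n):
        train = np.arange(n) != h
        y_train = is_ad[train]
        if y_train.all() or not y_train.any():
            raise ValueError(f"fold {h}: single-class training set")
        clf = SVC(kernel="rbf", gamma=gamma, C=cost)
        clf.fit(posteriors[train], y_train)
        preds[h] = bool(clf.predict(posteriors[h : h + 1])[0])
    tp = (preds & is_ad).sum()
    tn = (~preds & ~is_ad).sum()
    accuracy = (tp + tn) / n
    sens = tp / is_ad.sum()
    spec = tn / (~is_ad).sum()
    return float(accuracy), float(sens), float(spec)
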