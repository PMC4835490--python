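"""Voxel-wise likelihood of hypoperfusion and prior-corrected posteriors.

The likelihood at a voxel is the Gaussian survival function
``L = 1 - Phi((x - mu) / sigma)``: values near 1 flag hypoperfusion, 0.5 is
normal, near 0 is hyperperfusion.  Priors (gray-matter probability and the
disease-predictive map) enter as an arithmetic mean of element-wise
products, ``P = mean_m(L * pi_m)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import ndtr

from .volume_io import Volume3D, VoxelMask, linearize

if TYPE_CHECKING:  # pragma: no cover
    from .healthy_model import HealthyModel

logger = logging.getLogger(__name__)

SCORE_KINDS = ("tscore", "likelihood", "prior", "posterior")


@dataclass
class ScoreMap:
    """Per-voxel scalar map for one subject, in mask (linearized) order."""

    values: np.ndarray
    kind: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in SCORE_KINDS:
            raise ValueError(f"unknown score kind {self.kind!r}")
        if self.kind in ("likelihood", "prior", "posterior"):
            v = self.values
            if (v < 0).any() or (v > 1).any():
                raise ValueError(f"{self.kind} values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def to_volume(self, mask: VoxelMask, fill: float = 0.0) -> Volume3D:
        from .volume_io import delinearize

        return delinearize(self.values, mask, fill=fill, subject_id=self.subject_id)


@dataclass
class PriorSet:
    """Named prior maps (e.g. gm, predictive), each element-wise in [0, 1]."""

    priors: dict[str, ScoreMap]

    def __post_init__(self) -> None:
        if not self.priors:
            raise ValueError("need at least one prior")
        lengths = {len(p) for p in self.priors.values()}
        if len(lengths) != 1:
            raise ValueError("priors have inconsistent lengths")
        for name, p in self.priors.items():
            if p.kind != "prior":
                raise ValueError(f"prior {name!r} has kind {p.kind!r}")

    @property
    def n_priors(self) -> int:
        return len(self.priors)


def likelihood_map(
    subject: np.ndarray, model: "HealthyModel", subject_id: str = ""
) -> ScoreMap:
    """Survival-function likelihood of hypoperfusion per voxel."""
    subject = np.asarray(subject, dtype=np.float64)
    if subject.shape != model.mu.shape:
        raise ValueError("subject vector length does not match model")
    z = (subject - model.mu) / model.sigma
    return ScoreMap(values=ndtr(-z), kind="likelihood", subject_id=subject_id)


def posterior_map(L: ScoreMap, priors: PriorSet) -> ScoreMap:
    """Mean over priors of the element-wise product with the likelihood."""
    if L.kind != "likelihood":
        raise ValueError("first argument must be a likelihood map")
    acc = np.zeros_like(L.values)
    for name, p in priors.priors.items():
        if len(p) != len(L):
            raise ValueError(f"prior {name!r} length does not match likelihood")
        acc += L.values * p.values
    return ScoreMap(
        values=acc / priors.n_priors, kind="posterior", subject_id=L.subject_id
    )


def gm_prior(
    gm_probability: Volume3D, mask: VoxelMask, subject_id: str = ""
) -> ScoreMap:
    """Gray-matter probability linearized over the mask; suppresses white
    matter and out-of-brain signal in the posterior.  Values outside [0, 1]
    are clipped with a warning."""
    vals = linearize(gm_probability, mask)
    n_out = int(((vals < 0) | (vals > 1)).sum())
    if n_out:
        logger.warning(
            "gm prior %s: clipped %d values outside [0, 1]", subject_id, n_out
        )
        vals = np.clip(vals, 0.0, 1.0)
    return ScoreMap(values=vals, kind="prior", subject_id=subject_id)
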