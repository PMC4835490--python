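"""Disease-predictive prior via PCA-reduced ordinary least squares.

With many more voxels J than subjects N, per-voxel regression weights are
obtained by the Gram-matrix eigen-trick: eigendecompose the N x N matrix
N^-1 X X^T of the centered design, map the top-K eigenvectors back to voxel
space, solve OLS in the K-dimensional projection, and back-project the
coefficients.  The resulting weight vector, min-max rescaled to [0, 1],
serves as the second prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .comparison import ScoreMap

DEFAULT_N_COMPONENTS = 20
EIG_TOL = 1e-12


@dataclass
class RegressionDesign:
    """Stacked likelihood rows X and group codes y (HC -> -1, AD -> +1)."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        n = self.X.shape[0]
        if n < 3:
            raise ValueError("need >= 3 subjects for the regression design")
        if self.y.shape != (n,) or len(self.subject_ids) != n:
            raise ValueError("design row count mismatch")
        if not (set(np.unique(self.y)) <= {-1.0, 1.0}):
            raise ValueError("y must be coded -1 (HC) / +1 (AD)")
        if len(set(self.y)) < 2:
            raise ValueError("both classes must be present")

    @classmethod
    def from_likelihoods(
        cls, likelihoods: Sequence[ScoreMap], groups: Sequence[str]
    ) -> "RegressionDesign":
        X = np.stack([L.values for L in likelihoods])
        y = np.array([1.0 if g.startswith("AD") else -1.0 for g in groups])
        return cls(X=X, y=y, subject_ids=[L.subject_id for L in likelihoods])

    def without(self, exclude: Sequence[str]) -> "RegressionDesign":
        keep = [i for i, s in enumerate(self.subject_ids) if s not in set(exclude)]
        return RegressionDesign(
            X=self.X[keep],
            y=self.y[keep],
            subject_ids=[self.subject_ids[i] for i in keep],
        )


@dataclass
class PCARegressionResult:
    U: np.ndarray  # J x K data-space eigenvectors, unit norm columns
    lambdas: np.ndarray  # K eigenvalues, descending
    V: np.ndarray  # N x K small-space eigenvectors
    beta_reduced: np.ndarray  # K
    beta_full: np.ndarray  # J = U @ beta_reduced
    K: int


def pca_highdim(X: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-K principal directions of a wide matrix via the N x N Gram trick.

    Centers X by column means, eigendecomposes N^-1 X X^T, and maps
    small-space eigenvectors v_j to unit-norm data-space directions
    u_j = (N lambda_j)^-1/2 X^T v_j.  Components with eigenvalue at or below
    numerical tolerance are dropped with a warning.

    Returns (U, lambdas, V).
    """
    X = np.asarray(X, dtype=np.float64)
    n, j = X.shape
    if K > n - 1:
        raise ValueError(f"K={K} exceeds N-1={n - 1}")
    Xc = X - X.mean(axis=0)
    gram = Xc @ Xc.T / n
    evals, evecs = np.linalg.eigh(gram)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lambdas = evals[:K]
    V = evecs[:, :K]
    tol = max(EIG_TOL, EIG_TOL * max(evals.max(), 0.0))
    valid = lambdas > tol
    if not valid.all():
        k_eff = int(valid.sum())
        warnings.warn(
            f"reduced K from {K} to {k_eff}: eigenvalues at numerical tolerance",
            RuntimeWarning,
            stacklevel=2,
        )
        lambdas, V = lambdas[:k_eff], V[:, :k_eff]
    U = Xc.T @ (V / np.sqrt(n * lambdas))
    return U, lambdas, V


def fit_reduced_ols(X_reduced: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS via normal equations, pseudoinverse fallback on rank deficiency."""
    X_reduced = np.asarray(X_reduced, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xtx = X_reduced.T @ X_reduced
    xty = X_reduced.T @ y
    try:
        return np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(xtx) @ xty


def rescale_beta(beta: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Map raw voxel weights onto [0, 1] to form a prior."""
    beta = np.asarray(beta, dtype=np.float64)
    if method == "minmax":
        lo, hi = beta.min(), beta.max()
        if hi == lo:
            return np.full_like(beta, 0.5)
        return (beta - lo) / (hi - lo)
    if method == "abs":
        m = np.abs(beta).max()
        return np.abs(beta) / m if m > 0 else np.full_like(beta, 0.5)
    if method == "clip":
        return np.clip(beta, 0.0, 1.0)
    raise ValueError(f"unknown rescale method {method!r}")


def pca_regression(
    design: RegressionDesign, K: int = DEFAULT_N_COMPONENTS
) -> PCARegressionResult:
    n = design.X.shape[0]
    k = min(K, n - 1)
    U, lambdas, V = pca_highdim(design.X, k)
    Xc = design.X - design.X.mean(axis=0)
    X_reduced = Xc @ U
    beta_reduced = fit_reduced_ols(X_reduced, design.y)
    beta_full = U @ beta_reduced
    return PCARegressionResult(
        U=U,
        lambdas=lambdas,
        V=V,
        beta_reduced=beta_reduced,
        beta_full=beta_full,
        K=len(lambdas),
    )


def build_predictive_prior(
    design: RegressionDesign,
    K: int = DEFAULT_N_COMPONENTS,
    exclude: Sequence[str] = (),
    rescale: str = "minmax",
) -> ScoreMap:
    """Fit the PCA regression without ``exclude`` and rescale the voxel
    weights into a [0, 1] prior map.  Raises if exclusion leaves one class."""
    train = design.without(exclude) if exclude else design
    result = pca_regression(train, K=K)
    return ScoreMap(
        values=rescale_beta(result.beta_full, rescale),
        kind="prior",
        subject_id="predictive",
    )
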