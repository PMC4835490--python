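"""Post-processing: truncated Gaussian smoothing and per-volume feature scaling."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume3D, VoxelMask, linearize


@dataclass(frozen=True)
class SmoothingConfig:
    """Gaussian smoothing parameters in voxel units.

    ``kernel_size`` is the window edge extent s; the realized window is the
    smallest centered odd window containing it, i.e. half-width ceil(s/2)
    (7^3 taps for s = 6).
    """

    sigma: float = 2.0
    kernel_size: int = 6

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")

    @property
    def half_width(self) -> int:
        return math.ceil(self.kernel_size / 2)


def gaussian_kernel_1d(sigma: float, half_width: int) -> np.ndarray:
    """Truncated 1D Gaussian on [-half_width, half_width], renormalized to sum 1."""
    x = np.arange(-half_width, half_width + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(volume: Volume3D, cfg: SmoothingConfig | None = None) -> Volume3D:
    """Separable 3D Gaussian convolution, zero-padded boundaries.

    The truncated kernel is renormalized to sum 1, so constants are preserved
    away from the boundary.
    """
    cfg = cfg or SmoothingConfig()
    smoothed = ndimage.gaussian_filter(
        volume.data,
        sigma=cfg.sigma,
        mode="constant",
        cval=0.0,
        radius=cfg.half_width,
    )
    return Volume3D(
        data=smoothed, voxel_size=volume.voxel_size, subject_id=volume.subject_id
    )


def feature_scale(
    volume: Volume3D, mask: VoxelMask | None = None, method: str = "minmax"
) -> Volume3D:
    """Per-volume intensity normalization over masked voxels.

    ``minmax`` (default): v' = (v - min) / (max - min), masked voxels land in
    [0, 1].  ``global_mean``: v' = v / mean(v) over the mask.  Unmasked voxels
    are set to 0 either way.  Removes global CBF offset/scale differences
    between subjects (labeling efficiency, global hypoperfusion).
    """
    if mask is None:
        mask = VoxelMask.full(volume.shape)
    vals = linearize(volume, mask)
    out = np.zeros(volume.shape, dtype=np.float64)
    if method == "minmax":
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            raise ValueError(
                f"degenerate volume {volume.subject_id!r}: max == min over mask"
            )
        out[mask.keep] = (vals - lo) / (hi - lo)
    elif method == "global_mean":
        m = vals.mean()
        if m == 0:
            raise ValueError(
                f"degenerate volume {volume.subject_id!r}: zero mean over mask"
            )
        out[mask.keep] = vals / m
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return Volume3D(
        data=out, voxel_size=volume.voxel_size, subject_id=volume.subject_id
    )


def preprocess_volume(
    volume: Volume3D,
    mask: VoxelMask,
    smoothing: SmoothingConfig | None = None,
    scaling_method: str = "minmax",
) -> Volume3D:
    """Smooth then feature-scale (over the mask), the fixed stage order."""
    return feature_scale(gaussian_smooth(volume, smoothing), mask, scaling_method)
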