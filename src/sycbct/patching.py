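"""Patch sampling for training and Gaussian-weighted sliding-window fusion.

Training draws random 3D patches (with replacement, uniform origins)
jointly from the MRI and CBCT of a prepared pair.  Inference tiles the
volume with a half-patch stride, predicts each patch, weights every
prediction by a separable Gaussian window and overlap-adds, normalising
by the accumulated weight — a partition-of-unity fusion that removes
seam artifacts at patch borders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .io_volumes import Volume
from .preprocess import PairedStudy

__all__ = [
    "PatchSpec",
    "GaussianWindow",
    "PATCH_PRESETS",
    "sample_random_patches",
    "tile_origins",
    "gaussian_window",
    "fuse_patches",
]


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry; the inference stride is half the size per axis."""

    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        size = tuple(int(s) for s in self.size)
        if len(size) != 3 or any(s < 2 or s % 2 for s in size):
            raise ValueError(f"patch dimensions must be even and >= 2, got {size}")
        object.__setattr__(self, "size", size)

    @property
    def stride(self) -> tuple[int, int, int]:
        return tuple(s // 2 for s in self.size)  # type: ignore[return-value]


#: the two patch geometries used for training/inference experiments
PATCH_PRESETS = {
    "large": PatchSpec((128, 128, 16)),
    "small": PatchSpec((64, 64, 16)),
}


@dataclass(frozen=True)
class GaussianWindow:
    """Separable per-voxel fusion weights of patch shape, peak at centre."""

    weights: np.ndarray
    sigma: tuple[float, float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("window weights must be strictly positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "sigma", tuple(float(s) for s in self.sigma))


def gaussian_window(spec: PatchSpec, sigma_frac: float = 0.125) -> GaussianWindow:
    """Separable Gaussian ``exp(-d^2 / 2 sigma^2)`` per axis.

    ``d`` is the offset from the patch centre ``(n - 1) / 2`` and
    ``sigma = sigma_frac * n`` for axis length ``n``.  The continuous
    profile peaks at 1 at the centre; the default ``sigma_frac`` of 1/8
    down-weights patch borders by ~e^-8.
    """
    if sigma_frac <= 0:
        raise ValueError("sigma_frac must be positive")
    axes = []
    sigmas = []
    for n in spec.size:
        sigma = sigma_frac * n
        d = np.arange(n) - (n - 1) / 2.0
        axes.append(np.exp(-0.5 * (d / sigma) ** 2))
        sigmas.append(sigma)
    w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return GaussianWindow(weights=w, sigma=tuple(sigmas))


def _axis_origins(dim: int, size: int, stride: int) -> np.ndarray:
    if dim < size:
        raise ValueError(f"axis extent {dim} smaller than patch size {size}")
    origins = list(range(0, dim - size + 1, stride))
    if origins[-1] != dim - size:
        origins.append(dim - size)  # flush with the boundary, no padding
    return np.asarray(origins)


def tile_origins(vol_dims: Sequence[int], spec: PatchSpec) -> list[tuple[int, int, int]]:
    """Ordered sliding-window origins with half-patch stride.

    Per axis: ``0, s, 2s, ...`` with ``s = size/2``, plus a final origin
    flush with the boundary when ``dim - size`` is not a multiple of
    ``s``.  The union of patches covers every voxel.
    """
    per_axis = [_axis_origins(d, s, st) for d, s, st in zip(vol_dims, spec.size, spec.stride)]
    return [
        (int(x), int(y), int(z))
        for x in per_axis[0]
        for y in per_axis[1]
        for z in per_axis[2]
    ]


def sample_random_patches(
    pair: PairedStudy, spec: PatchSpec, n: int, seed: int | np.random.Generator = 0
) -> list[tuple[np.ndarray, np.ndarray, tuple[int, int, int]]]:
    """Draw ``n`` aligned (mri_patch, cbct_patch, origin) triples.

    Origins are uniform over all valid positions (with replacement);
    the MRI and CBCT patches are cut at identical origins.
    """
    dims = pair.mri.shape
    for d, s in zip(dims, spec.size):
        if d < s:
            raise ValueError(f"patch size {spec.size} does not fit volume {dims}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mri = np.asarray(pair.mri.values)
    cbct = np.asarray(pair.cbct.values)
    out = []
    highs = [d - s + 1 for d, s in zip(dims, spec.size)]
    origins = np.stack([rng.integers(0, h, size=n) for h in highs], axis=1)
    for ox, oy, oz in origins:
        sl = (slice(ox, ox + spec.size[0]), slice(oy, oy + spec.size[1]), slice(oz, oz + spec.size[2]))
        out.append((mri[sl].copy(), cbct[sl].copy(), (int(ox), int(oy), int(oz))))
    return out


def fuse_patches(
    patches: Sequence[tuple[np.ndarray, tuple[int, int, int]]],
    window: GaussianWindow,
    vol_dims: Sequence[int],
    *,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    modality: str = "SYCBCT",
) -> Volume:
    """Weight-normalised overlap-add of patch predictions.

    Every output voxel is ``sum(w * pred) / sum(w)`` over the patches
    covering it, so constant predictions fuse to the same constant and
    smooth fields show no seams.  Raises if any voxel is uncovered.
    """
    acc = np.zeros(tuple(vol_dims), dtype=np.float64)
    wsum = np.zeros(tuple(vol_dims), dtype=np.float64)
    w = window.weights
    for pred, origin in patches:
        pred = np.asarray(pred, dtype=np.float64)
        if pred.shape != w.shape:
            raise ValueError(f"prediction shape {pred.shape} != window shape {w.shape}")
        sl = tuple(slice(o, o + s) for o, s in zip(origin, pred.shape))
        acc[sl] += w * pred
        wsum[sl] += w
    if (wsum == 0).any():
        raise ValueError(f"{int((wsum == 0).sum())} voxel(s) not covered by any patch")
    return Volume(acc / wsum, spacing, modality)
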