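"""Preprocessing: rigid MI registration, isotropic reslicing, circular
masking, axis cropping and intensity normalisation.

The preparation pipeline turns a raw (MRI, CBCT) pair into the form the
network trains on: both volumes resampled to a common isotropic spacing,
multiplied by a circular binary mask in every axial plane to suppress
background, cropped to the informative axis ranges, and min-max
normalised to ``[-1, 1]``.  The fixed stage order is
resample -> mask -> crop -> normalise (masking before cropping, since
the mask disk is defined on the full-field axial geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .io_volumes import Volume

__all__ = [
    "RigidTransform",
    "CropRegion",
    "PairedStudy",
    "NormalizationRecord",
    "register_rigid_mi",
    "mutual_information",
    "resample_to_isotropic",
    "apply_circle_mask",
    "crop_to_region",
    "normalize_intensities",
    "denormalize_intensities",
    "prepare_pair",
]


@dataclass(frozen=True)
class RigidTransform:
    """A rigid (rotation + translation) map of physical (mm) space.

    A point ``p`` (mm) maps to ``R @ (p - center) + center + t`` where
    ``R`` applies the x, y, z rotations (intrinsic, in that order) and
    ``t`` is the translation in mm.
    """

    rotations: tuple[float, float, float] = (0.0, 0.0, 0.0)  # radians about x, y, z
    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm

    def __post_init__(self) -> None:
        for name in ("rotations", "translations", "center"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != 3 or not all(np.isfinite(v)):
                raise ValueError(f"{name} must be three finite numbers")
            object.__setattr__(self, name, v)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotations).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of mm points forward through the transform."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center)
        return (p - c) @ self.matrix.T + c + np.asarray(self.translations)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``.

        The composite is re-expressed about ``self.center``.
        """
        r = self.matrix @ other.matrix
        # solve for t' such that R p + shift == self(other(p)) about center c
        c = np.asarray(self.center)
        probe = self.apply(other.apply(np.zeros((1, 3))))[0]
        # composite: p -> r @ (p - c) + c + t'  with t' chosen to match probe at 0
        t = probe - (r @ (-c) + c)
        ang = Rotation.from_matrix(r).as_euler("xyz")
        return RigidTransform(tuple(ang), tuple(t), tuple(c))

    def invert(self) -> "RigidTransform":
        rinv = self.matrix.T
        c = np.asarray(self.center)
        t = np.asarray(self.translations)
        # forward: q = R(p - c) + c + t  =>  p = R^T (q - c - t) + c
        ang = Rotation.from_matrix(rinv).as_euler("xyz")
        tinv = rinv @ (-t)
        return RigidTransform(tuple(ang), tuple(tinv), tuple(c))

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotations, 0) and np.allclose(self.translations, 0)


@dataclass(frozen=True)
class CropRegion:
    """Inclusive 1-based index intervals per axis (clinical slice numbering)."""

    x_range: tuple[int, int]
    y_range: tuple[int, int]
    z_range: tuple[int, int]

    def __post_init__(self) -> None:
        for name in ("x_range", "y_range", "z_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name}=({lo}, {hi}) is not a valid 1-based inclusive interval")
            object.__setattr__(self, name, (int(lo), int(hi)))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        """0-based half-open slices equivalent to the 1-based ranges."""
        return tuple(slice(lo - 1, hi) for lo, hi in (self.x_range, self.y_range, self.z_range))  # type: ignore[return-value]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo + 1 for lo, hi in (self.x_range, self.y_range, self.z_range))  # type: ignore[return-value]


#: the informative axis ranges on the full-scale 512-cube grid
DEFAULT_CROP = CropRegion((21, 490), (1, 360), (41, 380))


@dataclass
class PairedStudy:
    """A registered (MRI, CBCT) pair: the unit of training/evaluation data."""

    mri: Volume
    cbct: Volume
    registered: bool = False
    transform: RigidTransform = field(default_factory=RigidTransform)

    def __post_init__(self) -> None:
        if self.registered:
            if self.mri.shape != self.cbct.shape:
                raise ValueError(
                    f"registered pair must share dimensions, got {self.mri.shape} vs {self.cbct.shape}"
                )
            if not np.allclose(self.mri.spacing, self.cbct.spacing):
                raise ValueError("registered pair must share spacing")


@dataclass(frozen=True)
class NormalizationRecord:
    """Affine record ``original = normalized * scale + offset``."""

    scale: float
    offset: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# mutual information + rigid registration


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Histogram mutual information (nats) between two equal-shape images."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("MI undefined for a constant volume")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _resample_through(vol: Volume, t: RigidTransform, cval: float, order: int = 1) -> np.ndarray:
    """Pull-back resample: output voxel v gets input value at t^{-1}(v)."""
    spacing = np.asarray(vol.spacing)
    inv = t.invert()
    # voxel -> mm, apply inverse transform, mm -> voxel
    r = inv.matrix
    c = np.asarray(inv.center)
    off = np.asarray(inv.translations)
    # input_index = D^-1 (R (D i - c) + c + off) where D = diag(spacing)
    m = (r * spacing[None, :]) / spacing[:, None]
    o = (r @ (-c) + c + off) / spacing
    return ndimage.affine_transform(
        np.asarray(vol.values, dtype=float), m, offset=o, order=order, cval=cval, mode="constant"
    )


@dataclass(frozen=True)
class MIRegistrationOptions:
    """Search configuration for :func:`register_rigid_mi`."""

    translation_bound_mm: float = 6.0
    rotation_bound_rad: float = 0.15
    coarse_steps: int = 5
    bins: int = 32
    maxiter: int = 60
    downsample: int = 1
    initial: RigidTransform | None = None


def register_rigid_mi(
    moving: Volume, fixed: Volume, opts: MIRegistrationOptions | None = None
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed`` by
    maximising histogram mutual information.

    A coarse grid over translations seeds a Powell refinement over all
    six rigid parameters.  Deterministic for fixed options.  The returned
    transform is the one to *apply to the moving volume* (pull-back
    resampling) to align it with the fixed volume.
    """
    opts = opts or MIRegistrationOptions()
    if np.std(np.asarray(moving.values)) == 0 or np.std(np.asarray(fixed.values)) == 0:
        raise ValueError("MI undefined for a constant volume")

    d = max(1, int(opts.downsample))
    mov = moving.values[::d, ::d, ::d].astype(float)
    fix = fixed.values[::d, ::d, ::d].astype(float)
    spacing = tuple(s * d for s in moving.spacing)
    center = tuple((n - 1) / 2 * s for n, s in zip(mov.shape, spacing))
    mov_vol = Volume(mov, spacing, moving.modality, moving.intensity_units)
    cval = float(mov.min())

    def neg_mi(params: np.ndarray) -> float:
        t = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
        resampled = _resample_through(mov_vol, t, cval=cval)
        return -mutual_information(resampled, fix, bins=opts.bins)

    # coarse translation grid (rotations at the initial guess)
    init = opts.initial or RigidTransform(center=center)
    best = np.array(list(init.rotations) + list(init.translations))
    grid = np.linspace(-opts.translation_bound_mm, opts.translation_bound_mm, opts.coarse_steps)
    best_val = neg_mi(best)
    for tx in grid:
        for ty in grid:
            for tz in grid:
                cand = best.copy()
                cand[3:] = init.translations + np.array([tx, ty, tz])
                val = neg_mi(cand)
                if val < best_val:
                    best_val, best = val, cand

    res = optimize.minimize(
        neg_mi,
        best,
        method="Powell",
        options={"maxiter": opts.maxiter, "xtol": 1e-3, "ftol": 1e-6},
    )
    # on noiseless piecewise-constant images the MI surface has a flat
    # plateau around the optimum; keep the seed unless Powell strictly
    # improves, so the search cannot drift across the plateau
    p = res.x if res.fun < best_val - 1e-12 else best
    # re-express the center on the full-resolution grid (same physical point)
    return RigidTransform(tuple(p[:3]), tuple(p[3:]), center)


# ---------------------------------------------------------------------------
# reslicing / masking / cropping / normalisation


def resample_to_isotropic(vol: Volume, target_spacing: float = 0.3) -> Volume:
    """Trilinear resample onto an isotropic grid of ``target_spacing`` mm.

    Output dimensions are ``round(dim * spacing / target)`` per axis.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    in_spacing = np.asarray(vol.spacing)
    if np.allclose(in_spacing, target_spacing):
        return replace(vol, values=np.asarray(vol.values).copy())
    out_shape = tuple(int(round(n * s / target_spacing)) for n, s in zip(vol.shape, in_spacing))
    zoom = target_spacing / in_spacing  # input voxels advanced per output voxel
    coords = np.meshgrid(
        *[np.arange(n) * z for n, z in zip(out_shape, zoom)], indexing="ij"
    )
    out = ndimage.map_coordinates(
        np.asarray(vol.values, dtype=float), coords, order=1, mode="nearest"
    )
    return Volume(out, (target_spacing,) * 3, vol.modality, vol.intensity_units)


def circle_mask_2d(width: int, height: int, radius_px: float) -> np.ndarray:
    """Boolean disk of the given pixel radius centred at ((W-1)/2, (H-1)/2)."""
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    x = np.arange(width)[:, None] - cx
    y = np.arange(height)[None, :] - cy
    return x * x + y * y <= radius_px * radius_px


def apply_circle_mask(vol: Volume, radius_px: float = 256) -> Volume:
    """Zero every voxel whose axial in-plane distance from the slice
    centre exceeds ``radius_px`` pixels; all axial slices are masked
    identically."""
    w, h, _ = vol.shape
    mask = circle_mask_2d(w, h, radius_px)
    out = np.asarray(vol.values, dtype=float) * mask[:, :, None]
    return vol.with_values(out)


def crop_to_region(vol: Volume, region: CropRegion) -> Volume:
    """Crop to the 1-based inclusive per-axis index intervals."""
    for (lo, hi), n, name in zip(
        (region.x_range, region.y_range, region.z_range), vol.shape, "xyz"
    ):
        if hi > n:
            raise ValueError(f"{name}-range ({lo}, {hi}) exceeds volume extent {n}")
    return vol.with_values(np.asarray(vol.values)[region.slices].copy())


def normalize_intensities(
    vol: Volume, lo: float = -1.0, hi: float = 1.0
) -> tuple[Volume, NormalizationRecord]:
    """Affine min-max map of the volume onto ``[lo, hi]``.

    Returns the normalised volume and a record allowing exact inversion.
    A constant volume maps to the interval midpoint and is flagged.
    """
    v = np.asarray(vol.values, dtype=float)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        mid = (lo + hi) / 2.0
        rec = NormalizationRecord(scale=1.0, offset=vmin - mid, degenerate=True)
        return vol.with_values(np.full_like(v, mid)), rec
    scale = (vmax - vmin) / (hi - lo)
    offset = vmin - lo * scale
    rec = NormalizationRecord(scale=scale, offset=offset)
    return vol.with_values((v - offset) / scale), rec


def denormalize_intensities(vol: Volume, rec: NormalizationRecord) -> Volume:
    """Invert :func:`normalize_intensities` via its record."""
    return vol.with_values(np.asarray(vol.values, dtype=float) * rec.scale + rec.offset)


def prepare_pair(
    study: PairedStudy,
    region: CropRegion | None = None,
    radius_px: float | None = 256,
    target_spacing: float | None = 0.3,
    lo: float = -1.0,
    hi: float = 1.0,
) -> tuple[PairedStudy, dict[str, NormalizationRecord]]:
    """Run the full preparation pipeline on a registered pair.

    Stages (in fixed order): resample to isotropic spacing, circular
    axial mask, crop, min-max normalise to ``[lo, hi]``.  Pass ``None``
    for a stage parameter to skip that stage.  Returns the prepared pair
    and the per-modality normalisation records needed to restore the
    CBCT intensity scale after synthesis.
    """
    if not study.registered:
        raise ValueError("pair must be registered first (see register_rigid_mi)")
    records: dict[str, NormalizationRecord] = {}
    out = {}
    for name, vol in (("mri", study.mri), ("cbct", study.cbct)):
        if target_spacing is not None:
            vol = resample_to_isotropic(vol, target_spacing)
        if radius_px is not None:
            vol = apply_circle_mask(vol, radius_px)
        if region is not None:
            vol = crop_to_region(vol, region)
        vol, rec = normalize_intensities(vol, lo, hi)
        records[name] = rec
        out[name] = vol
    return PairedStudy(mri=out["mri"], cbct=out["cbct"], registered=True, transform=study.transform), records
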