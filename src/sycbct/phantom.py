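"""Synthetic registered MRI/CBCT head-phantom pairs with ground truth.

Real paired dental CBCT/MRI volumes cannot be redistributed, so every
stage of the pipeline is exercised on phantoms: a head-shaped
soft-tissue ellipsoid in air containing hard-tissue primitives (a
jaw-arc tube plus tooth-like ellipsoids).  The phantom provides what a
patient scan cannot — exact per-voxel tissue labels, a known (and per
class invertible) MRI<->CBCT intensity relation, and fully controllable
corruption: additive Gaussian noise, a streak-artifact overlay on the
CBCT, and an optional rigid misalignment of the MRI.

Intensity model
---------------
CBCT values are the per-class means (air < soft < hard, HU-like scale)
plus optional streaks and noise.  MRI values emulate a bone-visible
short-TE contrast: soft tissue brightest, hard tissue intermediate, air
dark — the contrast ordering is *inverted* relative to CBCT for the
soft/hard pair, so the network genuinely has to learn a non-identity
intensity remap.  The MRI is mildly blurred to mimic the softer bone
margins of MR imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io_volumes import Volume
from .preprocess import PairedStudy, RigidTransform, _resample_through

__all__ = [
    "IntensityMap",
    "PhantomConfig",
    "TissueLabelVolume",
    "generate_phantom",
    "apply_misregistration",
    "AIR",
    "SOFT",
    "HARD",
]

AIR, SOFT, HARD = 0, 1, 2


@dataclass(frozen=True)
class IntensityMap:
    """Per-class mean levels for the two modalities (air, soft, hard)."""

    cbct: tuple[float, float, float] = (0.0, 400.0, 1400.0)
    mri: tuple[float, float, float] = (40.0, 800.0, 300.0)

    def __post_init__(self) -> None:
        a, s, h = self.cbct
        if not (a < s < h):
            raise ValueError(f"CBCT class means must satisfy air < soft < hard, got {self.cbct}")
        if len(set(self.mri)) != 3:
            raise ValueError("MRI class means must be distinct (per-class invertibility)")


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of one synthetic head phantom pair.

    Defaults mirror a single clinical acquisition: a 512-cube isotropic
    0.3 mm grid.  Tests and scaled-down runs pass smaller grids.
    """

    grid_size: int = 512
    spacing: float = 0.3  # mm, isotropic
    n_hard_structures: int = 9  # 1 jaw arc + 8 tooth ellipsoids
    head_radius_frac: float = 0.85
    intensity_map: IntensityMap = field(default_factory=IntensityMap)
    noise_sigma_mri: float = 20.0
    noise_sigma_cbct: float = 40.0
    streak_amplitude: float = 200.0  # 0 disables
    n_streaks: int = 4
    mri_smoothing_sigma: float = 0.7  # voxels
    misregistration: RigidTransform = field(default_factory=RigidTransform)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if self.n_hard_structures < 0:
            raise ValueError("n_hard_structures must be >= 0")
        if self.noise_sigma_mri < 0 or self.noise_sigma_cbct < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not (0 < self.head_radius_frac <= 1):
            raise ValueError("head_radius_frac must lie in (0, 1]")


@dataclass
class TissueLabelVolume:
    """Ground-truth per-voxel labels over {air, soft, hard}."""

    labels: np.ndarray  # int grid with values AIR/SOFT/HARD
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if not np.isin(self.labels, (AIR, SOFT, HARD)).all():
            raise ValueError("labels must take values in {air, soft, hard}")
        self.spacing = tuple(float(s) for s in self.spacing)

    def mask(self, cls: int) -> np.ndarray:
        return self.labels == cls


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _label_grid(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.grid_size
    labels = np.full((n, n, n), AIR, dtype=np.int8)
    half = (n - 1) / 2.0
    center = (half, half, half)

    # head: soft-tissue ellipsoid, mildly anisotropic so no axis is special
    r = cfg.head_radius_frac * half
    head_axes = (r, 0.92 * r, 0.96 * r)
    labels[_ellipsoid_mask(labels.shape, center, head_axes)] = SOFT

    if cfg.n_hard_structures >= 1:
        # jaw arc: tube following a half-circle in the lower axial band,
        # opening towards the back (+y)
        arc_r = 0.55 * r
        tube_r = max(1.5, 0.08 * r)
        zc = half - 0.35 * r
        t = np.linspace(-0.45 * np.pi, 0.45 * np.pi, max(16, int(2 * arc_r)))
        cx = half + arc_r * np.sin(t)
        cy = half - 0.15 * r - arc_r * (np.cos(t) - 1) * 0.5 - 0.0
        for px, py in zip(cx, cy):
            lo = [max(0, int(np.floor(v - tube_r - 1))) for v in (px, py, zc)]
            hi = [min(n, int(np.ceil(v + tube_r + 2))) for v in (px, py, zc)]
            sub = tuple(slice(l, h) for l, h in zip(lo, hi))
            gx, gy, gz = np.ogrid[sub]
            d2 = (gx - px) ** 2 + (gy - py) ** 2 + (gz - zc) ** 2
            labels[sub][d2 <= tube_r**2] = HARD

        # tooth-like ellipsoids along the arc, jittered by the seed
        n_teeth = cfg.n_hard_structures - 1
        if n_teeth > 0:
            tt = np.linspace(-0.4 * np.pi, 0.4 * np.pi, n_teeth)
            jitter = rng.uniform(-0.02, 0.02, size=(n_teeth, 3)) * r
            tooth = (0.06 * r + 1.0, 0.06 * r + 1.0, 0.12 * r + 1.5)
            for k, a in enumerate(tt):
                px = half + arc_r * np.sin(a) + jitter[k, 0]
                py = half - 0.15 * r - arc_r * (np.cos(a) - 1) * 0.5 + jitter[k, 1]
                pz = zc + 0.10 * r + jitter[k, 2]
                m = _ellipsoid_mask(labels.shape, (px, py, pz), tooth)
                labels[m] = HARD

    return labels


def _streak_field(shape, amplitude: float, n_streaks: int, rng: np.random.Generator) -> np.ndarray:
    """Random bright/dark straight lines through every axial slice.

    Lines are constant along z (rod-like), mimicking the radial scatter
    streaks of cone-beam reconstructions without simulating physics.
    """
    w, h, _ = shape
    x = np.arange(w)[:, None] - (w - 1) / 2
    y = np.arange(h)[None, :] - (h - 1) / 2
    field2d = np.zeros((w, h))
    for _ in range(n_streaks):
        theta = rng.uniform(0, np.pi)
        rho = rng.uniform(-0.4, 0.4) * min(w, h)
        sign = rng.choice([-1.0, 1.0])
        width = rng.uniform(0.8, 2.0)
        d = np.abs(x * np.cos(theta) + y * np.sin(theta) - rho)
        field2d += sign * amplitude * np.exp(-0.5 * (d / width) ** 2)
    return np.repeat(field2d[:, :, None], shape[2], axis=2)


def generate_phantom(cfg: PhantomConfig) -> tuple[PairedStudy, TissueLabelVolume]:
    """Generate one registered (MRI, CBCT) phantom pair plus ground truth.

    Identical configs (including seed) produce bit-identical output.
    When ``cfg.misregistration`` is not the identity the returned study
    has ``registered=False`` and carries the injected transform, so the
    registration stage can be exercised against a known answer.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = _label_grid(cfg, rng)
    spacing = (cfg.spacing,) * 3

    cb_means = np.asarray(cfg.intensity_map.cbct)
    mr_means = np.asarray(cfg.intensity_map.mri)

    cbct = cb_means[labels].astype(np.float64)
    if cfg.streak_amplitude > 0 and cfg.n_streaks > 0:
        streaks = _streak_field(labels.shape, cfg.streak_amplitude, cfg.n_streaks, rng)
        inside = labels != AIR
        cbct[inside] += streaks[inside]
    if cfg.noise_sigma_cbct > 0:
        cbct += rng.normal(0.0, cfg.noise_sigma_cbct, size=cbct.shape)

    mri = mr_means[labels].astype(np.float64)
    if cfg.mri_smoothing_sigma > 0:
        mri = ndimage.gaussian_filter(mri, cfg.mri_smoothing_sigma)
    if cfg.noise_sigma_mri > 0:
        mri += rng.normal(0.0, cfg.noise_sigma_mri, size=mri.shape)

    mri_vol = Volume(mri, spacing, "MRI", "a.u.")
    cbct_vol = Volume(cbct, spacing, "CBCT", "HU-like")

    misaligned = not cfg.misregistration.is_identity
    if misaligned:
        mri_vol = apply_misregistration(mri_vol, cfg.misregistration)

    study = PairedStudy(
        mri=mri_vol,
        cbct=cbct_vol,
        registered=not misaligned,
        transform=cfg.misregistration,
    )
    return study, TissueLabelVolume(labels=labels, spacing=spacing)


def region_partition(
    vertices_mm: np.ndarray, grid_size: int, spacing: float
) -> dict[str, np.ndarray]:
    """Partition mesh vertices into the four reporting regions.

    The phantom stands in for landmark-defined planes: the axial plane
    through the head centre separates maxilla (upper) from mandible
    (lower), and the coronal plane separates anterior (front, -y) from
    posterior.  Returns boolean masks over the vertices; a region absent
    from the mesh is omitted.
    """
    v = np.atleast_2d(np.asarray(vertices_mm, dtype=float))
    c = (grid_size - 1) / 2.0 * spacing
    parts = {
        "maxilla": v[:, 2] >= c,
        "mandible": v[:, 2] < c,
        "anterior": v[:, 1] < c,
        "posterior": v[:, 1] >= c,
    }
    return {k: m for k, m in parts.items() if m.any()}


def apply_misregistration(vol: Volume, t: RigidTransform, air_level: float | None = None) -> Volume:
    """Resample a volume through a rigid transform (trilinear).

    Content moves *forward* through ``t``; voxels sampled from outside
    the field of view take the air level (the volume minimum unless
    given explicitly).
    """
    if t.is_identity:
        return vol.with_values(np.asarray(vol.values).copy())
    cval = float(np.min(vol.values)) if air_level is None else float(air_level)
    out = _resample_through(vol, t, cval=cval)
    return vol.with_values(out)
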