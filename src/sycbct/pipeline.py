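"""End-to-end orchestration: phantom -> preprocess -> train -> synthesize
-> evaluate, with a provenance manifest.

A single global seed fans out to named per-stage generators so every
stage is independently reproducible.  ``run_pipeline`` is the
programmatic equivalent of the ``sycbct run-all`` command.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io_volumes import Volume, write_volume, write_mesh_stl
from .metrics import (
    DeviationReport,
    MetricsReport,
    SsimParams,
    align_icp,
    evaluate_pair,
    extract_surface,
    segment_tissues,
    surface_deviation_rms,
)
from .patching import PATCH_PRESETS, PatchSpec, fuse_patches, gaussian_window, sample_random_patches, tile_origins
from .phantom import HARD, PhantomConfig, TissueLabelVolume, generate_phantom, region_partition
from .preprocess import (
    MIRegistrationOptions,
    NormalizationRecord,
    PairedStudy,
    apply_circle_mask,
    normalize_intensities,
    denormalize_intensities,
    register_rigid_mi,
)
from .phantom import apply_misregistration
from .nn.network import NetworkSpec, build_network, count_parameters
from .nn.train import TrainConfig, save_checkpoint, train

__all__ = ["PipelineConfig", "synthesize", "run_pipeline"]


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of a full scaled-down run on phantom data."""

    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(grid_size=32))
    patch: str = "small"  # preset name, or explicit size via patch_size
    patch_size: tuple[int, int, int] | None = (16, 16, 8)
    n_train_patches: int = 96
    network_scale_divisor: int = 8  # kernel counts / divisor for desk-scale runs
    train: TrainConfig = field(default_factory=lambda: TrainConfig(batch_size=8, max_iterations=120, eval_every=30))
    sigma_frac: float = 0.125
    mask_radius: float | None = None  # None -> half the grid
    register: bool = False
    ssim_window: str = "global"
    iso_fraction: float = 0.5  # isosurface level between soft and hard means
    seed: int = 0
    out_dir: str = "run"

    def patch_spec(self) -> PatchSpec:
        if self.patch_size is not None:
            return PatchSpec(tuple(self.patch_size))
        return PATCH_PRESETS[self.patch]

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, frozenset):
                return sorted(o)
            return o

        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def synthesize(
    model,
    mri: Volume,
    spec: PatchSpec,
    sigma_frac: float = 0.125,
    norm_record: NormalizationRecord | None = None,
) -> Volume:
    """Sliding-window synthesis: tile -> predict -> Gaussian-weighted fuse.

    ``mri`` must be preprocessed identically to training (masked,
    cropped, normalised).  If a normalisation record for the reference
    modality is given, the fused output is mapped back onto the
    reference intensity scale.
    """
    dims = mri.shape
    origins = tile_origins(dims, spec)
    window = gaussian_window(spec, sigma_frac)
    values = np.asarray(mri.values, dtype=np.float64)
    preds = []
    for o in origins:
        sl = tuple(slice(a, a + s) for a, s in zip(o, spec.size))
        preds.append((model.predict(values[sl]), o))
    fused = fuse_patches(preds, window, dims, spacing=mri.spacing, modality="SYCBCT")
    if norm_record is not None:
        fused = denormalize_intensities(fused, norm_record)
        fused = Volume(fused.values, mri.spacing, "SYCBCT", "HU-like")
    return fused


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full scaled-down pipeline; returns the run directory.

    Writes the phantom pair, the synthesized volume, a model
    checkpoint, image-quality and surface-deviation reports, and a
    manifest (config hash, seed, versions).  Deterministic for a fixed
    config.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- phantom ------------------------------------------------------
    ph_cfg = dataclasses.replace(cfg.phantom, seed=_stage_seed(cfg.seed, "phantom"))
    study, labels = generate_phantom(ph_cfg)

    # --- registration (only when the phantom was misaligned) ----------
    if not study.registered:
        if not cfg.register:
            raise ValueError("phantom is misregistered but registration is disabled")
        t = register_rigid_mi(study.mri, study.cbct, MIRegistrationOptions())
        mri = apply_misregistration(study.mri, t)
        study = PairedStudy(mri=mri, cbct=study.cbct, registered=True, transform=t)

    # --- preprocessing ------------------------------------------------
    radius = cfg.mask_radius if cfg.mask_radius is not None else ph_cfg.grid_size / 2
    mri = apply_circle_mask(study.mri, radius)
    cbct = apply_circle_mask(study.cbct, radius)
    mri_n, rec_mri = normalize_intensities(mri)
    cbct_n, rec_cbct = normalize_intensities(cbct)
    pair = PairedStudy(mri=mri_n, cbct=cbct_n, registered=True, transform=study.transform)

    # --- training -----------------------------------------------------
    patch_spec = cfg.patch_spec()
    net_spec = NetworkSpec().scaled(cfg.network_scale_divisor)
    model = build_network(net_spec, seed=_stage_seed(cfg.seed, "init"))
    patches = sample_random_patches(
        pair, patch_spec, cfg.n_train_patches, seed=_stage_seed(cfg.seed, "patches")
    )
    train_pairs = [(m, c) for m, c, _ in patches]
    tcfg = dataclasses.replace(cfg.train, seed=_stage_seed(cfg.seed, "train"))
    model, history = train(model, train_pairs, tcfg)

    # --- synthesis ----------------------------------------------------
    sy = synthesize(model, mri_n, patch_spec, cfg.sigma_frac, norm_record=rec_cbct)

    # --- evaluation ---------------------------------------------------
    fov = np.ones(labels.labels.shape, dtype=bool)
    masks = segment_tissues(
        cbct.values,
        thresholds=_class_thresholds(ph_cfg),
        fov=fov,
        source="thresholded_reference",
    )
    rng_hi = float(np.asarray(cbct.values).max() - np.asarray(cbct.values).min())
    report = evaluate_pair(sy, cbct, masks, SsimParams(dynamic_range=rng_hi, window=cfg.ssim_window))

    deviation: DeviationReport | None = None
    try:
        iso = _iso_level(ph_cfg, cfg.iso_fraction)
        ref_mesh = extract_surface(cbct, iso)
        sy_mesh = extract_surface(sy, iso)
        t = align_icp(sy_mesh, ref_mesh)
        aligned = dataclasses.replace(sy_mesh, vertices=t.apply(sy_mesh.vertices))
        regions = region_partition(aligned.vertices, ph_cfg.grid_size, ph_cfg.spacing)
        deviation = surface_deviation_rms(ref_mesh, aligned, regions=regions)
        write_mesh_stl(ref_mesh, out / "cbct_surface.stl")
        write_mesh_stl(aligned, out / "sycbct_surface.stl")
    except ValueError:
        pass  # no isosurface at this scale (e.g. synthesis missed hard tissue)

    # --- outputs ------------------------------------------------------
    write_volume(study.mri, out / "mri.nii.gz")
    write_volume(study.cbct, out / "cbct.nii.gz")
    write_volume(sy, out / "sycbct.nii.gz")
    write_volume(
        Volume(labels.labels.astype(np.float64), (ph_cfg.spacing,) * 3, "CBCT", "label"),
        out / "labels.nii.gz",
    )
    save_checkpoint(out / "model.npz", model, history)

    results = {
        "metrics": report.to_dict(),
        "surface_deviation": deviation.to_dict() if deviation else None,
        "history": {
            "iterations": history.iterations,
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "lr": history.lr,
            "best_val_loss": history.best_val_loss,
            "stopped_early": history.stopped_early,
        },
        "n_parameters": int(model.n_parameters),
    }
    (out / "metrics.json").write_text(json.dumps(results, indent=2))
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "sycbct_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "network_parameters": int(model.n_parameters),
        "full_network_parameters": count_parameters(NetworkSpec()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _class_thresholds(ph_cfg: PhantomConfig) -> tuple[float, float]:
    a, s, h = ph_cfg.intensity_map.cbct
    return ((a + s) / 2, (s + h) / 2)


def _iso_level(ph_cfg: PhantomConfig, frac: float) -> float:
    _, s, h = ph_cfg.intensity_map.cbct
    return s + frac * (h - s)
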