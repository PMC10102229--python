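"""Volume and mesh containers plus file IO.

Conventions used throughout the package:

* A :class:`Volume` stores its scalar grid with axes ``(x, y, z)`` =
  (sagittal index, coronal index, axial index).  An *axial* slice is a
  fixed-``z`` plane ``values[:, :, k]``, a *coronal* slice a fixed-``y``
  plane and a *sagittal* slice a fixed-``x`` plane.
* Voxel indices are 0-based; physical coordinates in millimetres are
  obtained by multiplying the index by the per-axis spacing.  Meshes are
  always expressed in millimetres.
* The canonical on-disk format is NIfTI-1 (spacing travels in the
  header).  8-bit BMP slice stacks are supported as a secondary format
  for interoperability with slice-based viewers; because BMP is 8-bit,
  writing records a linear scale/offset in a JSON sidecar so the
  intensity scale can be recovered.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "SurfaceMesh",
    "read_volume",
    "write_volume",
    "export_slice_stack",
    "write_mesh_stl",
    "read_mesh_stl",
    "AXES",
]

#: axis name -> index into the (x, y, z) grid whose coordinate is fixed
#: when cutting a 2D slice of that orientation.
AXES = {"sagittal": 0, "coronal": 1, "axial": 2}

MODALITIES = ("MRI", "CBCT", "SYCBCT")


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing and a modality tag.

    Parameters
    ----------
    values
        3D array indexed ``[x, y, z]``.
    spacing
        Millimetres per voxel along ``(x, y, z)``; all strictly positive.
    modality
        One of ``"MRI"``, ``"CBCT"``, ``"SYCBCT"``.
    intensity_units
        Free-text description of the value scale (e.g. ``"HU-like"``).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "CBCT"
    intensity_units: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"grid dimensions must be >= 1, got {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have three components")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive and finite, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "Volume":
        """Copy of this volume with new voxel data, same metadata."""
        return replace(self, values=values)


@dataclass
class SurfaceMesh:
    """A triangle mesh in millimetre coordinates."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh has non-finite vertex coordinates")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


# ---------------------------------------------------------------------------
# volume IO


def _nifti_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def read_volume(
    path: str | Path,
    format: str = "nifti",
    *,
    spacing: Sequence[float] | None = None,
    modality: str = "CBCT",
) -> Volume:
    """Read a volume from disk.

    ``format="nifti"`` reads a single ``.nii``/``.nii.gz`` file; spacing
    comes from the header.  ``format="bmp_stack"`` reads every
    ``*_axial_*.bmp`` file in the directory ``path`` (sorted by slice
    index) and stacks them along ``z``; spacing must be supplied by the
    caller (BMP carries none).  If a ``<prefix>_scale.json`` sidecar is
    present the 8-bit values are mapped back to the original scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "nifti":
        img = nib.load(str(path))
        values = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        return Volume(values=values, spacing=tuple(float(z) for z in zooms), modality=modality)
    if format == "bmp_stack":
        import imageio.v3 as iio

        files = sorted(path.glob("*_axial_*.bmp"))
        if not files:
            raise FileNotFoundError(f"no *_axial_*.bmp slices under {path}")
        slices = [iio.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice dimensions: {sorted(shapes)}")
        # each 2D file is values[:, :, k] -> stack along the last axis
        values = np.stack(slices, axis=-1).astype(np.float64)
        sidecars = sorted(path.glob("*_scale.json"))
        if sidecars:
            meta = json.loads(sidecars[0].read_text())
            values = values * meta["scale"] + meta["offset"]
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
        return Volume(values=values, spacing=tuple(spacing), modality=modality)
    raise ValueError(f"unknown format {format!r}")


def write_volume(vol: Volume, path: str | Path, format: str = "nifti", *, prefix: str = "vol") -> None:
    """Write a volume to disk.

    NIfTI is lossless for float dtypes.  ``bmp_stack`` writes 8-bit axial
    slices named ``<prefix>_axial_<index:04d>.bmp`` under the directory
    ``path`` after a linear min-max rescale to 0..255; the scale and
    offset are recorded in ``<prefix>_scale.json`` so values round-trip
    to within half a quantisation step.
    """
    path = Path(path)
    if format == "nifti":
        if not path.parent.exists():
            raise FileNotFoundError(f"parent directory {path.parent} does not exist")
        img = nib.Nifti1Image(np.asarray(vol.values), _nifti_affine(vol.spacing))
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
        return
    if format == "bmp_stack":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        v = np.asarray(vol.values, dtype=np.float64)
        vmin, vmax = float(v.min()), float(v.max())
        if vmax > vmin:
            scale = (vmax - vmin) / 255.0
        else:
            scale = 1.0
        quant = np.clip(np.rint((v - vmin) / scale), 0, 255).astype(np.uint8)
        for k in range(v.shape[2]):
            iio.imwrite(path / f"{prefix}_axial_{k:04d}.bmp", quant[:, :, k])
        sidecar = {"scale": scale, "offset": vmin, "spacing": list(vol.spacing)}
        (path / f"{prefix}_scale.json").write_text(json.dumps(sidecar))
        return
    raise ValueError(f"unknown format {format!r}")


def export_slice_stack(
    vol: Volume,
    axes: Iterable[str] = ("axial", "coronal", "sagittal"),
    out_dir: str | Path | None = None,
    *,
    count_only: bool = False,
    prefix: str = "vol",
) -> int:
    """Reslice a volume into per-axis 2D image stacks.

    For each requested orientation one 8-bit BMP per index along that
    axis is written (unless ``count_only``), so a 512-cube resliced along
    all three axes yields 1,536 images per modality.  Returns the number
    of 2D images (written or counted).
    """
    axes = list(axes)
    unknown = [a for a in axes if a not in AXES]
    if unknown:
        raise ValueError(f"unknown axes {unknown}; expected subset of {sorted(AXES)}")
    shape = vol.shape
    count = sum(shape[AXES[a]] for a in axes)
    if count_only:
        return count
    if out_dir is None:
        raise ValueError("out_dir required unless count_only")
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    v = np.asarray(vol.values, dtype=np.float64)
    vmin, vmax = float(v.min()), float(v.max())
    scale = (vmax - vmin) / 255.0 if vmax > vmin else 1.0
    quant = np.clip(np.rint((v - vmin) / scale), 0, 255).astype(np.uint8)
    for axis_name in axes:
        ax = AXES[axis_name]
        for k in range(shape[ax]):
            sl = np.take(quant, k, axis=ax)
            iio.imwrite(out_dir / f"{prefix}_{axis_name}_{k:04d}.bmp", sl)
    return count


# ---------------------------------------------------------------------------
# mesh IO


def write_mesh_stl(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a triangle mesh as binary STL (float32 vertex precision)."""
    import trimesh

    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise ValueError("cannot write an empty mesh")
    degenerate = (
        (mesh.faces[:, 0] == mesh.faces[:, 1])
        | (mesh.faces[:, 1] == mesh.faces[:, 2])
        | (mesh.faces[:, 0] == mesh.faces[:, 2])
    )
    if degenerate.any():
        raise ValueError(f"{int(degenerate.sum())} degenerate face(s) with repeated vertices")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path), file_type="stl")


def read_mesh_stl(path: str | Path) -> SurfaceMesh:
    """Read a binary STL into a :class:`SurfaceMesh` (vertices merged)."""
    import trimesh

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    tm = trimesh.load_mesh(str(path), file_type="stl")
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
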