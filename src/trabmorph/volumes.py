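"""Volume data model and I/O for 3D CT-like images with physical voxel spacing.

Axis convention: arrays are indexed ``(slice, row, col)`` = (z, y, x), with the
slice axis being the craniocaudal axis of the scan. Coordinates are
voxel-center based and 0-indexed; the physical position of voxel ``(i, j, k)``
is ``origin + (i, j, k) * spacing`` (all in millimetres).

Spacing is mandatory metadata. A file without spacing information and without
an explicit override is rejected rather than silently assumed to be 1 mm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "ScalarVolume",
    "BinaryVolume",
    "read_volume",
    "write_volume",
    "resample_volume",
]

Triple = tuple[float, float, float]
VolumeFormat = Literal["tiff_stack", "metaimage", "nifti"]


def _check_spacing(spacing) -> Triple:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {spacing}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be positive and finite, got {spacing}")
    return spacing


@dataclass
class ScalarVolume:
    """A 3D grid of real intensities with anisotropic mm spacing.

    Parameters
    ----------
    data
        3D array of finite intensities (arbitrary CT-like units).
    spacing
        Voxel size in mm, ordered ``(slice, row, col)``.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    meta
        Free-form metadata (e.g. phantom ground truth) carried along.
    """

    data: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"data must be a non-empty 3D array, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> Triple:
        """Physical size in mm along each axis (n * spacing)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))


@dataclass
class BinaryVolume:
    """A bone/marrow segmentation on the same grid semantics as ScalarVolume."""

    mask: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3 or min(self.mask.shape) < 1:
            raise ValueError(f"mask must be a non-empty 3D array, got shape {self.mask.shape}")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> Triple:
        return tuple(n * s for n, s in zip(self.mask.shape, self.spacing))

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())

    def to_scalar(self, fg: float = 1.0, bg: float = 0.0) -> ScalarVolume:
        """Cast to an intensity volume with the given phase levels."""
        data = np.where(self.mask, np.float64(fg), np.float64(bg))
        return ScalarVolume(data, self.spacing, self.origin)


def _infer_format(path: Path) -> VolumeFormat:
    name = path.name.lower()
    if name.endswith((".mhd", ".mha")):
        return "metaimage"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")) or path.is_dir():
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from path {path!r}")


def read_volume(
    path: str | os.PathLike,
    format: VolumeFormat | None = None,
    spacing: Triple | None = None,
) -> ScalarVolume:
    """Read a 3D volume from disk.

    ``spacing`` overrides (or supplies, for headerless TIFF stacks) the voxel
    size in mm, ordered (slice, row, col). Missing spacing is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)

    if fmt == "tiff_stack":
        import tifffile

        if path.is_dir():
            files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
            if not files:
                raise IOError(f"no TIFF slices found in directory {path}")
            data = np.stack([tifffile.imread(str(f)) for f in files], axis=0)
        else:
            data = tifffile.imread(str(path))
            if data.ndim == 2:
                data = data[None]
        if spacing is None:
            raise ValueError(
                "TIFF stacks carry no reliable 3D spacing metadata; "
                "pass spacing=(slice, row, col) in mm explicitly"
            )
        return ScalarVolume(np.asarray(data), spacing)

    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        if data.ndim == 2:
            data = data[None]
        sp_xyz = img.GetSpacing()
        file_spacing = tuple(float(s) for s in reversed(sp_xyz))
        origin = tuple(float(o) for o in reversed(img.GetOrigin()))
        return ScalarVolume(data, spacing or file_spacing, origin)

    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)  # (x, y, z) per NIfTI convention
        if data.ndim != 3:
            raise IOError(f"expected a 3D NIfTI image, got shape {data.shape}")
        data = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        if spacing is None:
            if any(z <= 0 for z in zooms):
                raise ValueError(f"NIfTI pixdim invalid ({zooms}); pass spacing explicitly")
            spacing = tuple(float(z) for z in reversed(zooms))
        return ScalarVolume(data, spacing)

    raise ValueError(f"unsupported format {fmt!r}")


def write_volume(
    vol: ScalarVolume | BinaryVolume,
    path: str | os.PathLike,
    format: VolumeFormat | None = None,
) -> None:
    """Write a volume to disk; integer data round-trips bit-exactly.

    Binary masks are written as uint8 (bone = 1).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if isinstance(vol, BinaryVolume):
        data = vol.mask.astype(np.uint8)
    else:
        data = vol.data
    spacing, origin = vol.spacing, vol.origin

    if fmt == "tiff_stack":
        import tifffile

        tifffile.imwrite(str(path), data)
        return

    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)
        img.SetSpacing(tuple(reversed(spacing)))
        img.SetOrigin(tuple(reversed(origin)))
        sitk.WriteImage(img, str(path))
        return

    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(reversed(spacing)) + [1.0])
        img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
        img.header.set_zooms(tuple(reversed(spacing)))
        nib.save(img, str(path))
        return

    raise ValueError(f"unsupported format {fmt!r}")


def resample_volume(
    vol: ScalarVolume,
    new_spacing: Triple,
    interpolation: Literal["linear", "nearest"] = "linear",
) -> ScalarVolume:
    """Resample onto a new voxel grid, preserving the physical extent.

    Output voxel ``i`` is centered at ``origin + i * new_spacing``; values are
    interpolated from the input grid (linear or nearest). Constant volumes are
    reproduced exactly.
    """
    from scipy import ndimage

    new_spacing = _check_spacing(new_spacing)
    if any(ns > ext for ns, ext in zip(new_spacing, vol.extent)):
        raise ValueError(
            f"new_spacing {new_spacing} exceeds the volume extent {vol.extent} on some axis"
        )
    order = {"linear": 1, "nearest": 0}[interpolation]
    out_shape = tuple(
        max(1, int(round(n * s / ns))) for n, s, ns in zip(vol.shape, vol.spacing, new_spacing)
    )
    grids = [
        np.arange(m, dtype=np.float64) * ns / s
        for m, ns, s in zip(out_shape, new_spacing, vol.spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(
        vol.data.astype(np.float64), np.stack(coords), order=order, mode="nearest"
    )
    return ScalarVolume(out, new_spacing, vol.origin)
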