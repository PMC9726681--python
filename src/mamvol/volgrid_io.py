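"""Volume containers, NIfTI-1 I/O and isotropic resampling.

All geometry is expressed in RAS world millimetres. Voxel indices are
0-based and a voxel's world position is the position of its *center*:

    world = origin + direction @ (spacing * index)

``VolumeImage`` holds a scalar intensity grid, ``LabelMap`` an integer
grid over ``{0, 1, 2}`` (0 = background, 1 = left mammillary body,
2 = right mammillary body) on the same kind of geometry. Every image in
the pipeline is resampled onto a 0.5 mm isotropic grid before any
volumetric analysis; :func:`resample_isotropic` implements that stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "LabelMap",
    "VolGridError",
    "FormatError",
    "GeometryMismatchError",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "resample_isotropic",
    "resample_labels",
    "same_geometry",
]

GEOM_ATOL_MM = 1e-5  # geometry round-trip tolerance


class VolGridError(ValueError):
    """Base class for volume-grid errors."""


class FormatError(VolGridError):
    """Raised when a file is not readable NIfTI-1."""


class GeometryMismatchError(VolGridError):
    """Raised when two grids expected to share geometry do not."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3:
        raise VolGridError(f"{name} must be a scalar or 3-vector, got {x!r}")
    return v


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar intensity image with world geometry.

    Parameters
    ----------
    voxels : (nx, ny, nz) float array
        Intensities in arbitrary units; must be finite.
    spacing_mm : 3-vector
        Voxel edge lengths, all > 0.
    origin_mm : 3-vector
        World position of the center of voxel (0, 0, 0).
    orientation : (3, 3) array
        Direction cosine matrix (orthonormal, det ±1); identity = RAS
        axis-aligned.
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise VolGridError(f"voxels must be 3D, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise VolGridError("voxel intensities must be finite")
        sp = _as_vec3(self.spacing_mm, "spacing_mm")
        if np.any(sp <= 0):
            raise VolGridError(f"spacing must be positive, got {sp}")
        org = _as_vec3(self.origin_mm, "origin_mm")
        ori = np.asarray(self.orientation, dtype=float)
        if ori.shape != (3, 3):
            raise VolGridError("orientation must be 3x3")
        if not np.allclose(ori @ ori.T, np.eye(3), atol=1e-6):
            raise VolGridError("orientation must be orthonormal")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", sp)
        object.__setattr__(self, "origin_mm", org)
        object.__setattr__(self, "orientation", ori)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (RAS mm) map."""
        A = np.eye(4)
        A[:3, :3] = self.orientation @ np.diag(self.spacing_mm)
        A[:3, 3] = self.origin_mm
        return A

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world_center(self) -> np.ndarray:
        """World position of the grid's geometric center."""
        c_idx = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.origin_mm + self.orientation @ (self.spacing_mm * c_idx)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin_mm + (self.orientation @ (self.spacing_mm * idx).T).T

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        rel = (self.orientation.T @ (world - self.origin_mm).T).T
        return rel / self.spacing_mm

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        return replace(self, voxels=voxels)

    def background_value(self) -> float:
        """Intensity assumed outside the field of view (median of corners)."""
        v = self.voxels
        corners = [v[i, j, k] for i in (0, -1) for j in (0, -1) for k in (0, -1)]
        return float(np.median(corners))


@dataclass(frozen=True)
class LabelMap:
    """A 3D integer label grid over {0, 1, 2} sharing VolumeImage geometry."""

    labels: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise VolGridError(f"labels must be 3D, got shape {lab.shape}")
        lab = lab.astype(np.int16, copy=False)
        values = np.unique(lab)
        if not np.all(np.isin(values, [0, 1, 2])):
            raise VolGridError(f"label values must be in {{0,1,2}}, got {values}")
        sp = _as_vec3(self.spacing_mm, "spacing_mm")
        if np.any(sp <= 0):
            raise VolGridError(f"spacing must be positive, got {sp}")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "spacing_mm", sp)
        object.__setattr__(self, "origin_mm", _as_vec3(self.origin_mm, "origin_mm"))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = self.orientation @ np.diag(self.spacing_mm)
        A[:3, 3] = self.origin_mm
        return A

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world_center(self) -> np.ndarray:
        c_idx = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.origin_mm + self.orientation @ (self.spacing_mm * c_idx)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin_mm + (self.orientation @ (self.spacing_mm * idx).T).T

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        rel = (self.orientation.T @ (world - self.origin_mm).T).T
        return rel / self.spacing_mm

    def with_labels(self, labels: np.ndarray) -> "LabelMap":
        return replace(self, labels=labels)


def same_geometry(a, b, atol_mm: float = GEOM_ATOL_MM) -> bool:
    """True if two grids agree in shape, spacing, origin and orientation."""
    arr_a = a.voxels if isinstance(a, VolumeImage) else a.labels
    arr_b = b.voxels if isinstance(b, VolumeImage) else b.labels
    return (
        arr_a.shape == arr_b.shape
        and np.allclose(a.spacing_mm, b.spacing_mm, atol=atol_mm)
        and np.allclose(a.origin_mm, b.origin_mm, atol=atol_mm)
        and np.allclose(a.orientation, b.orientation, atol=1e-6)
    )


def _geometry_from_affine(affine: np.ndarray):
    M = affine[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise FormatError("degenerate affine in NIfTI header")
    orientation = M / spacing
    origin = affine[:3, 3]
    return spacing, origin, orientation


def read_volume(path) -> VolumeImage:
    """Read a NIfTI-1 (.nii/.nii.gz) intensity volume.

    Raises :class:`FormatError` on anything that is not readable NIfTI.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
    except Exception as exc:  # nibabel raises many concrete types
        raise FormatError(f"not a readable NIfTI-1 file: {path} ({exc})") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}: {path}")
    spacing, origin, orientation = _geometry_from_affine(affine)
    return VolumeImage(data, spacing, origin, orientation)


def write_volume(image: VolumeImage, path) -> None:
    nii = nib.Nifti1Image(image.voxels.astype(np.float32), image.affine)
    nii.header.set_xyzt_units("mm")
    nib.save(nii, str(path))


def read_labels(path) -> LabelMap:
    """Read a NIfTI-1 label map; values are rounded to nearest integer."""
    vol = read_volume(path)
    return LabelMap(
        np.rint(vol.voxels).astype(np.int16),
        vol.spacing_mm,
        vol.origin_mm,
        vol.orientation,
    )


def write_labels(labels: LabelMap, path) -> None:
    nii = nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine)
    nii.header.set_xyzt_units("mm")
    nib.save(nii, str(path))


def _resampled_grid(shape, spacing, target_mm: float):
    extent = np.asarray(shape, dtype=float) * spacing
    new_shape = np.maximum(1, np.ceil(extent / target_mm - 1e-9).astype(int))
    return tuple(int(n) for n in new_shape)


def resample_isotropic(
    image: VolumeImage, target_mm: float = 0.5, mode: str = "trilinear"
) -> VolumeImage:
    """Resample onto an isotropic ``target_mm`` grid.

    The output grid is anchored at the original first-voxel center (the
    origin is unchanged) and covers the original physical extent to
    within one voxel. ``mode`` is ``"trilinear"`` for intensities or
    ``"nearest"``; samples falling outside the input field of view take
    the image's background intensity.
    """
    if target_mm <= 0:
        raise VolGridError(f"target_mm must be positive, got {target_mm}")
    if mode not in ("trilinear", "nearest"):
        raise VolGridError(f"unknown interpolation mode {mode!r}")
    new_shape = _resampled_grid(image.shape, image.spacing_mm, target_mm)
    # new index m -> old fractional index m * target / old_spacing
    scale = target_mm / image.spacing_mm
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) * s for n, s in zip(new_shape, scale)],
        indexing="ij",
    )
    order = 1 if mode == "trilinear" else 0
    out = ndimage.map_coordinates(
        image.voxels,
        np.stack(grids),
        order=order,
        mode="constant",
        cval=image.background_value(),
    )
    return VolumeImage(
        out,
        np.full(3, float(target_mm)),
        image.origin_mm,
        image.orientation,
    )


def resample_labels(labels: LabelMap, target_mm: float = 0.5) -> LabelMap:
    """Nearest-neighbor resampling of a label map (background fill 0)."""
    if target_mm <= 0:
        raise VolGridError(f"target_mm must be positive, got {target_mm}")
    new_shape = _resampled_grid(labels.shape, labels.spacing_mm, target_mm)
    scale = target_mm / labels.spacing_mm
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) * s for n, s in zip(new_shape, scale)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        labels.labels.astype(np.int16),
        np.stack(grids),
        order=0,
        mode="constant",
        cval=0,
    )
    return LabelMap(out, np.full(3, float(target_mm)), labels.origin_mm, labels.orientation)
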