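"""Volume and mesh I/O with explicit physical-space conventions.

Every downstream stage of the pipeline works in scanner physical space
(LPS, millimetres). This module is the only place voxel indices are
converted to/from physical coordinates: a :class:`CTVolume` carries the
full grid metadata (spacing, origin, 3x3 direction matrix) and meshes are
always expressed in mm.

Array convention: volume data is stored with index order ``(i, j, k)``
mapping to physical ``origin + direction @ (spacing * index)`` — i.e. the
first array axis is the fastest-varying image axis, matching SimpleITK's
``GetPixel(i, j, k)`` convention (note SimpleITK's numpy bridge returns
``(k, j, i)`` arrays; the transpose happens here, once).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .errors import MeshError, MetadataError

log = logging.getLogger(__name__)

VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")
MESH_SUFFIXES = (".stl", ".ply")


def _check_direction(direction: np.ndarray) -> None:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise MetadataError(f"direction matrix must be 3x3, got {d.shape}")
    if abs(abs(np.linalg.det(d)) - 1.0) > 1e-6 or not np.allclose(
        d @ d.T, np.eye(3), atol=1e-6
    ):
        raise MetadataError("direction matrix is not orthonormal (|det| != 1)")


@dataclass
class CTVolume:
    """A 3D CT image with Hounsfield-like intensities in physical space.

    Attributes
    ----------
    data : (ni, nj, nk) float array
        Intensities; any rescale slope/intercept from the file header has
        already been applied.
    spacing : (3,) float array, mm
    origin : (3,) float array, mm — physical position of voxel (0, 0, 0)
    direction : (3, 3) orthonormal matrix mapping index axes to physical axes
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.data.ndim != 3:
            raise MetadataError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise MetadataError(f"spacing must be 3 positive values, got {self.spacing}")
        _check_direction(self.direction)
        if not np.all(np.isfinite(self.data)):
            raise MetadataError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (N, 3) to mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin + (self.direction @ (idx * self.spacing).T).T

    def grid_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates, valid only for identity direction."""
        if not np.allclose(self.direction, np.eye(3)):
            raise MetadataError("grid_coordinates requires identity direction")
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


@dataclass
class BinaryMask:
    """A boolean mask on the same physical grid as its source CTVolume."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        _check_direction(self.direction)

    @classmethod
    def like(cls, volume, data: np.ndarray) -> "BinaryMask":
        return cls(data, volume.spacing, volume.origin, volume.direction)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_mm3(self) -> float:
        """Mask volume as voxel count x voxel volume."""
        return float(self.data.sum()) * self.voxel_volume_mm3

    def index_to_physical(self, idx):
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin + (self.direction @ (idx * self.spacing).T).T


def _sitk_to_ctvolume(img: sitk.Image) -> CTVolume:
    arr = sitk.GetArrayFromImage(img)  # (k, j, i)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return CTVolume(
        data=data,
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
        direction=direction,
    )


def _ctvolume_to_sitk(volume: CTVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.direction.ravel()))
    return img


def _validate_nifti_spacing(path: Path) -> None:
    # inspect the raw header: nibabel/ITK silently repair zero pixdims to
    # 1 mm on load, which is exactly the default this check must refuse
    opener = gzip.open if path.name.lower().endswith(".gz") else open
    with opener(path, "rb") as fh:
        head = fh.read(112)
    if len(head) < 112:
        raise MetadataError(f"{path}: truncated NIfTI header")
    sizeof_hdr = np.frombuffer(head, "<i4", count=1, offset=0)[0]
    byte_order = "<" if sizeof_hdr == 348 else ">"
    pixdim = np.frombuffer(head, f"{byte_order}f4", count=3, offset=80)
    if np.any(~np.isfinite(pixdim)) or np.any(pixdim <= 0):
        raise MetadataError(
            f"{path}: NIfTI header has non-positive pixdim {pixdim}; "
            "refusing to default voxel spacing to 1 mm"
        )


def _validate_metaimage_spacing(path: Path) -> None:
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rb") as fh:
            head = fh.read(8192).decode("latin-1", errors="replace")
    except OSError as exc:
        raise MetadataError(f"{path}: cannot read MetaImage header: {exc}") from exc
    if "ElementSpacing" not in head and "ElementSize" not in head:
        raise MetadataError(
            f"{path}: MetaImage header lacks ElementSpacing; "
            "refusing to default voxel spacing to 1 mm"
        )


def read_volume(path) -> CTVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Intensities are returned with any header rescale slope/intercept
    applied; spacing/origin/direction come from the header (LPS). A header
    without explicit voxel spacing raises :class:`MetadataError` rather
    than silently assuming 1 mm.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file does not exist: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        _validate_nifti_spacing(path)
    elif name.endswith((".mha", ".mhd")):
        _validate_metaimage_spacing(path)
    else:
        raise IOError(f"unsupported volume format: {path} (expected {VOLUME_SUFFIXES})")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    vol = _sitk_to_ctvolume(img)
    if not np.all(np.isfinite(vol.data)):
        raise MetadataError(f"{path}: volume contains non-finite intensities")
    return vol


def write_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI or MetaImage; round-trips data exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    try:
        sitk.WriteImage(_ctvolume_to_sitk(volume), str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot write volume {path}: {exc}") from exc


def ensure_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Flip winding if the signed volume is negative, so volume is positive."""
    if mesh.is_winding_consistent and mesh.volume < 0:
        log.info("mesh had inward orientation (signed volume %.3g); flipping", mesh.volume)
        mesh.invert()
    return mesh


def read_mesh(path, provenance: str | None = None) -> trimesh.Trimesh:
    """Read an STL or PLY surface; coordinates are taken to be mm.

    Non-manifold input is flagged with a warning, never silently repaired:
    volumetric operations downstream will refuse it explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file does not exist: {path}")
    if path.suffix.lower() not in MESH_SUFFIXES:
        raise IOError(f"unsupported mesh format: {path} (expected {MESH_SUFFIXES})")
    mesh = trimesh.load_mesh(str(path), process=False)
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise MeshError(f"{path}: file contains no mesh geometry")
        mesh = trimesh.util.concatenate(geoms)
    if len(mesh.faces) == 0:
        raise MeshError(f"{path}: mesh has no faces")
    if not mesh.is_watertight:
        warnings.warn(f"{path}: mesh is not watertight (non-manifold edges present)")
    mesh = ensure_outward(mesh)
    if provenance is not None:
        mesh.metadata["provenance"] = provenance
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    mesh.export(str(path))


def resample_isotropic(volume: CTVolume, target_spacing: float) -> CTVolume:
    """Resample to isotropic spacing with linear interpolation.

    The output grid covers the same physical extent (origin preserved,
    per-axis size rescaled by spacing ratio, rounded up).
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if target_spacing > 4.0 * float(np.min(volume.spacing)):
        log.warning(
            "resampling to %.3g mm, coarser than 4x the native %.3g mm spacing",
            target_spacing,
            float(np.min(volume.spacing)),
        )
    img = _ctvolume_to_sitk(volume)
    new_size = [
        int(np.ceil(n * s / target_spacing))
        for n, s in zip(volume.shape, volume.spacing)
    ]
    res = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        sitk.sitkLinear,
        img.GetOrigin(),
        (target_spacing,) * 3,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    return _sitk_to_ctvolume(res)
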