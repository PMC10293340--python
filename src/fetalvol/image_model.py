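"""Core image and label-map containers with NIfTI I/O and grid resampling.

A fetal MRI study volume is represented as a :class:`VolumeImage`: a 3D scalar
grid plus per-axis voxel spacing in millimetres.  Segmentations are
:class:`LabelMap` instances on the same grid, with a fixed five-class alphabet
(background, fetus, placenta, umbilical cord, amniotic fluid).  Only
axis-aligned geometries are supported: the NIfTI affine is a diagonal scaling
plus translation, which is what the phantom generator produces and all the
downstream arithmetic assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Fixed class alphabet shared by every LabelMap in the pipeline.  Index 0 is
#: an explicit "everything else" class for maternal tissue outside the four
#: delineated intrauterine structures, required by softmax classification over
#: a slab that covers the whole uterus and its surroundings.
CLASS_NAMES: tuple[str, ...] = (
    "background",
    "fetus",
    "placenta",
    "umbilical_cord",
    "amniotic_fluid",
)
N_CLASSES = len(CLASS_NAMES)

BACKGROUND, FETUS, PLACENTA, UMBILICAL_CORD, AMNIOTIC_FLUID = range(N_CLASSES)


class FormatError(ValueError):
    """Raised when a file does not hold a supported 3D axis-aligned image."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(x) for x in spacing)
    if len(s) != 3 or any(x <= 0 or not np.isfinite(x) for x in s):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing!r}")
    return s


@dataclass
class VolumeImage:
    """3D scalar image with voxel spacing and origin in millimetres."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D array")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(x) for x in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMap:
    """Integer class map on the same grid as its paired :class:`VolumeImage`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    class_names: tuple[str, ...] = field(default=CLASS_NAMES)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("labels must be integer-valued")
            self.labels = self.labels.astype(np.uint8)
        if self.labels.min() < 0 or self.labels.max() >= len(self.class_names):
            raise ValueError(
                f"labels must lie in [0, {len(self.class_names) - 1}]"
            )
        self.labels = self.labels.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(x) for x in self.origin)
        self.class_names = tuple(self.class_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ClassProbabilities:
    """Per-voxel class distribution: shape (nx, ny, nz, n_classes)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 4:
            raise ValueError("probs must be 4D (3 spatial axes + classes)")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.probs.shape[:3]

    def check_normalized(self, tol: float = 1e-5) -> bool:
        s = self.probs.sum(axis=-1)
        return bool(np.all(np.abs(s - 1.0) <= tol))

    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.probs, axis=-1).astype(np.uint8)


# ---------------------------------------------------------------------------
# NIfTI I/O.  Volumes are stored as float32, label maps as uint8.  The affine
# is diagonal(spacing) with the origin in the translation column.


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path) -> VolumeImage:
    """Read a 3D NIfTI-1 file as a :class:`VolumeImage`."""
    data, spacing, origin = _load_nifti(path)
    return VolumeImage(data.astype(np.float32), spacing, origin)


def _check_writable_target(path) -> None:
    import os

    if os.path.isdir(path):
        raise IsADirectoryError(f"{path} is a directory, not a file")


def write_volume(v: VolumeImage, path) -> None:
    _check_writable_target(path)
    img = nib.Nifti1Image(v.voxels.astype(np.float32), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    """Read a NIfTI-1 label map; values must lie in the 5-class alphabet."""
    data, spacing, origin = _load_nifti(path)
    return LabelMap(data.astype(np.uint8), spacing, origin)


def write_labels(l: LabelMap, path) -> None:
    _check_writable_target(path)
    img = nib.Nifti1Image(l.labels.astype(np.uint8), _affine(l.spacing, l.origin))
    img.header.set_zooms(l.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling


def resample_isotropic(v: VolumeImage, target_mm: float, mode: str = "linear") -> VolumeImage:
    """Resample onto an isotropic grid of ``target_mm`` voxels.

    The physical extent (shape × spacing) is preserved to within one voxel per
    axis.  ``mode='linear'`` uses trilinear interpolation (intensities);
    ``mode='nearest'`` preserves the label alphabet (label maps).  The acquired
    fetal slab is anisotropic (typically 1.8 × 1.4 × 2.5 mm) while tri-planar
    slicing treats all axes equivalently, so inference always runs on an
    isotropic grid; 1.5 mm, near the finest acquired in-plane resolution, is
    the conventional target.
    """
    if not np.isfinite(target_mm) or target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm!r}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")

    old_spacing = np.asarray(v.spacing, dtype=float)
    old_shape = np.asarray(v.shape, dtype=float)
    new_shape = np.maximum(1, np.round(old_shape * old_spacing / target_mm)).astype(int)
    if tuple(new_shape) == v.shape and np.allclose(old_spacing, target_mm):
        return VolumeImage(v.voxels.copy(), (target_mm,) * 3, v.origin)

    # Sample at new voxel centres expressed in old voxel index coordinates.
    coords = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * target_mm / old_spacing[a] - 0.5
            for a, n in enumerate(new_shape)
        ],
        indexing="ij",
    )
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        v.voxels.astype(np.float32), coords, order=order, mode="nearest"
    )
    return VolumeImage(out, (float(target_mm),) * 3, v.origin)


def resample_labels_isotropic(l: LabelMap, target_mm: float) -> LabelMap:
    """Nearest-neighbour isotropic resampling for label maps."""
    v = VolumeImage(l.labels.astype(np.float32), l.spacing, l.origin)
    out = resample_isotropic(v, target_mm, mode="nearest")
    return LabelMap(out.voxels.astype(np.uint8), out.spacing, out.origin, l.class_names)


def resample_labels_to_grid(l: LabelMap, shape, spacing, origin=(0.0, 0.0, 0.0)) -> LabelMap:
    """Nearest-neighbour resampling of a label map onto an explicit target grid."""
    spacing = _check_spacing(spacing)
    old_spacing = np.asarray(l.spacing, dtype=float)
    coords = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * spacing[a] / old_spacing[a] - 0.5
            for a, n in enumerate(shape)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(l.labels, coords, order=0, mode="nearest")
    return LabelMap(out.astype(np.uint8), spacing, origin, l.class_names)
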