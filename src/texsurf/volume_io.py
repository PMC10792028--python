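"""Spacing-aware 3D volume and mask I/O.

All arrays follow the ``(z, y, x)`` axis convention with 0-based voxel
indices; a voxel is a unit cell whose physical position is
``origin + index * spacing`` (millimetres).  DICOM series are rescaled to
Hounsfield units at read time via the per-file slope/intercept; NIfTI and
NRRD volumes are passed through unchanged, so synthetic phantoms keep their
constructed intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.errors import InvalidDicomError

__all__ = [
    "Volume",
    "MaskVolume",
    "read_dicom_series",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
]


@dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array ordered ``(z, y, x)``.  Hounsfield units for CT reads,
        arbitrary for phantoms.
    spacing:
        ``(dz, dy, dx)`` in mm, strictly positive.
    origin:
        Physical offset of voxel ``(0, 0, 0)`` in mm; informational.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must have three axes of length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValueError("spacing components must be strictly positive and finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class MaskVolume:
    """A binary (0/1) volume, typically paired with a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask data must have three axes")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValueError("spacing components must be strictly positive and finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def voxel_count(self) -> int:
        return int(self.data.sum())


def _slice_normal(ds: pydicom.Dataset) -> np.ndarray:
    iop = getattr(ds, "ImageOrientationPatient", None)
    if iop is None:
        return np.array([0.0, 0.0, 1.0])
    row = np.asarray(iop[:3], dtype=float)
    col = np.asarray(iop[3:], dtype=float)
    return np.cross(row, col)


def read_dicom_series(directory_path: str | Path) -> Volume:
    """Read a single-series directory of single-frame CT files.

    Slices are sorted by their through-plane position (projection of
    ``ImagePositionPatient`` onto the slice normal), pixel values are
    rescaled to HU with each file's ``RescaleSlope``/``RescaleIntercept``,
    and the slice gap is taken from the sorted positions.  A non-uniform
    gap (beyond 1% of the median) raises a warning and the median gap is
    used.
    """
    directory_path = Path(directory_path)
    datasets = []
    for path in sorted(p for p in directory_path.iterdir() if p.is_file()):
        try:
            datasets.append(pydicom.dcmread(path))
        except InvalidDicomError:
            continue
    if not datasets:
        raise ValueError("no images found")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError("multiple series")

    normal = _slice_normal(datasets[0])
    positions = []
    for ds in datasets:
        ipp = np.asarray(
            getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0]), dtype=float
        )
        positions.append(float(ipp @ normal))
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    data = np.stack(slices, axis=0)

    if len(positions) > 1:
        gaps = np.diff(positions)
        dz = float(np.median(gaps))
        if dz <= 0:
            raise ValueError("degenerate slice positions")
        if np.max(np.abs(gaps - dz)) > 0.01 * dz:
            warnings.warn(
                "non-uniform slice gap; using median gap", stacklevel=2
            )
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    px = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    spacing = (dz, float(px[0]), float(px[1]))
    ipp0 = np.asarray(
        getattr(datasets[0], "ImagePositionPatient", [0.0, 0.0, 0.0]), dtype=float
    )
    return Volume(data, spacing, origin=(float(ipp0[2]), float(ipp0[1]), float(ipp0[0])))


_KNOWN_EXTENSIONS = (".nii", ".nii.gz", ".nrrd")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _KNOWN_EXTENSIONS):
        raise ValueError(f"unsupported format: {path.name}")


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI (``.nii``/``.nii.gz``) or NRRD volume.

    The returned array is ordered ``(z, y, x)`` with spacing taken from
    the file header.
    """
    path = Path(path)
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # already (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return Volume(data, spacing, origin)


def read_mask(path: str | Path) -> MaskVolume:
    """Read a binary mask volume; nonzero voxels map to 1."""
    vol = read_volume(path)
    return MaskVolume((vol.data > 0).astype(np.uint8), vol.spacing, vol.origin)


def _write(data: np.ndarray, spacing, origin, path: Path) -> None:
    _check_extension(path)
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(float(s) for s in reversed(spacing)))
    img.SetOrigin(tuple(float(o) for o in reversed(origin)))
    sitk.WriteImage(img, str(path))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a scalar volume to NIfTI or NRRD (by extension)."""
    _write(np.asarray(volume.data), volume.spacing, volume.origin, Path(path))


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    """Write a binary mask; the file reads back with values exactly {0, 1}."""
    _write(mask.data.astype(np.uint8), mask.spacing, mask.origin, Path(path))
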