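"""NIfTI volume I/O and the core grid data model.

Conventions used throughout the package:

* voxel indexing is 0-based and the array axis order is ``(x, y, z)``, matching
  the on-disk NIfTI data order;
* ``Volume.affine`` is the 4x4 voxel-index -> world-mm mapping from the NIfTI
  header;
* label masks are stored as unsigned 8-bit integers so that round trips through
  disk are exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np


class Sequence(enum.Enum):
    """MRI sequence label of a volume."""

    T1 = "T1"
    T1GAD = "T1GAD"
    STIR = "STIR"
    OTHER = "OTHER"


class Location(enum.Enum):
    """Primary tumor site."""

    ORAL_CAVITY = "oral_cavity"
    OROPHARYNX = "oropharynx"
    HYPOPHARYNX = "hypopharynx"


@dataclass
class Volume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data
        3D array of intensities, axis order (x, y, z).
    affine
        4x4 homogeneous matrix mapping voxel indices to world millimetres.
    sequence
        MRI sequence the volume was acquired with.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    sequence: Sequence = Sequence.OTHER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive along every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "Volume | LabelMask", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class LabelMask(Volume):
    """A binary mask sharing the grid model of :class:`Volume`."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(np.unique(self.data), (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "LabelMask":
        return replace(self, data=data)


@dataclass
class MultiSequenceCase:
    """One subject: T1 and STIR volumes, optional contrast-enhanced T1, and the
    reference tumor mask drawn on (and aligned with) the T1 grid.

    ``t1gad`` may be ``None``: contrast scans are missing in a small fraction of
    subjects and the corresponding network channel is zeroed downstream.
    """

    case_id: str
    t1: Volume
    stir: Volume
    reference: LabelMask
    t1gad: Optional[Volume] = None
    location: Location = Location.OROPHARYNX
    t_stage: str = "T2"
    n_stage: str = "N0"

    def __post_init__(self) -> None:
        if not self.t1.same_grid(self.reference):
            raise ValueError(f"{self.case_id}: reference mask must share the T1 grid")

    @property
    def has_t1gad(self) -> bool:
        return self.t1gad is not None

    def sequences(self) -> dict[Sequence, Optional[Volume]]:
        """Channel-ordered mapping (T1, T1GAD, STIR); absent T1gad maps to None."""
        return {Sequence.T1: self.t1, Sequence.T1GAD: self.t1gad, Sequence.STIR: self.stir}


def read_volume(path: str | Path, sequence: Sequence = Sequence.OTHER) -> Volume:
    """Read a 3D NIfTI file into a :class:`Volume`.

    Spacing and orientation come from the header affine.  Non-3D images are
    rejected: this pipeline operates on single-sequence scalar volumes only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    return Volume(data=data, affine=np.asarray(img.affine), sequence=sequence)


def read_mask(path: str | Path) -> LabelMask:
    """Read a binary mask from NIfTI."""
    v = read_volume(path)
    return LabelMask(data=v.data, affine=v.affine)


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume to NIfTI (.nii or .nii.gz)."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = v.data
    if isinstance(v, LabelMask):
        data = data.astype(np.uint8)
    elif not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, v.affine), str(path))


def write_mask(m: LabelMask, path: str | Path) -> None:
    write_volume(m, path)


def zero_pad(v: Volume, width: int) -> Volume:
    """Pad ``width`` zero voxels on every side of every axis.

    The border exists so that patches extracted near the field-of-view edge are
    always full-sized; padding with zeros leaves the intensity sum unchanged.
    """
    if width < 0:
        raise ValueError("pad width must be >= 0")
    if width == 0:
        return v.with_data(v.data.copy())
    padded = np.pad(v.data, width, mode="constant", constant_values=0)
    # shift the origin so world coordinates of the original voxels are preserved
    affine = v.affine.copy()
    affine[:3, 3] -= affine[:3, :3] @ np.full(3, width)
    out = v.with_data(padded)
    out.affine = affine
    return out


def center_crop(v: Volume, width: int) -> Volume:
    """Inverse of :func:`zero_pad`: remove ``width`` voxels from every side."""
    if width < 0:
        raise ValueError("crop width must be >= 0")
    if width == 0:
        return v.with_data(v.data.copy())
    if min(v.shape) <= 2 * width:
        raise ValueError("crop width too large for volume")
    sl = tuple(slice(width, n - width) for n in v.shape)
    affine = v.affine.copy()
    affine[:3, 3] += affine[:3, :3] @ np.full(3, width)
    out = v.with_data(v.data[sl].copy())
    out.affine = affine
    return out
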