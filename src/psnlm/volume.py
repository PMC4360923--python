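"""Volume and mask containers plus NIfTI-1 I/O.

All image math in this package runs on :class:`Volume`, a thin wrapper
around a 3D float64 array with voxel spacing in millimetres.  No
reorientation is performed: arrays are kept in the axis order they are
stored in, with 0-based ``(i, j, k)`` indices — the denoising method is
orientation-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "Mask", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A 3D scalar field in arbitrary scanner units.

    Parameters
    ----------
    data : ndarray
        3D array; cast to float64 on construction.  All values must be
        finite.
    spacing : tuple of float
        Voxel spacing in mm per axis, strictly positive.  Default (1, 1, 1).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"not a 3D volume: got {self.data.ndim} dimensions")
        if self.data.size == 0:
            raise ValueError("empty volume")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """A new Volume sharing this volume's spacing."""
        return Volume(data, self.spacing)


@dataclass
class Mask:
    """A boolean 3D field aligned to a :class:`Volume`."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"not a 3D mask: got {self.data.ndim} dimensions")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def check_same_shape(volume: Volume, other: Volume | Mask) -> None:
    """Raise if the pair is not voxel-aligned."""
    if volume.shape != other.shape:
        raise ValueError(f"shape mismatch: {volume.shape} vs {other.shape}")


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 volume, casting intensities to float64.

    The shape is taken from the header; 2D or 4D payloads are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(f"not a 3D volume: {path} has {data.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    return Volume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms))


def write_volume(v: Volume, path: str | Path, dtype: np.dtype | type = np.float32) -> None:
    """Write a volume as NIfTI-1.

    ``dtype`` controls the on-disk representation (default float32).  The
    round trip ``read_volume(write_volume(v))`` is bitwise only when the
    stored dtype represents every value exactly; pass ``np.float64`` when
    exact round trips matter (internal compute is always float64).
    """
    path = Path(path)
    affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(v.data.astype(dtype), affine)
    img.header.set_zooms(v.spacing)
    img.to_filename(str(path))


def read_mask(path: str | Path) -> Mask:
    """Read a NIfTI mask: nonzero voxels are True."""
    v = read_volume(path)
    return Mask(v.data != 0)


def write_mask(m: Mask, path: str | Path, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a mask as a 0/1 NIfTI volume."""
    write_volume(Volume(m.data.astype(np.float64), spacing), path, dtype=np.uint8)
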