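"""3D image volumes with world-space geometry.

A :class:`VolumeImage` couples a voxel array with the affine that maps
0-based voxel indices to millimetre coordinates in a right-handed patient
frame.  The affine is the single source of geometry truth; spacing, origin
and orientation are derived views of it.  NIfTI-1 is the on-disk format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "affine_from_geometry", "read_volume", "write_volume"]

_ORTHO_TOL = 1e-6


def affine_from_geometry(
    spacing: np.ndarray | tuple,
    origin: np.ndarray | tuple = (0.0, 0.0, 0.0),
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Build a 4x4 voxel-to-world affine from spacing (mm), origin (mm) and
    an orthonormal 3x3 direction matrix (identity if omitted)."""
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    R = np.eye(3) if orientation is None else np.asarray(orientation, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = R * spacing[np.newaxis, :]
    aff[:3, 3] = np.asarray(origin, dtype=float)
    return aff


@dataclass
class VolumeImage:
    """A 3D intensity volume with voxel-to-world affine geometry.

    Parameters
    ----------
    data
        3D array of intensities; must be finite.
    affine
        4x4 voxel-index (0-based) to world (mm) transform.
    modality
        Free-form tag such as ``"T2W"``, ``"DWI_b800"`` or ``"ADC"``.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = ""
    allow_nan: bool = False  # resampling with a NaN fill sets this

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        finite = np.isfinite(self.data)
        if self.allow_nan:
            finite |= np.isnan(self.data)
        if not np.all(finite):
            raise ValueError("volume intensities must be finite")
        R = self.orientation
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("orientation matrix is not orthonormal")

    # -- derived geometry ------------------------------------------------
    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        """World coordinates (mm) of voxel (0, 0, 0)."""
        return self.affine[:3, 3].copy()

    @property
    def orientation(self) -> np.ndarray:
        """Orthonormal direction-cosine matrix (affine columns normalised)."""
        return self.affine[:3, :3] / self.spacing[np.newaxis, :]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    # -- coordinate mapping ----------------------------------------------
    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) continuous voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_geometry(self, other: "VolumeImage", tol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def copy_with(self, data: np.ndarray, modality: str | None = None) -> "VolumeImage":
        return VolumeImage(
            data=np.asarray(data, dtype=float),
            affine=self.affine.copy(),
            modality=self.modality if modality is None else modality,
        )


def read_volume(path: str | Path, modality: str = "") -> VolumeImage:
    """Read a NIfTI-1 file into a :class:`VolumeImage`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
    return VolumeImage(data=data, affine=np.asarray(img.affine, dtype=float), modality=modality)


def write_volume(vol: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; geometry round-trips through the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    nib.save(img, str(path))
    return path
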