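"""3-D volume containers, NIfTI I/O, affine transforms and mask resampling.

Volumes are kept in their native grid: a scalar array plus the 4x4
voxel-index-to-world-mm affine from the NIfTI header. Intensities are never
rescaled beyond the format's own scl_slope/scl_inter. Binary region and
lesion masks are resampled between grids with nearest-neighbour sampling so
that overlap arithmetic stays a pure voxel count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Volume3D",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "read_affine",
    "write_affine",
    "resample_mask",
]


class VolumeError(ValueError):
    """Raised for malformed volumes or transforms."""


@dataclass
class Volume3D:
    """A 3-D scalar grid with its voxel-to-world geometry.

    Parameters
    ----------
    data
        3-D array. Hounsfield units for CTA volumes, {0, 1} for masks.
    affine
        4x4 matrix mapping 0-based voxel indices (homogeneous) to world
        coordinates in millimetres, as stored in the NIfTI header.
    """

    data: np.ndarray
    affine: np.ndarray
    voxel_dims: tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3-D volume, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise VolumeError("singular voxel-to-world affine")
        dims = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        if np.any(dims <= 0):
            raise VolumeError("voxel dimensions must be positive")
        self.voxel_dims = tuple(float(d) for d in dims)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 affine block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def same_grid(self, other: "Volume3D", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass
class AffineTransform:
    """A 4x4 homogeneous world-mm to world-mm transform.

    The dialect is a plain world-coordinate affine; FSL FLIRT's native
    scaled-voxel .mat convention is *not* parsed and must be converted by
    the user before use.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise VolumeError("transform must be a 4x4 matrix")
        if not np.allclose(self.matrix[3], [0.0, 0.0, 0.0, 1.0], atol=1e-8):
            raise VolumeError("transform last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise VolumeError("transform is not invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1 volume.

    Applies the header's scl_slope/scl_inter scaling (via nibabel) and
    nothing else. Raises on non-3-D images; a trailing singleton fourth
    dimension is an error as well, since it signals a time series.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeError(f"expected 3-D volume, got {img.ndim}-D: {path}")
    data = np.asanyarray(img.dataobj)
    return Volume3D(data=np.asarray(data), affine=np.asarray(img.affine))


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz by extension)."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    nib.save(img, str(path))


def read_affine(path: str | Path) -> AffineTransform:
    """Read a 4x4 whitespace-delimited world-mm affine text file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        rows.append([float(tok) for tok in line.split()])
    arr = np.asarray(rows, dtype=float)
    if arr.shape != (4, 4):
        raise VolumeError(f"expected a 4x4 matrix in {path}, got shape {arr.shape}")
    return AffineTransform(arr)


def write_affine(transform: AffineTransform, path: str | Path) -> None:
    np.savetxt(str(path), transform.matrix, fmt="%.10g")


def resample_mask(
    mask: Volume3D,
    reference: Volume3D,
    transform: AffineTransform | None = None,
) -> Volume3D:
    """Resample a binary mask onto a reference grid by nearest neighbour.

    ``transform`` maps mask-world coordinates to reference-world coordinates
    (identity if omitted). Each reference voxel centre is pushed through
    ``mask.affine^-1 @ transform^-1 @ reference.affine`` and the nearest
    mask voxel is taken; samples outside the mask field of view are 0.

    Nearest-neighbour (no partial-volume weighting) keeps the output binary
    so the >=30% overlap rule stays an exact voxel-count ratio.
    """
    if not mask.is_binary():
        raise VolumeError("resample_mask requires a binary mask")
    if transform is None:
        transform = AffineTransform.identity()
    # output voxel index -> input voxel index, as one homogeneous matrix
    m = np.linalg.inv(mask.affine) @ np.linalg.inv(transform.matrix) @ reference.affine
    out = ndimage.affine_transform(
        mask.data.astype(np.uint8),
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=reference.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    if mask.data.any() and not out.any():
        logger.warning(
            "resampled mask is empty: mask lies outside the reference field of view"
        )
    return Volume3D(data=out.astype(np.uint8), affine=reference.affine.copy())
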