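"""Volumetric containers and NIfTI-1 I/O.

Every stage of the package operates on two containers: :class:`Volume`
(scalar grids — image intensities, tissue fractions, bias fields) and
:class:`BinaryMask` (boolean grids on the same geometry).  Both carry a
4x4 voxel-index -> world-mm affine in the NIfTI sform convention (RAS+,
0-based voxel indices).  The whole pipeline works on a common 1 mm
isotropic grid; inputs on other grids are resampled on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ContractError, GeometryError

#: relative tolerance on affine entries when deciding two grids match
GEOMETRY_RTOL = 1e-4


def _check_geometry(data: np.ndarray, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise ContractError(f"expected a 3-D grid, got shape {data.shape}")
    if min(data.shape) < 1:
        raise ContractError(f"every axis must have length >= 1, got {data.shape}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ContractError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ContractError("affine is singular")


def spacing_of(affine: np.ndarray) -> np.ndarray:
    """Voxel spacing in mm: column norms of the 3x3 affine block."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def geometry_matches(a: "Volume | BinaryMask", b: "Volume | BinaryMask",
                     rtol: float = GEOMETRY_RTOL) -> bool:
    return (a.data.shape == b.data.shape
            and np.allclose(a.affine, b.affine, rtol=rtol, atol=rtol))


def require_same_geometry(a, b, what: str = "operands") -> None:
    if not geometry_matches(a, b):
        raise GeometryError(
            f"{what} have mismatched geometry: "
            f"shapes {a.data.shape} vs {b.data.shape}, "
            f"affines\n{a.affine}\nvs\n{b.affine}")


@dataclass
class Volume:
    """A 3-D scalar grid with world geometry.

    Parameters
    ----------
    data : ndarray
        3-D scalar grid.
    affine : ndarray
        4x4 voxel-index -> world-mm transform (NIfTI sform, RAS+).
    dtype_role : {"intensity", "fraction", "bias"}
        Semantic role; ``fraction`` data must lie in [0, 1].
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    dtype_role: str = "intensity"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        _check_geometry(self.data, self.affine)
        if self.dtype_role not in ("intensity", "fraction", "bias"):
            raise ContractError(f"unknown dtype_role {self.dtype_role!r}")
        if not np.all(spacing_of(self.affine) > 0):
            raise ContractError("spacing must be strictly positive on all axes")
        if self.dtype_role == "fraction":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ContractError(
                    f"fraction volume has values outside [0,1]: [{lo}, {hi}]")
            np.clip(self.data, 0.0, 1.0, out=self.data)

    @property
    def spacing(self) -> np.ndarray:
        return spacing_of(self.affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def with_data(self, data: np.ndarray, dtype_role: str | None = None) -> "Volume":
        """New Volume on the same geometry."""
        return Volume(data, self.affine.copy(),
                      dtype_role if dtype_role is not None else self.dtype_role)

    def world_center(self) -> np.ndarray:
        """World coordinates of the grid center."""
        idx = (np.asarray(self.shape, dtype=float) - 1) / 2
        return self.affine[:3, :3] @ idx + self.affine[:3, 3]


@dataclass
class BinaryMask:
    """A 3-D boolean grid sharing :class:`Volume`'s geometry contract."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ContractError(
                    f"mask values must be exactly {{0,1}}, found {uniq[:10]}")
            arr = arr.astype(bool)
        self.data = arr
        self.affine = np.asarray(self.affine, dtype=np.float64)
        _check_geometry(self.data, self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return spacing_of(self.affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(np.asarray(data, dtype=bool), self.affine.copy())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        require_same_geometry(self, other, "masks")
        return self.with_data(self.data & other.data)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        require_same_geometry(self, other, "masks")
        return self.with_data(self.data | other.data)

    def __invert__(self) -> "BinaryMask":
        return self.with_data(~self.data)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path, dtype_role: str = "intensity") -> Volume:
    """Read a 3-D NIfTI-1 file as a :class:`Volume`.

    Raises an :class:`OSError` for a missing file and a
    :class:`ContractError` for a non-3-D image.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ContractError(
            f"expected a 3-D image, file {path} has shape {data.shape}")
    return Volume(data.astype(np.float64), np.asarray(img.affine), dtype_role)


def read_mask(path) -> BinaryMask:
    """Read a NIfTI file as a :class:`BinaryMask` (values must be {0,1})."""
    vol = read_volume(path)
    return BinaryMask(vol.data.astype(np.int16), vol.affine)


def write_volume(vol: Volume | BinaryMask, path) -> None:
    """Write a Volume (float64) or BinaryMask (uint8) to NIfTI-1."""
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float64)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_sform(vol.affine, code=1)
    img.header.set_qform(vol.affine, code=1)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"nearest": 0, "trilinear": 1}


def resample_to_grid(vol: Volume | BinaryMask, target_spacing,
                     interp: str = "trilinear") -> Volume | BinaryMask:
    """Resample onto a grid with the given spacing, preserving world extent.

    Masks may only be resampled with nearest-neighbour interpolation.
    """
    if interp not in _INTERP_ORDER:
        raise ContractError(f"interp must be one of {list(_INTERP_ORDER)}")
    target_spacing = np.asarray(target_spacing, dtype=float)
    if target_spacing.shape == ():
        target_spacing = np.repeat(target_spacing, 3)
    if not np.all(target_spacing > 0):
        raise ContractError("target_spacing must be positive")
    is_mask = isinstance(vol, BinaryMask)
    if is_mask and interp != "nearest":
        raise ContractError("binary masks must be resampled with interp='nearest'")

    old_spacing = vol.spacing
    if np.allclose(old_spacing, target_spacing, rtol=1e-6):
        return vol.with_data(vol.data.copy())

    zoom = old_spacing / target_spacing
    new_shape = np.maximum(1, np.ceil(np.asarray(vol.shape) * zoom)).astype(int)
    # new affine: same direction cosines, voxel size scaled; keep the corner
    # of voxel (0,0,0) fixed in world space
    direction = vol.affine[:3, :3] / old_spacing[np.newaxis, :]
    new_affine = np.eye(4)
    new_affine[:3, :3] = direction * target_spacing[np.newaxis, :]
    new_affine[:3, 3] = vol.affine[:3, 3]

    # map output index -> input index
    matrix = np.linalg.inv(vol.affine) @ new_affine
    src = vol.data.astype(np.float64)
    out = ndimage.affine_transform(
        src, matrix[:3, :3], offset=matrix[:3, 3], output_shape=tuple(new_shape),
        order=_INTERP_ORDER[interp], mode="constant", cval=0.0)
    if is_mask:
        return BinaryMask(out > 0.5, new_affine)
    return Volume(out, new_affine, vol.dtype_role)
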