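"""NIfTI volume I/O and the in-memory grid container.

All downstream modules operate on :class:`VolumeGrid`, a 3-D array together
with its voxel dimensions (mm) and a 4x4 voxel-to-world affine.  Volumes are
reoriented on load to the closest right-handed RAS+ axis order (the MNI
convention), so that masks and atlases always share one coordinate
convention regardless of how they were stored on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import orientations as nibo

from .errors import FormatError, GeometryError, ValidationError

DTYPE_TAGS = ("binary", "probability", "label", "intensity")

# dtype used on disk per tag; floats for probability/intensity
_SAVE_DTYPE = {
    "binary": np.uint8,
    "label": np.int32,
    "probability": np.float32,
    "intensity": np.float32,
}


@dataclass
class VolumeGrid:
    """A 3-D scalar lattice with voxel geometry.

    Parameters
    ----------
    data:
        3-D array in (i, j, k) index order.
    voxel_dims:
        Positive voxel edge lengths in mm per axis.
    affine:
        4x4 voxel-index -> world-mm matrix.
    dtype_tag:
        One of ``binary``, ``probability``, ``label``, ``intensity``.
    scale:
        For probability volumes, the value of "certain membership": 1.0 for
        atlases encoded 0-1, 100.0 for percent-encoded atlases.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray
    dtype_tag: str = "intensity"
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValidationError(f"voxel_dims must be three positive mm values, got {self.voxel_dims}")
        if self.dtype_tag not in DTYPE_TAGS:
            raise ValidationError(f"unknown dtype_tag {self.dtype_tag!r}")
        if self.dtype_tag == "binary":
            bad = np.setdiff1d(np.unique(self.data), [0, 1])
            if bad.size:
                raise ValidationError(f"binary volume contains values outside {{0, 1}}: {bad[:10].tolist()}")
        elif self.dtype_tag == "probability":
            if self.scale not in (1.0, 100.0):
                raise ValidationError(f"probability scale must be 1 or 100, got {self.scale}")
            lo, hi = float(np.min(self.data, initial=0)), float(np.max(self.data, initial=0))
            if lo < 0 or hi > self.scale:
                raise ValidationError(
                    f"probability values outside [0, {self.scale}]: range [{lo}, {hi}]"
                )
        elif self.dtype_tag == "label":
            if not np.issubdtype(self.data.dtype, np.integer):
                if not np.array_equal(self.data, np.round(self.data)):
                    raise ValidationError("label volume contains non-integer values")
                self.data = self.data.astype(np.int32)
            if np.min(self.data, initial=0) < 0:
                raise ValidationError("label volume contains negative values")

    # -- geometry helpers --------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def copy(self) -> "VolumeGrid":
        return replace(self, data=self.data.copy(), affine=self.affine.copy())


def grid_like(ref: VolumeGrid, data: np.ndarray, dtype_tag: str, scale: float = 1.0) -> VolumeGrid:
    """A new grid sharing *ref*'s geometry."""
    return VolumeGrid(data, ref.voxel_dims, ref.affine, dtype_tag, scale)


def default_affine(voxel_dims, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_dims)
    aff[:3, 3] = origin
    return aff


# ---------------------------------------------------------------------------
# Load / save
# ---------------------------------------------------------------------------

def load_volume(path, expect: str = "intensity") -> VolumeGrid:
    """Read a NIfTI-1 volume (optionally .gz), reoriented to canonical RAS+.

    ``expect`` declares the value contract (``binary``, ``probability``,
    ``label`` or ``intensity``) and is enforced on the loaded data.  For
    probability volumes the encoding scale (0-1 vs percent 0-100) is detected
    from the data maximum (> 1.5 implies percent).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    scale = 1.0
    if expect == "probability":
        scale = 100.0 if float(np.max(data, initial=0)) > 1.5 else 1.0
    if expect in ("binary", "label"):
        if not np.array_equal(data, np.round(data)):
            raise ValidationError(f"{path}: {expect} volume contains non-integer values")
        data = np.round(data).astype(np.int32)
    try:
        return VolumeGrid(data, zooms, img.affine, dtype_tag=expect, scale=scale)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def save_volume(grid: VolumeGrid, path) -> None:
    """Write *grid* as NIfTI-1; round-trips exactly for integer dtypes."""
    if not np.all(np.isfinite(grid.data)):
        raise ValidationError("volume contains non-finite values; refusing to write")
    path = Path(path)
    dtype = _SAVE_DTYPE[grid.dtype_tag]
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=dtype), grid.affine)
    img.header.set_zooms(grid.voxel_dims)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def canonicalise_orientation(grid: VolumeGrid) -> VolumeGrid:
    """Permute/flip axes so voxel axes align with RAS+ world axes.

    World coordinates of every voxel centre are preserved (the affine is
    updated consistently), so mask foreground counts and world-space
    centroids are invariant.  Idempotent.
    """
    if abs(np.linalg.det(grid.affine[:3, :3])) < 1e-12:
        raise GeometryError("singular affine; cannot determine orientation")
    ornt = nibo.io_orientation(grid.affine)
    target = np.array([[0, 1], [1, 1], [2, 1]], dtype=float)
    if np.array_equal(ornt, target):
        return grid
    transform = nibo.ornt_transform(ornt, target)
    data = nibo.apply_orientation(grid.data, transform)
    affine = grid.affine @ nibo.inv_ornt_aff(transform, grid.shape)
    dims = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    return VolumeGrid(data, dims, affine, grid.dtype_tag, grid.scale)
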