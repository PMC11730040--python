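"""Connected-component extraction and moment-based lesion sizing.

A cerebral microbleed (CMB) appears in a binary lesion map as a compact
connected blob.  Each blob's diameter is defined as the major-axis length of
the uniform-density solid ellipsoid with the same second-order central
moments as the voxel set (same spread and orientation), expressed in mm.
For a solid ellipsoid of semi-axis ``a`` the central second moment along
that axis is ``a^2 / 5``, so the major-axis length is ``2*sqrt(5*lmax)``
where ``lmax`` is the largest eigenvalue of the moment matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .image_io import VolumeGrid

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class LesionComponent:
    """One connected lesion.

    ``voxels`` is an (N, 3) integer array of (i, j, k) indices;
    ``bounding_box`` is half-open ``((lo_i, hi_i), (lo_j, hi_j), (lo_k, hi_k))``.
    """

    component_id: int
    voxels: np.ndarray
    bounding_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    centroid_voxel: tuple[float, float, float]
    centroid_mm: tuple[float, float, float]
    diameter_mm: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(int(x) for x in v) for v in self.voxels}


def compute_centroid(voxels: np.ndarray, voxel_dims) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-axis arithmetic mean of voxel indices, and its mm-scaled version."""
    voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
    if voxels.size == 0:
        raise ValidationError("cannot compute the centroid of an empty component")
    cv = voxels.mean(axis=0)
    cm = cv * np.asarray(voxel_dims, dtype=float)
    return tuple(cv), tuple(cm)


def estimate_diameter(voxels: np.ndarray, voxel_dims) -> float:
    """Major-axis length (mm) of the moment-matched solid ellipsoid.

    Moments are computed in mm space: each index axis is scaled by its voxel
    dimension before forming the 3x3 central covariance of voxel centres.
    Each voxel also contributes its own extent, ``d_a^2 / 20`` per axis (the
    central second moment of a solid ball of diameter ``d_a``), so a single
    voxel has nonzero spread and reports exactly one voxel of diameter.  The
    result is floored at ``max(voxel_dims)``: no lesion is thinner than one
    voxel.
    """
    voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
    if voxels.size == 0:
        raise ValidationError("cannot size an empty component")
    dims = np.asarray(voxel_dims, dtype=float)
    if dims.shape != (3,) or np.any(dims <= 0):
        raise ValidationError(f"voxel_dims must be three positive mm values, got {voxel_dims}")
    mm = voxels * dims
    centred = mm - mm.mean(axis=0)
    cov = centred.T @ centred / len(mm)
    cov = cov + np.diag(dims**2 / 20.0)
    lmax = float(np.linalg.eigvalsh(cov)[-1])
    return max(2.0 * np.sqrt(5.0 * lmax), float(dims.max()))


def label_components(mask: VolumeGrid, connectivity: int = 26) -> list[LesionComponent]:
    """Partition a binary mask into maximal connected lesions.

    Component ids are assigned in raster-scan order of each component's
    first-encountered voxel, starting at 1.  ``connectivity`` is 6 (faces),
    18 (faces+edges) or 26 (faces+edges+corners).
    """
    if mask.dtype_tag != "binary":
        raise ValidationError(f"label_components requires a binary mask, got {mask.dtype_tag!r}")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValidationError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        return []
    # enforce raster order of first-encountered voxel
    first_flat = ndimage.labeled_comprehension(
        np.arange(labels.size).reshape(labels.shape), labels, np.arange(1, n + 1), np.min, int, -1
    )
    order = np.argsort(first_flat)
    dims = np.asarray(mask.voxel_dims)
    out: list[LesionComponent] = []
    slices = ndimage.find_objects(labels)
    for new_id, old_idx in enumerate(order, start=1):
        old_label = old_idx + 1
        sl = slices[old_label - 1]
        sub = labels[sl] == old_label
        vox = np.argwhere(sub) + np.array([s.start for s in sl])
        bbox = tuple((int(vox[:, a].min()), int(vox[:, a].max()) + 1) for a in range(3))
        cv, cm = compute_centroid(vox, dims)
        diam = estimate_diameter(vox, dims)
        out.append(
            LesionComponent(
                component_id=new_id,
                voxels=vox,
                bounding_box=bbox,  # type: ignore[arg-type]
                centroid_voxel=cv,  # type: ignore[arg-type]
                centroid_mm=cm,  # type: ignore[arg-type]
                diameter_mm=diam,
            )
        )
    return out


def lesion_table(components: list[LesionComponent]) -> pd.DataFrame:
    """Per-lesion report: id, voxel count, centroid, diameter, bounding box."""
    rows = []
    for c in components:
        rows.append(
            {
                "component_id": c.component_id,
                "n_voxels": c.n_voxels,
                "centroid_i": c.centroid_voxel[0],
                "centroid_j": c.centroid_voxel[1],
                "centroid_k": c.centroid_voxel[2],
                "centroid_x_mm": c.centroid_mm[0],
                "centroid_y_mm": c.centroid_mm[1],
                "centroid_z_mm": c.centroid_mm[2],
                "diameter_mm": c.diameter_mm,
                "oversized": c.diameter_mm > 10.0,  # MARS defines CMBs as 2-10 mm
                "bbox_i_lo": c.bounding_box[0][0],
                "bbox_i_hi": c.bounding_box[0][1],
                "bbox_j_lo": c.bounding_box[1][0],
                "bbox_j_hi": c.bounding_box[1][1],
                "bbox_k_lo": c.bounding_box[2][0],
                "bbox_k_hi": c.bounding_box[2][1],
            }
        )
    cols = [
        "component_id", "n_voxels", "centroid_i", "centroid_j", "centroid_k",
        "centroid_x_mm", "centroid_y_mm", "centroid_z_mm", "diameter_mm", "oversized",
        "bbox_i_lo", "bbox_i_hi", "bbox_j_lo", "bbox_j_hi", "bbox_k_lo", "bbox_k_hi",
    ]
    return pd.DataFrame(rows, columns=cols)
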