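"""MARS structure atlas: construction, lookup table, and spatial transform.

The Microbleed Anatomical Rating Scale (MARS) counts microbleeds per
anatomical structure, grouped into three regions:

* infratentorial — brainstem, cerebellum;
* deep — basal ganglia, thalamus, internal/external capsules, corpus
  callosum, deep white matter;
* lobar — frontal, parietal, temporal, occipital lobes and insula.

The atlas is built from per-structure masks (probabilistic atlases are
binarised at a percent threshold first).  Cortical lobe masks are dilated so
the lobar region reaches the grey-white junction; the capsules and corpus
callosum are carved out of the deep white matter mask because they are rated
separately.  Overlaps are resolved by a fixed priority (infratentorial >
named deep structures > deep white matter > dilated lobar), with ties within
a priority tier going to the structure whose undilated mask is nearest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .image_io import VolumeGrid, grid_like

REGIONS = ("infratentorial", "deep", "lobar")

#: MARS region membership per structure.
STRUCTURE_REGION: dict[str, str] = {
    "brainstem": "infratentorial",
    "cerebellum": "infratentorial",
    "basal_ganglia": "deep",
    "thalamus": "deep",
    "internal_capsule": "deep",
    "external_capsule": "deep",
    "corpus_callosum": "deep",
    "deep_white_matter": "deep",
    "frontal": "lobar",
    "parietal": "lobar",
    "temporal": "lobar",
    "occipital": "lobar",
    "insula": "lobar",
}

STRUCTURES = tuple(STRUCTURE_REGION)

#: deep structures rated separately from (and carved out of) deep white matter
_NAMED_DEEP = ("basal_ganglia", "thalamus", "internal_capsule", "external_capsule", "corpus_callosum")
_WM_EXCLUDE = ("internal_capsule", "external_capsule", "corpus_callosum")

# overlap priority tiers, higher wins; within a tier the nearest undilated
# mask wins, exact ties go to the lower structure code
_PRIORITY = {}
for _s, _r in STRUCTURE_REGION.items():
    if _r == "infratentorial":
        _PRIORITY[_s] = 4
    elif _s in _NAMED_DEEP:
        _PRIORITY[_s] = 3
    elif _s == "deep_white_matter":
        _PRIORITY[_s] = 2
    else:
        _PRIORITY[_s] = 1


@dataclass(frozen=True)
class StructureDef:
    """One row of the atlas lookup table."""

    code: int
    name: str
    region: str
    source: str = ""
    threshold: float | None = None  # percent scale; None for discrete sources
    dilate: bool = False

    def __post_init__(self) -> None:
        if self.code <= 0:
            raise ValidationError(f"structure code must be positive, got {self.code}")
        if self.name not in STRUCTURE_REGION:
            raise ValidationError(f"unknown structure name {self.name!r}")
        if self.region != STRUCTURE_REGION[self.name]:
            raise ValidationError(
                f"{self.name} belongs to region {STRUCTURE_REGION[self.name]!r}, not {self.region!r}"
            )
        if self.threshold is not None and not (0 < self.threshold <= 100):
            raise ValidationError(f"threshold must lie in (0, 100], got {self.threshold}")


@dataclass
class MarsAtlas:
    """Integer label volume plus its lookup table."""

    labels: VolumeGrid
    lut: list[StructureDef]
    space_tag: str = "template"  # or "subject"

    def __post_init__(self) -> None:
        codes = {s.code for s in self.lut}
        present = set(np.unique(self.labels.data).tolist()) - {0}
        missing = present - codes
        if missing:
            raise ValidationError(f"label values without LUT entry: {sorted(missing)}")

    def structure_of(self, code: int) -> StructureDef:
        for s in self.lut:
            if s.code == code:
                return s
        raise ValidationError(f"no LUT entry for code {code}")

    def mask_of(self, name: str) -> np.ndarray:
        code = next(s.code for s in self.lut if s.name == name)
        return self.labels.data == code


def default_lut() -> list[StructureDef]:
    """The standard MARS lookup table.

    Sources: Harvard-Oxford subcortical (probabilistic; threshold 50 for
    brainstem, basal ganglia and thalamus, 60 for deep white matter), the
    MNI structural atlas (discrete; cerebellum and cortical lobes, dilated),
    and the JHU ICBM-DTI-81 white-matter labels (discrete; capsules and
    corpus callosum).
    """
    rows = [
        (1, "brainstem", "harvard_oxford_subcortical", 50.0, False),
        (2, "cerebellum", "mni_structural", None, False),
        (3, "basal_ganglia", "harvard_oxford_subcortical", 50.0, False),
        (4, "thalamus", "harvard_oxford_subcortical", 50.0, False),
        (5, "internal_capsule", "jhu_icbm_dti81", None, False),
        (6, "external_capsule", "jhu_icbm_dti81", None, False),
        (7, "corpus_callosum", "jhu_icbm_dti81", None, False),
        (8, "deep_white_matter", "harvard_oxford_subcortical", 60.0, False),
        (9, "frontal", "mni_structural", None, True),
        (10, "parietal", "mni_structural", None, True),
        (11, "temporal", "mni_structural", None, True),
        (12, "occipital", "mni_structural", None, True),
        (13, "insula", "mni_structural", None, True),
    ]
    return [
        StructureDef(code, name, STRUCTURE_REGION[name], source, thr, dil)
        for code, name, source, thr, dil in rows
    ]


def write_lut(lut: list[StructureDef], path) -> None:
    pd.DataFrame(
        [
            {"code": s.code, "name": s.name, "region": s.region, "source": s.source,
             "threshold": s.threshold, "dilate": s.dilate}
            for s in lut
        ]
    ).to_csv(path, index=False)


def read_lut(path) -> list[StructureDef]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        thr = None if pd.isna(r.get("threshold")) else float(r["threshold"])
        out.append(
            StructureDef(int(r["code"]), str(r["name"]), str(r["region"]),
                         str(r.get("source", "")), thr, bool(r["dilate"]))
        )
    return out


# ---------------------------------------------------------------------------
# Mask construction
# ---------------------------------------------------------------------------

def binarise_structure(prob: VolumeGrid, threshold_percent: float) -> VolumeGrid:
    """Threshold a probabilistic map (inclusive: foreground iff p >= t).

    ``threshold_percent`` is always given on the percent scale; it is mapped
    onto the volume's declared encoding scale (0-1 or 0-100) before use.
    """
    if not (0 < threshold_percent <= 100):
        raise ValidationError(f"threshold must lie in (0, 100], got {threshold_percent}")
    if prob.dtype_tag != "probability":
        raise ValidationError(f"binarise_structure expects a probability volume, got {prob.dtype_tag!r}")
    thr = threshold_percent * prob.scale / 100.0
    return grid_like(prob, (prob.data >= thr).astype(np.uint8), "binary")


def _element(size: int, shape: str) -> np.ndarray:
    if size < 1:
        raise ValidationError(f"structuring element size must be >= 1, got {size}")
    if shape == "cube":
        return np.ones((size,) * 3, dtype=bool)
    if shape == "ball":
        r = (size - 1) / 2.0
        g = np.indices((size,) * 3) - r
        return (g**2).sum(axis=0) <= r**2 + 1e-9
    if shape == "cross":
        el = np.zeros((size,) * 3, dtype=bool)
        c = size // 2
        el[:, c, c] = el[c, :, c] = el[c, c, :] = True
        return el
    raise ValidationError(f"unknown structuring element shape {shape!r}")


def dilate_mask(mask: VolumeGrid, size_voxels: int = 3, shape: str = "cube") -> VolumeGrid:
    """Morphological dilation with a 3-D element of the given width."""
    if mask.dtype_tag != "binary":
        raise ValidationError(f"dilate_mask expects a binary mask, got {mask.dtype_tag!r}")
    out = ndimage.binary_dilation(mask.data.astype(bool), structure=_element(size_voxels, shape))
    return grid_like(mask, out.astype(np.uint8), "binary")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_atlas(
    structures: list[tuple[StructureDef, VolumeGrid]],
    dilation_size: int = 3,
    dilation_shape: str = "cube",
    space_tag: str = "template",
) -> MarsAtlas:
    """Merge per-structure binary masks into one MARS label volume.

    Steps: (i) cortical masks flagged ``dilate`` are dilated so the lobar
    region covers the grey-white junction; (ii) the capsules and corpus
    callosum are removed from the deep white matter mask; (iii) masks are
    merged under the priority infratentorial > named deep structures > deep
    white matter > lobar.  Within a tier, contested voxels go to the
    structure whose *undilated* mask is nearest (Euclidean distance in mm);
    exact ties go to the lower code.  Every voxel gets exactly one label.
    """
    if not structures:
        raise ValidationError("assemble_atlas needs at least one structure")
    ref = structures[0][1]
    bad = [sd.name for sd, g in structures if not g.same_geometry(ref)]
    if bad:
        raise ValidationError(f"structure masks with mismatched geometry: {bad}")
    names = [sd.name for sd, _ in structures]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate structure names in atlas input")

    raw = {sd.name: (sd, g.data.astype(bool)) for sd, g in structures}

    # (ii) white-matter exclusion
    if "deep_white_matter" in raw:
        sd, wm = raw["deep_white_matter"]
        for other in _WM_EXCLUDE:
            if other in raw:
                wm = wm & ~raw[other][1]
        raw["deep_white_matter"] = (sd, wm)

    # (i) lobar dilation; keep undilated masks for tie-breaking
    final: dict[str, np.ndarray] = {}
    undilated: dict[str, np.ndarray] = {}
    for name, (sd, m) in raw.items():
        undilated[name] = m
        final[name] = (
            ndimage.binary_dilation(m, structure=_element(dilation_size, dilation_shape))
            if sd.dilate
            else m
        )

    # (iii) merge, low priority first so high priority overwrites
    labels = np.zeros(ref.shape, dtype=np.int32)
    dims = np.asarray(ref.voxel_dims)
    for tier in sorted(set(_PRIORITY[n] for n in final)):
        tier_structs = sorted(
            [raw[n][0] for n in final if _PRIORITY[n] == tier], key=lambda s: s.code
        )
        if len(tier_structs) == 1:
            sd = tier_structs[0]
            labels[final[sd.name]] = sd.code
            continue
        tier_label = np.zeros(ref.shape, dtype=np.int32)
        best_dist = np.full(ref.shape, np.inf)
        for sd in tier_structs:
            m = final[sd.name]
            if not m.any():
                continue
            src = undilated[sd.name] if undilated[sd.name].any() else m
            dist = ndimage.distance_transform_edt(~src, sampling=dims)
            take = m & (dist < best_dist)
            tier_label[take] = sd.code
            best_dist = np.where(take, dist, best_dist)
        claimed = tier_label > 0
        labels[claimed] = tier_label[claimed]

    lut = [sd for sd, _ in structures]
    return MarsAtlas(grid_like(ref, labels, "label"), lut, space_tag)


# ---------------------------------------------------------------------------
# Transform to subject space
# ---------------------------------------------------------------------------

def transform_atlas(atlas: MarsAtlas, affine_4x4: np.ndarray, target: VolumeGrid) -> MarsAtlas:
    """Resample the atlas into subject space through a world affine.

    ``affine_4x4`` maps template-space world coordinates to subject-space
    world coordinates.  Each structure's binary mask is pulled through the
    inverse map with trilinear interpolation, thresholded at 0.5, and the
    masks are re-merged under the assembly priority rules (no re-dilation:
    lobar masks were already extended in template space).
    """
    A = np.asarray(affine_4x4, dtype=float)
    if A.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {A.shape}")
    if abs(np.linalg.det(A)) < 1e-12:
        raise GeometryError("singular template-to-subject affine")

    # target voxel -> template voxel, composed as one matrix
    tmpl = atlas.labels
    M = np.linalg.inv(tmpl.affine) @ np.linalg.inv(A) @ target.affine
    grid = np.indices(target.shape, dtype=float).reshape(3, -1)
    coords = M[:3, :3] @ grid + M[:3, 3:4]

    pieces: list[tuple[StructureDef, VolumeGrid]] = []
    for sd in atlas.lut:
        mask = (tmpl.data == sd.code).astype(np.float32)
        vals = ndimage.map_coordinates(mask, coords, order=1, mode="constant", cval=0.0)
        out = (vals >= 0.5).reshape(target.shape).astype(np.uint8)
        pieces.append((replace(sd, dilate=False), grid_like(target, out, "binary")))
    moved = assemble_atlas(pieces, space_tag="subject")
    return MarsAtlas(moved.labels, list(atlas.lut), "subject")


# ---------------------------------------------------------------------------
# Affine loading
# ---------------------------------------------------------------------------

def load_affine(path) -> np.ndarray:
    """Read a whitespace-delimited 4x4 world-to-world affine."""
    try:
        mat = np.loadtxt(path)
    except (OSError, ValueError) as exc:
        raise GeometryError(f"cannot read affine matrix from {path}: {exc}") from exc
    if mat.shape != (4, 4):
        raise GeometryError(f"affine file must hold a 4x4 matrix, got {mat.shape}")
    return mat


def _fsl_scaled_mat(grid: VolumeGrid) -> np.ndarray:
    """Voxel -> FSL scaled-mm coordinates for one grid (x flipped when the
    voxel-to-world matrix has positive determinant, per the FLIRT convention)."""
    D = np.eye(4)
    D[:3, :3] = np.diag(grid.voxel_dims)
    if np.linalg.det(grid.affine[:3, :3]) > 0:
        F = np.eye(4)
        F[0, 0] = -1.0
        F[0, 3] = grid.shape[0] - 1
        D = D @ F
    return D


def flirt_to_world(mat: np.ndarray, src: VolumeGrid, dst: VolumeGrid) -> np.ndarray:
    """Convert a FLIRT-style matrix (scaled-voxel dialect) to a world affine.

    FLIRT matrices map source scaled-mm coordinates to reference scaled-mm
    coordinates; the returned matrix maps source world coordinates to
    reference world coordinates, as expected by :func:`transform_atlas`.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (4, 4):
        raise GeometryError(f"expected a 4x4 matrix, got {mat.shape}")
    S_src = _fsl_scaled_mat(src)
    S_dst = _fsl_scaled_mat(dst)
    return dst.affine @ np.linalg.inv(S_dst) @ mat @ S_src @ np.linalg.inv(src.affine)
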