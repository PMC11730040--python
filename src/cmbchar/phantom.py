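"""Self-contained synthetic phantoms for every stage of the pipeline.

The phantom stands in for real SWI-derived data: it lays out the thirteen
MARS structures as disjoint geometric primitives on a small isotropic grid
(default 64^3 at 0.9 mm), renders per-structure probability maps with a
two-voxel soft border, plants digitised spherical lesions with known
centres, diameters and intended structures, and can degrade the lesion mask
(jitter / drop / split-merge) to emulate an imperfect upstream segmentation.
The layout is geometrically, not anatomically, faithful — it exercises the
code paths, not the neuroanatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .image_io import VolumeGrid, default_affine, grid_like
from .lesion_features import label_components
from .mars_atlas import STRUCTURE_REGION, MarsAtlas, StructureDef, assemble_atlas


@dataclass(frozen=True)
class StructurePrimitive:
    name: str
    kind: str  # "box" | "ball"
    centre: tuple[float, float, float]  # voxel coordinates
    extent: tuple[float, float, float]  # full widths (box) / diameters (ball), voxels

    def __post_init__(self) -> None:
        if self.name not in STRUCTURE_REGION:
            raise ValidationError(f"unknown structure {self.name!r}")
        if self.kind not in ("box", "ball"):
            raise ValidationError(f"primitive kind must be box or ball, got {self.kind!r}")
        if any(e <= 0 for e in self.extent):
            raise ValidationError(f"degenerate primitive extent {self.extent}")


@dataclass(frozen=True)
class LesionSpec:
    centre_voxel: tuple[float, float, float]
    diameter_mm: float
    structure: str


@dataclass(frozen=True)
class Perturbation:
    kind: str = "none"  # none | jitter | drop | split_merge
    sigma_mm: float = 0.0
    p: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "jitter", "drop", "split_merge"):
            raise ValidationError(f"unknown perturbation {self.kind!r}")
        if self.kind == "jitter" and self.sigma_mm <= 0:
            raise ValidationError("jitter needs sigma_mm > 0")
        if self.kind in ("drop", "split_merge") and not (0 <= self.p <= 1):
            raise ValidationError(f"probability must lie in [0, 1], got {self.p}")


def default_structures() -> list[StructurePrimitive]:
    """Thirteen disjoint primitives on the default 64^3 grid.

    Boxes of width 10 voxels on a 16-voxel lattice (6-voxel gaps), split
    over two axial levels; the cerebellum is a ball to exercise the second
    primitive kind.
    """
    e = (10.0, 10.0, 10.0)
    rows = [
        ("brainstem", "box", (10, 10, 14), e),
        ("cerebellum", "ball", (26, 10, 14), (10.0, 10.0, 10.0)),
        ("basal_ganglia", "box", (42, 10, 14), e),
        ("thalamus", "box", (56, 10, 14), e),
        ("internal_capsule", "box", (10, 26, 14), e),
        ("external_capsule", "box", (26, 26, 14), e),
        ("corpus_callosum", "box", (42, 26, 14), e),
        ("deep_white_matter", "box", (56, 26, 14), e),
        ("frontal", "box", (10, 42, 44), e),
        ("parietal", "box", (26, 42, 44), e),
        ("temporal", "box", (42, 42, 44), e),
        ("occipital", "box", (56, 42, 44), e),
        ("insula", "box", (10, 56, 44), e),
    ]
    return [StructurePrimitive(n, k, tuple(map(float, c)), ext) for n, k, c, ext in rows]


def default_lesions(structures: list[StructurePrimitive] | None = None) -> list[LesionSpec]:
    """One lesion per structure, at the structure centre, 2.7-5.4 mm."""
    structures = default_structures() if structures is None else structures
    diameters = [3.6, 4.5, 2.7, 5.4]
    return [
        LesionSpec(p.centre, diameters[i % len(diameters)], p.name)
        for i, p in enumerate(structures)
    ]


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (0.9, 0.9, 0.9)
    structures: list[StructurePrimitive] = field(default_factory=default_structures)
    lesions: list[LesionSpec] | None = None  # None -> one default lesion per structure
    perturbation: Perturbation = field(default_factory=Perturbation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesions is None:
            self.lesions = default_lesions(self.structures)
        names = {p.name for p in self.structures}
        for les in self.lesions:
            if not (1.0 <= les.diameter_mm <= 12.0):
                raise ValidationError(f"lesion diameter {les.diameter_mm} mm outside [1, 12]")
            if any(c < 0 or c >= s for c, s in zip(les.centre_voxel, self.grid_shape)):
                raise ValidationError(f"lesion centre {les.centre_voxel} outside grid")
            if les.structure not in names:
                raise ValidationError(f"lesion targets absent structure {les.structure!r}")

    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_dims)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_primitive(prim: StructurePrimitive, shape) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    c = np.asarray(prim.centre).reshape(3, 1, 1, 1)
    e = np.asarray(prim.extent).reshape(3, 1, 1, 1)
    if prim.kind == "box":
        inside = np.all((idx >= c - e / 2) & (idx < c + e / 2), axis=0)
    else:
        inside = (((idx - c) / (e / 2)) ** 2).sum(axis=0) <= 1.0
    return inside


def make_atlas_phantom(spec: PhantomSpec) -> tuple[dict[str, VolumeGrid], MarsAtlas]:
    """Per-structure probability maps plus the ground-truth label atlas.

    Probability is 100 inside the primitive and falls off linearly over two
    voxels of Euclidean distance outside, so binarising at threshold 50
    recovers the primitive to within a one-voxel shell.
    """
    aff = spec.affine()
    probmaps: dict[str, VolumeGrid] = {}
    pieces: list[tuple[StructureDef, VolumeGrid]] = []
    if not spec.structures:
        empty = VolumeGrid(np.zeros(spec.grid_shape, dtype=np.int32), spec.voxel_dims, aff, "label")
        return probmaps, MarsAtlas(empty, [], "template")
    for code, prim in enumerate(spec.structures, start=1):
        inside = _render_primitive(prim, spec.grid_shape)
        if not inside.any():
            raise ValidationError(f"primitive {prim.name} renders empty on grid {spec.grid_shape}")
        dist = ndimage.distance_transform_edt(~inside)
        prob = np.clip(100.0 * (1.0 - dist / 2.0), 0.0, 100.0).astype(np.float32)
        probmaps[prim.name] = VolumeGrid(prob, spec.voxel_dims, aff, "probability", scale=100.0)
        sd = StructureDef(code, prim.name, STRUCTURE_REGION[prim.name],
                          source="phantom", threshold=50.0, dilate=False)
        pieces.append((sd, VolumeGrid(inside.astype(np.uint8), spec.voxel_dims, aff, "binary")))
    atlas = assemble_atlas(pieces, space_tag="template")
    return probmaps, atlas


def _render_ball_mm(centre_voxel, diameter_mm, shape, voxel_dims) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    dims = np.asarray(voxel_dims).reshape(3, 1, 1, 1)
    c = np.asarray(centre_voxel).reshape(3, 1, 1, 1)
    d2 = (((idx - c) * dims) ** 2).sum(axis=0)
    return d2 <= (diameter_mm / 2.0) ** 2


def make_lesion_mask(spec: PhantomSpec) -> tuple[VolumeGrid, pd.DataFrame]:
    """Digitised-ball lesions and their ground-truth table.

    Each lesion covers the voxels whose centres lie within ``diameter/2`` mm
    of the lesion centre.  Overlapping lesions are rejected.
    """
    mask = np.zeros(spec.grid_shape, dtype=np.uint8)
    rows = []
    for i, les in enumerate(spec.lesions, start=1):
        ball = _render_ball_mm(les.centre_voxel, les.diameter_mm, spec.grid_shape, spec.voxel_dims)
        if not ball.any():
            raise ValidationError(f"lesion {i} ({les.diameter_mm} mm) renders empty")
        if (mask.astype(bool) & ball).any():
            raise ValidationError(f"lesion {i} overlaps an earlier lesion")
        mask[ball] = 1
        rows.append(
            {"lesion_id": i,
             "centre_i": les.centre_voxel[0], "centre_j": les.centre_voxel[1],
             "centre_k": les.centre_voxel[2],
             "diameter_mm": les.diameter_mm, "structure": les.structure,
             "region": STRUCTURE_REGION[les.structure], "n_voxels": int(ball.sum())}
        )
    grid = VolumeGrid(mask, spec.voxel_dims, spec.affine(), "binary")
    return grid, pd.DataFrame(rows)


def make_calibration_lesion(
    axis_voxels: float = 6.0,
    aspect: float = 0.75,
    voxel_dims=(0.9, 0.9, 0.9),
    grid_shape=(32, 32, 32),
    centre=None,
) -> VolumeGrid:
    """A prolate spheroid whose measured moment axis equals its nominal one.

    Small digitised balls carry a quantisation bias in their second-order
    moments (a 6-voxel ball measures ~6.5 voxels); a prolate spheroid of
    nominal major diameter ``axis_voxels`` and minor/major ratio ``aspect``
    has a clear principal direction and its digitisation measures the
    nominal axis to within ~0.5% at the default settings — the worked-size
    calibration shape.
    """
    if centre is None:
        centre = tuple((s - 1) // 2 for s in grid_shape)
    idx = np.indices(grid_shape, dtype=float)
    c = np.asarray(centre, dtype=float).reshape(3, 1, 1, 1)
    semi = np.array([axis_voxels / 2.0, aspect * axis_voxels / 2.0, aspect * axis_voxels / 2.0])
    u = (idx - c) / semi.reshape(3, 1, 1, 1)
    inside = (u**2).sum(axis=0) <= 1.0
    return VolumeGrid(inside.astype(np.uint8), voxel_dims, default_affine(voxel_dims), "binary")


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------

def perturb_mask(
    mask: VolumeGrid,
    perturbation: Perturbation,
    seed: int,
) -> VolumeGrid:
    """Deterministically degrade a lesion mask to emulate segmentation error.

    ``jitter`` shifts each lesion by a Gaussian mm offset (rounded to whole
    voxels); ``drop`` deletes each lesion with probability p (false
    negatives); ``split_merge`` erodes or dilates each selected lesion to
    change its apparent size.  Identical seed -> identical output.
    """
    if perturbation.kind == "none":
        return mask.copy()
    rng = np.random.default_rng(seed)
    comps = label_components(mask, connectivity=26)
    dims = np.asarray(mask.voxel_dims)
    shape = np.asarray(mask.shape)
    out = np.zeros(mask.shape, dtype=np.uint8)
    struct26 = ndimage.generate_binary_structure(3, 3)
    for c in comps:
        vox = c.voxels
        if perturbation.kind == "drop":
            if rng.random() < perturbation.p:
                continue
        elif perturbation.kind == "jitter":
            offset_mm = rng.normal(0.0, perturbation.sigma_mm, size=3)
            shift = np.round(offset_mm / dims).astype(int)
            vox = vox + shift
            keep = np.all((vox >= 0) & (vox < shape), axis=1)
            vox = vox[keep]
        elif perturbation.kind == "split_merge":
            if rng.random() < perturbation.p:
                sub = np.zeros(mask.shape, dtype=bool)
                sub[tuple(c.voxels.T)] = True
                if rng.random() < 0.5:
                    eroded = ndimage.binary_erosion(sub, structure=struct26)
                    if not eroded.any():  # keep at least the centroid voxel
                        eroded = np.zeros_like(sub)
                        ci = tuple(int(round(x)) for x in c.centroid_voxel)
                        eroded[ci] = True
                    vox = np.argwhere(eroded)
                else:
                    vox = np.argwhere(ndimage.binary_dilation(sub, structure=struct26))
        if len(vox):
            out[tuple(vox.T)] = 1
    return grid_like(mask, out, "binary")
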