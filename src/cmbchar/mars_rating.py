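"""Assign lesions to MARS structures and aggregate counts.

Each lesion is assigned to exactly one atlas structure by looking up the
label at its (rounded) centroid voxel; structure counts are aggregated into
the three MARS region counts.  Lesions whose centroid falls on background
(label 0) or outside the grid are reported as *unclassified* rather than
silently dropped or reassigned.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .image_io import VolumeGrid, grid_like
from .lesion_features import LesionComponent, label_components
from .mars_atlas import REGIONS, STRUCTURE_REGION, MarsAtlas

UNCLASSIFIED = "unclassified"


@dataclass
class LesionAssignment:
    component_id: int
    structure: str  # structure name or "unclassified"
    region: str  # region name or "unclassified"
    diameter_mm: float
    centroid_mm: tuple[float, float, float]


@dataclass
class MarsRating:
    """Machine twin of a filled MARS form for one subject."""

    subject_id: str
    structure_counts: dict[str, int]
    region_counts: dict[str, int]
    unclassified_count: int
    total: int
    per_lesion: list[LesionAssignment] = field(default_factory=list)

    def validate(self) -> None:
        for region in REGIONS:
            members = [s for s, r in STRUCTURE_REGION.items() if r == region]
            expect = sum(self.structure_counts.get(s, 0) for s in members)
            if self.region_counts.get(region, 0) != expect:
                raise ValidationError(
                    f"region count for {region} ({self.region_counts.get(region)}) "
                    f"!= sum of member structures ({expect})"
                )
        if self.total != sum(self.region_counts.values()) + self.unclassified_count:
            raise ValidationError("total != sum(region counts) + unclassified")
        if len(self.per_lesion) != self.total:
            raise ValidationError("per-lesion table length != total lesion count")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "structure_counts": dict(self.structure_counts),
            "region_counts": dict(self.region_counts),
            "unclassified_count": self.unclassified_count,
            "total": self.total,
            "per_lesion": [
                {
                    "component_id": a.component_id,
                    "structure": a.structure,
                    "region": a.region,
                    "diameter_mm": round(a.diameter_mm, 1),
                    "centroid_x_mm": a.centroid_mm[0],
                    "centroid_y_mm": a.centroid_mm[1],
                    "centroid_z_mm": a.centroid_mm[2],
                }
                for a in self.per_lesion
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def form_rows(self) -> pd.DataFrame:
        """MARS-form style table: one row per structure plus region totals."""
        rows = [
            {"region": STRUCTURE_REGION[s], "structure": s, "count": self.structure_counts.get(s, 0)}
            for s in STRUCTURE_REGION
        ]
        for region in REGIONS:
            rows.append({"region": region, "structure": "(region total)",
                         "count": self.region_counts.get(region, 0)})
        rows.append({"region": UNCLASSIFIED, "structure": UNCLASSIFIED,
                     "count": self.unclassified_count})
        return pd.DataFrame(rows)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def assign_structure(centroid_voxel, atlas: MarsAtlas) -> str:
    """Structure name at the lesion centroid, or ``unclassified``.

    The centroid is rounded half-away-from-zero to the nearest voxel index;
    indices outside the grid and label 0 both map to ``unclassified``.
    """
    idx = _round_half_away(np.asarray(centroid_voxel, dtype=float))
    shape = atlas.labels.shape
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        return UNCLASSIFIED
    code = int(atlas.labels.data[tuple(idx)])
    if code == 0:
        return UNCLASSIFIED
    return atlas.structure_of(code).name


def _assign_majority(component: LesionComponent, atlas: MarsAtlas) -> str:
    """Majority vote over the lesion's voxels (ties: smaller code, then
    unclassified last); alternative for boundary-straddling lesions."""
    labels = atlas.labels.data[tuple(component.voxels.T)]
    counts = Counter(int(v) for v in labels)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0] == 0, kv[0]))
    code = ranked[0][0]
    return UNCLASSIFIED if code == 0 else atlas.structure_of(code).name


def rate_subject(
    mask: VolumeGrid,
    atlas: MarsAtlas,
    subject_id: str = "subject",
    connectivity: int = 26,
    method: str = "centroid",
) -> MarsRating:
    """Full rating of one subject's binary CMB mask.

    Extracts connected lesions, sizes each one, assigns each to a MARS
    structure (``method``: ``centroid`` lookup, or ``majority`` vote over
    lesion voxels), and aggregates structure- and region-wise counts.
    """
    if not mask.same_geometry(atlas.labels):
        raise ValidationError("lesion mask and atlas do not share grid geometry")
    if method not in ("centroid", "majority"):
        raise ValidationError(f"unknown assignment method {method!r}")
    components = label_components(mask, connectivity=connectivity)
    per_lesion: list[LesionAssignment] = []
    structure_counts: Counter[str] = Counter()
    unclassified = 0
    for c in components:
        if method == "centroid":
            structure = assign_structure(c.centroid_voxel, atlas)
        else:
            structure = _assign_majority(c, atlas)
        region = STRUCTURE_REGION.get(structure, UNCLASSIFIED)
        if structure == UNCLASSIFIED:
            unclassified += 1
        else:
            structure_counts[structure] += 1
        per_lesion.append(
            LesionAssignment(c.component_id, structure, region, c.diameter_mm, c.centroid_mm)
        )
    region_counts = {r: 0 for r in REGIONS}
    for s, n in structure_counts.items():
        region_counts[STRUCTURE_REGION[s]] += n
    rating = MarsRating(
        subject_id=subject_id,
        structure_counts={s: structure_counts.get(s, 0) for s in STRUCTURE_REGION},
        region_counts=region_counts,
        unclassified_count=unclassified,
        total=len(components),
        per_lesion=per_lesion,
    )
    rating.validate()
    return rating


def cohort_table(ratings: list[MarsRating]) -> pd.DataFrame:
    """Long-format multi-subject table (subject, structure, region, count)."""
    rows = []
    for r in ratings:
        for s in STRUCTURE_REGION:
            rows.append({"subject_id": r.subject_id, "structure": s,
                         "region": STRUCTURE_REGION[s], "count": r.structure_counts.get(s, 0)})
        rows.append({"subject_id": r.subject_id, "structure": UNCLASSIFIED,
                     "region": UNCLASSIFIED, "count": r.unclassified_count})
    return pd.DataFrame(rows)


def prevalence_map(masks: list[VolumeGrid]) -> VolumeGrid:
    """Voxelwise count, across subjects, of subjects with a lesion there."""
    if not masks:
        raise ValidationError("prevalence_map needs at least one mask")
    ref = masks[0]
    for m in masks[1:]:
        if not m.same_geometry(ref):
            raise ValidationError("prevalence_map: masks do not share grid geometry")
    for m in masks:
        if m.dtype_tag != "binary":
            raise ValidationError("prevalence_map expects binary masks")
    counts = np.zeros(ref.shape, dtype=np.int32)
    for m in masks:
        counts += m.data.astype(np.int32)
    return grid_like(ref, counts, "label")
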