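"""Lesion-level comparison of automated against manual CMB characterisation.

Predicted and reference lesions are paired one-to-one by voxel overlap
(greedy, largest overlap first).  From the matching we derive:

* size agreement — per-lesion absolute diameter error and its mean (MAE);
* region metrics — per-region sensitivity, precision and F1 of the MARS
  region assignment, plus overall accuracy over matched lesions;
* confusion matrices over structures and over regions (matched lesions);
* a false-negative histogram per manual structure.

A matched lesion counts for region R as a true positive if both ratings
place it in R, as a false negative of R if only the manual rating does, and
as a false positive of R if only the automated rating does.  Unmatched
reference lesions are false negatives of their manual region; unmatched
predictions enter precision through their automated region only (they have
no manual rating).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .lesion_features import LesionComponent
from .mars_atlas import REGIONS, STRUCTURES
from .mars_rating import UNCLASSIFIED

_VALID_REGION_LABELS = set(REGIONS) | {UNCLASSIFIED}


@dataclass(frozen=True)
class LesionMatch:
    pred_id: int | None
    ref_id: int | None
    overlap_voxels: int
    status: str  # true_positive | false_positive | false_negative


@dataclass
class RegionEvaluation:
    per_region: dict[str, dict[str, float]]
    overall_accuracy: float | None
    size_abs_errors: list[float]
    size_mae: float | None
    confusion_structure: pd.DataFrame
    confusion_region: pd.DataFrame
    fn_by_structure: dict[str, int]
    matches: list[LesionMatch] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_region": {
                r: {k: round(v, 2) for k, v in m.items()} for r, m in self.per_region.items()
            },
            "overall_accuracy": None if self.overall_accuracy is None else round(self.overall_accuracy, 2),
            "size_mae_mm": None if self.size_mae is None else round(self.size_mae, 1),
            "size_error_summary": error_summary(self.size_abs_errors),
            "confusion_region": self.confusion_region.to_dict(),
            "confusion_structure": self.confusion_structure.to_dict(),
            "fn_by_structure": dict(self.fn_by_structure),
            "n_true_positive": sum(m.status == "true_positive" for m in self.matches),
            "n_false_positive": sum(m.status == "false_positive" for m in self.matches),
            "n_false_negative": sum(m.status == "false_negative" for m in self.matches),
        }


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _centroid_dist(a: LesionComponent, b: LesionComponent) -> float:
    return float(np.linalg.norm(np.asarray(a.centroid_mm) - np.asarray(b.centroid_mm)))


def match_lesions(
    pred: list[LesionComponent],
    ref: list[LesionComponent],
    criterion: str = "overlap",
    max_centroid_mm: float = 5.0,
) -> list[LesionMatch]:
    """One-to-one pairing of predicted and reference lesions.

    Default criterion: at least one voxel of overlap, paired greedily by
    descending overlap; ties broken by smaller centroid distance, then lower
    ids.  ``criterion="centroid"`` instead pairs by centroid distance
    <= ``max_centroid_mm`` (ascending distance), for masks that abut without
    overlapping.  Unmatched predictions become false positives, unmatched
    references false negatives.
    """
    if criterion not in ("overlap", "centroid"):
        raise ValidationError(f"unknown matching criterion {criterion!r}")
    candidates = []
    if criterion == "overlap":
        ref_sets = {r.component_id: r.voxel_set() for r in ref}
        for p in pred:
            pset = p.voxel_set()
            for r in ref:
                ov = len(pset & ref_sets[r.component_id])
                if ov >= 1:
                    candidates.append((-ov, _centroid_dist(p, r), p.component_id, r.component_id, ov))
    else:
        for p in pred:
            for r in ref:
                d = _centroid_dist(p, r)
                if d <= max_centroid_mm:
                    candidates.append((d, 0.0, p.component_id, r.component_id,
                                       len(p.voxel_set() & r.voxel_set())))
    candidates.sort()
    used_p: set[int] = set()
    used_r: set[int] = set()
    matches: list[LesionMatch] = []
    for _key, _d, pid, rid, ov in candidates:
        if pid in used_p or rid in used_r:
            continue
        used_p.add(pid)
        used_r.add(rid)
        matches.append(LesionMatch(pid, rid, ov, "true_positive"))
    for p in pred:
        if p.component_id not in used_p:
            matches.append(LesionMatch(p.component_id, None, 0, "false_positive"))
    for r in ref:
        if r.component_id not in used_r:
            matches.append(LesionMatch(None, r.component_id, 0, "false_negative"))
    return matches


# ---------------------------------------------------------------------------
# Size error
# ---------------------------------------------------------------------------

def size_error(
    matches: list[LesionMatch],
    pred_sizes: dict[int, float],
    ref_sizes: dict[int, float],
) -> tuple[list[float], float | None]:
    """Per-true-positive |predicted - manual| diameter (mm) and its mean."""
    errors = []
    for m in matches:
        if m.status != "true_positive":
            continue
        if m.pred_id not in pred_sizes or m.ref_id not in ref_sizes:
            raise ValidationError(f"missing size for matched pair ({m.pred_id}, {m.ref_id})")
        errors.append(abs(pred_sizes[m.pred_id] - ref_sizes[m.ref_id]))
    mae = float(np.mean(errors)) if errors else None
    return errors, mae


def error_summary(abs_errors: list[float], small_mm: float = 1.0, large_mm: float = 6.0) -> dict:
    """Report-style summary of size errors.

    Percentages are rounded to the nearest whole percent, matching how such
    results are conventionally quoted (e.g. 11 of 185 lesions -> 6%).
    """
    n = len(abs_errors)
    if n == 0:
        return {"n": 0, "mae_mm": None, "pct_below_small": None, "pct_above_large": None,
                "small_mm": small_mm, "large_mm": large_mm}
    arr = np.asarray(abs_errors, dtype=float)
    return {
        "n": n,
        "mae_mm": round(float(arr.mean()), 1),
        "pct_below_small": int(round(100.0 * float((arr < small_mm).sum()) / n)),
        "pct_above_large": int(round(100.0 * float((arr > large_mm).sum()) / n)),
        "small_mm": small_mm,
        "large_mm": large_mm,
    }


# ---------------------------------------------------------------------------
# Region metrics
# ---------------------------------------------------------------------------

def f1_score(sensitivity: float, precision: float) -> float:
    """Harmonic mean; 0 when both are 0."""
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def region_metrics(
    pairs: list[tuple[str | None, str | None]],
) -> tuple[dict[str, dict[str, float]], float | None]:
    """Per-region sensitivity/precision/F1 and overall accuracy.

    ``pairs`` holds one (automated region, manual region) entry per lesion;
    ``None`` on one side marks an unmatched lesion (false positive when the
    manual side is None, false negative when the automated side is None).
    Overall accuracy is the fraction of matched lesions whose two region
    labels agree.
    """
    for p, r in pairs:
        for lab in (p, r):
            if lab is not None and lab not in _VALID_REGION_LABELS:
                raise ValidationError(f"invalid region label {lab!r}")
    per_region: dict[str, dict[str, float]] = {}
    for region in REGIONS:
        tp = sum(1 for p, r in pairs if p == region and r == region)
        fn = sum(1 for p, r in pairs if r == region and p != region)
        fp = sum(1 for p, r in pairs if p == region and r != region)
        sens = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        per_region[region] = {"sensitivity": sens, "precision": prec, "f1": f1_score(sens, prec)}
    matched = [(p, r) for p, r in pairs if p is not None and r is not None]
    accuracy = (sum(1 for p, r in matched if p == r) / len(matched)) if matched else None
    return per_region, accuracy


def count_level_region_metrics(
    pred_counts: dict[str, int], ref_counts: dict[str, int]
) -> dict[str, dict[str, float]]:
    """Count-level alternative for subscore-only references (no manual masks):
    per region, TP = min(predicted count, manual count)."""
    out = {}
    for region in REGIONS:
        p, r = pred_counts.get(region, 0), ref_counts.get(region, 0)
        tp = min(p, r)
        sens = tp / r if r else 0.0
        prec = tp / p if p else 0.0
        out[region] = {"sensitivity": sens, "precision": prec, "f1": f1_score(sens, prec)}
    return out


def confusion_matrices(
    pred_assign: dict[int, tuple[str, str]],
    ref_assign: dict[int, tuple[str, str]],
    matches: list[LesionMatch],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Structure- and region-wise confusion over matched lesions.

    ``pred_assign``/``ref_assign`` map component id -> (structure, region).
    Cell (i, j) counts matched lesions rated manually as i and automatically
    as j; rows are manual labels, columns automated.
    """
    s_labels = list(STRUCTURES) + [UNCLASSIFIED]
    r_labels = list(REGIONS) + [UNCLASSIFIED]
    cs = pd.DataFrame(0, index=s_labels, columns=s_labels, dtype=int)
    cr = pd.DataFrame(0, index=r_labels, columns=r_labels, dtype=int)
    for m in matches:
        if m.status != "true_positive":
            continue
        ps, pr = pred_assign[m.pred_id]
        rs, rr = ref_assign[m.ref_id]
        cs.loc[rs, ps] += 1
        cr.loc[rr, pr] += 1
    return cs, cr


def metrics_from_region_confusion(confusion_region: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Recompute sensitivity/precision/F1 from a region confusion matrix
    alone (internal-consistency oracle for matched lesions)."""
    out = {}
    for region in REGIONS:
        tp = int(confusion_region.loc[region, region])
        fn = int(confusion_region.loc[region].sum()) - tp
        fp = int(confusion_region[region].sum()) - tp
        sens = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        out[region] = {"sensitivity": sens, "precision": prec, "f1": f1_score(sens, prec)}
    return out


def fn_histogram(matches: list[LesionMatch], ref_structures: dict[int, str]) -> dict[str, int]:
    """False negatives per manual structure."""
    counts: Counter[str] = Counter()
    for m in matches:
        if m.status == "false_negative":
            counts[ref_structures[m.ref_id]] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# Whole-subject convenience
# ---------------------------------------------------------------------------

def evaluate_subject(
    pred_components: list[LesionComponent],
    ref_components: list[LesionComponent],
    pred_assign: dict[int, tuple[str, str]],
    ref_assign: dict[int, tuple[str, str]],
    criterion: str = "overlap",
) -> RegionEvaluation:
    """Match, size-compare and region-compare one subject's lesion sets.

    Assignment maps give (structure, region) per component id, as produced
    by :func:`cmbchar.mars_rating.rate_subject`.
    """
    matches = match_lesions(pred_components, ref_components, criterion=criterion)
    pred_sizes = {c.component_id: c.diameter_mm for c in pred_components}
    ref_sizes = {c.component_id: c.diameter_mm for c in ref_components}
    errors, mae = size_error(matches, pred_sizes, ref_sizes)

    pairs: list[tuple[str | None, str | None]] = []
    for m in matches:
        if m.status == "true_positive":
            pairs.append((pred_assign[m.pred_id][1], ref_assign[m.ref_id][1]))
        elif m.status == "false_positive":
            pairs.append((pred_assign[m.pred_id][1], None))
        else:
            pairs.append((None, ref_assign[m.ref_id][1]))
    per_region, accuracy = region_metrics(pairs)
    cs, cr = confusion_matrices(pred_assign, ref_assign, matches)
    fn = fn_histogram(matches, {cid: s for cid, (s, _r) in ref_assign.items()})
    return RegionEvaluation(
        per_region=per_region,
        overall_accuracy=accuracy,
        size_abs_errors=errors,
        size_mae=mae,
        confusion_structure=cs,
        confusion_region=cr,
        fn_by_structure=fn,
        matches=matches,
    )
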