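"""Metrics and evaluation harnesses.

IoU and the COCO-style AP family (AP averaged over IoU 0.50:0.05:0.95, plus
AP50 and AP75 at fixed thresholds), a stratified ten-fold cross-validation
driver, and the four-variant end-to-end ablation grid (direct sampling vs
patch filtering, with and without the coarse localization stage).

End-to-end identification accuracy is grain-level:

    accuracy = correctly labeled grains / (ground-truth grains + false positives)

where a grain counts as correct when some forwarded identification matches
it (IoU >= 0.5 for box-level outputs, containment for patch-level outputs)
and carries its true taxon, and a false positive is an identification that
matches no ground-truth grain. The denominator includes false positives so
that misidentifying impurities or blank tiles as pollen costs accuracy —
the failure mode the filtering and localization stages exist to remove.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

IOU_GRID = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x0, y0, x1, y1) boxes in [0, 1].

    Symmetric; 0 for disjoint boxes; degenerate (zero-area) boxes give 0
    with a warning.
    """
    a = np.asarray(box_a, float)
    b = np.asarray(box_b, float)
    area_a = max(a[2] - a[0], 0) * max(a[3] - a[1], 0)
    area_b = max(b[2] - b[0], 0) * max(b[3] - b[1], 0)
    if area_a == 0 or area_b == 0:
        warnings.warn("degenerate box in IoU; returning 0")
        return 0.0
    ix = min(a[2], b[2]) - max(a[0], b[0])
    iy = min(a[3], b[3]) - max(a[1], b[1])
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return float(inter / (area_a + area_b - inter))


def _match_greedy(
    detections: list[tuple[int, tuple, float]],
    ground_truths: dict[int, list[tuple]],
    iou_thr: float,
) -> np.ndarray:
    """True/false-positive flags for score-ranked detections.

    Greedy protocol: walk detections by descending score; each claims the
    highest-IoU unmatched ground truth of its image at IoU >= threshold.
    """
    order = sorted(range(len(detections)), key=lambda i: -detections[i][2])
    used: dict[int, set[int]] = {k: set() for k in ground_truths}
    tp = np.zeros(len(detections), bool)
    for rank, i in enumerate(order):
        img, box, _ = detections[i]
        gts = ground_truths.get(img, [])
        best_j, best_iou = -1, iou_thr
        for j, g in enumerate(gts):
            if j in used.setdefault(img, set()):
                continue
            v = iou(box, g)
            if v >= best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            used[img].add(best_j)
            tp[rank] = True
    return tp


def average_precision(
    detections: list[tuple[int, tuple, float]],
    ground_truths: dict[int, list[tuple]],
    iou_thr: float = 0.5,
    n_points: int = 101,
) -> float:
    """Interpolated average precision at one IoU threshold.

    ``detections`` are (image_id, box, score); ``ground_truths`` maps
    image_id -> boxes. Precision is interpolated to its running maximum and
    sampled on a uniform recall grid (101-point, COCO-style); ``n_points=11``
    gives the classical 11-point variant. Zero ground truths -> NaN with a
    warning; zero detections -> 0.
    """
    n_gt = sum(len(v) for v in ground_truths.values())
    if n_gt == 0:
        warnings.warn("average precision undefined without ground truths")
        return float("nan")
    if not detections:
        return 0.0
    tp = _match_greedy(detections, ground_truths, iou_thr)
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(~tp)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope (running max from the right)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    grid = np.linspace(0, 1, n_points)
    idx = np.searchsorted(recall, grid, side="left")
    sampled = np.where(idx < len(env), env[np.clip(idx, 0, len(env) - 1)], 0.0)
    return float(sampled.mean())


@dataclass
class ApReport:
    """AP averaged over the 0.50:0.05:0.95 IoU grid, with AP50/AP75."""

    ap: float
    ap50: float
    ap75: float
    by_threshold: dict[float, float] = field(default_factory=dict)
    per_class: dict[str, "ApReport"] = field(default_factory=dict)


def ap_report(
    detections: list[tuple[int, tuple, float]],
    ground_truths: dict[int, list[tuple]],
    n_points: int = 101,
) -> ApReport:
    """Evaluate AP on the standard IoU grid for one category."""
    by_thr = {
        float(t): average_precision(detections, ground_truths, t, n_points)
        for t in IOU_GRID
    }
    vals = np.asarray(list(by_thr.values()))
    return ApReport(float(np.mean(vals)), by_thr[0.5], by_thr[0.75], by_thr)


def ap_report_by_class(
    detections_by_class: dict[str, list[tuple[int, tuple, float]]],
    ground_truths_by_class: dict[str, dict[int, list[tuple]]],
    n_points: int = 101,
) -> ApReport:
    """Per-class AP reports plus their unweighted mean."""
    per = {
        name: ap_report(detections_by_class.get(name, []), gts, n_points)
        for name, gts in ground_truths_by_class.items()
    }
    aps = [r.ap for r in per.values()]
    ap50 = [r.ap50 for r in per.values()]
    ap75 = [r.ap75 for r in per.values()]
    out = ApReport(float(np.nanmean(aps)), float(np.nanmean(ap50)), float(np.nanmean(ap75)))
    out.per_class = per
    return out


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    fold_metrics: list[float]
    fold_assignments: list[np.ndarray]  # test indices per fold

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_metrics))

    @property
    def quartiles(self) -> tuple[float, float, float]:
        q = np.percentile(self.fold_metrics, [25, 50, 75])
        return tuple(float(v) for v in q)


def ten_fold_cv(labels, trainer, seed: int = 0, n_folds: int = 10) -> CvResult:
    """Stratified k-fold driver.

    ``trainer(train_idx, test_idx) -> metric`` is called once per fold; the
    folds are a disjoint stratified partition of the index range. Classes
    with fewer than ``n_folds`` members are rejected (augment the data
    instead of silently merging folds).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < n_folds]
    if len(small):
        raise ValueError(
            f"classes {small.tolist()} have fewer than {n_folds} instances; "
            "augment the dataset before cross-validating"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    metrics, assignments = [], []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        metrics.append(float(trainer(train_idx, test_idx)))
        assignments.append(test_idx)
    return CvResult(metrics, assignments)


# ---------------------------------------------------------------------------
# End-to-end identification accuracy and the ablation grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AblationVariant:
    """One row of the ablation grid: sampling strategy x localization.

    ``direct_sampling`` forwards every tile (no patch filter);
    ``coarse_localization`` toggles the detection stage. Fine-grained
    classification is always on.
    """

    direct_sampling: bool
    coarse_localization: bool

    @property
    def name(self) -> str:
        parts = ["DS" if self.direct_sampling else "DP"]
        if self.coarse_localization:
            parts.append("CL")
        parts.append("FC")
        return "+".join(parts)


ABLATION_VARIANTS = {
    "ds-cl-fc": AblationVariant(True, True),
    "ds-fc": AblationVariant(True, False),
    "dp-fc": AblationVariant(False, False),
    "dp-cl-fc": AblationVariant(False, True),
}


def identification_accuracy(n_correct: int, n_gt: int, n_false_pos: int) -> float:
    """Grain-level accuracy with false positives in the denominator."""
    denom = n_gt + n_false_pos
    return float(n_correct) / denom if denom else float("nan")


def score_grain_identifications(
    gt_boxes: list[tuple], gt_labels: list[int],
    pred_boxes: list[tuple], pred_labels: list[int],
    iou_thr: float = 0.5,
) -> tuple[int, int]:
    """(n_correct, n_false_pos) for box-level identifications on one image.

    Predictions are matched greedily (each ground truth claimed once at
    IoU >= threshold); a matched grain is correct iff the labels agree; an
    unmatched prediction is a false positive.
    """
    matched = [False] * len(gt_boxes)
    n_correct = n_fp = 0
    for pb, pl in zip(pred_boxes, pred_labels):
        best_j, best_v = -1, iou_thr
        for j, gb in enumerate(gt_boxes):
            if matched[j]:
                continue
            v = iou(pb, gb)
            if v >= best_v:
                best_j, best_v = j, v
        if best_j < 0:
            n_fp += 1
        else:
            matched[best_j] = True
            if pred_labels is not None and gt_labels[best_j] == pl:
                n_correct += 1
    return n_correct, n_fp


def run_ablation(variant: AblationVariant | str, corpus, seed: int = 0, **kwargs) -> float:
    """End-to-end identification accuracy of one ablation variant on a
    synthetic corpus (delegates to the pipeline driver)."""
    from .pipeline import run_variant  # local import: pipeline builds on this module

    if isinstance(variant, str):
        variant = ABLATION_VARIANTS[variant]
    return run_variant(variant, corpus, seed=seed, **kwargs)
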