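"""Per-bounding-box metrics: precision/recall, PR curves, average precision.

AP uses all-point interpolation over consecutive recall levels,
AP = sum_n (R_n - R_{n-1}) * P_interp(R_n) with P_interp(R) the maximum
precision attained at recall >= R and R_0 = 0.  This follows the
summation form of the definition exactly rather than the 101-point
recall sampling used by pycocotools; the two typically agree to ~0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .matching import box_size_class, iou
from .model import DEFAULT_IOU_GRID, VideoRecord

__all__ = [
    "PRPoint",
    "APReport",
    "precision_recall",
    "pr_curve",
    "average_precision",
    "ap_report",
]


@dataclass(frozen=True)
class PRPoint:
    recall: float
    precision: float
    score: float  # threshold at which this operating point is attained


@dataclass
class APReport:
    ap_per_iou: dict[float, float]
    ap_50_95: float
    ap_by_size: dict[str, float]
    n_gt: int
    n_det: int

    def to_dict(self) -> dict:
        return {
            "ap_per_iou": {f"{k:.2f}": v for k, v in self.ap_per_iou.items()},
            "ap_50_95": self.ap_50_95,
            "ap_by_size": dict(self.ap_by_size),
            "n_gt": self.n_gt,
            "n_det": self.n_det,
        }


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN).

    With no predictions at all, precision is defined as 1.0 (nothing
    claimed, nothing wrong) so PR curves start at the top-left; recall
    with no ground truth positives is defined as 0.0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    r = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return p, r


def _ranked_matches(
    videos: Sequence[VideoRecord],
    iou_thr: float,
    delta: float = 0.0,
) -> tuple[list[tuple[float, object, object]], int]:
    """Globally rank detections by score and greedily match per frame.

    Returns (ranked list of (score, matched GT or None, det box), total
    GT count).  A lower-ranked detection can only claim GT boxes left
    unmatched by higher-ranked ones in the same frame.
    """
    entries = []  # (score, entry ordinal, frame key, det, gts)
    frame_gts: dict[tuple[str, int], list] = {}
    n_gt = 0
    ordinal = 0
    for video in videos:
        for fr in video.frames:
            key = (video.video_id, fr.frame_idx)
            frame_gts[key] = list(fr.gt)
            n_gt += len(fr.gt)
            for det in fr.dets:
                if det.score >= delta:
                    entries.append((det.score, ordinal, key, det))
                    ordinal += 1
    entries.sort(key=lambda e: (-e[0], e[1]))
    matched: dict[tuple[str, int], set[int]] = {k: set() for k in frame_gts}
    ranked: list[tuple[float, object, object]] = []
    for score, _, key, det in entries:
        gts = frame_gts[key]
        taken = matched[key]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if j in taken:
                continue
            v = iou(det, g)
            if v >= iou_thr and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken.add(best_j)
            ranked.append((score, gts[best_j], det))
        else:
            ranked.append((score, None, det))
    return ranked, n_gt


def pr_curve(
    videos: Sequence[VideoRecord],
    iou_thr: float,
    delta: float = 0.0,
    size_class: str | None = None,
    size_mode: str = "max_side",
) -> list[PRPoint]:
    """Precision-recall curve over a dataset at one IoU threshold.

    One point per detection rank, with cumulative TP/FP counts from
    score-ordered greedy matching.  With ``size_class`` given, the
    curve is restricted to GT boxes of that size class: a detection
    matched to a GT of another class is excluded, and an unmatched
    detection counts as FP only if its own size falls in the class.
    """
    ranked, n_gt = _ranked_matches(videos, iou_thr, delta)
    if size_class is not None:
        n_gt = sum(
            1
            for video in videos
            for fr in video.frames
            for g in fr.gt
            if box_size_class(g, size_mode) == size_class
        )
    points: list[PRPoint] = []
    tp = fp = 0
    for score, gt, det in ranked:
        if gt is not None:
            if size_class is not None and box_size_class(gt, size_mode) != size_class:
                continue
            tp += 1
        else:
            if size_class is not None and box_size_class(det, size_mode) != size_class:
                continue
            fp += 1
        p, r = precision_recall(tp, fp, n_gt - tp)
        points.append(PRPoint(recall=r, precision=p, score=score))
    return points


def average_precision(curve: Sequence[PRPoint]) -> float:
    """Area under the PR curve by all-point interpolation."""
    if not curve:
        return 0.0
    n = len(curve)
    p_env = [0.0] * n
    running = 0.0
    for i in range(n - 1, -1, -1):
        running = max(running, curve[i].precision)
        p_env[i] = running
    ap = 0.0
    prev_r = 0.0
    for i in range(n):
        ap += (curve[i].recall - prev_r) * p_env[i]
        prev_r = curve[i].recall
    return ap


def ap_report(
    videos: Sequence[VideoRecord],
    iou_grid: Iterable[float] = DEFAULT_IOU_GRID,
    size_mode: str = "max_side",
    delta: float = 0.0,
) -> APReport:
    """AP per IoU threshold, their mean (AP_0.5:0.95), and per-size AP."""
    grid = list(iou_grid)
    if not grid:
        raise ValueError("iou_grid must be non-empty")
    n_gt = sum(len(fr.gt) for v in videos for fr in v.frames)
    n_det = sum(len(fr.dets) for v in videos for fr in v.frames)
    if n_gt == 0:
        raise ValueError("AP is undefined on a split with no ground-truth boxes")
    ap_per_iou = {
        thr: average_precision(pr_curve(videos, thr, delta=delta)) for thr in grid
    }
    ap_50_95 = sum(ap_per_iou.values()) / len(ap_per_iou)
    sizes_present = {
        box_size_class(g, size_mode) for v in videos for fr in v.frames for g in fr.gt
    }
    ap_by_size: dict[str, float] = {}
    for cls in ("small", "medium", "large"):
        if cls not in sizes_present:
            continue
        vals = [
            average_precision(
                pr_curve(videos, thr, delta=delta, size_class=cls, size_mode=size_mode)
            )
            for thr in grid
        ]
        ap_by_size[cls] = sum(vals) / len(vals)
    return APReport(ap_per_iou, ap_50_95, ap_by_size, n_gt, n_det)
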