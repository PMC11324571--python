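"""Frame-level classification, TPR/FPR and ROC analysis.

A frame with ground truth is a TP only when *every* polyp in it is
matched by a detection at the working IoU threshold (typically 0.2);
otherwise it is a FN.  A frame without ground truth is a FP when any
detection above threshold fires, else a TN.  Positive frames with
extra spurious boxes therefore remain TP/FN — the four classes
partition frames by GT presence first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matching import match_frame
from .model import FrameRecord, VideoRecord

__all__ = ["FrameConfusion", "ROCCurve", "classify_frame", "confusion", "roc_curve"]

MAX_DEFAULT_GRID = 256


@dataclass
class FrameConfusion:
    tp: int
    fp: int
    fn: int
    tn: int
    delta_used: float
    iou_used: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def tpr(self) -> float:
        if self.tp + self.fn == 0:
            raise ValueError(
                "TPR undefined: the evaluated split contains no positive frames"
            )
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        if self.fp + self.tn == 0:
            raise ValueError(
                "FPR undefined: the evaluated split contains no negative frames"
            )
        return self.fp / (self.fp + self.tn)


@dataclass
class ROCCurve:
    points: list[tuple[float, float, float]]  # (fpr, tpr, delta), sorted by fpr
    auc: float


def classify_frame(frame: FrameRecord, delta: float, iou_thr: float) -> str:
    """Classify one frame as 'TP', 'FP', 'FN' or 'TN'."""
    if frame.gt:
        m = match_frame(frame.dets, frame.gt, delta, iou_thr)
        return "TP" if m.fn == 0 else "FN"
    if any(d.score >= delta for d in frame.dets):
        return "FP"
    return "TN"


def confusion(
    videos: Sequence[VideoRecord], delta: float, iou_thr: float = 0.2
) -> FrameConfusion:
    """Frame confusion counts summed over all videos."""
    counts = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for video in videos:
        for fr in video.frames:
            counts[classify_frame(fr, delta, iou_thr)] += 1
    return FrameConfusion(
        counts["TP"], counts["FP"], counts["FN"], counts["TN"], delta, iou_thr
    )


def default_delta_grid(videos: Sequence[VideoRecord]) -> list[float]:
    """Distinct detection scores, subsampled to <=256 values, plus {0, 1}."""
    scores = sorted({d.score for v in videos for fr in v.frames for d in fr.dets})
    if len(scores) > MAX_DEFAULT_GRID:
        idx = np.linspace(0, len(scores) - 1, MAX_DEFAULT_GRID).round().astype(int)
        scores = [scores[i] for i in idx]
    return sorted(set(scores) | {0.0, 1.0})


def roc_curve(
    videos: Sequence[VideoRecord],
    delta_grid: Sequence[float] | None = None,
    iou_thr: float = 0.2,
) -> ROCCurve:
    """ROC over a threshold sweep, with AUC by the trapezoidal rule.

    One (FPR, TPR) point per delta in the grid; the anchors (0,0) and
    (1,1) are appended so the area is taken over the full FPR range.
    """
    if delta_grid is None:
        delta_grid = default_delta_grid(videos)
    delta_grid = list(delta_grid)
    if not delta_grid:
        raise ValueError("delta_grid must be non-empty")
    if any(d < 0 or d > 1 for d in delta_grid):
        raise ValueError("delta values must lie in [0, 1]")
    points = []
    for delta in delta_grid:
        c = confusion(videos, delta, iou_thr)
        points.append((c.fpr, c.tpr, delta))
    points.sort(key=lambda p: (p[0], p[1]))
    anchored = [(0.0, 0.0, float("nan"))] + points + [(1.0, 1.0, float("nan"))]
    fprs = np.array([p[0] for p in anchored])
    tprs = np.array([p[1] for p in anchored])
    auc = float(np.trapezoid(tprs, fprs))
    return ROCCurve(points=anchored, auc=auc)
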