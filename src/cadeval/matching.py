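"""IoU and per-frame assignment of predicted boxes to ground truth.

Matching is greedy and one-to-one in the COCO style: predictions are
visited in descending score order and each claims the still-unmatched
GT box of highest IoU, provided that IoU reaches the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .model import GTBox, ScoredBox

__all__ = ["iou", "match_frame", "box_size_class", "FrameMatching"]

SIZE_SMALL_PX = 100.0
SIZE_MEDIUM_PX = 200.0


def iou(a, b) -> float:
    """Intersection-over-union of two boxes with x1/y1/x2/y2 attributes.

    Returns 0.0 for disjoint boxes; raises on degenerate (zero-area)
    input since IoU is then undefined.
    """
    area_a = (a.x2 - a.x1) * (a.y2 - a.y1)
    area_b = (b.x2 - b.x1) * (b.y2 - b.y1)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("iou of a degenerate (zero-area) box is undefined")
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (area_a + area_b - inter)


@dataclass
class FrameMatching:
    """Outcome of matching one frame's detections against its GT boxes."""

    tp_pairs: list[tuple[ScoredBox, GTBox, float]]
    fp_boxes: list[ScoredBox]
    fn_gts: list[GTBox]
    delta_used: float
    iou_thr_used: float

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_boxes)

    @property
    def fn(self) -> int:
        return len(self.fn_gts)


def match_frame(
    dets: Sequence[ScoredBox],
    gts: Sequence[GTBox],
    delta: float,
    iou_thr: float,
) -> FrameMatching:
    """Greedily assign detections to GT boxes within one frame.

    Only detections with score >= ``delta`` participate ("score
    exceeding delta" is read inclusively so that delta=0 keeps every
    detection).  Ties in score are broken by larger best-IoU, then by
    input order.  Unmatched detections are FPs, unmatched GTs FNs.
    """
    active = [d for d in dets if d.score >= delta]
    order = sorted(
        range(len(active)),
        key=lambda i: (
            -active[i].score,
            -max((iou(active[i], g) for g in gts), default=0.0),
            i,
        ),
    )
    matched_gt: set[int] = set()
    tp_pairs: list[tuple[ScoredBox, GTBox, float]] = []
    fp_boxes: list[ScoredBox] = []
    for i in order:
        det = active[i]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if j in matched_gt:
                continue
            v = iou(det, g)
            if v >= iou_thr and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched_gt.add(best_j)
            tp_pairs.append((det, gts[best_j], best_iou))
        else:
            fp_boxes.append(det)
    fn_gts = [g for j, g in enumerate(gts) if j not in matched_gt]
    return FrameMatching(tp_pairs, fp_boxes, fn_gts, delta, iou_thr)


def box_size_class(box, mode: str = "max_side") -> str:
    """Classify a box as small / medium / large.

    Size is max(width, height) in ``max_side`` mode or sqrt(area) in
    ``sqrt_area`` mode, measured at native resolution; small < 100 px,
    medium < 200 px, large otherwise.
    """
    w = box.x2 - box.x1
    h = box.y2 - box.y1
    if mode == "max_side":
        s = max(w, h)
    elif mode == "sqrt_area":
        s = math.sqrt(w * h)
    else:
        raise ValueError(f"unknown size mode {mode!r}")
    if s < SIZE_SMALL_PX:
        return "small"
    if s < SIZE_MEDIUM_PX:
        return "medium"
    return "large"
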