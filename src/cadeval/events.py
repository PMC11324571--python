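"""Event-level, clinic-oriented metrics.

A *detection event* is a maximal run of consecutive detection-positive
frames (>= 1 box at or above the score threshold delta) whose length
reaches ceil(tau * fps) frames, i.e. spans at least tau seconds.  An
event is a *FP event* when every box inside it fails to reach the
working IoU (default 0.2) against any GT box; averaged over videos this
gives the average FP events per patient.  An event is a *TP event* for
a polyp when it begins no later than sigma seconds after the polyp's
first annotated appearance and its boxes overlap that polyp (see
``event_match_mode``); per-polyp recall is the fraction of polyps with
at least one TP event.  Sweeping delta, tau or sigma while fixing the
other two traces a FROC curve of per-polyp recall against FP events
per patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matching import iou
from .model import EvalConfig, PolypTrack, VideoRecord

__all__ = [
    "DetectionEvent",
    "FROCPoint",
    "detection_flags",
    "min_event_frames",
    "segment_events",
    "classify_event",
    "video_events",
    "fp_events_per_patient",
    "per_polyp_recall",
    "froc_sweep",
    "DEFAULT_DELTA_GRID",
    "DEFAULT_TAU_GRID",
    "DEFAULT_SIGMA_GRID",
]

DEFAULT_DELTA_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))  # 0.1 .. 0.9
DEFAULT_TAU_GRID = tuple(round(0.2 * i, 1) for i in range(1, 16))  # 0.2 .. 3.0 s
DEFAULT_SIGMA_GRID = (1.0, 3.0, 5.0, 10.0, 15.0)  # seconds

FrameMasks = Mapping[str, Sequence[bool]] | None


@dataclass
class DetectionEvent:
    video_id: str
    start_frame: int
    end_frame: int  # inclusive
    duration_s: float
    label: str  # 'TP' | 'FP' | 'mixed'
    matched_polyp_ids: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class FROCPoint:
    swept_value: float
    per_polyp_recall: float
    avg_fp_events_per_patient: float


def min_event_frames(tau: float, fps: float) -> int:
    """Frames needed so that a run spans at least tau seconds.

    k = ceil(tau * fps), with a small guard so exact products such as
    2.0 * 25 are not pushed up by floating-point noise.
    """
    if tau <= 0 or fps <= 0:
        raise ValueError("tau and fps must be positive")
    return max(1, math.ceil(tau * fps - 1e-9))


def detection_flags(
    video: VideoRecord, delta: float, frame_mask: Sequence[bool] | None = None
) -> np.ndarray:
    """Boolean per-frame flags: does any detection reach the threshold?

    ``frame_mask`` restricts evaluation to a frame subset (e.g. the
    start-stop-polyp intervals); excluded frames are forced negative so
    runs cannot cross them.
    """
    flags = np.array(
        [any(d.score >= delta for d in fr.dets) for fr in video.frames], dtype=bool
    )
    if frame_mask is not None:
        mask = np.asarray(frame_mask, dtype=bool)
        if mask.shape != flags.shape:
            raise ValueError("frame_mask length must equal the video frame count")
        flags &= mask
    return flags


def segment_events(
    flags: Sequence[bool], fps: float, tau: float, gap_tolerance: int = 0
) -> list[tuple[int, int]]:
    """Maximal qualifying runs of detection-positive frames.

    Runs separated by at most ``gap_tolerance`` negative frames are
    merged first; a merged run qualifies as one event iff it contains
    at least ceil(tau * fps) frames.  Returns inclusive (start, end)
    index pairs.
    """
    flags = np.asarray(flags, dtype=bool)
    k = min_event_frames(tau, fps)
    runs: list[list[int]] = []
    in_run = False
    for i, f in enumerate(flags):
        if f:
            if in_run:
                runs[-1][1] = i
            else:
                runs.append([i, i])
                in_run = True
        else:
            in_run = False
    if gap_tolerance > 0 and runs:
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] - 1 <= gap_tolerance:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        runs = merged
    return [(s, e) for s, e in runs if e - s + 1 >= k]


def _event_boxes(video, start, end, delta, frame_mask=None):
    """(frame_idx, det) pairs inside the event at or above threshold."""
    out = []
    for idx in range(start, end + 1):
        if frame_mask is not None and not frame_mask[idx]:
            continue
        for d in video.frames[idx].dets:
            if d.score >= delta:
                out.append((idx, d))
    return out


def classify_event(
    span: tuple[int, int],
    video: VideoRecord,
    delta: float,
    iou_event: float,
    sigma: float,
    tracks: Sequence[PolypTrack],
    mode: str = "any_box",
    frame_mask: Sequence[bool] | None = None,
) -> DetectionEvent:
    """Label one event span as a TP, FP or mixed event.

    FP: every box in the event has max IoU < ``iou_event`` against its
    frame's GT.  TP for polyp p: the event starts no later than sigma
    seconds after p's first annotated appearance, and the overlap
    criterion holds — ``any_box``: at least one box in the event
    overlaps one of p's GT boxes with IoU >= iou_event; ``all_boxes``:
    every box overlaps some GT and at least one overlaps p.  The event
    may begin before p appears (an ongoing run that then locks onto the
    polyp); matching only counts at frames where p is annotated.
    Events that are neither FP nor TP are labeled 'mixed'.
    """
    if mode not in ("any_box", "all_boxes"):
        raise ValueError(f"unknown event match mode {mode!r}")
    start, end = span
    boxes = _event_boxes(video, start, end, delta, frame_mask)
    any_gt_overlap = False
    all_overlap_some_gt = True
    overlaps_track: dict[str, bool] = {}
    for idx, det in boxes:
        gts = video.frames[idx].gt
        ious = [(g, iou(det, g)) for g in gts]
        if any(v >= iou_event for _, v in ious):
            any_gt_overlap = True
            for g, v in ious:
                if v >= iou_event:
                    overlaps_track[g.polyp_id] = True
        else:
            all_overlap_some_gt = False
    start_time = start / video.fps
    matched: set[str] = set()
    for t in tracks:
        if t.video_id != video.video_id:
            continue
        if start_time > t.onset_time_s(video.fps) + sigma:
            continue
        if not overlaps_track.get(t.polyp_id, False):
            continue
        if mode == "all_boxes" and not all_overlap_some_gt:
            continue
        matched.add(t.polyp_id)
    if not any_gt_overlap:
        label = "FP"
    elif matched:
        label = "TP"
    else:
        label = "mixed"
    return DetectionEvent(
        video_id=video.video_id,
        start_frame=start,
        end_frame=end,
        duration_s=(end - start + 1) / video.fps,
        label=label,
        matched_polyp_ids=matched,
    )


def video_events(
    video: VideoRecord,
    tracks: Sequence[PolypTrack],
    config: EvalConfig,
    frame_mask: Sequence[bool] | None = None,
) -> list[DetectionEvent]:
    """All classified detection events of one video under a config."""
    flags = detection_flags(video, config.delta, frame_mask)
    spans = segment_events(flags, video.fps, config.tau, config.gap_tolerance)
    return [
        classify_event(
            span,
            video,
            config.delta,
            config.iou_event,
            config.sigma,
            tracks,
            config.event_match_mode,
            frame_mask,
        )
        for span in spans
    ]


def fp_events_per_patient(
    videos: Sequence[VideoRecord],
    delta: float,
    tau: float,
    iou_event: float = 0.2,
    gap_tolerance: int = 0,
    frame_masks: FrameMasks = None,
) -> float:
    """Mean number of FP-labeled events per full-procedure video."""
    if not videos:
        raise ValueError("fp_events_per_patient requires at least one video")
    cfg = EvalConfig(
        delta=delta, tau=tau, iou_event=iou_event, gap_tolerance=gap_tolerance
    )
    total = 0
    for video in videos:
        mask = frame_masks.get(video.video_id) if frame_masks else None
        events = video_events(video, (), cfg, mask)
        total += sum(1 for e in events if e.label == "FP")
    return total / len(videos)


def per_polyp_recall(
    videos: Sequence[VideoRecord],
    tracks: Sequence[PolypTrack],
    delta: float,
    tau: float,
    sigma: float,
    iou_event: float = 0.2,
    mode: str = "any_box",
    gap_tolerance: int = 0,
    frame_masks: FrameMasks = None,
) -> float:
    """Fraction of polyps with >= 1 TP event within their sigma window."""
    if not tracks:
        raise ValueError("per_polyp_recall requires at least one polyp track")
    cfg = EvalConfig(
        delta=delta,
        tau=tau,
        sigma=sigma,
        iou_event=iou_event,
        event_match_mode=mode,
        gap_tolerance=gap_tolerance,
    )
    detected: set[tuple[str, str]] = set()
    for video in videos:
        mask = frame_masks.get(video.video_id) if frame_masks else None
        for event in video_events(video, tracks, cfg, mask):
            if event.label == "TP":
                detected.update((video.video_id, pid) for pid in event.matched_polyp_ids)
    return sum(1 for t in tracks if (t.video_id, t.polyp_id) in detected) / len(tracks)


def froc_sweep(
    videos: Sequence[VideoRecord],
    tracks: Sequence[PolypTrack],
    sweep: str,
    grid: Sequence[float] | None = None,
    config: EvalConfig | None = None,
    frame_masks: FrameMasks = None,
) -> list[FROCPoint]:
    """FROC curve: sweep one of delta / tau / sigma, fix the other two.

    Default grids: delta 0.1..0.9 step 0.1; tau 0.2..3.0 s step 0.2;
    sigma {1, 3, 5, 10, 15} s.  Sigma sweeps leave the FP column
    constant by construction (FP labeling does not involve sigma).
    """
    if sweep not in ("delta", "tau", "sigma"):
        raise ValueError(f"sweep must be 'delta', 'tau' or 'sigma', got {sweep!r}")
    if config is None:
        config = EvalConfig()
    if grid is None:
        grid = {
            "delta": DEFAULT_DELTA_GRID,
            "tau": DEFAULT_TAU_GRID,
            "sigma": DEFAULT_SIGMA_GRID,
        }[sweep]
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    if sorted(grid) != grid:
        raise ValueError("sweep grid must be sorted ascending")
    points = []
    for value in grid:
        cfg = config.with_(**{sweep: value})
        recall = per_polyp_recall(
            videos,
            tracks,
            cfg.delta,
            cfg.tau,
            cfg.sigma,
            cfg.iou_event,
            cfg.event_match_mode,
            cfg.gap_tolerance,
            frame_masks,
        )
        fp_rate = fp_events_per_patient(
            videos, cfg.delta, cfg.tau, cfg.iou_event, cfg.gap_tolerance, frame_masks
        )
        points.append(FROCPoint(value, recall, fp_rate))
    return points
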