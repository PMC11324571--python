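"""Core domain types for CADe video polyp-detection evaluation.

The atoms are axis-aligned boxes in continuous pixel coordinates
(x1, y1, x2, y2) at native image resolution, with area
(x2 - x1) * (y2 - y1) and no inclusive-pixel correction, matching
COCO-style arithmetic.  Frames are 0-indexed and gap-free within a
video; frame ``i`` covers the time interval ``[i/fps, (i+1)/fps)``
seconds, so a run of ``k`` frames spans ``k/fps`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "GTBox",
    "ScoredBox",
    "FrameRecord",
    "VideoRecord",
    "PolypTrack",
    "EvalConfig",
    "derive_polyp_tracks",
]

DEFAULT_IOU_GRID = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


def _check_box(x1: float, y1: float, x2: float, y2: float) -> None:
    if x1 < 0 or y1 < 0:
        raise ValueError(f"box coordinates must be >= 0, got ({x1}, {y1}, {x2}, {y2})")
    if x2 <= x1 or y2 <= y1:
        raise ValueError(f"box must have x2 > x1 and y2 > y1, got ({x1}, {y1}, {x2}, {y2})")


@dataclass(frozen=True)
class GTBox:
    """A ground-truth polyp bounding box, tagged with its polyp identity."""

    x1: float
    y1: float
    x2: float
    y2: float
    polyp_id: str

    def __post_init__(self) -> None:
        _check_box(self.x1, self.y1, self.x2, self.y2)

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class ScoredBox:
    """A predicted bounding box with a detection confidence in [0, 1]."""

    x1: float
    y1: float
    x2: float
    y2: float
    score: float

    def __post_init__(self) -> None:
        _check_box(self.x1, self.y1, self.x2, self.y2)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass
class FrameRecord:
    """One video frame: its ground truth and its detector output."""

    video_id: str
    frame_idx: int
    gt: list[GTBox] = field(default_factory=list)
    dets: list[ScoredBox] = field(default_factory=list)

    @property
    def is_positive(self) -> bool:
        return len(self.gt) > 0


@dataclass
class VideoRecord:
    """An ordered, gap-free frame sequence for one full-procedure video.

    Frame indices must run 0..n-1 with no gaps: the event metrics rely
    on temporal contiguity, and full-procedure recordings have no
    pauses or dropped segments.
    """

    video_id: str
    fps: float
    frames: list[FrameRecord]
    cohort_id: str | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        for i, fr in enumerate(self.frames):
            if fr.frame_idx != i:
                raise ValueError(
                    f"video {self.video_id!r}: frame indices must be 0..n-1 without "
                    f"gaps; position {i} holds frame_idx {fr.frame_idx}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def positive_frames(self) -> list[int]:
        return [fr.frame_idx for fr in self.frames if fr.is_positive]


@dataclass(frozen=True)
class PolypTrack:
    """One distinct polyp: its first and last annotated appearance."""

    polyp_id: str
    video_id: str
    first_frame: int
    last_frame: int

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError(
                f"track {self.polyp_id!r}: first_frame {self.first_frame} > "
                f"last_frame {self.last_frame}"
            )

    def onset_time_s(self, fps: float) -> float:
        return self.first_frame / fps


@dataclass(frozen=True)
class EvalConfig:
    """Operating parameters of the evaluation.

    delta : detection score threshold; boxes with score >= delta count.
    tau : minimum event duration in seconds for a run of consecutive
        detection-positive frames to qualify as a detection event.
    sigma : detection window in seconds after a polyp's first annotated
        appearance within which a matching event counts toward
        per-polyp recall.
    iou_event : IoU threshold for frame- and event-level matching.
    iou_grid : IoU thresholds for average precision (COCO 0.50:0.95).
    event_match_mode : 'any_box' (one overlapping box makes the event a
        TP for the polyp) or 'all_boxes' (every box in the event must
        overlap some GT).
    gap_tolerance : missing frames tolerated inside an event run.
    size_mode : box size measured by 'max_side' or 'sqrt_area'.
    """

    delta: float = 0.6
    tau: float = 1.0
    sigma: float = 3.0
    iou_event: float = 0.2
    iou_grid: tuple[float, ...] = DEFAULT_IOU_GRID
    event_match_mode: str = "any_box"
    gap_tolerance: int = 0
    size_mode: str = "max_side"

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not 0.0 < self.iou_event <= 1.0:
            raise ValueError(f"iou_event must lie in (0, 1], got {self.iou_event}")
        if self.event_match_mode not in ("any_box", "all_boxes"):
            raise ValueError(f"unknown event_match_mode {self.event_match_mode!r}")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")
        if self.size_mode not in ("max_side", "sqrt_area"):
            raise ValueError(f"unknown size_mode {self.size_mode!r}")

    def with_(self, **kwargs) -> "EvalConfig":
        return replace(self, **kwargs)


def derive_polyp_tracks(videos: Iterable[VideoRecord]) -> list[PolypTrack]:
    """Derive one :class:`PolypTrack` per distinct (video, polyp_id) pair.

    first_frame / last_frame are the min / max annotated frame of the
    polyp; annotation gaps inside the interval (occlusion, poor
    framing) are allowed.  A polyp_id appearing in two different videos
    is an error: identities are namespaced per video.
    """
    seen_in: dict[str, str] = {}
    spans: dict[tuple[str, str], tuple[int, int]] = {}
    for video in videos:
        for fr in video.frames:
            for gt in fr.gt:
                owner = seen_in.setdefault(gt.polyp_id, video.video_id)
                if owner != video.video_id:
                    raise ValueError(
                        f"polyp_id {gt.polyp_id!r} appears in videos {owner!r} and "
                        f"{video.video_id!r}; polyp identities are per-video"
                    )
                key = (video.video_id, gt.polyp_id)
                lo, hi = spans.get(key, (fr.frame_idx, fr.frame_idx))
                spans[key] = (min(lo, fr.frame_idx), max(hi, fr.frame_idx))
    return [
        PolypTrack(polyp_id=pid, video_id=vid, first_frame=lo, last_frame=hi)
        for (vid, pid), (lo, hi) in sorted(spans.items())
    ]


def tracks_for_video(tracks: Sequence[PolypTrack], video_id: str) -> list[PolypTrack]:
    return [t for t in tracks if t.video_id == video_id]
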