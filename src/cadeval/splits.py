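"""Dataset split construction and summary arithmetic.

Two granularities coexist:

* count-level: published datasets enter as :class:`DatasetCounts`
  (frames / positives / negatives / polyps) and are combined into
  training splits such as the Unified Colonoscopy Dataset (UCD) by
  pure arithmetic;
* frame-level: full-procedure test videos enter as
  :class:`~cadeval.model.VideoRecord` collections and are carved into
  evaluation splits — all-video, minus-train (first five videos of
  each cohort held out), start-stop-polyp (only frames between each
  polyp's first and last appearance), and per-polyp subsamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import PolypTrack, VideoRecord

__all__ = [
    "DatasetCounts",
    "SplitMember",
    "SplitManifest",
    "VideoStats",
    "video_stats",
    "build_ucd",
    "select_first_k_videos",
    "rc_mt",
    "rc_ssp",
    "subsample_positives",
    "summarize_split",
    "split_frame_masks",
    "split_videos",
]


@dataclass(frozen=True)
class DatasetCounts:
    """Published summary counts of one source dataset."""

    name: str
    n_frames: int
    n_positive_frames: int
    n_negative_frames: int
    n_polyps: int | None  # None when the source reports it as unclear

    def __post_init__(self) -> None:
        if self.n_frames != self.n_positive_frames + self.n_negative_frames:
            raise ValueError(
                f"{self.name}: frames ({self.n_frames}) != positives "
                f"({self.n_positive_frames}) + negatives ({self.n_negative_frames})"
            )


@dataclass(frozen=True)
class SplitMember:
    member_id: str  # video_id or dataset_id
    frames: tuple[int, ...] | None = None  # None = all frames


@dataclass
class SplitManifest:
    name: str
    members: list[SplitMember]
    summary: dict[str, int | None] = field(default_factory=dict)

    def member_ids(self) -> list[str]:
        return [m.member_id for m in self.members]


@dataclass(frozen=True)
class VideoStats:
    video_id: str
    cohort_id: str | None
    n_frames: int
    n_positive_frames: int
    n_negative_frames: int
    n_polyps: int


def video_stats(video: VideoRecord) -> VideoStats:
    pos = sum(1 for fr in video.frames if fr.is_positive)
    polyps = {g.polyp_id for fr in video.frames for g in fr.gt}
    return VideoStats(
        video_id=video.video_id,
        cohort_id=video.cohort_id,
        n_frames=video.n_frames,
        n_positive_frames=pos,
        n_negative_frames=video.n_frames - pos,
        n_polyps=len(polyps),
    )


def _sum_counts(counts: Iterable[DatasetCounts]) -> dict[str, int | None]:
    counts = list(counts)
    polyps: int | None = 0
    for c in counts:
        if c.n_polyps is None:
            polyps = None  # 'unclear' poisons the sum
            break
        polyps += c.n_polyps
    return {
        "n_polyps": polyps,
        "n_positive_frames": sum(c.n_positive_frames for c in counts),
        "n_negative_frames": sum(c.n_negative_frames for c in counts),
        "n_frames": sum(c.n_frames for c in counts),
    }


def build_ucd(*datasets: DatasetCounts, name: str = "UCD") -> SplitManifest:
    """Union of source datasets into one training split; summary sums."""
    ids = [d.name for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate dataset ids in {ids}")
    return SplitManifest(
        name=name,
        members=[SplitMember(d.name) for d in datasets],
        summary=_sum_counts(datasets),
    )


def select_first_k_videos(
    rc_videos: Sequence[VideoStats], cohort_id: str, k: int = 5
) -> list[str]:
    """The k lowest-ordinal video ids of a cohort (lexicographic order)."""
    members = sorted(v.video_id for v in rc_videos if v.cohort_id == cohort_id)
    if not members and k > 0:
        raise ValueError(f"unknown cohort {cohort_id!r}")
    if len(members) < k:
        raise ValueError(
            f"cohort {cohort_id!r} has only {len(members)} videos, need {k}"
        )
    return members[:k]


def _video_split(name: str, stats: Sequence[VideoStats]) -> SplitManifest:
    return SplitManifest(
        name=name,
        members=[SplitMember(s.video_id) for s in stats],
        summary={
            "n_polyps": sum(s.n_polyps for s in stats),
            "n_positive_frames": sum(s.n_positive_frames for s in stats),
            "n_negative_frames": sum(s.n_negative_frames for s in stats),
            "n_frames": sum(s.n_frames for s in stats),
        },
    )


def rc_mt(rc_videos: Sequence[VideoStats], k: int = 5) -> SplitManifest:
    """Minus-train split: drop the first ``k`` videos of every cohort."""
    cohorts = sorted({v.cohort_id for v in rc_videos if v.cohort_id is not None})
    held_out: set[str] = set()
    for cohort in cohorts:
        held_out.update(select_first_k_videos(rc_videos, cohort, k))
    kept = [v for v in rc_videos if v.video_id not in held_out]
    return _video_split("RC_MT", kept)


def rc_ssp(
    videos: Sequence[VideoRecord], tracks: Sequence[PolypTrack]
) -> SplitManifest:
    """Start-stop-polyp split: keep only frames between each polyp's
    first and last appearance (union of per-track intervals); all
    positive frames are preserved, negatives outside the intervals are
    dropped, and videos without polyps contribute no frames."""
    members = []
    n_pos = n_neg = 0
    polyps = 0
    for video in videos:
        keep = np.zeros(video.n_frames, dtype=bool)
        for t in tracks:
            if t.video_id == video.video_id:
                keep[t.first_frame : t.last_frame + 1] = True
                polyps += 1
        frames = tuple(int(i) for i in np.flatnonzero(keep))
        members.append(SplitMember(video.video_id, frames))
        for i in frames:
            if video.frames[i].is_positive:
                n_pos += 1
            else:
                n_neg += 1
    return SplitManifest(
        name="RC_SSP",
        members=members,
        summary={
            "n_polyps": polyps,
            "n_positive_frames": n_pos,
            "n_negative_frames": n_neg,
            "n_frames": n_pos + n_neg,
        },
    )


def subsample_positives(
    videos: Sequence[VideoRecord],
    tracks: Sequence[PolypTrack],
    n_per_polyp: int = 100,
    neg_fraction: float = 0.0,
    seed: int = 0,
    name: str | None = None,
) -> SplitManifest:
    """Per-polyp positive subsample plus a global fraction of negatives.

    Keeps min(n_per_polyp, available) positive frames per track, drawn
    uniformly without replacement, plus floor(neg_fraction * total
    negatives) negative frames drawn globally; fully reproducible from
    ``seed``.
    """
    if not 0.0 <= neg_fraction <= 1.0:
        raise ValueError(f"neg_fraction must lie in [0, 1], got {neg_fraction}")
    rng = np.random.default_rng(seed)
    by_video: dict[str, set[int]] = {v.video_id: set() for v in videos}
    vmap = {v.video_id: v for v in videos}
    for t in sorted(tracks, key=lambda t: (t.video_id, t.polyp_id)):
        video = vmap[t.video_id]
        frames = [
            fr.frame_idx
            for fr in video.frames
            if any(g.polyp_id == t.polyp_id for g in fr.gt)
        ]
        take = min(n_per_polyp, len(frames))
        chosen = rng.choice(len(frames), size=take, replace=False)
        by_video[t.video_id].update(frames[i] for i in sorted(chosen))
    negatives = [
        (v.video_id, fr.frame_idx)
        for v in videos
        for fr in v.frames
        if not fr.is_positive
    ]
    n_neg = math.floor(neg_fraction * len(negatives))
    if n_neg > 0:
        chosen = rng.choice(len(negatives), size=n_neg, replace=False)
        for i in sorted(chosen):
            vid, idx = negatives[i]
            by_video[vid].add(idx)
    members = [
        SplitMember(vid, tuple(sorted(frames))) for vid, frames in by_video.items()
    ]
    manifest = SplitManifest(
        name=name or f"RC_{n_per_polyp},{neg_fraction:g}", members=members
    )
    manifest.summary = summarize_split(manifest, vmap)
    return manifest


def summarize_split(
    manifest: SplitManifest, videos: Mapping[str, VideoRecord]
) -> dict[str, int]:
    """Polyp / positive / negative / frame counts of a frame-level split."""
    n_pos = n_neg = 0
    polyp_ids: set[tuple[str, str]] = set()
    for m in manifest.members:
        video = videos[m.member_id]
        idxs = range(video.n_frames) if m.frames is None else m.frames
        for i in idxs:
            fr = video.frames[i]
            if fr.is_positive:
                n_pos += 1
                polyp_ids.update((video.video_id, g.polyp_id) for g in fr.gt)
            else:
                n_neg += 1
    return {
        "n_polyps": len(polyp_ids),
        "n_positive_frames": n_pos,
        "n_negative_frames": n_neg,
        "n_frames": n_pos + n_neg,
    }


def split_frame_masks(
    manifest: SplitManifest, videos: Mapping[str, VideoRecord]
) -> dict[str, np.ndarray]:
    """Per-video boolean masks selecting the split's frames, for the
    event metrics' restricted evaluation."""
    masks = {}
    for m in manifest.members:
        video = videos[m.member_id]
        mask = np.ones(video.n_frames, dtype=bool)
        if m.frames is not None:
            mask[:] = False
            mask[list(m.frames)] = True
        masks[video.video_id] = mask
    return masks


def split_videos(
    manifest: SplitManifest, videos: Mapping[str, VideoRecord]
) -> list[VideoRecord]:
    """The VideoRecords named by a split, in member order."""
    return [videos[m.member_id] for m in manifest.members]
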