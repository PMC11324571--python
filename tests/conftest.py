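"""Shared fixtures: hand-built tiny videos and seeded simulated datasets."""

from __future__ import annotations

import pytest

from cadeval.model import FrameRecord, GTBox, ScoredBox, VideoRecord
from cadeval.simulate import SimConfig, simulate_dataset


def make_video(
    video_id: str = "v1",
    fps: float = 1.0,
    n_frames: int = 10,
    gt: dict[int, list[tuple]] | None = None,
    dets: dict[int, list[tuple]] | None = None,
    cohort_id: str | None = None,
) -> VideoRecord:
    """Build a VideoRecord from sparse frame -> box-tuple maps.

    GT tuples are (x1, y1, x2, y2, polyp_id); detection tuples are
    (x1, y1, x2, y2, score).
    """
    gt = gt or {}
    dets = dets or {}
    frames = [
        FrameRecord(
            video_id,
            i,
            gt=[GTBox(*t) for t in gt.get(i, [])],
            dets=[ScoredBox(*t) for t in dets.get(i, [])],
        )
        for i in range(n_frames)
    ]
    return VideoRecord(video_id=video_id, fps=fps, frames=frames, cohort_id=cohort_id)


@pytest.fixture
def video_factory():
    return make_video


@pytest.fixture(scope="session")
def sim_small():
    """Two short procedures under mid-range operating characteristics."""
    cfg = SimConfig(n_videos=2, fps=5.0, video_len_s=120.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_default():
    """The default study conditions (4 procedures of 10 min at 10 fps)."""
    return simulate_dataset(SimConfig(seed=11))
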