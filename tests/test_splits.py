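"""Split construction: count arithmetic, hold-outs, frame restriction,
and per-polyp subsampling."""

import pytest

from cadeval.model import derive_polyp_tracks
from cadeval.splits import (
    DatasetCounts,
    build_ucd,
    rc_mt,
    rc_ssp,
    select_first_k_videos,
    split_frame_masks,
    subsample_positives,
    summarize_split,
    video_stats,
)
from .conftest import make_video

# Published summary counts of the three source datasets combined into
# the unified training split (frames / positives / negatives / polyps).
KUMC = DatasetCounts("KUMC", 37_899, 35_981, 1_918, 80)
SUN = DatasetCounts("SUN", 158_690, 49_136, 109_554, 100)
LDPOLYP = DatasetCounts("LDPolypVideo", 139_640, 33_875, 105_765, 200)
POLYPGEN = DatasetCounts("PolypGen", 8_037, 3_121, 4_916, None)


class TestBuildUCD:
    def test_published_counts_sum(self):
        ucd = build_ucd(KUMC, SUN, LDPOLYP)
        assert ucd.summary["n_polyps"] == 380
        assert ucd.summary["n_positive_frames"] == 118_992
        assert ucd.summary["n_negative_frames"] == 217_237
        assert ucd.summary["n_frames"] == 336_229

    def test_ldpolyp_frames_include_extracted_negatives(self):
        # 40,266 annotated + 99,374 sampled negative frames
        assert LDPOLYP.n_frames == 40_266 + 99_374

    def test_empty_union(self):
        assert build_ucd().summary["n_frames"] == 0

    def test_duplicate_dataset_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_ucd(KUMC, KUMC)

    def test_unclear_polyp_count_poisons_sum(self):
        u = build_ucd(KUMC, POLYPGEN)
        assert u.summary["n_polyps"] is None
        assert u.summary["n_frames"] == KUMC.n_frames + POLYPGEN.n_frames

    def test_counts_must_be_consistent(self):
        with pytest.raises(ValueError):
            DatasetCounts("bad", 10, 4, 5, 1)


def _rc_like_videos():
    """12 tiny videos across 4 cohorts, some with polyps."""
    videos = []
    for c in range(1, 5):
        for i in range(3):
            vid = f"{c:03d}-{i + 1:03d}"
            gt = (
                {j: [(0, 0, 20, 20, f"{vid}_p")] for j in range(2, 5)}
                if i != 1
                else {}
            )
            videos.append(
                make_video(vid, n_frames=10, gt=gt, cohort_id=f"{c:03d}")
            )
    return videos


class TestFirstKAndMinusTrain:
    def test_first_k_is_lexicographic(self):
        stats = [video_stats(v) for v in _rc_like_videos()]
        assert select_first_k_videos(stats, "001", 2) == ["001-001", "001-002"]

    def test_k_zero_is_empty(self):
        stats = [video_stats(v) for v in _rc_like_videos()]
        assert select_first_k_videos(stats, "001", 0) == []

    def test_unknown_cohort_rejected(self):
        stats = [video_stats(v) for v in _rc_like_videos()]
        with pytest.raises(ValueError, match="unknown cohort"):
            select_first_k_videos(stats, "999", 2)

    def test_too_few_videos_rejected(self):
        stats = [video_stats(v) for v in _rc_like_videos()]
        with pytest.raises(ValueError, match="only"):
            select_first_k_videos(stats, "001", 5)

    def test_minus_train_partitions_counts(self):
        videos = _rc_like_videos()
        stats = [video_stats(v) for v in videos]
        mt = rc_mt(stats, k=1)
        held = {
            v
            for c in ("001", "002", "003", "004")
            for v in select_first_k_videos(stats, c, 1)
        }
        assert set(mt.member_ids()) == {s.video_id for s in stats} - held
        # counts are additive across the partition
        total = sum(s.n_frames for s in stats)
        held_frames = sum(s.n_frames for s in stats if s.video_id in held)
        assert mt.summary["n_frames"] == total - held_frames
        total_polyps = sum(s.n_polyps for s in stats)
        held_polyps = sum(s.n_polyps for s in stats if s.video_id in held)
        assert mt.summary["n_polyps"] == total_polyps - held_polyps

    def test_minus_train_of_exactly_held_out_videos_is_empty(self):
        videos = [v for v in _rc_like_videos() if v.video_id.endswith("-001")]
        stats = [video_stats(v) for v in videos]
        mt = rc_mt(stats, k=1)
        assert mt.member_ids() == []
        assert mt.summary["n_frames"] == 0


class TestStartStopPolyp:
    def test_single_track_keeps_its_interval(self):
        gt = {i: [(0, 0, 20, 20, "p")] for i in range(10, 21)}
        video = make_video(n_frames=40, gt=gt)
        tracks = derive_polyp_tracks([video])
        ssp = rc_ssp([video], tracks)
        (member,) = ssp.members
        assert member.frames == tuple(range(10, 21))
        assert ssp.summary["n_frames"] == 11

    def test_video_without_polyps_contributes_no_frames(self):
        video = make_video(n_frames=20)
        ssp = rc_ssp([video], [])
        assert ssp.members[0].frames == ()
        assert ssp.summary["n_frames"] == 0

    def test_overlapping_tracks_union(self):
        gt = {i: [(0, 0, 20, 20, "a")] for i in range(5, 16)}
        for i in range(10, 31):
            gt.setdefault(i, []).append((30, 30, 50, 50, "b"))
        video = make_video(n_frames=40, gt=gt)
        tracks = derive_polyp_tracks([video])
        ssp = rc_ssp([video], tracks)
        (member,) = ssp.members
        assert member.frames == tuple(range(5, 31))
        assert ssp.summary["n_frames"] == 26

    def test_positives_preserved_negatives_reduced(self, sim_small):
        videos, tracks = sim_small
        vmap = {v.video_id: v for v in videos}
        ssp = rc_ssp(videos, tracks)
        full_pos = sum(len(v.positive_frames()) for v in videos)
        full_neg = sum(v.n_frames for v in videos) - full_pos
        assert ssp.summary["n_positive_frames"] == full_pos
        assert ssp.summary["n_negative_frames"] <= full_neg
        # recomputing the summary from the manifest agrees
        assert summarize_split(ssp, vmap) == ssp.summary


class TestSubsamplePositives:
    def test_clamps_to_available_positives(self):
        gt = {i: [(0, 0, 20, 20, "p")] for i in range(50)}
        video = make_video(n_frames=60, gt=gt)
        tracks = derive_polyp_tracks([video])
        sub = subsample_positives([video], tracks, n_per_polyp=100, seed=1)
        assert sub.summary["n_positive_frames"] == 50

    def test_no_negatives_when_fraction_zero(self, sim_small):
        videos, tracks = sim_small
        sub = subsample_positives(videos, tracks, n_per_polyp=10, neg_fraction=0.0, seed=1)
        assert sub.summary["n_negative_frames"] == 0

    def test_negative_fraction_global_floor(self, sim_small):
        videos, tracks = sim_small
        n_neg_total = sum(
            1 for v in videos for fr in v.frames if not fr.is_positive
        )
        sub = subsample_positives(videos, tracks, n_per_polyp=10, neg_fraction=0.1, seed=1)
        assert sub.summary["n_negative_frames"] == int(0.1 * n_neg_total)

    def test_deterministic_under_seed(self, sim_small):
        videos, tracks = sim_small
        a = subsample_positives(videos, tracks, n_per_polyp=20, neg_fraction=0.1, seed=9)
        b = subsample_positives(videos, tracks, n_per_polyp=20, neg_fraction=0.1, seed=9)
        assert [(m.member_id, m.frames) for m in a.members] == [
            (m.member_id, m.frames) for m in b.members
        ]
        c = subsample_positives(videos, tracks, n_per_polyp=20, neg_fraction=0.1, seed=10)
        assert [(m.member_id, m.frames) for m in a.members] != [
            (m.member_id, m.frames) for m in c.members
        ]

    def test_invalid_neg_fraction_rejected(self, sim_small):
        videos, tracks = sim_small
        with pytest.raises(ValueError):
            subsample_positives(videos, tracks, neg_fraction=1.5, seed=1)


def test_split_frame_masks_match_members(sim_small):
    videos, tracks = sim_small
    vmap = {v.video_id: v for v in videos}
    ssp = rc_ssp(videos, tracks)
    masks = split_frame_masks(ssp, vmap)
    for member in ssp.members:
        mask = masks[member.member_id]
        assert mask.sum() == len(member.frames)
        assert all(mask[i] for i in member.frames)
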