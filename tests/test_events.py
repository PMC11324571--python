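"""Detection-event formation, classification, and the FROC metrics."""

import numpy as np
import pytest

from cadeval.events import (
    DEFAULT_SIGMA_GRID,
    DEFAULT_TAU_GRID,
    classify_event,
    detection_flags,
    fp_events_per_patient,
    froc_sweep,
    min_event_frames,
    per_polyp_recall,
    segment_events,
)
from cadeval.model import EvalConfig, derive_polyp_tracks
from cadeval.simulate import SimConfig, oracle_count_runs, simulate_dataset
from cadeval.splits import rc_ssp, split_frame_masks
from .conftest import make_video


class TestDetectionFlags:
    def test_silent_detector(self):
        video = make_video(n_frames=5)
        assert not detection_flags(video, 0.0).any()

    def test_threshold_splits_scores(self):
        video = make_video(
            n_frames=2,
            dets={0: [(0, 0, 10, 10, 0.3)], 1: [(0, 0, 10, 10, 0.7)]},
        )
        assert detection_flags(video, 0.5).tolist() == [False, True]
        assert detection_flags(video, 0.0).tolist() == [True, True]


class TestSegmentEvents:
    def test_two_runs_at_tau_two(self):
        flags = [1, 1, 0, 1, 1, 1, 0]
        assert segment_events(flags, fps=1.0, tau=2.0) == [(0, 1), (3, 5)]

    def test_all_false(self):
        assert segment_events([0] * 6, fps=1.0, tau=1.0) == []

    def test_subthreshold_run_is_no_event(self):
        k = min_event_frames(2.0, 5.0)  # 10 frames
        flags = [1] * (k - 1)
        assert segment_events(flags, fps=5.0, tau=2.0) == []

    def test_gap_tolerance_merges_runs(self):
        flags = [1, 1, 0, 1, 1, 1, 0]
        assert segment_events(flags, fps=1.0, tau=2.0, gap_tolerance=1) == [(0, 5)]

    def test_exact_tau_fps_product_not_inflated(self):
        # tau * fps = 2.0 * 25 = 50 exactly; a 50-frame run qualifies
        assert min_event_frames(2.0, 25.0) == 50

    def test_equals_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            flags = rng.random(n) < rng.uniform(0.1, 0.9)
            k = int(rng.integers(1, 8))
            events = segment_events(flags, fps=1.0, tau=float(k))
            assert len(events) == oracle_count_runs(flags, k)
            # and every reported run is maximal and long enough
            for s, e in events:
                assert e - s + 1 >= k
                assert flags[s : e + 1].all()
                assert s == 0 or not flags[s - 1]
                assert e == n - 1 or not flags[e + 1]


def _event_video(gt=None, dets=None, n_frames=30, fps=1.0):
    return make_video(n_frames=n_frames, fps=fps, gt=gt or {}, dets=dets or {})


class TestClassifyEvent:
    def test_event_on_negative_frames_is_fp(self):
        dets = {i: [(100, 100, 120, 120, 0.9)] for i in range(3)}
        video = _event_video(dets=dets)
        ev = classify_event((0, 2), video, 0.5, 0.2, 3.0, [], "any_box")
        assert ev.label == "FP"
        assert ev.duration_s == 3.0

    def test_event_within_sigma_is_tp(self):
        # polyp appears at frame 10; event starts at frame 11 (1 s later)
        gt = {i: [(0, 0, 20, 20, "p")] for i in range(10, 20)}
        dets = {i: [(0, 0, 20, 20, 0.9)] for i in range(11, 15)}
        video = _event_video(gt=gt, dets=dets)
        tracks = derive_polyp_tracks([video])
        ev = classify_event((11, 14), video, 0.5, 0.2, 3.0, tracks, "any_box")
        assert ev.label == "TP"
        assert ev.matched_polyp_ids == {"p"}

    def test_event_after_window_is_not_tp(self):
        gt = {i: [(0, 0, 20, 20, "p")] for i in range(10, 25)}
        dets = {i: [(0, 0, 20, 20, 0.9)] for i in range(15, 20)}  # starts 5 s late
        video = _event_video(gt=gt, dets=dets)
        tracks = derive_polyp_tracks([video])
        ev = classify_event((15, 19), video, 0.5, 0.2, 3.0, tracks, "any_box")
        assert ev.label == "mixed"
        assert not ev.matched_polyp_ids

    def test_any_box_vs_all_boxes_on_partial_overlap(self):
        gt = {10: [(0, 0, 20, 20, "p")], 11: [(0, 0, 20, 20, "p")]}
        dets = {
            10: [(0, 0, 20, 20, 0.9)],  # overlaps the polyp
            11: [(200, 200, 220, 220, 0.9)],  # far away
        }
        video = _event_video(gt=gt, dets=dets)
        tracks = derive_polyp_tracks([video])
        any_ev = classify_event((10, 11), video, 0.5, 0.2, 3.0, tracks, "any_box")
        all_ev = classify_event((10, 11), video, 0.5, 0.2, 3.0, tracks, "all_boxes")
        assert any_ev.label == "TP"
        assert all_ev.label == "mixed"

    def test_event_starting_before_onset_may_match(self):
        # an ongoing run that locks onto the polyp when it appears
        gt = {i: [(0, 0, 20, 20, "p")] for i in range(10, 15)}
        dets = {i: [(300, 300, 320, 320, 0.9)] for i in range(5, 10)}
        dets.update({i: [(0, 0, 20, 20, 0.9)] for i in range(10, 13)})
        video = _event_video(gt=gt, dets=dets)
        tracks = derive_polyp_tracks([video])
        ev = classify_event((5, 12), video, 0.5, 0.2, 3.0, tracks, "any_box")
        assert ev.label == "TP"


class TestFpEventsPerPatient:
    def test_silent_detector(self):
        assert fp_events_per_patient([_event_video()], 0.5, 1.0) == 0.0

    def test_mean_over_videos(self):
        def fp_video(vid, n_events):
            dets = {}
            for e in range(n_events):
                for i in range(e * 5, e * 5 + 2):
                    dets[i] = [(100, 100, 120, 120, 0.9)]
            return make_video(vid, n_frames=30, dets=dets)

        videos = [fp_video("v1", 3), fp_video("v2", 1)]
        assert fp_events_per_patient(videos, 0.5, 2.0) == 2.0

    def test_fp_events_on_positive_frames_count(self):
        # boxes present but all off-polyp: still a FP event
        gt = {i: [(0, 0, 20, 20, "p")] for i in range(5)}
        dets = {i: [(200, 200, 220, 220, 0.9)] for i in range(5)}
        video = _event_video(gt=gt, dets=dets, n_frames=10)
        assert fp_events_per_patient([video], 0.5, 2.0) == 1.0


class TestPerPolypRecall:
    def test_perfect_continuous_detection(self):
        gt = {i: [(0, 0, 20, 20, "p")] for i in range(5, 15)}
        dets = {i: [(0, 0, 20, 20, 0.9)] for i in range(5, 15)}
        video = _event_video(gt=gt, dets=dets)
        tracks = derive_polyp_tracks([video])
        assert per_polyp_recall([video], tracks, 0.5, 1.0, 3.0) == 1.0

    def test_no_detections(self):
        gt = {i: [(0, 0, 20, 20, "p")] for i in range(5, 15)}
        video = _event_video(gt=gt)
        tracks = derive_polyp_tracks([video])
        assert per_polyp_recall([video], tracks, 0.5, 1.0, 3.0) == 0.0

    def test_half_of_four_tracks(self):
        gt = {}
        dets = {}
        starts = {"a": 0, "b": 20, "c": 40, "d": 60}
        for pid, s in starts.items():
            for i in range(s, s + 10):
                gt.setdefault(i, []).append((0, 0, 20, 20, pid))
        for pid in ("a", "c"):
            for i in range(starts[pid], starts[pid] + 5):
                dets.setdefault(i, []).append((0, 0, 20, 20, 0.9))
        video = _event_video(gt=gt, dets=dets, n_frames=80)
        tracks = derive_polyp_tracks([video])
        assert len(tracks) == 4
        assert per_polyp_recall([video], tracks, 0.5, 2.0, 3.0) == 0.5

    def test_zero_tracks_rejected(self):
        with pytest.raises(ValueError):
            per_polyp_recall([_event_video()], [], 0.5, 1.0, 3.0)


@pytest.fixture(scope="module")
def sim():
    return simulate_dataset(SimConfig(n_videos=3, fps=5.0, video_len_s=180.0, seed=21))


class TestFrocSweep:

    def test_delta_sweep_monotone_on_fixture(self, sim):
        videos, tracks = sim
        pts = froc_sweep(videos, tracks, "delta")
        recalls = [p.per_polyp_recall for p in pts]
        fps_ = [p.avg_fp_events_per_patient for p in pts]
        assert recalls == sorted(recalls, reverse=True)
        assert fps_ == sorted(fps_, reverse=True)

    def test_tau_sweep_monotone(self, sim):
        videos, tracks = sim
        pts = froc_sweep(videos, tracks, "tau")
        assert len(pts) == len(DEFAULT_TAU_GRID) == 15
        recalls = [p.per_polyp_recall for p in pts]
        fps_ = [p.avg_fp_events_per_patient for p in pts]
        assert recalls == sorted(recalls, reverse=True)
        assert fps_ == sorted(fps_, reverse=True)

    def test_sigma_sweep_recall_up_fp_constant(self, sim):
        videos, tracks = sim
        pts = froc_sweep(videos, tracks, "sigma")
        assert len(pts) == len(DEFAULT_SIGMA_GRID)
        recalls = [p.per_polyp_recall for p in pts]
        assert recalls == sorted(recalls)
        assert len({p.avg_fp_events_per_patient for p in pts}) == 1

    def test_ssp_restriction_never_increases_fp_events(self, sim):
        videos, tracks = sim
        vmap = {v.video_id: v for v in videos}
        masks = split_frame_masks(rc_ssp(videos, tracks), vmap)
        for delta in (0.1, 0.4, 0.7):
            full = fp_events_per_patient(videos, delta, 1.0)
            restricted = fp_events_per_patient(videos, delta, 1.0, frame_masks=masks)
            assert restricted <= full

    def test_unknown_sweep_rejected(self, sim):
        videos, tracks = sim
        with pytest.raises(ValueError):
            froc_sweep(videos, tracks, "gamma")


def test_recall_one_for_instant_sensitive_detector_when_sigma_ge_tau():
    """A detector firing on every annotated frame from polyp onset gives
    per-polyp recall 1.0 whenever sigma >= tau (tracks last > tau)."""
    cfg = SimConfig(
        n_videos=2, fps=5.0, video_len_s=120.0, p_d=1.0, p_f=0.0, rho=0.0, seed=3
    )
    videos, tracks = simulate_dataset(cfg)
    for tau in (0.4, 1.0):
        for sigma in (tau, 2 * tau, 5.0):
            assert per_polyp_recall(videos, tracks, 0.0, tau, sigma) == 1.0
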