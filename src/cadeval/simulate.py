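"""Synthetic full-procedure detector-stream simulator.

Generates videos that reproduce the statistical structure the event
metrics assume: a handful of polyp tracks with first/last appearance
times embedded in a long, mostly-negative procedure; per-positive-frame
detection with sensitivity ``p_d``; temporally correlated false-positive
bursts at per-negative-frame rate ``p_f``; and separable score
distributions for true and false detections.  The temporal correlation
is a two-state Markov chain on the emit/no-emit state: with probability
``rho`` the previous state repeats, otherwise the state is redrawn
Bernoulli, so the stationary emission rate stays at the nominal
probability while ``rho`` lengthens runs (burstiness).

Also provides the brute-force run-counting oracle and the closed-form
expectation of FP event counts under i.i.d. frame flags, used to
cross-check the event machinery.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .model import FrameRecord, GTBox, PolypTrack, ScoredBox, VideoRecord

__all__ = [
    "SimConfig",
    "simulate_procedure",
    "simulate_dataset",
    "oracle_count_runs",
    "expected_fp_events",
    "enumerate_expected_fp_events",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated colonoscopy procedure.

    Defaults emulate a realistic deployment scenario scaled to desk
    size: a 10-minute procedure at 10 fps with 3 polyps whose on-screen
    tracks last ~10 s (lognormal), a detector with 60% per-positive-
    frame sensitivity, a 2% per-negative-frame FP rate with strong
    temporal persistence (rho=0.9 at 10 fps makes FP bursts last about
    one second, the scale reported for deployed CADe alerts), and
    TP/FP scores drawn from
    Beta(8, 2) / Beta(2, 8) so that delta sweeps exercise the full
    FROC range.  Roughly 95% of frames are negative, mirroring the
    dominance of non-polyp scenes in full procedures.
    """

    n_videos: int = 4
    fps: float = 10.0
    video_len_s: float = 600.0
    n_polyps_per_video: int = 3
    track_mean_log_s: float = math.log(10.0)  # lognormal median 10 s
    track_sigma_log: float = 0.5
    p_d: float = 0.6
    p_f: float = 0.02
    rho: float = 0.9
    tp_score_ab: tuple[float, float] = (8.0, 2.0)
    fp_score_ab: tuple[float, float] = (2.0, 8.0)
    image_size: tuple[int, int] = (1920, 1080)  # (width, height) px
    box_mean_log_px: float = math.log(120.0)  # lognormal median side 120 px
    box_sigma_log: float = 0.4
    # occlusion/poor-framing gaps: annotation dropout inside a track,
    # after an initial continuously-annotated onset window
    gt_dropout: float = 0.05
    onset_continuous_s: float = 2.0
    jitter_frac: float = 0.15  # guarantees IoU >= 0.2 vs GT (see methods)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_d", "p_f", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fps <= 0 or self.video_len_s <= 0:
            raise ValueError("fps and video_len_s must be positive")
        if not 0.0 <= self.jitter_frac < 0.5:
            raise ValueError("jitter_frac must lie in [0, 0.5)")


def _markov_flags(rng: np.random.Generator, n: int, p: float, rho: float) -> np.ndarray:
    """Binary sequence with stationary rate p and persistence rho."""
    flags = np.empty(n, dtype=bool)
    if n == 0:
        return flags
    flags[0] = rng.random() < p
    repeat = rng.random(n) < rho
    fresh = rng.random(n) < p
    for i in range(1, n):
        flags[i] = flags[i - 1] if repeat[i] else fresh[i]
    return flags


def _run_correlated_scores(
    rng: np.random.Generator,
    flags: np.ndarray,
    ab: tuple[float, float],
    jitter_sd: float = 0.03,
) -> np.ndarray:
    """Per-frame scores, correlated within each emission run.

    One Beta(ab) base score per maximal run of True flags, plus small
    per-frame Gaussian jitter: a burst comes from one (true or
    confounding) structure, so its confidence varies slowly, and a
    score threshold passes or rejects the burst as a whole.
    """
    n = len(flags)
    scores = np.zeros(n)
    i = 0
    while i < n:
        if flags[i]:
            base = rng.beta(*ab)
            while i < n and flags[i]:
                scores[i] = float(np.clip(base + rng.normal(0.0, jitter_sd), 0.0, 1.0))
                i += 1
        else:
            i += 1
    return scores


def _clip_box(x1, y1, x2, y2, w, h):
    return max(x1, 0.0), max(y1, 0.0), min(x2, float(w)), min(y2, float(h))


def _sample_gt_box(rng: np.random.Generator, cfg: SimConfig) -> tuple[float, ...]:
    w_img, h_img = cfg.image_size
    side_x = float(np.exp(rng.normal(cfg.box_mean_log_px, cfg.box_sigma_log)))
    side_y = float(np.exp(rng.normal(cfg.box_mean_log_px, cfg.box_sigma_log)))
    side_x = min(max(side_x, 10.0), w_img / 2)
    side_y = min(max(side_y, 10.0), h_img / 2)
    x1 = rng.uniform(0, w_img - side_x)
    y1 = rng.uniform(0, h_img - side_y)
    return x1, y1, x1 + side_x, y1 + side_y


def _jittered_detection(rng, gt: GTBox, cfg: SimConfig, score: float) -> ScoredBox:
    # translation by < jitter_frac of each side keeps IoU comfortably
    # above the 0.2 working threshold: (1-j)^2 / (2-(1-j)^2) >= 0.2
    # holds for all j < 0.5 at j = 0.15 with margin.
    dx = rng.uniform(-cfg.jitter_frac, cfg.jitter_frac) * gt.width
    dy = rng.uniform(-cfg.jitter_frac, cfg.jitter_frac) * gt.height
    w_img, h_img = cfg.image_size
    x1, y1, x2, y2 = _clip_box(
        gt.x1 + dx, gt.y1 + dy, gt.x2 + dx, gt.y2 + dy, w_img, h_img
    )
    return ScoredBox(x1, y1, x2, y2, score)


def _sample_fp_box(
    rng, cfg: SimConfig, gts: Sequence[GTBox], score: float
) -> ScoredBox:
    from .matching import iou

    w_img, h_img = cfg.image_size
    for _ in range(200):
        x1, y1, x2, y2 = _sample_gt_box(rng, cfg)
        box = ScoredBox(x1, y1, x2, y2, score)
        if all(iou(box, g) < 0.05 for g in gts):
            return box
    raise RuntimeError("could not place a FP box clear of all GT boxes")


def _place_tracks(
    rng: np.random.Generator, cfg: SimConfig, n_frames: int, video_id: str
) -> list[tuple[str, int, int]]:
    """Non-overlapping (polyp_id, first, last) intervals, uniform placement."""
    placed: list[tuple[int, int]] = []
    out = []
    for p in range(cfg.n_polyps_per_video):
        dur_s = float(np.exp(rng.normal(cfg.track_mean_log_s, cfg.track_sigma_log)))
        dur = max(1, min(int(round(dur_s * cfg.fps)), n_frames))
        for _ in range(500):
            first = int(rng.integers(0, n_frames - dur + 1))
            last = first + dur - 1
            if all(last < lo or first > hi for lo, hi in placed):
                placed.append((first, last))
                out.append((f"{video_id}_p{p}", first, last))
                break
        else:
            raise RuntimeError(
                "could not place polyp tracks without overlap; lower the polyp "
                "rate or track duration"
            )
    return sorted(out, key=lambda t: t[1])


def simulate_procedure(cfg: SimConfig, video_id: str = "sim000") -> VideoRecord:
    """Simulate one full-procedure video with GT and detections attached.

    Deterministic given (cfg.seed, video_id): identical inputs yield
    byte-identical streams.
    """
    # crc32 gives a process-stable per-video stream offset
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, zlib.crc32(video_id.encode()) % 2**31])
    )
    n_frames = int(round(cfg.video_len_s * cfg.fps))
    tracks = _place_tracks(rng, cfg, n_frames, video_id)

    # one GT box per annotated frame per polyp, drifting slowly
    gt_per_frame: dict[int, list[GTBox]] = {}
    w_img, h_img = cfg.image_size
    onset_frames = int(round(cfg.onset_continuous_s * cfg.fps))
    for pid, first, last in tracks:
        x1, y1, x2, y2 = _sample_gt_box(rng, cfg)
        w_box, h_box = x2 - x1, y2 - y1
        for f in range(first, last + 1):
            dx, dy = rng.normal(0.0, 1.0, size=2)
            x1 = min(max(x1 + dx, 0.0), w_img - w_box)
            y1 = min(max(y1 + dy, 0.0), h_img - h_box)
            # occlusion gap: skip annotation, but never during the onset
            # window or on the track's final frame
            in_onset = f - first < onset_frames
            if not in_onset and f != last and rng.random() < cfg.gt_dropout:
                continue
            gt_per_frame.setdefault(f, []).append(
                GTBox(x1, y1, x1 + w_box, y1 + h_box, pid)
            )

    positive = np.zeros(n_frames, dtype=bool)
    for f in gt_per_frame:
        positive[f] = True

    det_flags_pos = _markov_flags(rng, n_frames, cfg.p_d, cfg.rho)
    det_flags_neg = _markov_flags(rng, n_frames, cfg.p_f, cfg.rho)
    tp_scores = _run_correlated_scores(rng, det_flags_pos, cfg.tp_score_ab)
    fp_scores = _run_correlated_scores(rng, det_flags_neg, cfg.fp_score_ab)

    frames: list[FrameRecord] = []
    for f in range(n_frames):
        gts = gt_per_frame.get(f, [])
        dets: list[ScoredBox] = []
        if positive[f]:
            if det_flags_pos[f]:
                for g in gts:
                    dets.append(_jittered_detection(rng, g, cfg, tp_scores[f]))
        else:
            if det_flags_neg[f]:
                dets.append(_sample_fp_box(rng, cfg, gts, fp_scores[f]))
        frames.append(FrameRecord(video_id, f, gts, dets))
    return VideoRecord(video_id=video_id, fps=cfg.fps, frames=frames)


def simulate_dataset(cfg: SimConfig) -> tuple[list[VideoRecord], list[PolypTrack]]:
    """Simulate ``cfg.n_videos`` procedures and derive their polyp tracks."""
    from .model import derive_polyp_tracks

    videos = [simulate_procedure(cfg, f"sim{i:03d}") for i in range(cfg.n_videos)]
    return videos, derive_polyp_tracks(videos)


def oracle_count_runs(flags: Sequence[bool], k: int) -> int:
    """Count maximal runs of True of length >= k by naive linear scan.

    Intentionally simple — the verification oracle for the event
    segmentation, independent of :func:`cadeval.events.segment_events`.
    """
    flags = list(bool(f) for f in flags)
    n = len(flags)
    count = 0
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            # [i, j] is maximal: flags[i-1] and flags[j+1] are False/absent
            if j - i + 1 >= k:
                count += 1
            i = j + 1
        else:
            i += 1
    return count


def expected_fp_events(n: int, p: float, k: int) -> float:
    """Expected number of maximal True-runs of length >= k in n i.i.d.
    Bernoulli(p) flags: p^k * (1 + (n - k) * (1 - p)).

    A qualifying run starts at position 0 with probability p^k, or at
    position i >= 1 with probability (1-p) * p^k; there are n - k such
    interior start positions.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return p**k * (1 + (n - k) * (1 - p))


def enumerate_expected_fp_events(n: int, p: float, k: int) -> float:
    """Exhaustive-enumeration oracle for :func:`expected_fp_events`.

    Sums P(sequence) * oracle_count_runs(sequence, k) over all 2^n flag
    sequences; tractable for n <= ~16.
    """
    if n > 20:
        raise ValueError("exhaustive enumeration is intended for small n")
    total = 0.0
    for bits in product((False, True), repeat=n):
        m = sum(bits)
        prob = (p**m) * ((1 - p) ** (n - m))
        total += prob * oracle_count_runs(bits, k)
    return total
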