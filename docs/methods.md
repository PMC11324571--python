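# Methods

This note documents the models, conventions and numerical choices
behind `cadeval`, and what its synthetic test substrate does and does
not establish about behavior on real colonoscopy data.

## Geometry and timing conventions

Boxes are continuous pixel rectangles (x1, y1, x2, y2) at native image
resolution with area (x2−x1)(y2−y1); no inclusive-pixel (+1)
correction is applied, so IoU arithmetic is exact for hand-checkable
examples and consistent with COCO-style area handling. Pascal VOC's
1-based inclusive corners are converted on load by subtracting 1 from
xmin/ymin.

Frames are 0-indexed and gap-free within a video; frame *i* covers
[i/fps, (i+1)/fps) seconds, so a run of *k* frames spans k/fps
seconds and "an event spanning τ seconds" means a run of at least
k = ⌈τ·fps⌉ frames (computed with a 1e−9 guard so exact products such
as 2.0 × 25 are not inflated by floating-point noise). fps is a
manifest field, never inferred: event metrics are meaningless without
it, and full-procedure recordings from different sites differ in frame
rate.

"Score exceeding δ" is implemented inclusively (score ≥ δ) so that
δ = 0 means "keep every detection" exactly; likewise "IoU exceeding
the threshold" is IoU ≥ threshold.

## Matching and per-box AP

Within a frame, detections are matched to GT greedily in descending
score order (ties broken by larger IoU, then input order), each
claiming the unmatched GT of highest IoU ≥ threshold — the COCO
convention. Greedy matching can in principle fall one short of the
optimal assignment (a high-score box claiming the only GT another box
could use); randomized tests against an optimal-assignment oracle
bound how rarely this occurs and the suite logs any shortfall.

AP uses all-point interpolation: AP = Σₙ (Rₙ−Rₙ₋₁)·P_interp(Rₙ) with
P_interp(R) the maximum precision at recall ≥ R and R₀ = 0, evaluated
at every detection rank. This follows the summation definition
literally rather than pycocotools' 101-point recall sampling; the two
typically agree within ~0.01. The PR ranking is global across the
dataset, with per-frame matching replayed in rank order so a
lower-ranked detection can only claim GTs left by higher ranks.
Precision at zero predictions is defined as 1.0 (the 0/0 corner), so
PR curves start at the top-left. Size stratification (small < 100 px,
medium < 200 px by max side; √area optionally) partitions GT boxes; a
detection matched to an out-of-class GT is excluded from that class's
curve, and unmatched detections count as FP in the class of their own
size.

## Per-frame classification

The four frame classes partition frames by GT presence first: a frame
with polyps is TP only if *every* polyp is matched (else FN) — a
positive frame with extra spurious boxes therefore stays TP/FN and is
never FP. This is a documented decision for mixed frames, which the
four-way definition alone does not settle. The default δ grid for ROC
is the set of distinct detection scores, subsampled to ≤ 256 values
plus {0, 1}; AUC is trapezoidal over the achieved (FPR, TPR) points
with (0,0)/(1,1) anchors appended.

## Event metrics

Events are formed at frame granularity: a frame is detection-positive
when ≥ 1 box clears δ. One event per maximal qualifying run — an
uninterrupted false activation reads as a single alert to the
endoscopist, not ⌊duration/τ⌋ alerts. `gap_tolerance` (default 0,
strict consecutiveness) merges runs separated by at most that many
negative frames before applying the length test, because deployed UIs
often debounce.

An event is a FP event iff every box in it fails IoU ≥ 0.2 (default)
against every GT box of its frame — including events on annotated
frames whose boxes are all off-polyp. A TP event for polyp *p*
requires the event to start no later than σ seconds after *p*'s first
annotated appearance; an event that begins *before* onset (an ongoing
run that locks onto the polyp) may qualify, since matching is only
evaluated at frames where *p* is annotated. Two overlap modes exist
because the operational and the strict reading of "the event's boxes
overlap the polyp" differ: `any_box` (default; one overlapping box
suffices) and `all_boxes` (every box must overlap some GT, at least
one overlapping *p*). Events neither FP nor TP are labeled `mixed`,
reported separately, and counted in neither the FP average nor the
recall numerator.

Guaranteed monotonicities — FP events and recall non-increasing in τ,
recall non-decreasing in σ, FP count independent of σ — are asserted
as hard properties. Monotonicity in δ is *not* a theorem (raising δ
can split one long run into two qualifying runs), and the
start-stop-polyp restriction can likewise split a run across an
interval boundary; both hold as strong empirical trends and are
asserted on seeded simulation fixtures only.

## Splits

Count-level splits (the unified training set) are pure sums of
published per-dataset counts; a source whose polyp count is reported
as unclear propagates `None` rather than a guess. Frame-level splits
operate on loaded videos: "first five videos per cohort" orders by
lexicographic video id (the source numbering); the start-stop-polyp
view keeps the union of [first, last] annotation intervals per video;
per-polyp subsampling draws uniformly without replacement per track
(min(n, available)) plus a global ⌊fraction × negatives⌋ random
negative sample, reproducible from a seed. Uniform-random sampling and
global (not per-video) negative draws are choices, recorded here
because the source procedures do not specify them.

## The simulator

`SimConfig` defaults define the study conditions: 4 procedures of
600 s at 10 fps (scaled-down full procedures; desk-size but two orders
of magnitude above the event-length scale), 3 polyp tracks per video
with lognormal(ln 10, 0.5) durations in seconds placed uniformly
without overlap, per-positive-frame sensitivity p_d = 0.6, per-
negative-frame FP rate p_f = 0.02, and persistence ρ = 0.9 on the
binary emit state (a two-state Markov chain: repeat with probability
ρ, else redraw Bernoulli — stationary rate stays at the nominal
probability while runs lengthen). At 10 fps, ρ = 0.9 makes FP bursts
last about a second, the scale reported for deployed CADe alert
events; ~95% of frames are negative, mirroring the dominance of
non-polyp scenes. Scores are Beta(8, 2) for true and Beta(2, 8) for
false detections — separated enough that δ sweeps traverse the full
FROC range — drawn once per emission run with small per-frame jitter
(σ = 0.03), because a burst originates from one structure whose
confidence varies slowly; i.i.d. per-frame scores would let a
threshold shred bursts into sub-τ fragments, which is not how
persistent false structures behave.

True detections are the GT box translated by at most 15% of each side,
which bounds IoU ≥ (0.85²)/(2−0.85²) ≈ 0.57 — comfortably above the
0.2 working threshold, so simulated TPs are unambiguous. FP boxes are
placed by rejection sampling to IoU < 0.05 against all GT of their
frame, so simulated FPs are unambiguous too. Tracks are continuously
annotated for their first 2 s and on their final frame; afterwards
each frame is dropped with probability 0.05 to emulate occlusion and
poor-framing gaps (this also puts negative frames *inside* polyp
intervals, so the start-stop-polyp restriction is non-trivial).
Everything is deterministic given (seed, video id), with per-video
streams derived via CRC32 so determinism survives process restarts.

What passing tests show: the metric implementations are correct
against independent oracles (brute-force run scanning, exhaustive
enumeration of the FP-event expectation p^k(1+(n−k)(1−p)) — validated
against the 2^n enumeration before use — and optimal-assignment
matching), and their monotone structure holds under realistic run
statistics. What they do not show: anything about appearance-driven
failure modes (debris, illumination, endoscope motion), detector score
calibration on real video, or the actual operating numbers of any real
CADe system — the simulator models run structure and score separation,
not images.

## Problem sizes and tolerances

The default test substrate uses 2–4 videos of 120–600 s at 5–10 fps;
oracle suites use 1,000 random flag sequences, 300 random PR
instances (≤ 10 detections), exhaustive enumeration up to n = 12
frames, and Monte-Carlo at n = 10⁴ frames × 60 replicates compared
within 3 standard errors (with a Poisson SE floor √(E/reps) for cells
whose expectation is ~10⁻³ and whose sample variance degenerates to
zero). The chance-level AUC check uses 10⁴ frames and a ±0.02 band.

## Known limitations

- Cross-video polyp identity is out of scope; polyp ids are
  namespaced per video.
- Tracking-based (box-level) event association is not implemented;
  events are frame-level constructs, the only form computable from
  per-frame annotations.
- Greedy matching is the COCO convention, not an optimal assignment;
  see above for the bound on the difference.
- The simulator emits at most one FP box per negative frame; FP *box*
  density is not modeled beyond the event level the metrics consume.
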