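# cadeval

Clinic-oriented evaluation of video polyp-detection (CADe) systems.

Computer-aided detection systems for colonoscopy overlay candidate
polyp boxes on the live video feed. Classical object-detection metrics
— per-box average precision, per-frame ROC — say little about what an
endoscopist experiences: how often the system raises a false alarm
during a procedure, and whether it flags a polyp in the first seconds
it is on screen, when an early alert can prevent a miss. `cadeval`
implements both families of metrics over full-procedure videos, plus
the dataset-split bookkeeping and a synthetic detector-stream
simulator that makes every metric testable without clinical data.

It is a library first (importable API + `examples/`), with a thin
`cadeval` command-line wrapper for pipeline use.

## The metrics

**Per-box.** A predicted box *B* with score ≥ δ matches a ground-truth
box *GT* when IoU(B, GT) = |B∩GT| / |B∪GT| reaches a threshold.
Precision P = TP/(TP+FP) and recall R = TP/(TP+FN) over a global score
ranking give a PR curve; AP = Σₙ (Rₙ − Rₙ₋₁)·P_interp(Rₙ) with
all-point interpolation, averaged over IoU ∈ {0.50, 0.55, …, 0.95}
(AP₀.₅:₀.₉₅), with small/medium/large stratification of GT boxes
(< 100 px / < 200 px / rest).

**Per-frame.** A frame containing polyps is TP when *every* polyp is
matched at the working IoU (0.2), else FN; a polyp-free frame is FP
when any detection fires, else TN. TPR = TP/(TP+FN) against
FPR = FP/(FP+TN) over a δ sweep gives the ROC and its AUC.

**Per-polyp / per-patient (event level).** A *detection event* is a
maximal run of consecutive detection-positive frames spanning at least
τ seconds. An event whose boxes never reach IoU 0.2 against any GT is
a *FP event*; the mean count per video is the **average FP events per
patient**. An event that begins within σ seconds of a polyp's first
appearance and overlaps it is a TP event for that polyp; the fraction
of polyps with at least one TP event is the **per-polyp recall**.
Sweeping one of (δ, τ, σ) while fixing the others traces a FROC curve
of recall against FP events per patient.

## Worked example

`examples/02_event_metrics_froc.py` simulates four 10-minute
procedures at 10 fps (12 polyps in total) and evaluates the stream:

```
per-polyp recall within    3 s = 58.3%
per-polyp recall within   15 s = 100.0%
average FP events per patient at delta=0.6: 0.00

FROC (delta sweep, tau = 1 s, sigma = 3 s):
 delta   recall  FP/patient
   0.1     0.67        3.75
   0.2     0.67        1.75
   0.3     0.67        0.75
   ...
   0.9     0.00        0.00
```

Reading: at a permissive threshold (δ = 0.1) the simulated detector
finds two thirds of polyps within 3 s of appearance at the cost of
~4 false alerts per procedure; tightening δ silences the alerts and
then starts costing recall. Widening the response window σ raises
recall (to 100% at 15 s here) without changing the FP count — σ only
enters TP labeling. The other examples cover per-box/per-frame metrics
(`01`), split arithmetic (`03`), and the on-disk formats (`04`).

## Data in and out

Ground truth: COCO JSON, per-frame Pascal VOC XML
(`{video_id}_{frame_idx}.xml`), or a CSV dialect
(`video_id,frame_idx,x1,y1,x2,y2,polyp_id`). Detections: COCO results
JSON or CSV (`…,score`). Videos are described by a YAML/JSON manifest
carrying `video_id, cohort_id, fps, n_frames, gt_path, det_path` —
frame sequences must be gap-free, and fps is always explicit. The
simulator writes exactly these formats, closing the loop for
end-to-end tests:

```sh
cadeval simulate --out-dir data --seed 5 --n-videos 2
cadeval evaluate --manifest data/manifest.yaml --out report.json
cadeval froc     --manifest data/manifest.yaml --out froc.csv --plot froc.png --sweep delta
```

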