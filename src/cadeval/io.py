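"""Readers and writers for the standard annotation/detection formats.

Supported ground truth: COCO-style JSON (bbox = [x, y, w, h], corner
form internally), per-frame Pascal VOC XML (1-based inclusive pixel
coordinates, converted by subtracting 1 from xmin/ymin), and a CSV
dialect.  Detections: COCO results JSON ([{image_id, bbox, score}]) or
CSV.  CSV dialects (UTF-8, '.' decimal separator):

    ground truth: video_id,frame_idx,x1,y1,x2,y2,polyp_id
    detections:   video_id,frame_idx,x1,y1,x2,y2,score

Dataset manifests are YAML/JSON files with a ``videos`` list of
{video_id, cohort_id, fps, n_frames, gt_path, det_path}; fps is always
carried explicitly in the manifest, never inferred.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .model import FrameRecord, GTBox, ScoredBox, VideoRecord

__all__ = [
    "ManifestEntry",
    "load_manifest",
    "load_gt_coco",
    "load_gt_voc",
    "load_gt_csv",
    "load_detections",
    "attach_detections",
    "load_video",
    "write_gt_csv",
    "write_detections_csv",
    "write_gt_coco",
    "write_manifest",
]

DetMap = dict[tuple[str, int], list[ScoredBox]]

VOC_FILENAME_RE = re.compile(r"^(?P<video_id>.+)_(?P<frame_idx>\d+)\.xml$")


@dataclass(frozen=True)
class ManifestEntry:
    video_id: str
    fps: float
    n_frames: int
    cohort_id: str | None = None
    gt_path: str | None = None
    det_path: str | None = None


def load_manifest(path: str | Path) -> list[ManifestEntry]:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    if not isinstance(data, dict) or "videos" not in data:
        raise ValueError(f"manifest {path} must contain a 'videos' list")
    entries = []
    for v in data["videos"]:
        try:
            entries.append(
                ManifestEntry(
                    video_id=str(v["video_id"]),
                    fps=float(v["fps"]),
                    n_frames=int(v["n_frames"]),
                    cohort_id=v.get("cohort_id"),
                    gt_path=v.get("gt_path"),
                    det_path=v.get("det_path"),
                )
            )
        except KeyError as exc:
            raise ValueError(f"manifest {path}: video entry missing key {exc}") from exc
    return entries


def write_manifest(path: str | Path, entries: Sequence[ManifestEntry]) -> None:
    data = {
        "videos": [
            {
                "video_id": e.video_id,
                "cohort_id": e.cohort_id,
                "fps": e.fps,
                "n_frames": e.n_frames,
                "gt_path": e.gt_path,
                "det_path": e.det_path,
            }
            for e in entries
        ]
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=False)
        else:
            json.dump(data, fh, indent=1)


def _assemble_videos(
    boxes: Mapping[tuple[str, int], list[GTBox]],
    frames_per_video: Mapping[str, set[int]],
    fps: Mapping[str, float] | float,
    cohorts: Mapping[str, str] | None = None,
) -> list[VideoRecord]:
    videos = []
    for vid in sorted(frames_per_video):
        idxs = frames_per_video[vid]
        n = max(idxs) + 1
        missing = sorted(set(range(n)) - idxs)
        if missing:
            shown = ", ".join(map(str, missing[:10]))
            raise ValueError(
                f"video {vid!r}: frame indices must be gap-free 0..{n - 1}; "
                f"missing {shown}{'...' if len(missing) > 10 else ''}"
            )
        v_fps = fps[vid] if isinstance(fps, Mapping) else float(fps)
        frames = [
            FrameRecord(vid, i, gt=list(boxes.get((vid, i), []))) for i in range(n)
        ]
        videos.append(
            VideoRecord(
                video_id=vid,
                fps=v_fps,
                frames=frames,
                cohort_id=cohorts.get(vid) if cohorts else None,
            )
        )
    return videos


def load_gt_coco(
    path: str | Path,
    video_map: Mapping[int, tuple[str, int]],
    fps: Mapping[str, float] | float,
) -> list[VideoRecord]:
    """Load COCO-format ground truth into gap-free VideoRecords.

    ``video_map`` maps each COCO image id to (video_id, frame_idx);
    every image id in the file must be covered.  Annotation bboxes
    [x, y, w, h] are converted to corner form.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    for key in ("images", "annotations"):
        if key not in data:
            raise ValueError(f"COCO file {path} missing required key {key!r}")
    frames_per_video: dict[str, set[int]] = {}
    for img in data["images"]:
        img_id = img["id"]
        if img_id not in video_map:
            raise ValueError(f"image id {img_id} not covered by video_map")
        vid, idx = video_map[img_id]
        frames_per_video.setdefault(vid, set()).add(idx)
    boxes: dict[tuple[str, int], list[GTBox]] = {}
    for ann in data["annotations"]:
        img_id = ann["image_id"]
        if img_id not in video_map:
            raise ValueError(f"annotation {ann.get('id')} references unknown image id {img_id}")
        vid, idx = video_map[img_id]
        x, y, w, h = ann["bbox"]
        pid = str(ann.get("polyp_id", ann.get("instance_id", ann.get("id"))))
        boxes.setdefault((vid, idx), []).append(GTBox(x, y, x + w, y + h, pid))
    return _assemble_videos(boxes, frames_per_video, fps)


def load_gt_voc(
    directory: str | Path,
    fps: Mapping[str, float] | float,
    n_frames: Mapping[str, int] | None = None,
) -> list[VideoRecord]:
    """Load per-frame Pascal VOC XML ground truth from a directory.

    Filenames follow ``{video_id}_{frame_idx}.xml``.  A file without
    <object> elements is a negative frame; two files mapping to the
    same (video, frame) are an error.  VOC's 1-based inclusive corners
    become the internal convention by subtracting 1 from xmin/ymin.
    ``n_frames`` extends videos with trailing negative frames beyond
    the last XML file (VOC dumps often omit them).
    """
    directory = Path(directory)
    frames_per_video: dict[str, set[int]] = {}
    boxes: dict[tuple[str, int], list[GTBox]] = {}
    for f in sorted(directory.glob("*.xml")):
        m = VOC_FILENAME_RE.match(f.name)
        if not m:
            raise ValueError(
                f"VOC filename {f.name!r} does not match '{{video_id}}_{{frame_idx}}.xml'"
            )
        vid = m.group("video_id")
        idx = int(m.group("frame_idx"))
        if idx in frames_per_video.get(vid, set()):
            raise ValueError(f"duplicate VOC file for video {vid!r} frame {idx}")
        frames_per_video.setdefault(vid, set()).add(idx)
        try:
            root = ET.parse(f).getroot()
        except ET.ParseError as exc:
            raise ValueError(f"unparseable VOC XML {f}: {exc}") from exc
        for obj in root.iter("object"):
            bnd = obj.find("bndbox")
            if bnd is None:
                raise ValueError(f"{f}: <object> without <bndbox>")
            xmin = float(bnd.findtext("xmin")) - 1
            ymin = float(bnd.findtext("ymin")) - 1
            xmax = float(bnd.findtext("xmax"))
            ymax = float(bnd.findtext("ymax"))
            name = obj.findtext("name") or "polyp"
            boxes.setdefault((vid, idx), []).append(GTBox(xmin, ymin, xmax, ymax, name))
    if n_frames:
        for vid, n in n_frames.items():
            frames_per_video.setdefault(vid, set()).update(range(n))
    return _assemble_videos(boxes, frames_per_video, fps)


def load_gt_csv(
    path: str | Path,
    fps: Mapping[str, float] | float,
    n_frames: Mapping[str, int] | None = None,
) -> list[VideoRecord]:
    """Load ground truth from the CSV dialect.

    ``n_frames`` names the videos to load and their lengths (negative
    frames carry no CSV row, so lengths cannot be inferred); rows for
    other videos in a shared file are ignored.
    """
    df = pd.read_csv(
        path, dtype={"video_id": str, "polyp_id": str}, float_precision="round_trip"
    )
    expected = ["video_id", "frame_idx", "x1", "y1", "x2", "y2", "polyp_id"]
    if list(df.columns) != expected:
        raise ValueError(f"GT CSV {path} must have columns {expected}, got {list(df.columns)}")
    if n_frames is None:
        raise ValueError("GT CSV loading requires n_frames (frames with no boxes are implicit)")
    boxes: dict[tuple[str, int], list[GTBox]] = {}
    frames_per_video = {vid: set(range(n)) for vid, n in n_frames.items()}
    for row in df.itertuples(index=False):
        vid, idx = row.video_id, int(row.frame_idx)
        if vid not in frames_per_video:
            continue
        if idx not in frames_per_video[vid]:
            raise ValueError(f"GT CSV row for video {vid!r} frame {idx} outside n_frames")
        boxes.setdefault((vid, idx), []).append(
            GTBox(row.x1, row.y1, row.x2, row.y2, row.polyp_id)
        )
    return _assemble_videos(boxes, frames_per_video, fps)


def load_detections(path: str | Path, video_map: Mapping[int, tuple[str, int]] | None = None) -> DetMap:
    """Load detections from COCO results JSON or the CSV dialect.

    Returns a mapping (video_id, frame_idx) -> list of ScoredBox;
    frames without an entry have zero detections.
    """
    path = Path(path)
    out: DetMap = {}
    if path.suffix == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        for item in data:
            img_id = item["image_id"]
            if video_map is None:
                raise ValueError("COCO results need a video_map for image ids")
            if img_id not in video_map:
                raise ValueError(f"detection references unknown image id {img_id}")
            vid, idx = video_map[img_id]
            x, y, w, h = item["bbox"]
            if w <= 0 or h <= 0:
                raise ValueError(f"detection at image {img_id} has non-positive size")
            out.setdefault((vid, idx), []).append(
                ScoredBox(x, y, x + w, y + h, float(item["score"]))
            )
        return out
    df = pd.read_csv(path, dtype={"video_id": str}, float_precision="round_trip")
    if df.empty:
        return out
    expected = ["video_id", "frame_idx", "x1", "y1", "x2", "y2", "score"]
    if list(df.columns) != expected:
        raise ValueError(f"detection CSV {path} must have columns {expected}")
    for row in df.itertuples(index=False):
        out.setdefault((row.video_id, int(row.frame_idx)), []).append(
            ScoredBox(row.x1, row.y1, row.x2, row.y2, float(row.score))
        )
    return out


def attach_detections(videos: Iterable[VideoRecord], dets: DetMap) -> None:
    """Attach a detection map to loaded videos, in place."""
    known = set()
    for video in videos:
        for fr in video.frames:
            fr.dets = list(dets.get((video.video_id, fr.frame_idx), []))
            known.add((video.video_id, fr.frame_idx))
    stray = set(dets) - known
    if stray:
        raise ValueError(f"detections reference unknown frames: {sorted(stray)[:5]}")


def load_video(entry: ManifestEntry, base_dir: str | Path = ".") -> VideoRecord:
    """Materialize one manifest entry into a VideoRecord."""
    base = Path(base_dir)
    if entry.gt_path is None:
        raise ValueError(f"manifest entry {entry.video_id!r} has no gt_path")
    gt_path = base / entry.gt_path
    if gt_path.suffix == ".csv":
        videos = load_gt_csv(
            gt_path, fps={entry.video_id: entry.fps}, n_frames={entry.video_id: entry.n_frames}
        )
    elif gt_path.is_dir():
        videos = load_gt_voc(
            gt_path, fps={entry.video_id: entry.fps}, n_frames={entry.video_id: entry.n_frames}
        )
    else:
        raise ValueError(f"unsupported gt_path {gt_path}")
    matches = [v for v in videos if v.video_id == entry.video_id]
    if len(matches) != 1:
        raise ValueError(f"gt_path {gt_path} does not define video {entry.video_id!r}")
    video = matches[0]
    video.cohort_id = entry.cohort_id
    if entry.det_path is not None:
        dets = load_detections(base / entry.det_path)
        own = {k: v for k, v in dets.items() if k[0] == entry.video_id}
        attach_detections([video], own)
    return video


def write_gt_csv(path: str | Path, videos: Iterable[VideoRecord]) -> None:
    rows = [
        (v.video_id, fr.frame_idx, g.x1, g.y1, g.x2, g.y2, g.polyp_id)
        for v in videos
        for fr in v.frames
        for g in fr.gt
    ]
    # %.17g survives the text round trip bit-exactly for float64
    pd.DataFrame(
        rows, columns=["video_id", "frame_idx", "x1", "y1", "x2", "y2", "polyp_id"]
    ).to_csv(path, index=False, float_format="%.17g")


def write_detections_csv(path: str | Path, videos: Iterable[VideoRecord]) -> None:
    rows = [
        (v.video_id, fr.frame_idx, d.x1, d.y1, d.x2, d.y2, d.score)
        for v in videos
        for fr in v.frames
        for d in fr.dets
    ]
    pd.DataFrame(
        rows, columns=["video_id", "frame_idx", "x1", "y1", "x2", "y2", "score"]
    ).to_csv(path, index=False, float_format="%.17g")


def write_gt_coco(path: str | Path, videos: Sequence[VideoRecord]) -> dict[int, tuple[str, int]]:
    """Write ground truth as COCO JSON; returns the image-id map used."""
    images, annotations = [], []
    video_map: dict[int, tuple[str, int]] = {}
    img_id = 0
    ann_id = 0
    for v in videos:
        for fr in v.frames:
            img_id += 1
            video_map[img_id] = (v.video_id, fr.frame_idx)
            images.append({"id": img_id, "file_name": f"{v.video_id}_{fr.frame_idx}.png"})
            for g in fr.gt:
                ann_id += 1
                annotations.append(
                    {
                        "id": ann_id,
                        "image_id": img_id,
                        "category_id": 1,
                        "bbox": [g.x1, g.y1, g.width, g.height],
                        "area": g.area,
                        "polyp_id": g.polyp_id,
                        "iscrowd": 0,
                    }
                )
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "polyp"}],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
    return video_map
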