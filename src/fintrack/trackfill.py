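"""Gap-filling bounding-box tracker.

An upstream object detector localizes the animal with high confidence only in
a subset of frames.  This module turns those sparse high-confidence
detections ("anchors") into a complete per-frame track by template matching:
each maximal run of anchor-less frames (a *missing segment*) is filled by
tracking forward from the anchor immediately before it and backward from the
anchor immediately after it, each direction running to the segment midpoint.

The template tracker is deliberately simple and training-free: the template
is the pixel patch of the initializing anchor box, matched by zero-normalized
cross-correlation (ZNCC) against a local search window in each successive
frame.  Because missing segments are short and inter-frame motion is a few
pixels, a fixed template with a modest search radius is sufficient and avoids
drift from template updating.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage.feature import match_template

__all__ = [
    "BBox",
    "Detection",
    "MissingSegment",
    "TrackRecord",
    "Track",
    "select_anchors",
    "find_missing_segments",
    "track_template",
    "fill_segment",
    "build_track",
    "read_detections",
    "write_detections",
]

#: sources a per-frame box can come from
SOURCE_DETECTED = "detected"
SOURCE_FORWARD = "tracked_forward"
SOURCE_BACKWARD = "tracked_backward"


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box ``[x0, x1) x [y0, y1)`` in pixel coordinates.

    Origin is the image top-left corner, x rightward, y downward.
    """

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"invalid bbox: need x0<x1 and y0<y1, got {self.astuple()}"
            )
        if not all(map(math.isfinite, self.astuple())):
            raise ValueError("bbox coordinates must be finite")

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def translate(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def union(self, other: "BBox") -> "BBox":
        return BBox(
            min(self.x0, other.x0),
            min(self.y0, other.y0),
            max(self.x1, other.x1),
            max(self.y1, other.y1),
        )

    def inflate(self, frac: float) -> "BBox":
        """Grow the box by ``frac`` of its width/height on each side."""
        dx, dy = self.width * frac, self.height * frac
        return BBox(self.x0 - dx, self.y0 - dy, self.x1 + dx, self.y1 + dy)

    def clip(self, width: int, height: int) -> "BBox":
        """Clip to the image rectangle ``[0,width) x [0,height)``.

        Raises if the box lies fully outside the image.
        """
        x0, y0 = max(self.x0, 0.0), max(self.y0, 0.0)
        x1, y1 = min(self.x1, float(width)), min(self.y1, float(height))
        if not (x0 < x1 and y0 < y1):
            raise ValueError("bbox lies outside image bounds")
        return BBox(x0, y0, x1, y1)

    def round(self) -> tuple[int, int, int, int]:
        """Integer pixel bounds ``(ix0, iy0, ix1, iy1)`` (at least 1x1)."""
        ix0, iy0 = int(round(self.x0)), int(round(self.y0))
        ix1, iy1 = int(round(self.x1)), int(round(self.y1))
        return ix0, iy0, max(ix1, ix0 + 1), max(iy1, iy0 + 1)

    def intersection_area(self, other: "BBox") -> float:
        w = min(self.x1, other.x1) - max(self.x0, other.x0)
        h = min(self.y1, other.y1) - max(self.y0, other.y0)
        return max(w, 0.0) * max(h, 0.0)

    def iou(self, other: "BBox") -> float:
        inter = self.intersection_area(other)
        return inter / (self.area + other.area - inter)


@dataclass(frozen=True)
class Detection:
    """A detector output: frame index, box and confidence in [0, 1]."""

    frame: int
    bbox: BBox
    confidence: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be >= 0")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class MissingSegment:
    """Maximal run of frames [start, end] without an anchor detection."""

    start: int
    end: int
    pre_anchor: Optional[Detection] = None
    post_anchor: Optional[Detection] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")
        if self.pre_anchor is None and self.post_anchor is None:
            raise ValueError("segment needs at least one flanking anchor")
        if self.pre_anchor is not None and self.pre_anchor.frame != self.start - 1:
            raise ValueError("pre_anchor must sit at frame start-1")
        if self.post_anchor is not None and self.post_anchor.frame != self.end + 1:
            raise ValueError("post_anchor must sit at frame end+1")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TrackRecord:
    frame: int
    bbox: BBox
    source: str


@dataclass
class Track:
    """Complete per-frame track: exactly one box per frame, frames 0..n-1."""

    records: list[TrackRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.frame)
        frames = [r.frame for r in self.records]
        if frames != list(range(len(frames))):
            raise ValueError("track must have exactly one record per frame, "
                             "contiguous from 0")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> TrackRecord:
        return self.records[i]

    def __iter__(self):
        return iter(self.records)

    def bboxes(self) -> list[BBox]:
        return [r.bbox for r in self.records]

    def n_missing(self) -> int:
        """Frames lacking a bounding box — zero by construction."""
        return 0


# ---------------------------------------------------------------------------
# anchor selection and segment discovery


def select_anchors(
    detections: Iterable[Detection], conf_threshold: float = 0.70
) -> dict[int, Detection]:
    """Keep, per frame, the best detection with confidence strictly above
    ``conf_threshold``.

    Ties on confidence are broken by larger box area, then by input order.
    """
    if not 0.0 < conf_threshold <= 1.0:
        raise ValueError("conf_threshold must lie in (0, 1]")
    anchors: dict[int, Detection] = {}
    for det in detections:
        if det.confidence <= conf_threshold:
            continue
        cur = anchors.get(det.frame)
        if cur is None:
            anchors[det.frame] = det
        elif (det.confidence, det.bbox.area) > (cur.confidence, cur.bbox.area):
            anchors[det.frame] = det
    return anchors


def find_missing_segments(
    anchors: dict[int, Detection], n_frames: int
) -> list[MissingSegment]:
    """Maximal runs of anchor-less frames with their flanking anchors."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not anchors:
        raise ValueError("no high-confidence detections")
    segments: list[MissingSegment] = []
    run_start: Optional[int] = None
    for f in range(n_frames):
        if f in anchors:
            if run_start is not None:
                segments.append(
                    MissingSegment(
                        run_start,
                        f - 1,
                        pre_anchor=anchors.get(run_start - 1),
                        post_anchor=anchors[f],
                    )
                )
                run_start = None
        elif run_start is None:
            run_start = f
    if run_start is not None:
        segments.append(
            MissingSegment(run_start, n_frames - 1,
                           pre_anchor=anchors.get(run_start - 1),
                           post_anchor=None)
        )
    return segments


# ---------------------------------------------------------------------------
# template tracking


def _as_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return arr


def track_template(
    frames: Sequence[np.ndarray],
    init: Detection,
    target_frames: Sequence[int],
    search_radius: int,
) -> list[tuple[int, BBox]]:
    """Track ``init.bbox`` through ``target_frames`` by ZNCC matching.

    The template is frozen to the pixels of ``init.bbox`` in ``init.frame``.
    At each target frame the previous box is translated by the integer
    displacement (within +-``search_radius`` per axis) maximizing the
    zero-normalized cross-correlation; ZNCC ties are broken by smallest
    Euclidean displacement, then row-major order.  Box size stays constant.
    """
    if len(target_frames) == 0:
        return []
    img0 = _as_gray(frames[init.frame])
    h, w = img0.shape
    ix0, iy0, ix1, iy1 = init.bbox.round()
    tx0, ty0 = max(ix0, 0), max(iy0, 0)
    tx1, ty1 = min(ix1, w), min(iy1, h)
    if tx0 >= tx1 or ty0 >= ty1:
        raise ValueError("template bbox lies fully outside the image")
    template = img0[ty0:ty1, tx0:tx1]
    th, tw = template.shape
    r = int(search_radius)

    flat = float(np.ptp(template)) == 0.0
    if flat:
        warnings.warn("textureless template: falling back to zero displacement",
                      RuntimeWarning)

    out: list[tuple[int, BBox]] = []
    px, py = tx0, ty0  # current top-left, integer
    for f in target_frames:
        if not flat:
            img = _as_gray(frames[f])
            sx0, sy0 = max(px - r, 0), max(py - r, 0)
            sx1, sy1 = min(px + tw + r, w), min(py + th + r, h)
            region = img[sy0:sy1, sx0:sx1]
            if region.shape[0] >= th and region.shape[1] >= tw:
                corr = match_template(region, template, pad_input=False)
                best = corr.max()
                ii, jj = np.nonzero(corr >= best - 1e-9)
                # candidate top-lefts and their displacement from (px, py)
                dys = sy0 + ii - py
                dxs = sx0 + jj - px
                order = np.lexsort((jj, ii, dys * dys + dxs * dxs))
                k = order[0]
                px, py = int(sx0 + jj[k]), int(sy0 + ii[k])
            # else: search region smaller than template; keep position
        bbox = BBox(px, py, px + tw, py + th).clip(w, h)
        out.append((f, bbox))
    return out


def default_search_radius(anchor: Detection) -> int:
    """Half the anchor's characteristic length, floored at 10 px."""
    return max(10, int(round(0.5 * math.sqrt(anchor.bbox.area))))


def fill_segment(
    frames: Sequence[np.ndarray],
    seg: MissingSegment,
    search_radius: Optional[int] = None,
) -> list[tuple[int, BBox, str]]:
    """Fill a missing segment by forward+backward tracking to its midpoint.

    With ``mid = floor((start+end)/2)`` the forward pass (from the anchor
    before the segment) covers ``start..mid`` and the backward pass (from the
    anchor after it) covers ``end..mid+1``.  A single-anchor boundary segment
    is filled entirely from that side.
    """
    mid = (seg.start + seg.end) // 2
    filled: list[tuple[int, BBox, str]] = []
    if seg.pre_anchor is not None and seg.post_anchor is not None:
        fwd_frames = list(range(seg.start, mid + 1))
        bwd_frames = list(range(seg.end, mid, -1))
    elif seg.pre_anchor is not None:
        fwd_frames = list(range(seg.start, seg.end + 1))
        bwd_frames = []
    else:
        fwd_frames = []
        bwd_frames = list(range(seg.end, seg.start - 1, -1))

    if fwd_frames:
        r = search_radius or default_search_radius(seg.pre_anchor)
        for f, bbox in track_template(frames, seg.pre_anchor, fwd_frames, r):
            filled.append((f, bbox, SOURCE_FORWARD))
    if bwd_frames:
        r = search_radius or default_search_radius(seg.post_anchor)
        for f, bbox in track_template(frames, seg.post_anchor, bwd_frames, r):
            filled.append((f, bbox, SOURCE_BACKWARD))
    filled.sort(key=lambda t: t[0])
    return filled


def build_track(
    frames: Sequence[np.ndarray],
    detections: Iterable[Detection],
    conf_threshold: float = 0.70,
    search_radius: Optional[int] = None,
) -> Track:
    """Complete per-frame track from sparse detections.

    Anchor frames pass through unchanged (source ``detected``); every missing
    segment is filled by :func:`fill_segment`, so the output covers all
    frames of the video with zero missing detections.
    """
    n_frames = len(frames)
    if n_frames < 1:
        raise ValueError("video must have at least one frame")
    anchors = select_anchors(detections, conf_threshold)
    anchors = {f: d for f, d in anchors.items() if f < n_frames}
    segments = find_missing_segments(anchors, n_frames)
    records = [TrackRecord(f, d.bbox, SOURCE_DETECTED) for f, d in anchors.items()]
    for seg in segments:
        for f, bbox, source in fill_segment(frames, seg, search_radius):
            records.append(TrackRecord(f, bbox, source))
    return Track(records)


# ---------------------------------------------------------------------------
# detections file interface: CSV `frame,x0,y0,x1,y1,confidence`


def read_detections(path: str | Path) -> list[Detection]:
    """Read a detections CSV (header ``frame,x0,y0,x1,y1,confidence``)."""
    dets: list[Detection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"frame", "x0", "y0", "x1", "y1", "confidence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"detections file must have columns {sorted(required)}")
        for row in reader:
            dets.append(
                Detection(
                    frame=int(row["frame"]),
                    bbox=BBox(float(row["x0"]), float(row["y0"]),
                              float(row["x1"]), float(row["y1"])),
                    confidence=float(row["confidence"]),
                )
            )
    return dets


def write_detections(detections: Iterable[Detection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "x0", "y0", "x1", "y1", "confidence"])
        for d in detections:
            writer.writerow([d.frame, *d.bbox.astuple(), d.confidence])
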