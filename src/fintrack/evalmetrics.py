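"""Tracking evaluation: normalized PCK, detection failure rate, bbox IoU.

PCK (percentage of correct keypoints) scores a centroid track: the fraction
of frames whose predicted centroid lies within a threshold distance of the
ground truth, with the distance normalized by the *characteristic length* —
the square root of the ground-truth bounding-box area — so that the metric
is invariant to apparent body size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .trackfill import BBox, Track

__all__ = [
    "PCKCurve",
    "characteristic_length",
    "pck",
    "failure_rate",
    "trajectory_overlap",
    "evaluate_tracking",
]

#: threshold grid for PCK curves (normalized distance)
DEFAULT_PCK_THRESHOLDS = np.round(np.arange(0.0, 1.0001, 0.02), 2)


@dataclass(frozen=True)
class PCKCurve:
    thresholds: np.ndarray
    values: np.ndarray  # fraction of frames correct at each threshold
    n_frames: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("PCK values must lie in [0, 1]")
        if np.any(np.diff(v) < -1e-12):
            raise ValueError("PCK must be nondecreasing in the threshold")

    def at(self, tau: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - tau)))
        if not math.isclose(self.thresholds[idx], tau, abs_tol=1e-9):
            raise ValueError(f"threshold {tau} not on the curve grid")
        return float(self.values[idx])


def characteristic_length(bbox: BBox) -> float:
    """Square root of the bounding-box area, in pixels."""
    return math.sqrt(bbox.area)


def pck(
    pred_centroids: Sequence[Sequence[float]],
    gt_centroids: Sequence[Sequence[float]],
    gt_bboxes: Sequence[BBox],
    thresholds: Optional[np.ndarray] = None,
    normalize_by: str = "gt",
    pred_bboxes: Optional[Sequence[BBox]] = None,
) -> PCKCurve:
    """PCK curve of predicted vs ground-truth centroids.

    The per-frame distance is divided by the characteristic length of the
    ground-truth box (``normalize_by="pred"`` switches to the predicted box,
    in which case ``pred_bboxes`` is required).
    """
    pred = np.asarray(pred_centroids, dtype=float)
    gt = np.asarray(gt_centroids, dtype=float)
    if pred.shape != gt.shape or len(pred) != len(gt_bboxes):
        raise ValueError("predicted/ground-truth lengths differ")
    if thresholds is None:
        thresholds = DEFAULT_PCK_THRESHOLDS
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    if normalize_by == "gt":
        norm_boxes = gt_bboxes
    elif normalize_by == "pred":
        if pred_bboxes is None:
            raise ValueError("normalize_by='pred' requires pred_bboxes")
        norm_boxes = pred_bboxes
    else:
        raise ValueError("normalize_by must be 'gt' or 'pred'")
    scale = np.array([characteristic_length(b) for b in norm_boxes])
    dist = np.linalg.norm(pred - gt, axis=1) / scale
    values = (dist[None, :] <= thresholds[:, None]).mean(axis=1)
    return PCKCurve(thresholds=thresholds, values=values, n_frames=len(pred))


def failure_rate(
    track: "Track | Iterable[Optional[BBox]]", n_frames: int
) -> tuple[int, float]:
    """Frames lacking a box, as a count and a percentage (one decimal).

    Accepts a complete :class:`Track` (always zero missing), a per-frame
    sequence of optional boxes, or a plain missing-frame count.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if isinstance(track, Track):
        missed = track.n_missing()
    elif isinstance(track, int):
        missed = track
    else:
        boxes = list(track)
        present = {i for i, b in enumerate(boxes) if b is not None}
        missed = n_frames - len(present)
    return missed, round(100.0 * missed / n_frames, 1)


def trajectory_overlap(
    pred_bboxes: Sequence[BBox],
    gt_bboxes: Sequence[BBox],
    iou_threshold: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Per-frame IoU of predicted vs ground-truth boxes.

    Returns the IoU series and the fraction of frames whose IoU exceeds
    ``iou_threshold``.
    """
    if len(pred_bboxes) != len(gt_bboxes):
        raise ValueError("predicted/ground-truth lengths differ")
    ious = np.array([p.iou(g) for p, g in zip(pred_bboxes, gt_bboxes)])
    return ious, float((ious > iou_threshold).mean())


def evaluate_tracking(
    pred_centroids: Sequence[Sequence[float]],
    pred_bboxes: Sequence[BBox],
    gt_centroids: Sequence[Sequence[float]],
    gt_bboxes: Sequence[BBox],
    thresholds: Optional[np.ndarray] = None,
    iou_threshold: float = 0.5,
) -> dict:
    """Bundle PCK, failure rate and IoU stats into a metrics dict."""
    curve = pck(pred_centroids, gt_centroids, gt_bboxes, thresholds)
    ious, frac = trajectory_overlap(pred_bboxes, gt_bboxes, iou_threshold)
    missed, pct = failure_rate([b for b in pred_bboxes], len(gt_bboxes))
    return {
        "pck": {
            "thresholds": [float(t) for t in curve.thresholds],
            "values": [float(v) for v in curve.values],
            "n_frames": curve.n_frames,
        },
        "pck_at_0.3": curve.at(0.30),
        "failure": {"missed": missed, "percentage": pct},
        "iou": {
            "mean": float(ious.mean()),
            "fraction_above_threshold": frac,
            "threshold": iou_threshold,
        },
    }
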