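"""Gate-crossing detection, the results document, and pipeline orchestration.

The end product of a trial analysis is a single JSON results document
joining the arena geometry (calibration, obstacles, Voronoi cells, virtual
gates), the complete per-frame track with flow-derived motion quantities,
and the ordered list of gate-crossing events — everything downstream
behavioural analysis needs, in one schema-validated file.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from shapely.geometry import LineString, Point

from . import arena_geometry as ag
from .motionflow import MotionState, analyze_motion
from .trackfill import (BBox, Detection, Track, TrackRecord, build_track,
                        read_detections)

__all__ = [
    "CrossingEvent",
    "ResultsDoc",
    "FrameDirectory",
    "detect_crossings",
    "visited_cells",
    "assemble_results",
    "write_results",
    "read_results",
    "run_pipeline",
]

logger = logging.getLogger("fintrack")

_RESULTS_KEYS = ("video", "calibration", "obstacles", "voronoi", "gates",
                 "frames", "crossings")


@dataclass(frozen=True)
class CrossingEvent:
    """The trajectory crossed a virtual gate between two frames."""

    gate_id: int
    frame: int  # the later frame of the crossing pair
    time_s: float

    def __post_init__(self) -> None:
        if self.frame < 0 or self.time_s < 0:
            raise ValueError("crossing frame/time must be nonnegative")


class FrameDirectory:
    """Frame accessor over a directory of numerically sorted images.

    Images are returned as grayscale float arrays in [0, 1].
    """

    def __init__(self, path: str | Path, pattern: str = "*.png"):
        self.path = Path(path)
        files = list(self.path.glob(pattern))
        if not files:
            raise FileNotFoundError(f"no frames matching {pattern} in {path}")

        def key(p: Path):
            nums = re.findall(r"\d+", p.stem)
            return (int(nums[-1]) if nums else 0, p.name)

        self.files = sorted(files, key=key)

    def __len__(self) -> int:
        return len(self.files)

    def __getitem__(self, i: int) -> np.ndarray:
        arr = np.asarray(iio.imread(self.files[i]), dtype=np.float64)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        if arr.max() > 1.0:
            arr = arr / 255.0
        return arr


def write_frames(frames: Sequence[np.ndarray], path: str | Path) -> None:
    """Write float [0,1] frames as 8-bit PNGs frame_000000.png, ..."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        img = np.clip(np.asarray(frame) * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(path / f"frame_{i:06d}.png", img)


# ---------------------------------------------------------------------------
# events


def detect_crossings(
    trajectory: np.ndarray,
    gates: Sequence[ag.Gate],
    fps: float,
    proximity_px: Optional[float] = None,
) -> list[CrossingEvent]:
    """Gate crossings of a centroid trajectory.

    A crossing is recorded whenever the segment between consecutive
    centroids intersects a gate segment (optionally also when a centroid
    passes within ``proximity_px`` of the gate).  Repeat events on the same
    gate in consecutive frames are merged into the first.  Events are
    ordered by frame and, within one step segment, by where along the step
    each gate is met, so two gates crossed in a single inter-frame step
    keep their true temporal order.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must be an (n, 2) array")
    raw: list[tuple[int, float, int]] = []  # (frame, along-step, gate_id)
    gate_lines = [(g.id, g.segment) for g in gates]
    for k in range(1, len(traj)):
        p, q = traj[k - 1], traj[k]
        degenerate_step = np.allclose(p, q)
        step = Point(p) if degenerate_step else LineString([p, q])
        for gid, line in gate_lines:
            along = 0.0
            if step.intersects(line):
                if not degenerate_step:
                    hit_geom = step.intersection(line)
                    rep = hit_geom.representative_point()
                    along = float(step.project(rep))
            elif proximity_px is not None and \
                    line.distance(Point(q)) <= proximity_px:
                along = float(step.length) if not degenerate_step else 0.0
            else:
                continue
            raw.append((k, along, gid))
    raw.sort()
    events: list[CrossingEvent] = []
    last_frame_for_gate: dict[int, int] = {}
    for frame, _, gid in raw:
        prev = last_frame_for_gate.get(gid)
        last_frame_for_gate[gid] = frame
        if prev is not None and frame - prev == 1:
            continue  # jitter: same gate on consecutive frames
        events.append(CrossingEvent(gate_id=gid, frame=frame,
                                    time_s=frame / fps))
    return events


def visited_cells(
    trajectory: np.ndarray, cells: Sequence[ag.VoronoiCell]
) -> list[int]:
    """Obstacle ids of cells containing at least one centroid, in
    first-visit order.  Boundary points count as inside; a centroid on a
    shared edge is attributed to the lower obstacle id.
    """
    ordered = sorted(cells, key=lambda c: c.obstacle_id)
    visited: list[int] = []
    seen: set[int] = set()
    for pt in np.asarray(trajectory, dtype=float):
        p = Point(pt)
        for cell in ordered:
            if cell.polygon.covers(p):
                if cell.obstacle_id not in seen:
                    seen.add(cell.obstacle_id)
                    visited.append(cell.obstacle_id)
                break
    return visited


# ---------------------------------------------------------------------------
# results document


@dataclass
class ResultsDoc:
    """The full trial output: geometry + per-frame motion + events."""

    video: dict  # n_frames, fps, width, height
    calibration: dict  # points, vp, mu
    obstacles: list[dict]
    voronoi: list[dict]
    gates: list[dict]
    frames: list[dict]  # frame, bbox, source, centroid, motion_vector, speed
    crossings: list[dict]

    def validate(self) -> "ResultsDoc":
        n = self.video["n_frames"]
        frame_ids = [f["frame"] for f in self.frames]
        if frame_ids != list(range(n)):
            raise ValueError("results must contain exactly one record per "
                             "frame, contiguous from 0")
        gate_ids = {g["id"] for g in self.gates}
        for c in self.crossings:
            if c["gate_id"] not in gate_ids:
                raise ValueError(
                    f"crossing references unknown gate id {c['gate_id']}")
        return self

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _RESULTS_KEYS}

    @classmethod
    def from_dict(cls, doc: dict) -> "ResultsDoc":
        for key in _RESULTS_KEYS:
            if key not in doc:
                raise ValueError(f"results document missing required key "
                                 f"'{key}'")
        return cls(**{k: doc[k] for k in _RESULTS_KEYS}).validate()

    def track(self) -> Track:
        return Track([TrackRecord(f["frame"], BBox(*f["bbox"]), f["source"])
                      for f in self.frames])

    def trajectory(self) -> np.ndarray:
        return np.array([f["centroid"] for f in self.frames])


def assemble_results(
    track: Track,
    motion: Sequence[MotionState],
    geometry: ag.GateLayout,
    crossings: Sequence[CrossingEvent],
    meta: dict,
) -> ResultsDoc:
    """Join all pipeline stages into a validated results document.

    ``meta`` must provide ``n_frames``, ``fps``, ``width`` and ``height``.
    """
    if len(track) != len(motion):
        raise ValueError("track and motion lengths differ")
    calib = geometry.calibration
    doc = ResultsDoc(
        video={k: meta[k] for k in ("n_frames", "fps", "width", "height")},
        calibration={
            "points": {f"P{i}": [float(v) for v in getattr(calib, f"p{i}")]
                       for i in range(1, 9)},
            "vp": [float(v) for v in geometry.homology.vp],
            "mu": float(geometry.homology.mu),
        },
        obstacles=[{"id": o.id, "bbox": list(o.bbox.astuple()),
                    "center": [float(v) for v in o.center],
                    "radius_px": o.radius_px} for o in geometry.obstacles],
        voronoi=[{"obstacle_id": c.obstacle_id, "bounded": c.bounded,
                  "polygon": np.asarray(c.vertices, dtype=float).tolist()}
                 for c in geometry.cells],
        gates=[{"id": g.id, "kind": g.kind, "a": g.a, "b": g.b,
                "endpoints": [list(map(float, e)) for e in g.endpoints],
                "length_px": float(g.length_px)} for g in geometry.gates],
        frames=[{"frame": r.frame, "bbox": list(r.bbox.astuple()),
                 "source": r.source,
                 "centroid": [float(v) for v in s.centroid],
                 "motion_vector": [float(v) for v in s.motion_vector],
                 "speed_px_per_s": float(s.speed),
                 "degenerate": bool(s.degenerate)}
                for r, s in zip(track, motion)],
        crossings=[{"gate_id": e.gate_id, "frame": e.frame,
                    "time_s": float(e.time_s)} for e in crossings],
    )
    return doc.validate()


def write_results(doc: ResultsDoc, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc.validate().to_dict()))


def read_results(path: str | Path) -> ResultsDoc:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed results file {path}: {exc}") from exc
    return ResultsDoc.from_dict(raw)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    frames: Sequence[np.ndarray],
    detections: Sequence[Detection],
    obstacles: Sequence[ag.Obstacle],
    calibration: ag.CalibrationPoints,
    fps: float = 60.0,
    conf_threshold: float = 0.70,
    flow_threshold: float = 0.1,
    gate_mode: str = "edge",
    flow_backend: str = "ilk",
) -> ResultsDoc:
    """End-to-end analysis of one trial.

    Stages: gap-filled tracking -> gate geometry -> flow motion analysis ->
    crossing detection -> results assembly.
    """
    img = np.asarray(frames[0])
    height, width = img.shape[:2]
    logger.info("tracking: %d frames, %d detections", len(frames),
                len(detections))
    track = build_track(frames, detections, conf_threshold=conf_threshold)
    logger.info("geometry: %d obstacles", len(obstacles))
    layout = ag.build_gates(obstacles, calibration, (width, height),
                            mode=gate_mode)
    logger.info("gates: %d", len(layout.gates))
    motion, trajectory = analyze_motion(frames, track, fps=fps,
                                        t=flow_threshold,
                                        backend=flow_backend)
    n_degen = sum(1 for s in motion if s.degenerate)
    if n_degen > 1:
        logger.warning("%d frames fell back to bbox-center centroid", n_degen)
    crossings = detect_crossings(trajectory, layout.gates, fps=fps)
    logger.info("crossings: %d", len(crossings))
    meta = {"n_frames": len(frames), "fps": fps, "width": width,
            "height": height}
    return assemble_results(track, motion, layout, crossings, meta)


def run_pipeline_from_files(
    frames_dir: str | Path,
    detections_csv: str | Path,
    obstacles_csv: str | Path,
    calibration_json: str | Path,
    **kwargs,
) -> ResultsDoc:
    frames = FrameDirectory(frames_dir)
    return run_pipeline(
        frames,
        read_detections(detections_csv),
        ag.read_obstacles(obstacles_csv),
        ag.read_calibration(calibration_json),
        **kwargs,
    )
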