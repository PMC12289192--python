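"""Synthetic overhead arena videos with full ground truth.

The generator emulates the behavioural assay the pipeline was designed for:
an overhead camera with mild perspective views a rectangular tank whose
floor carries 12-20 bright cylindrical obstacles, and a single fish swims
from one side toward a food target on the opposite wall, bending its body as
it goes.  Everything the pipeline consumes is produced in exactly the file
formats it reads — frames, a detections CSV with realistic dropout and
jitter, an obstacles CSV, a calibration JSON — together with a ground-truth
record (true per-frame boxes and body centroids, the analytic gate layout,
and the ordered gate-crossing and visited-cell sequences of the continuous
path) against which every stage can be scored.

Geometry is built directly in image coordinates from a parallel-plane
homology: obstacle tops (the *obstacle plane*) are the homology image of
their floor feet (the *ground plane*), so the calibration points P1-P8
derived from the scene are exactly consistent with the rendered layout.
For a downward-looking camera the vertical vanishing point is the nadir and
raised points appear pushed away from it, which corresponds to a negative
scale factor ``mu`` (still > -1).

Detection dropout defaults to 0.6, leaving high-confidence detections in
about 40% of frames — the anchor sparsity the gap-filling tracker has to
cope with in real footage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk as draw_disk

from . import arena_geometry as ag
from .trackfill import BBox, Detection

__all__ = [
    "SceneConfig",
    "Scene",
    "GroundTruth",
    "SimulatedTrial",
    "make_scene",
    "simulate_path",
    "render_frames",
    "simulate_detections",
    "generate_trial",
]


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one simulated trial."""

    width: int = 960
    height: int = 720
    n_obstacles: int = 12  # the assay used 12 or 20
    obstacle_radius_px: float = 26.0
    #: vertical vanishing point (nadir) and homology scale; mu < 0 because
    #: obstacle tops sit closer to the camera than their feet
    vp: tuple[float, float] = (430.0, 310.0)
    mu: float = -0.12
    #: tank-floor corner margin from the image border, px
    tank_margin: tuple[float, float] = (70.0, 60.0)
    #: fish body half-length and half-width, px
    fish_half_length: float = 24.0
    fish_half_width: float = 9.0
    #: lateral C-bend amplitude (px) and frequency (Hz)
    bend_amplitude_px: float = 6.0
    bend_hz: float = 2.0
    #: intermediate path waypoints between start and goal
    n_waypoints: int = 4
    #: cruising speed cap, px/frame
    max_step_px: float = 5.0
    #: probability a frame has NO high-confidence detection
    dropout_p: float = 0.6
    #: Gaussian sd of bbox-corner jitter on kept detections, px
    jitter_sd: float = 1.0
    #: surface-ripple intensity amplitude (on a 0-1 scale) and wavelength
    ripple_amplitude: float = 0.015
    ripple_wavelength_px: float = 150.0
    #: ripple phase speed, px/frame (kept below the flow mask threshold)
    ripple_speed_px: float = 0.08
    fps: float = 60.0
    n_frames: int = 200

    def __post_init__(self) -> None:
        if self.n_obstacles < 2:
            raise ValueError("need at least 2 obstacles")
        if not -1.0 < self.mu:
            raise ValueError("mu must exceed -1")
        if self.mu == 0.0:
            raise ValueError(
                "mu=0 collapses obstacle tops onto their feet (P5=P6); "
                "calibration needs distinct parallel planes")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")


@dataclass
class Scene:
    config: SceneConfig
    homology: ag.Homology
    floor_corners: np.ndarray  # P1..P4 clockwise from top-left, ground plane
    top_corners: np.ndarray  # projected corners, obstacle plane
    obstacles: list[ag.Obstacle]  # bboxes of obstacle tops
    calibration: ag.CalibrationPoints
    cells: list[ag.VoronoiCell]
    gates: list[ag.Gate]
    start: np.ndarray
    goal: np.ndarray


@dataclass
class GroundTruth:
    bboxes: list[BBox]  # tight per-frame fish boxes
    centroids: np.ndarray  # (n, 2) true body-pixel centroids
    gates: list[ag.Gate]
    crossing_sequence: list[int]  # ordered gate ids crossed by the path
    visited_cells: list[int]  # first-visit order of obstacle ids
    calibration: ag.CalibrationPoints
    positions: np.ndarray  # (n, 2) path positions (body frame origin)


@dataclass
class SimulatedTrial:
    scene: Scene
    frames: list[np.ndarray]
    ground_truth: GroundTruth
    detections: list[Detection]


# ---------------------------------------------------------------------------


def make_scene(config: SceneConfig, seed: int) -> Scene:
    """Lay out obstacles, derive calibration points and the analytic gates.

    Obstacle centers are rejection-sampled in the obstacle plane with a
    pairwise separation of at least 2.5 obstacle radii; calibration points
    P5-P8 are the top centers and homology-consistent floor feet of the two
    most widely separated obstacles.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    h = ag.Homology(vp=np.asarray(cfg.vp), mu=cfg.mu)
    mx, my = cfg.tank_margin
    floor = np.array([
        [mx, my],
        [cfg.width - mx, my],
        [cfg.width - mx, cfg.height - my],
        [mx, cfg.height - my],
    ])
    top = np.stack([h.apply(p) for p in floor])

    r = cfg.obstacle_radius_px
    lo = top.min(axis=0) + 1.6 * r
    hi = top.max(axis=0) - 1.6 * r
    min_sep = 2.5 * r
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < cfg.n_obstacles:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError(
                "could not place obstacles after 10000 attempts; "
                "reduce n_obstacles or obstacle radius")
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - o) >= min_sep for o in centers):
            centers.append(c)
    obstacles = [
        ag.Obstacle(id=i, bbox=BBox(c[0] - r, c[1] - r, c[0] + r, c[1] + r))
        for i, c in enumerate(centers)
    ]

    # calibration: two most separated obstacles give P5/P6 and P7/P8
    pts = np.stack(centers)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    ia, ib = np.unravel_index(np.argmax(d2), d2.shape)
    p5 = pts[ia]
    p6 = h.apply_inverse(p5)
    p7 = pts[ib]
    p8 = h.apply_inverse(p7)
    calib = ag.CalibrationPoints(p1=floor[0], p2=floor[1], p3=floor[2],
                                 p4=floor[3], p5=p5, p6=p6, p7=p7, p8=p8)

    cells = ag.compute_voronoi(obstacles)
    pairs = ag.adjacent_pairs(cells)
    o_gates = ag.obstacle_gates(pairs, obstacles)
    b_gates = ag.boundary_gates(obstacles, cells, top,
                                (cfg.width, cfg.height), start_id=len(o_gates))
    gates = o_gates + b_gates

    # the fish starts near the right wall and the food sits at the left wall
    y0 = rng.uniform(top[:, 1].min() + 3 * r, top[:, 1].max() - 3 * r)
    y1 = rng.uniform(top[:, 1].min() + 3 * r, top[:, 1].max() - 3 * r)
    start = np.array([top[:, 0].max() - 1.5 * r, y0])
    goal = np.array([top[:, 0].min() + 1.5 * r, y1])
    return Scene(config=cfg, homology=h, floor_corners=floor, top_corners=top,
                 obstacles=obstacles, calibration=calib, cells=cells,
                 gates=gates, start=start, goal=goal)


def _repel_from_obstacles(samples: np.ndarray, centers: np.ndarray,
                          clearance: float) -> np.ndarray:
    out = samples.copy()
    for c in centers:
        d = out - c
        dist = np.linalg.norm(d, axis=1)
        inside = dist < clearance
        if inside.any():
            safe = np.where(dist[inside] < 1e-9, 1e-9, dist[inside])
            out[inside] = c + d[inside] / safe[:, None] * clearance
    return out


def simulate_path(scene: Scene, seed: int,
                  n_frames: Optional[int] = None) -> np.ndarray:
    """Smooth per-frame path from start to goal avoiding obstacle discs.

    A jittered-waypoint spline is iteratively pushed out of obstacle
    clearance discs and smoothed, then resampled by arc length at a
    constant per-frame step (capped at ``max_step_px``); if the path is
    exhausted early the fish holds position at the goal.
    """
    cfg = scene.config
    if n_frames is None:
        n_frames = cfg.n_frames
    rng = np.random.default_rng(seed)
    centers = np.stack([o.center for o in scene.obstacles])
    clearance = cfg.obstacle_radius_px + cfg.fish_half_width + 6.0

    k = cfg.n_waypoints
    ts = np.linspace(0.0, 1.0, k + 2)
    base = scene.start[None, :] * (1 - ts)[:, None] + scene.goal[None, :] * ts[:, None]
    lateral = np.zeros_like(base)
    direction = scene.goal - scene.start
    n_hat = np.array([-direction[1], direction[0]])
    n_hat = n_hat / np.linalg.norm(n_hat)
    lateral[1:-1] = rng.normal(0.0, 40.0, size=(k, 1)) * n_hat[None, :]
    waypoints = base + lateral

    spline = CubicSpline(ts, waypoints, axis=0)
    dense = spline(np.linspace(0.0, 1.0, 3000))
    for _ in range(60):
        dense = _repel_from_obstacles(dense, centers, clearance)
        dense = gaussian_filter1d(dense, sigma=8.0, axis=0, mode="nearest")
        dense[0], dense[-1] = scene.start, scene.goal
    for _ in range(40):  # hard projection, no smoothing
        before = dense
        dense = _repel_from_obstacles(dense, centers, clearance - 2.0)
        if np.allclose(before, dense):
            break

    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    step = min(cfg.max_step_px, total / max(n_frames - 1, 1))
    targets = np.minimum(np.arange(n_frames) * step, total)
    xs = np.interp(targets, arclen, dense[:, 0])
    ys = np.interp(targets, arclen, dense[:, 1])
    return np.stack([xs, ys], axis=1)


# ---------------------------------------------------------------------------
# rendering

_BG_LEVEL = 0.25
_OBSTACLE_LEVEL = 0.85


def _fish_layer(cfg: SceneConfig, pos: np.ndarray, heading: float,
                bend_phase: float, shape: tuple[int, int]) -> np.ndarray:
    """Render the fish as overlapping discs along a bent midline.

    Disc brightness varies sinusoidally along the body, giving the
    multiplicative texture that template matching and optical flow need;
    the midline offset ``~ sin(phase) * (s/L)^2`` produces the C-bend.
    """
    layer = np.zeros(shape)
    L = cfg.fish_half_length
    u = np.array([np.cos(heading), np.sin(heading)])
    n = np.array([-u[1], u[0]])
    ss = np.linspace(-1.0, 1.0, 25)  # normalized body coordinate
    bend = cfg.bend_amplitude_px * np.sin(bend_phase)
    for s in ss:
        offset = bend * s * s
        p = pos + s * L * u + offset * n
        radius = cfg.fish_half_width * np.sqrt(max(1.0 - (s / 1.05) ** 2, 0.0)) + 1.2
        brightness = 0.60 + 0.30 * np.sin(2.0 * np.pi * 1.8 * s + 0.9)
        rr, cc = draw_disk((p[1], p[0]), radius, shape=shape)
        layer[rr, cc] = np.maximum(layer[rr, cc], brightness)
    return layer


def render_frames(
    scene: Scene, path: np.ndarray, bend_phases: Optional[np.ndarray] = None
) -> tuple[list[np.ndarray], GroundTruth]:
    """Render grayscale frames and record exact per-frame ground truth.

    Each frame composes: rippled background, bright obstacle discs (obstacle
    plane), and the textured bent-ellipse fish.  The true bbox is the tight
    box of rendered fish pixels; the true centroid is their pixel-mass mean.
    """
    cfg = scene.config
    n = len(path)
    h_px, w_px = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    k = 2.0 * np.pi / cfg.ripple_wavelength_px
    ripple_phase = k * (0.8 * xx + 0.6 * yy)
    omega = k * cfg.ripple_speed_px

    obstacle_mask = np.zeros((h_px, w_px), dtype=bool)
    for o in scene.obstacles:
        rr, cc = draw_disk((o.center[1], o.center[0]), o.radius_px,
                           shape=(h_px, w_px))
        obstacle_mask[rr, cc] = True

    headings = _path_headings(path)
    if bend_phases is None:
        bend_phases = 2.0 * np.pi * cfg.bend_hz * np.arange(n) / cfg.fps

    frames: list[np.ndarray] = []
    bboxes: list[BBox] = []
    centroids = np.zeros((n, 2))
    for i in range(n):
        if cfg.ripple_amplitude > 0:
            bg = _BG_LEVEL + cfg.ripple_amplitude * np.sin(ripple_phase - omega * i)
        else:
            bg = np.full((h_px, w_px), _BG_LEVEL)
        frame = np.where(obstacle_mask, _OBSTACLE_LEVEL, bg)
        fish = _fish_layer(cfg, path[i], headings[i], bend_phases[i],
                           (h_px, w_px))
        mask = fish > 0
        frame = np.where(mask, fish, frame)
        frames.append(np.clip(frame, 0.0, 1.0).astype(np.float32))

        ys_idx, xs_idx = np.nonzero(mask)
        bboxes.append(BBox(float(xs_idx.min()), float(ys_idx.min()),
                           float(xs_idx.max() + 1), float(ys_idx.max() + 1)))
        centroids[i] = (xs_idx.mean(), ys_idx.mean())

    crossing_seq, visited = _ground_truth_events(scene, path)
    gt = GroundTruth(bboxes=bboxes, centroids=centroids, gates=scene.gates,
                     crossing_sequence=crossing_seq, visited_cells=visited,
                     calibration=scene.calibration, positions=path)
    return frames, gt


def _path_headings(path: np.ndarray) -> np.ndarray:
    diffs = np.gradient(path, axis=0)
    headings = np.arctan2(diffs[:, 1], diffs[:, 0])
    # a loitering fish keeps its last heading
    still = np.linalg.norm(diffs, axis=1) < 1e-9
    for i in np.nonzero(still)[0]:
        if i > 0:
            headings[i] = headings[i - 1]
    return headings


def _ground_truth_events(scene: Scene, path: np.ndarray) -> tuple[list[int], list[int]]:
    """Crossing and visited-cell sequences of the continuous path.

    The path is resampled at 10x the frame rate so grazing crossings are
    attributed consistently with the underlying continuous motion.
    """
    from .pipeline_io import detect_crossings, visited_cells

    n = len(path)
    fine_t = np.linspace(0, n - 1, (n - 1) * 10 + 1)
    fine = np.stack([np.interp(fine_t, np.arange(n), path[:, 0]),
                     np.interp(fine_t, np.arange(n), path[:, 1])], axis=1)
    events = detect_crossings(fine, scene.gates, fps=scene.config.fps * 10)
    seq = [e.gate_id for e in events]
    visited = visited_cells(path, scene.cells)
    return seq, visited


# ---------------------------------------------------------------------------


def simulate_detections(
    gt: GroundTruth,
    dropout_p: float,
    jitter_sd: float,
    seed: int,
) -> list[Detection]:
    """Emulate a detector: dropout, confidence draws and bbox jitter.

    Each frame yields a high-confidence detection (confidence in
    (0.75, 1.0), corners jittered with the given sd) with probability
    ``1 - dropout_p``; dropped frames produce either nothing or a
    low-confidence row (confidence < 0.65).  At least one high-confidence
    detection is guaranteed: a fully dropped trial is redrawn with a
    warning.
    """
    if not 0.0 <= dropout_p < 1.0:
        raise ValueError("dropout_p must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    for attempt in range(100):
        dets: list[Detection] = []
        n_high = 0
        for f, bbox in enumerate(gt.bboxes):
            kept = rng.uniform() >= dropout_p
            jitter = rng.normal(0.0, jitter_sd, size=4) if jitter_sd > 0 else np.zeros(4)
            x0, y0, x1, y1 = np.asarray(bbox.astuple()) + jitter
            if x0 >= x1 or y0 >= y1:
                x0, y0, x1, y1 = bbox.astuple()
            if kept:
                conf = rng.uniform(0.75, 1.0)
                dets.append(Detection(f, BBox(x0, y0, x1, y1), conf))
                n_high += 1
            elif rng.uniform() < 0.5:
                conf = rng.uniform(0.0, 0.65)
                dets.append(Detection(f, BBox(x0, y0, x1, y1), conf))
        if n_high >= 1:
            return dets
        warnings.warn("all frames dropped; redrawing detections",
                      RuntimeWarning)
    raise RuntimeError("failed to produce any high-confidence detection")


def generate_trial(config: SceneConfig, seed: int) -> SimulatedTrial:
    """Scene + path + frames + ground truth + detections, fully seeded."""
    root = np.random.default_rng(seed)
    s_scene, s_path, s_det = (int(x) for x in
                              root.integers(0, 2**31 - 1, size=3))
    scene = make_scene(config, s_scene)
    path = simulate_path(scene, s_path)
    frames, gt = render_frames(scene, path)
    dets = simulate_detections(gt, config.dropout_p, config.jitter_sd, s_det)
    return SimulatedTrial(scene=scene, frames=frames, ground_truth=gt,
                          detections=dets)
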