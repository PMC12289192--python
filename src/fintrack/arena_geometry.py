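"""Virtual-gate geometry: Voronoi adjacency and parallel-plane homology.

The arena is a rectangular tank observed by an overhead camera with mild
perspective.  Cylindrical obstacles stand on the tank floor; their tops all
lie in a plane (the *obstacle plane*) parallel to the floor (the *ground
plane*).  Two kinds of traversable gap ("virtual gate") are computed:

* **obstacle gates** between pairs of obstacles whose Voronoi cells share an
  edge of positive length;
* **boundary gates** between an obstacle near the tank wall and an
  *imaginary obstacle* obtained by dropping the obstacle center
  perpendicularly onto the nearest projected tank edge.

Because tank corners are annotated on the ground plane while obstacle tops
live in the obstacle plane, the corners must first be mapped between the two
parallel planes.  In image coordinates with origin at the vertical vanishing
point ``vp`` this map is the one-parameter homology ``x' = x / (1 + mu)``:
``vp`` is its fixed point and every point moves along the ray through ``vp``.
The vanishing point is the intersection of the images of two vertical
segments (obstacle top/bottom pairs P5-P6 and P7-P8), and ``mu`` follows from
a single ground/obstacle point correspondence.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point, Polygon, box as shapely_box

from .trackfill import BBox

__all__ = [
    "CalibrationPoints",
    "Homology",
    "Obstacle",
    "VoronoiCell",
    "Gate",
    "vanishing_point",
    "estimate_mu",
    "estimate_homology",
    "apply_homology",
    "project_tank_corners",
    "compute_voronoi",
    "adjacent_pairs",
    "obstacle_gates",
    "boundary_obstacle_ids",
    "imaginary_obstacles",
    "boundary_gates",
    "build_gates",
    "read_calibration",
    "write_calibration",
    "read_obstacles",
    "write_obstacles",
]

GATE_OBSTACLE = "obstacle"
GATE_BOUNDARY = "boundary"


@dataclass(frozen=True)
class CalibrationPoints:
    """Eight manually annotated pixel points.

    P1..P4: tank-floor corners (ground plane), clockwise from top-left.
    P5/P6: top and bottom of one obstacle; P7/P8 of a second obstacle.
    Tops lie in the obstacle plane, bottoms in the ground plane.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray
    p5: np.ndarray
    p6: np.ndarray
    p7: np.ndarray
    p8: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8"):
            pt = np.asarray(getattr(self, name), dtype=np.float64).reshape(2)
            if not np.all(np.isfinite(pt)):
                raise ValueError(f"calibration point {name.upper()} not finite")
            object.__setattr__(self, name, pt)
        if np.allclose(self.p5, self.p6):
            raise ValueError("P5 and P6 coincide: obstacle has no visible height")
        if np.allclose(self.p7, self.p8):
            raise ValueError("P7 and P8 coincide: obstacle has no visible height")

    @property
    def corners(self) -> np.ndarray:
        return np.stack([self.p1, self.p2, self.p3, self.p4])


@dataclass(frozen=True)
class Homology:
    """Parallel-plane homology: vanishing point and scale factor ``mu``.

    In coordinates centered on ``vp`` the ground->obstacle map is
    ``x' = x / (1 + mu)``; ``mu > -1`` keeps it orientation-preserving.
    """

    vp: np.ndarray
    mu: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "vp",
                           np.asarray(self.vp, dtype=np.float64).reshape(2))
        if not self.mu > -1.0:
            raise ValueError("homology scale mu must exceed -1")

    def apply(self, pt: np.ndarray) -> np.ndarray:
        return apply_homology(pt, self)

    def apply_inverse(self, pt: np.ndarray) -> np.ndarray:
        """Obstacle plane -> ground plane."""
        pt = np.asarray(pt, dtype=np.float64)
        return self.vp + (pt - self.vp) * (1.0 + self.mu)


@dataclass(frozen=True)
class Obstacle:
    """A cylindrical obstacle, annotated by the bbox of its top face."""

    id: int
    bbox: BBox

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.bbox.center, dtype=np.float64)

    @property
    def radius_px(self) -> float:
        return (self.bbox.width + self.bbox.height) / 4.0


@dataclass(frozen=True)
class VoronoiCell:
    obstacle_id: int
    polygon: Polygon  # clipped to a finite frame for unbounded cells
    bounded: bool

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.polygon.exterior.coords)[:-1]


@dataclass(frozen=True)
class Gate:
    """A crossable segment between two obstacles, or obstacle and wall."""

    id: int
    kind: str  # "obstacle" | "boundary"
    a: int
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    length_px: float
    b: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in (GATE_OBSTACLE, GATE_BOUNDARY):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.length_px < 0:
            raise ValueError("gate length must be nonnegative")

    @property
    def segment(self) -> LineString:
        return LineString(self.endpoints)


# ---------------------------------------------------------------------------
# homology estimation


def vanishing_point(calib: CalibrationPoints) -> np.ndarray:
    """Intersection of the lines P5-P6 and P7-P8 (images of verticals)."""
    d1 = calib.p6 - calib.p5
    d2 = calib.p8 - calib.p7
    d1n = d1 / np.linalg.norm(d1)
    d2n = d2 / np.linalg.norm(d2)
    cross = d1n[0] * d2n[1] - d1n[1] * d2n[0]
    if abs(cross) <= 1e-9:
        raise ValueError("vanishing point at infinity; calibration unusable")
    # solve p5 + t*d1 = p7 + s*d2
    rhs = calib.p7 - calib.p5
    t = (rhs[0] * d2[1] - rhs[1] * d2[0]) / (d1[0] * d2[1] - d1[1] * d2[0])
    return calib.p5 + t * d1


def estimate_mu(
    vp: np.ndarray, ground_pt: np.ndarray, obstacle_pt: np.ndarray
) -> float:
    """Scale factor from one ground/obstacle-plane correspondence.

    ``mu = |ground - vp| / |obstacle - vp| - 1`` so that the homology
    ``x' = x / (1+mu)`` (vp-origin coordinates) maps ground to obstacle
    plane.  The three points must be nearly collinear: a perpendicular
    offset above 0.5 px warns, above 2 px raises.
    """
    vp = np.asarray(vp, dtype=np.float64)
    g = np.asarray(ground_pt, dtype=np.float64)
    o = np.asarray(obstacle_pt, dtype=np.float64)
    rg = np.linalg.norm(g - vp)
    ro = np.linalg.norm(o - vp)
    if ro == 0.0:
        raise ZeroDivisionError("obstacle point coincides with vanishing point")
    if rg == 0.0:
        raise ValueError("ground point coincides with vanishing point")
    if not np.allclose(g, o):
        u = (g - vp) / rg
        offset = abs((o - vp)[0] * u[1] - (o - vp)[1] * u[0])
        if offset > 2.0:
            raise ValueError(
                f"calibration points not collinear with vanishing point "
                f"(offset {offset:.2f} px)")
        if offset > 0.5:
            warnings.warn(
                f"calibration points {offset:.2f} px off the vanishing-point "
                "ray; mu may be imprecise", RuntimeWarning)
    return rg / ro - 1.0


def estimate_homology(calib: CalibrationPoints, average_pairs: bool = False) -> Homology:
    """Full calibration: vanishing point plus mu from P5/P6 (optionally
    averaged with the P7/P8 estimate)."""
    vp = vanishing_point(calib)
    mu = estimate_mu(vp, calib.p6, calib.p5)
    if average_pairs:
        mu = 0.5 * (mu + estimate_mu(vp, calib.p8, calib.p7))
    return Homology(vp=vp, mu=mu)


def apply_homology(pt: np.ndarray, h: Homology) -> np.ndarray:
    """Map a ground-plane image point to the obstacle plane."""
    pt = np.asarray(pt, dtype=np.float64)
    return h.vp + (pt - h.vp) / (1.0 + h.mu)


def project_tank_corners(calib: CalibrationPoints, h: Homology) -> np.ndarray:
    """P1'..P4': the floor corners mapped into the obstacle plane."""
    return np.stack([apply_homology(p, h) for p in calib.corners])


# ---------------------------------------------------------------------------
# Voronoi tessellation


def _finite_voronoi_polygons(vor: Voronoi, extent: float) -> list[np.ndarray]:
    """Reconstruct each Voronoi region as a finite polygon.

    Infinite ridges are extended by ``extent`` from the seed midpoints before
    closing the region (standard finite-reconstruction trick).
    """
    new_regions: list[np.ndarray] = []
    center = vor.points.mean(axis=0)
    all_ridges: dict[int, list[tuple[int, int, int]]] = {}
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        all_ridges.setdefault(p1, []).append((p2, v1, v2))
        all_ridges.setdefault(p2, []).append((p1, v1, v2))

    for p1, region_idx in enumerate(vor.point_region):
        vertices = vor.regions[region_idx]
        if -1 not in vertices:
            new_regions.append(vor.vertices[vertices])
            continue
        # reconstruct: keep finite vertices, add far points along infinite rays
        pts = [vor.vertices[v] for v in vertices if v >= 0]
        for p2, v1, v2 in all_ridges.get(p1, []):
            if v1 >= 0 and v2 >= 0:
                continue
            v_finite = v2 if v1 < 0 else v1
            tangent = vor.points[p2] - vor.points[p1]
            tangent = tangent / np.linalg.norm(tangent)
            normal = np.array([-tangent[1], tangent[0]])
            midpoint = (vor.points[p1] + vor.points[p2]) / 2.0
            direction = np.sign(np.dot(midpoint - center, normal)) * normal
            pts.append(vor.vertices[v_finite] + direction * extent)
        arr = np.asarray(pts)
        # order counterclockwise around the seed
        angles = np.arctan2(arr[:, 1] - vor.points[p1][1],
                            arr[:, 0] - vor.points[p1][0])
        new_regions.append(arr[np.argsort(angles)])
    return new_regions


def compute_voronoi(obstacles: Sequence[Obstacle]) -> list[VoronoiCell]:
    """Voronoi partition of the plane seeded by obstacle centers.

    Unbounded cells are flagged and truncated far outside the seed extent so
    every cell carries a finite polygon usable in intersection arithmetic.
    """
    if len(obstacles) < 2:
        raise ValueError("need at least 2 obstacles for a Voronoi partition")
    centers = np.stack([o.center for o in obstacles])
    diffs = centers[:, None, :] - centers[None, :, :]
    dists = np.sqrt((diffs ** 2).sum(-1))
    np.fill_diagonal(dists, np.inf)
    if dists.min() < 1e-6:
        raise ValueError("duplicate obstacle centers")

    span = max(np.ptp(centers[:, 0]), np.ptp(centers[:, 1]), 1.0)
    extent = 50.0 * span
    if len(obstacles) == 2:
        # two seeds: half-planes split by the perpendicular bisector
        a, b = centers
        mid = (a + b) / 2.0
        u = (b - a) / np.linalg.norm(b - a)
        n = np.array([-u[1], u[0]])
        cells = []
        for obst, sign in zip(obstacles, (-1.0, 1.0)):
            poly = Polygon([mid + extent * n, mid - extent * n,
                            mid - extent * n + sign * extent * u,
                            mid + extent * n + sign * extent * u])
            cells.append(VoronoiCell(obstacle_id=obst.id, polygon=poly,
                                     bounded=False))
        return cells
    vor = Voronoi(centers)
    polys = _finite_voronoi_polygons(vor, extent)
    cells = []
    for obst, region_idx, poly_pts in zip(obstacles, vor.point_region, polys):
        bounded = -1 not in vor.regions[region_idx]
        poly = Polygon(poly_pts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        cells.append(VoronoiCell(obstacle_id=obst.id, polygon=poly,
                                 bounded=bounded))
    return cells


def adjacent_pairs(cells: Sequence[VoronoiCell]) -> list[tuple[int, int]]:
    """Unordered id pairs whose cells share an edge of positive length.

    Cells meeting only at a single vertex (degenerate, e.g. cocircular
    seeds) are not adjacent: that contact is not a traversable gap.
    """
    pairs: list[tuple[int, int]] = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            inter = cells[i].polygon.intersection(cells[j].polygon)
            if inter.length > 1e-9:
                a, b = cells[i].obstacle_id, cells[j].obstacle_id
                pairs.append((min(a, b), max(a, b)))
    return sorted(pairs)


def obstacle_gates(
    pairs: Sequence[tuple[int, int]],
    obstacles: Sequence[Obstacle],
    mode: str = "edge",
    start_id: int = 0,
) -> list[Gate]:
    """One gate per adjacent obstacle pair.

    ``mode="edge"`` (default): length is the edge-to-edge gap
    ``max(0, |c_i - c_j| - r_i - r_j)``; ``mode="center"``: plain
    center-to-center distance.
    """
    if mode not in ("edge", "center"):
        raise ValueError("mode must be 'edge' or 'center'")
    by_id = {o.id: o for o in obstacles}
    gates = []
    for k, (i, j) in enumerate(pairs):
        oi, oj = by_id[i], by_id[j]
        d = float(np.linalg.norm(oi.center - oj.center))
        if mode == "edge":
            length = d - oi.radius_px - oj.radius_px
            if length < 0:
                warnings.warn(
                    f"obstacles {i} and {j} overlap; gate length clamped to 0",
                    RuntimeWarning)
                length = 0.0
        else:
            length = d
        gates.append(Gate(id=start_id + k, kind=GATE_OBSTACLE, a=i, b=j,
                          endpoints=(tuple(oi.center), tuple(oj.center)),
                          length_px=length))
    return gates


def boundary_obstacle_ids(
    cells: Sequence[VoronoiCell], image_bounds: tuple[int, int]
) -> list[int]:
    """Obstacles whose cell is unbounded or pokes outside the image."""
    w, h = image_bounds
    ids = []
    for cell in cells:
        if not cell.bounded:
            ids.append(cell.obstacle_id)
            continue
        v = cell.vertices
        outside = (v[:, 0] < 0) | (v[:, 0] > w) | (v[:, 1] < 0) | (v[:, 1] > h)
        if outside.any():
            ids.append(cell.obstacle_id)
    return ids


def _clip_cell(cell: VoronoiCell, image_bounds: tuple[int, int],
               inflate: float = 0.2) -> Polygon:
    # bounded polygons are required for intersection tests; inflating the
    # frame keeps the information of which tank edges an unbounded cell meets
    w, h = image_bounds
    frame = shapely_box(-inflate * w, -inflate * h,
                        (1 + inflate) * w, (1 + inflate) * h)
    return cell.polygon.intersection(frame)


def imaginary_obstacles(
    obstacle: Obstacle,
    cell: VoronoiCell,
    projected_corners: np.ndarray,
    image_bounds: tuple[int, int],
) -> list[np.ndarray]:
    """Wall feet of a boundary obstacle.

    For every projected tank edge (P1'P2', P2'P3', ...) that intersects the
    obstacle's (clipped) Voronoi cell, the obstacle center is translated
    perpendicularly onto that edge; the foot is clamped to the edge segment.
    """
    clipped = _clip_cell(cell, image_bounds)
    feet: list[np.ndarray] = []
    corners = np.asarray(projected_corners, dtype=np.float64)
    for k in range(4):
        a, b = corners[k], corners[(k + 1) % 4]
        edge = LineString([a, b])
        if not edge.intersects(clipped):
            continue
        ab = b - a
        t = float(np.dot(obstacle.center - a, ab) / np.dot(ab, ab))
        t = min(max(t, 0.0), 1.0)
        feet.append(a + t * ab)
    if not feet:
        warnings.warn(
            f"boundary obstacle {obstacle.id}: cell meets no projected tank "
            "edge; no imaginary obstacle created", RuntimeWarning)
    return feet


def boundary_gates(
    obstacles: Sequence[Obstacle],
    cells: Sequence[VoronoiCell],
    projected_corners: np.ndarray,
    image_bounds: tuple[int, int],
    mode: str = "edge",
    start_id: int = 0,
) -> list[Gate]:
    """One gate per (boundary obstacle, imaginary obstacle) pair."""
    cell_by_id = {c.obstacle_id: c for c in cells}
    b_ids = set(boundary_obstacle_ids(cells, image_bounds))
    gates = []
    k = 0
    for obst in obstacles:
        if obst.id not in b_ids:
            continue
        for foot in imaginary_obstacles(obst, cell_by_id[obst.id],
                                        projected_corners, image_bounds):
            d = float(np.linalg.norm(obst.center - foot))
            length = max(0.0, d - obst.radius_px) if mode == "edge" else d
            gates.append(Gate(id=start_id + k, kind=GATE_BOUNDARY, a=obst.id,
                              endpoints=(tuple(obst.center), tuple(foot)),
                              length_px=length))
            k += 1
    return gates


@dataclass
class GateLayout:
    """Bundle of everything the gate computation produces."""

    obstacles: list[Obstacle]
    calibration: CalibrationPoints
    homology: Homology
    projected_corners: np.ndarray
    cells: list[VoronoiCell]
    gates: list[Gate]

    def gate_by_id(self, gid: int) -> Gate:
        for g in self.gates:
            if g.id == gid:
                return g
        raise KeyError(gid)


def build_gates(
    obstacles: Sequence[Obstacle],
    calib: CalibrationPoints,
    image_bounds: tuple[int, int],
    mode: str = "edge",
    average_mu_pairs: bool = False,
) -> GateLayout:
    """End-to-end gate computation for one arena."""
    h = estimate_homology(calib, average_pairs=average_mu_pairs)
    corners = project_tank_corners(calib, h)
    cells = compute_voronoi(obstacles)
    pairs = adjacent_pairs(cells)
    o_gates = obstacle_gates(pairs, obstacles, mode=mode)
    b_gates = boundary_gates(obstacles, cells, corners, image_bounds,
                             mode=mode, start_id=len(o_gates))
    return GateLayout(obstacles=list(obstacles), calibration=calib,
                      homology=h, projected_corners=corners, cells=cells,
                      gates=o_gates + b_gates)


# ---------------------------------------------------------------------------
# file interfaces


def write_calibration(calib: CalibrationPoints, path: str | Path) -> None:
    doc = {"points": {f"P{i}": list(map(float, getattr(calib, f"p{i}")))
                      for i in range(1, 9)}}
    Path(path).write_text(json.dumps(doc, indent=2))


def read_calibration(path: str | Path) -> CalibrationPoints:
    doc = json.loads(Path(path).read_text())
    if "points" not in doc:
        raise ValueError("calibration file missing required key 'points'")
    pts = doc["points"]
    missing = [f"P{i}" for i in range(1, 9) if f"P{i}" not in pts]
    if missing:
        raise ValueError(f"calibration file missing points {missing}")
    return CalibrationPoints(**{f"p{i}": np.asarray(pts[f"P{i}"], dtype=float)
                                for i in range(1, 9)})


def write_obstacles(obstacles: Iterable[Obstacle], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x0", "y0", "x1", "y1"])
        for o in obstacles:
            writer.writerow([o.id, *o.bbox.astuple()])


def read_obstacles(path: str | Path) -> list[Obstacle]:
    obstacles = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "x0", "y0", "x1", "y1"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"obstacles file must have columns {sorted(required)}")
        for row in reader:
            obstacles.append(Obstacle(
                id=int(row["id"]),
                bbox=BBox(float(row["x0"]), float(row["y0"]),
                          float(row["x1"]), float(row["y1"]))))
    ids = [o.id for o in obstacles]
    if len(set(ids)) != len(ids):
        raise ValueError("obstacle ids must be unique")
    return obstacles
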