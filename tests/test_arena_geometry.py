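"""Geometry tests: homology against a full 3D pinhole-projection oracle,
Voronoi cells against a rasterized nearest-neighbor oracle, and gate
arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from fintrack.arena_geometry import (CalibrationPoints, Gate, Homology,
                                     Obstacle, adjacent_pairs,
                                     apply_homology, boundary_gates,
                                     boundary_obstacle_ids, build_gates,
                                     compute_voronoi, estimate_homology,
                                     estimate_mu, imaginary_obstacles,
                                     obstacle_gates, project_tank_corners,
                                     read_calibration, read_obstacles,
                                     vanishing_point, write_calibration,
                                     write_obstacles)
from fintrack.trackfill import BBox


def calib_from_points(p5, p6, p7, p8, corners=None):
    if corners is None:
        corners = [(0, 0), (100, 0), (100, 100), (0, 100)]
    return CalibrationPoints(p1=np.array(corners[0], float),
                             p2=np.array(corners[1], float),
                             p3=np.array(corners[2], float),
                             p4=np.array(corners[3], float),
                             p5=np.asarray(p5, float), p6=np.asarray(p6, float),
                             p7=np.asarray(p7, float), p8=np.asarray(p8, float))


def disc_obstacle(oid, cx, cy, r=10.0):
    return Obstacle(oid, BBox(cx - r, cy - r, cx + r, cy + r))


# ---------------------------------------------------------------------------
# pinhole-projection oracle


class PinholeScene:
    """A 3D camera viewing two parallel horizontal planes z=0 and z=h.

    Provides ground-truth projections so the homology chain can be checked
    end to end: the image of any vertical segment must pass through the
    camera's vertical vanishing point, and the plane-to-plane map must be
    the one-parameter homology.
    """

    def __init__(self, rng, plane_sep=None):
        # the one-parameter form of the plane-to-plane map assumes the image
        # plane is parallel to the scene planes (nadir view); yaw, focal
        # length, principal point and camera position stay free
        self.h = plane_sep if plane_sep is not None else rng.uniform(50, 150)
        f = rng.uniform(800, 1600)
        self.K = np.array([[f, 0, rng.uniform(400, 600)],
                           [0, f, rng.uniform(300, 500)],
                           [0, 0, 1.0]])
        cam = np.array([rng.uniform(-100, 100), rng.uniform(-100, 100),
                        rng.uniform(800, 1500)])
        yaw = rng.uniform(0, 2 * np.pi)
        Rz = np.array([[np.cos(yaw), -np.sin(yaw), 0],
                       [np.sin(yaw), np.cos(yaw), 0],
                       [0, 0, 1.0]])
        flip = np.diag([1.0, -1.0, -1.0])  # look straight down (-z)
        self.R = Rz @ flip
        self.t = -self.R @ cam

    def project(self, X):
        x = self.K @ (self.R @ np.asarray(X, float) + self.t)
        return x[:2] / x[2]

    def true_vanishing_point(self):
        d = self.K @ self.R @ np.array([0.0, 0.0, 1.0])
        return d[:2] / d[2]

    def calibration(self, rng):
        a = np.array([rng.uniform(-200, 200), rng.uniform(-200, 200)])
        b = np.array([rng.uniform(-200, 200), rng.uniform(-200, 200)])
        while np.linalg.norm(a - b) < 100:
            b = np.array([rng.uniform(-200, 200), rng.uniform(-200, 200)])
        return calib_from_points(
            p5=self.project([*a, self.h]), p6=self.project([*a, 0.0]),
            p7=self.project([*b, self.h]), p8=self.project([*b, 0.0]))


@pytest.mark.parametrize("seed", range(20))
def test_pinhole_oracle_round_trip(seed):
    """vanishing_point + estimate_mu + apply_homology reproduce rendered
    obstacle-plane positions to sub-micro-pixel accuracy."""
    rng = np.random.default_rng(seed)
    scene = PinholeScene(rng)
    calib = scene.calibration(rng)
    vp = vanishing_point(calib)
    assert np.allclose(vp, scene.true_vanishing_point(), atol=1e-6)
    mu = estimate_mu(vp, calib.p6, calib.p5)
    h = Homology(vp=vp, mu=mu)
    for _ in range(10):
        g = np.array([rng.uniform(-250, 250), rng.uniform(-250, 250)])
        ground_px = scene.project([*g, 0.0])
        top_px = scene.project([*g, scene.h])
        assert np.allclose(apply_homology(ground_px, h), top_px, atol=1e-6)


class TestVanishingPoint:
    def test_analytic_intersection(self):
        calib = calib_from_points((0, 10), (0, 20), (10, 10), (20, 20))
        assert np.allclose(vanishing_point(calib), (0, 0))

    def test_parallel_lines_error(self):
        calib = calib_from_points((0, 10), (0, 20), (5, 10), (5, 20))
        with pytest.raises(ValueError, match="at infinity"):
            vanishing_point(calib)


class TestEstimateMu:
    def test_ratio_formula(self):
        assert estimate_mu((0, 0), (100, 0), (80, 0)) == pytest.approx(0.25)

    def test_coincident_planes(self):
        assert estimate_mu((0, 0), (50, 50), (50, 50)) == pytest.approx(0.0)

    def test_obstacle_at_vp_errors(self):
        with pytest.raises(ZeroDivisionError):
            estimate_mu((0, 0), (10, 0), (0, 0))

    def test_collinearity_tolerance(self):
        with pytest.warns(RuntimeWarning, match="off the vanishing-point"):
            estimate_mu((0, 0), (100, 0), (80, 1.0))
        with pytest.raises(ValueError, match="not collinear"):
            estimate_mu((0, 0), (100, 0), (80, 3.0))


class TestApplyHomology:
    def test_mu_zero_identity(self, rng):
        h = Homology(vp=np.array([13.0, -7.0]), mu=0.0)
        pts = rng.uniform(-100, 100, size=(20, 2))
        for p in pts:
            assert np.allclose(apply_homology(p, h), p)

    def test_scaling_example(self):
        h = Homology(vp=np.array([0.0, 0.0]), mu=0.25)
        assert np.allclose(apply_homology((200, 100), h), (160, 80))

    def test_vp_fixed_point(self, rng):
        for mu in (-0.5, -0.1, 0.3, 2.0):
            vp = rng.uniform(-50, 50, 2)
            h = Homology(vp=vp, mu=mu)
            assert np.allclose(apply_homology(vp, h), vp)

    def test_mu_must_exceed_minus_one(self):
        with pytest.raises(ValueError):
            Homology(vp=np.zeros(2), mu=-1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(mu=st.floats(-0.9, 3.0),
           vx=st.floats(-100, 100), vy=st.floats(-100, 100),
           px=st.floats(-500, 500), py=st.floats(-500, 500))
    def test_collinearity_and_mu_round_trip(self, mu, vx, vy, px, py):
        """vp, pt and its image are collinear, and re-estimating mu from
        the (ground, image) pair recovers the original mu."""
        h = Homology(vp=np.array([vx, vy]), mu=mu)
        pt = np.array([px, py])
        if np.linalg.norm(pt - h.vp) < 1.0:
            return
        out = apply_homology(pt, h)
        cross = (pt - h.vp)[0] * (out - h.vp)[1] - (pt - h.vp)[1] * (out - h.vp)[0]
        assert abs(cross) < 1e-6 * max(1.0, np.linalg.norm(pt - h.vp) ** 2)
        assert estimate_mu(h.vp, pt, out) == pytest.approx(mu, abs=1e-9)

    def test_project_corners_elementwise(self):
        calib = calib_from_points((0, 10), (0, 20), (10, 10), (20, 20),
                                  corners=[(-100, -100), (100, -100),
                                           (100, 100), (-100, 100)])
        h = Homology(vp=np.zeros(2), mu=0.25)
        out = project_tank_corners(calib, h)
        assert np.allclose(out, 0.8 * calib.corners)


def test_calibration_round_trip_on_pinhole_scene(rng):
    """estimate_homology maps each calibration ground point exactly onto
    its paired obstacle-plane point."""
    scene = PinholeScene(rng)
    calib = scene.calibration(rng)
    h = estimate_homology(calib)
    assert np.allclose(apply_homology(calib.p6, h), calib.p5, atol=1e-6)
    h2 = estimate_homology(calib, average_pairs=True)
    assert np.allclose(apply_homology(calib.p8, h2), calib.p7, atol=1e-4)


# ---------------------------------------------------------------------------
# Voronoi


class TestComputeVoronoi:
    def test_two_seeds_half_planes(self):
        cells = compute_voronoi([disc_obstacle(0, 0, 0),
                                 disc_obstacle(1, 100, 0)])
        assert all(not c.bounded for c in cells)
        from shapely.geometry import Point
        assert cells[0].polygon.covers(Point(-30, 17))
        assert cells[1].polygon.covers(Point(130, -12))
        assert not cells[0].polygon.covers(Point(60, 0))
        assert len(adjacent_pairs(cells)) == 1

    def test_grid_3x3_boundedness(self):
        obstacles = [disc_obstacle(3 * i + j, 100 * j, 100 * i)
                     for i in range(3) for j in range(3)]
        cells = compute_voronoi(obstacles)
        bounded = {c.obstacle_id for c in cells if c.bounded}
        assert bounded == {4}
        ids = boundary_obstacle_ids(cells, (200, 200))
        assert set(ids) == set(range(9)) - {4}

    def test_duplicate_centers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            compute_voronoi([disc_obstacle(0, 5, 5), disc_obstacle(1, 5, 5)])
        with pytest.raises(ValueError, match="at least 2"):
            compute_voronoi([disc_obstacle(0, 5, 5)])

    def test_cells_contain_their_seed(self, rng):
        from shapely.geometry import Point
        centers = rng.uniform(0, 500, size=(15, 2))
        obstacles = [disc_obstacle(i, *c) for i, c in enumerate(centers)]
        for cell, obst in zip(compute_voronoi(obstacles), obstacles):
            assert cell.polygon.covers(Point(obst.center))

    def test_nearest_seed_oracle(self, rng):
        """Every sampled point lies in the cell of its nearest seed."""
        centers = rng.uniform(0, 400, size=(12, 2))
        obstacles = [disc_obstacle(i, *c) for i, c in enumerate(centers)]
        cells = compute_voronoi(obstacles)
        tree = cKDTree(centers)
        samples = rng.uniform(-50, 450, size=(2000, 2))
        _, nearest = tree.query(samples)
        from shapely.geometry import Point
        for pt, expect in zip(samples, nearest):
            d = np.linalg.norm(centers - pt, axis=1)
            d.sort()
            if d[1] - d[0] < 1e-6:
                continue  # skip near-equidistant samples
            inside = [c.obstacle_id for c in cells
                      if c.polygon.covers(Point(pt))]
            assert inside == [obstacles[expect].id]


def _raster_adjacency(centers, n=400, min_border=2):
    """Oracle: label a dense grid by nearest seed; two labels are adjacent
    if they share an 8-connected border of at least ``min_border`` pixels."""
    lo = centers.min(axis=0) - 60
    hi = centers.max(axis=0) + 60
    xs = np.linspace(lo[0], hi[0], n)
    ys = np.linspace(lo[1], hi[1], n)
    X, Y = np.meshgrid(xs, ys)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    _, labels = cKDTree(centers).query(pts)
    lab = labels.reshape(n, n)
    counts = {}
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = lab[max(0, -dy):n - max(0, dy), max(0, -dx):n - max(0, dx)]
        b = lab[max(0, dy):n + min(0, dy) or n, max(0, dx):n + min(0, dx) or n]
        diff = a != b
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            key = (min(u, v), max(u, v))
            counts[key] = counts.get(key, 0) + 1
    return {k for k, c in counts.items() if c >= min_border}


class TestAdjacency:
    def test_square_grid_excludes_diagonals(self):
        obstacles = [disc_obstacle(0, 0, 0), disc_obstacle(1, 100, 0),
                     disc_obstacle(2, 100, 100), disc_obstacle(3, 0, 100)]
        pairs = set(adjacent_pairs(compute_voronoi(obstacles)))
        assert pairs == {(0, 1), (1, 2), (2, 3), (0, 3)}

    def test_matches_rasterization_oracle(self, rng):
        centers = rng.uniform(0, 400, size=(14, 2))
        obstacles = [disc_obstacle(i, *c) for i, c in enumerate(centers)]
        cells = compute_voronoi(obstacles)
        pairs = set(adjacent_pairs(cells))
        oracle = _raster_adjacency(centers, min_border=4)
        # the raster can miss hairline ridges, so every oracle pair must be
        # found, and any extra pair must be a genuine (tiny) ridge: its
        # midpoint is equidistant from the two seeds and nearer to them
        # than to any other seed
        assert oracle <= pairs
        by_id = {c.obstacle_id: c for c in cells}
        for i, j in pairs - oracle:
            ridge = by_id[i].polygon.intersection(by_id[j].polygon)
            m = np.asarray(ridge.interpolate(0.5, normalized=True).coords[0])
            d = np.linalg.norm(centers - m, axis=1)
            assert abs(d[i] - d[j]) < 1e-6
            others = np.delete(d, [i, j])
            assert d[i] <= others.min() + 1e-6


class TestObstacleGates:
    def test_edge_to_edge_length(self):
        obstacles = [disc_obstacle(0, 0, 0, r=10), disc_obstacle(1, 100, 0, r=10)]
        [gate] = obstacle_gates([(0, 1)], obstacles)
        assert gate.length_px == pytest.approx(80.0)
        assert gate.kind == "obstacle" and (gate.a, gate.b) == (0, 1)

    def test_touching_clamped_with_warning(self):
        obstacles = [disc_obstacle(0, 0, 0, r=10), disc_obstacle(1, 15, 0, r=10)]
        with pytest.warns(RuntimeWarning, match="clamped"):
            [gate] = obstacle_gates([(0, 1)], obstacles)
        assert gate.length_px == 0.0

    def test_center_mode(self):
        obstacles = [disc_obstacle(0, 0, 0, r=10), disc_obstacle(1, 100, 0, r=10)]
        [gate] = obstacle_gates([(0, 1)], obstacles, mode="center")
        assert gate.length_px == pytest.approx(100.0)

    def test_symmetric_in_pair_order(self):
        obstacles = [disc_obstacle(0, 0, 0, r=5), disc_obstacle(1, 50, 30, r=8)]
        [g1] = obstacle_gates([(0, 1)], obstacles)
        [g2] = obstacle_gates([(1, 0)], obstacles)
        assert g1.length_px == pytest.approx(g2.length_px)


class TestImaginaryObstacles:
    def corners(self):
        return np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]])

    def test_orthogonal_foot(self):
        obstacles = [disc_obstacle(0, 10, 50, r=4), disc_obstacle(1, 70, 50, r=4)]
        cells = compute_voronoi(obstacles)
        feet = imaginary_obstacles(obstacles[0], cells[0], self.corners(),
                                   (100, 100))
        # left edge runs (0,100)->(0,0): the foot is the perpendicular drop
        assert any(np.allclose(f, (0, 50)) for f in feet)

    def test_corner_obstacle_two_edges(self):
        obstacles = [disc_obstacle(0, 15, 15, r=4), disc_obstacle(1, 60, 60, r=4)]
        cells = compute_voronoi(obstacles)
        feet = imaginary_obstacles(obstacles[0], cells[0], self.corners(),
                                   (100, 100))
        assert len(feet) == 2
        assert {tuple(np.round(f)) for f in feet} == {(15, 0), (0, 15)}

    def test_foot_clamped_to_edge_endpoint(self):
        obstacles = [disc_obstacle(0, 10, 40, r=4), disc_obstacle(1, 60, 40, r=4)]
        corners = np.array([[0.0, 50.0], [100.0, 50.0],
                            [100.0, 100.0], [0.0, 100.0]])
        feet = imaginary_obstacles(
            obstacles[0], compute_voronoi(obstacles)[0], corners, (100, 100))
        # foot onto the left edge x=0 (y in [50,100]) clamps to (0,50)
        assert any(np.allclose(f, (0, 50)) for f in feet)


class TestBoundaryGates:
    def test_wall_distance_minus_radius(self):
        obstacles = [disc_obstacle(0, 10, 50, r=4), disc_obstacle(1, 70, 50, r=4)]
        cells = compute_voronoi(obstacles)
        corners = np.array([[0.0, 0.0], [100.0, 0.0],
                            [100.0, 100.0], [0.0, 100.0]])
        gates = boundary_gates(obstacles, cells, corners, (100, 100))
        left = [g for g in gates if g.a == 0 and
                np.allclose(g.endpoints[1], (0, 50))]
        assert len(left) == 1
        assert left[0].length_px == pytest.approx(6.0)
        assert left[0].kind == "boundary" and left[0].b is None

    def test_one_obstacle_per_side(self):
        """Square tank, one obstacle near each wall: each gets a boundary
        gate to its wall with the analytic length."""
        corners = np.array([[0.0, 0.0], [200.0, 0.0],
                            [200.0, 200.0], [0.0, 200.0]])
        spots = [(100, 20), (180, 100), (100, 180), (20, 100)]
        obstacles = [disc_obstacle(i, x, y, r=10) for i, (x, y) in
                     enumerate(spots)]
        cells = compute_voronoi(obstacles)
        gates = boundary_gates(obstacles, cells, corners, (200, 200))
        for i, (x, y) in enumerate(spots):
            wall_dist = min(x, y, 200 - x, 200 - y)
            own = [g for g in gates if g.a == i]
            assert any(abs(g.length_px - (wall_dist - 10)) < 1e-6
                       for g in own)

    def test_all_gate_lengths_nonnegative(self, small_trial):
        assert all(g.length_px >= 0 for g in small_trial.scene.gates)


# ---------------------------------------------------------------------------
# file interfaces


def test_calibration_json_round_trip(tmp_path):
    calib = calib_from_points((1, 2), (3, 4), (5, 6), (7, 8))
    path = tmp_path / "calib.json"
    write_calibration(calib, path)
    back = read_calibration(path)
    for i in range(1, 9):
        assert np.allclose(getattr(back, f"p{i}"), getattr(calib, f"p{i}"))
    path.write_text('{"nope": 1}')
    with pytest.raises(ValueError, match="points"):
        read_calibration(path)


def test_obstacles_csv_round_trip(tmp_path):
    obstacles = [disc_obstacle(0, 30, 40, r=12), disc_obstacle(5, 99, 7, r=3)]
    path = tmp_path / "obstacles.csv"
    write_obstacles(obstacles, path)
    back = read_obstacles(path)
    assert [(o.id, o.bbox.astuple()) for o in back] == \
           [(o.id, o.bbox.astuple()) for o in obstacles]
    assert back[0].radius_px == pytest.approx(12.0)
    path.write_text("id,x0,y0,x1,y1\n1,0,0,5,5\n1,10,10,15,15\n")
    with pytest.raises(ValueError, match="unique"):
        read_obstacles(path)


def test_build_gates_end_to_end(small_trial):
    scene = small_trial.scene
    layout = build_gates(scene.obstacles, scene.calibration,
                         (scene.config.width, scene.config.height))
    assert abs(layout.homology.mu - scene.config.mu) < 1e-9
    assert [g.length_px for g in layout.gates] == \
           pytest.approx([g.length_px for g in scene.gates])
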