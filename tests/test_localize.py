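import itertools

import numpy as np
import pytest

from radiofix import (
    BearingFix,
    PositionFix,
    RangeModel,
    activity_budget,
    bearing_intersections,
    group_by_window,
    mcp_100,
    single_station_position,
    triangulate,
)
from radiofix.scene import azimuth_deg


def fix(station, t, brg, channel=150e3, rssi=70.0):
    return BearingFix(station_id=station, time_s=t, channel_khz=channel,
                      bearing_deg=brg, delta_brg_deg=0.0, rssi_max_dba=rssi)


STATIONS = {"A": (0.0, 0.0), "B": (1000.0, 0.0), "C": (500.0, 1500.0)}


def bearings_to(target, stations=STATIONS):
    return {sid: float(azimuth_deg(p[0], p[1], target[0], target[1]))
            for sid, p in stations.items()}


class TestGroupByWindow:
    def test_nearby_fixes_grouped(self):
        groups = group_by_window([fix("A", 100.0, 10.0), fix("B", 110.0, 20.0)],
                                 window_s=60.0)
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_small_window_splits(self):
        with pytest.warns(UserWarning):
            groups = group_by_window([fix("A", 100.0, 10.0),
                                      fix("B", 110.0, 20.0)], window_s=5.0)
        assert len(groups) == 2

    def test_duplicate_station_keeps_latest(self):
        groups = group_by_window([fix("A", 10.0, 1.0), fix("A", 20.0, 2.0),
                                  fix("A", 30.0, 3.0)], window_s=60.0)
        assert len(groups) == 1 and len(groups[0]) == 1
        assert groups[0][0].bearing_deg == 3.0

    def test_channels_never_mixed(self):
        groups = group_by_window([fix("A", 10.0, 1.0, channel=150e3),
                                  fix("B", 11.0, 2.0, channel=151e3)],
                                 window_s=60.0)
        assert len(groups) == 2


class TestBearingIntersections:
    def test_symmetric_crossing(self):
        pts = bearing_intersections([fix("A", 0.0, 45.0), fix("B", 0.0, 315.0)],
                                    STATIONS)
        assert len(pts) == 1
        assert pts[0] == pytest.approx((500.0, 500.0), abs=1e-9)

    def test_parallel_rays_never_meet(self):
        pts = bearing_intersections([fix("A", 0.0, 0.0), fix("B", 0.0, 0.0)],
                                    STATIONS)
        assert pts == []

    def test_backward_crossing_discarded(self):
        # rays point away from each other: the line crossing is behind
        pts = bearing_intersections([fix("A", 0.0, 270.0), fix("B", 0.0, 90.0)],
                                    STATIONS)
        assert pts == []

    def test_three_stations_noiseless_coincide_at_truth(self):
        target = (321.0, 654.0)
        brgs = bearings_to(target)
        group = [fix(s, 0.0, b) for s, b in brgs.items()]
        pts = bearing_intersections(group, STATIONS)
        assert len(pts) == 3
        for p in pts:
            assert p == pytest.approx(target, abs=1e-6)


class TestTriangulate:
    def test_noiseless_bearings_recover_target_exactly(self):
        target = (321.0, 654.0)
        group = [fix(s, 0.0, b) for s, b in bearings_to(target).items()]
        pos = triangulate(group, STATIONS)
        assert pos.method == "triangulated"
        assert pos.n_stations == 3
        assert (pos.east_m, pos.north_m) == pytest.approx(target, abs=1e-6)

    def test_two_station_crossing(self):
        target = (400.0, 700.0)
        sub = {k: STATIONS[k] for k in ("A", "B")}
        group = [fix(s, 0.0, b) for s, b in bearings_to(target, sub).items()]
        pos = triangulate(group, sub)
        assert pos.n_stations == 2
        assert (pos.east_m, pos.north_m) == pytest.approx(target, abs=1e-6)

    def test_permutation_invariance(self):
        target = (100.0, 900.0)
        group = [fix(s, 0.0, b) for s, b in bearings_to(target).items()]
        results = {tuple(np.round(
            (triangulate(list(perm), STATIONS).east_m,
             triangulate(list(perm), STATIONS).north_m), 9))
            for perm in itertools.permutations(group)}
        assert len(results) == 1

    def test_centroid_lies_inside_intersection_hull(self):
        rng = np.random.default_rng(8)
        from shapely.geometry import MultiPoint, Point
        for _ in range(20):
            target = rng.uniform(200.0, 1200.0, 2)
            group = [fix(s, 0.0, (b + rng.normal(0, 3.0)) % 360)
                     for s, b in bearings_to(tuple(target)).items()]
            pts = bearing_intersections(group, STATIONS)
            if not pts:
                continue
            pos = triangulate(group, STATIONS)
            hull = MultiPoint(pts).convex_hull
            assert hull.buffer(1e-6).covers(Point(pos.east_m, pos.north_m))

    def test_noisy_mean_position_unbiased(self):
        rng = np.random.default_rng(17)
        target = (450.0, 800.0)
        brgs = bearings_to(target)
        est = []
        for _ in range(1000):
            group = [fix(s, 0.0, (b + rng.normal(0.0, 2.0)) % 360)
                     for s, b in brgs.items()]
            pos = triangulate(group, STATIONS)
            if pos is not None:
                est.append((pos.east_m, pos.north_m))
        est = np.array(est)
        se = est.std(axis=0) / np.sqrt(len(est))
        bias = est.mean(axis=0) - np.array(target)
        assert np.all(np.abs(bias) < 5 * se + 5.0)

    def test_single_station_group_rejected(self):
        with pytest.raises(ValueError):
            triangulate([fix("A", 0.0, 10.0)], STATIONS)

    def test_no_forward_intersections_returns_none(self):
        assert triangulate([fix("A", 0.0, 270.0), fix("B", 0.0, 90.0)],
                           STATIONS) is None


class TestSingleStationPosition:
    def test_due_north(self):
        f = fix("A", 0.0, 0.0)
        f.distance_m = 100.0
        pos = single_station_position(f, (0.0, 0.0))
        assert (pos.east_m, pos.north_m) == pytest.approx((0.0, 100.0))
        assert pos.method == "single_station" and pos.n_stations == 1

    def test_due_east_via_range_model(self):
        model = RangeModel(1000.0, 0.9)
        f = fix("A", 0.0, 90.0, rssi=10.0)
        pos = single_station_position(f, (0.0, 0.0), model)
        assert pos.east_m == pytest.approx(1000.0 * 0.9 ** 10, rel=1e-9)
        assert pos.north_m == pytest.approx(0.0, abs=1e-9)

    def test_missing_model_rejected(self):
        with pytest.raises(ValueError):
            single_station_position(fix("A", 0.0, 0.0), (0.0, 0.0))

    def test_round_trip_against_geometry(self):
        target = (640.0, -480.0)
        brg = float(azimuth_deg(0.0, 0.0, *target))
        f = fix("A", 0.0, brg)
        f.distance_m = float(np.hypot(*target))
        pos = single_station_position(f, (0.0, 0.0))
        assert (pos.east_m, pos.north_m) == pytest.approx(target, abs=1e-6)


def brute_force_hull_area(points):
    """Gift-wrapping (Jarvis march) + shoelace, independent of shapely."""
    pts = sorted(set(map(tuple, points)))
    hull = []
    current = pts[0]  # lexicographically smallest point is on the hull
    while True:
        hull.append(current)
        cand = None
        for p in pts:
            if p == current:
                continue
            if cand is None:
                cand = p
                continue
            cross = ((cand[0] - current[0]) * (p[1] - current[1])
                     - (cand[1] - current[1]) * (p[0] - current[0]))
            farther = (np.hypot(p[0] - current[0], p[1] - current[1])
                       > np.hypot(cand[0] - current[0], cand[1] - current[1]))
            if cross < 0 or (cross == 0 and farther):
                cand = p
        current = cand
        if current == hull[0]:
            break
    x = np.array([p[0] for p in hull])
    y = np.array([p[1] for p in hull])
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestMCP:
    def test_unit_square(self):
        poly, area = mcp_100([(0, 0), (0, 1), (1, 1), (1, 0)])
        assert area == pytest.approx(1.0)

    def test_interior_points_ignored(self):
        corners = [(0, 0), (0, 2), (2, 2), (2, 0)]
        _, area1 = mcp_100(corners)
        _, area2 = mcp_100(corners + [(1.0, 1.0), (0.5, 1.5)])
        assert area2 == pytest.approx(area1)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        pts = rng.uniform(-100.0, 100.0, size=(40, 2))
        _, area = mcp_100(pts)
        assert area == pytest.approx(brute_force_hull_area(pts), rel=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            mcp_100([(0, 0), (1, 1)])
        with pytest.raises(ValueError):
            mcp_100([(0, 0), (1, 1), (2, 2)])  # collinear


def pos(t, e, n):
    return PositionFix(time_s=t, channel_khz=150e3, east_m=e, north_m=n,
                       n_stations=1, method="single_station")


class TestActivityBudget:
    def test_stationary_is_all_feeding(self):
        budget = activity_budget([pos(t, 5.0, 5.0) for t in range(0, 600, 60)])
        assert budget.search_time_s == 0.0
        assert budget.feeding_time_s == 540.0

    def test_constant_motion_is_all_search(self):
        budget = activity_budget([pos(60 * i, 200.0 * i, 0.0)
                                  for i in range(10)])
        assert budget.feeding_time_s == 0.0
        assert budget.search_time_s == 540.0

    def test_half_and_half_split(self):
        fixes = [pos(0, 0, 0), pos(60, 0, 0), pos(120, 500, 0),
                 pos(180, 500, 0), pos(240, 1000, 0)]
        budget = activity_budget(fixes)
        assert budget.feeding_time_s == 120.0
        assert budget.search_time_s == 120.0
        assert budget.labels == ("feeding", "search", "feeding", "search")

    def test_fewer_than_two_fixes_zero_budget(self):
        budget = activity_budget([pos(0, 0, 0)])
        assert budget.total_s == 0.0
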