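"""Multi-station localisation and spatial post-processing.

Bearing fixes from different stations that fall in the same triangulation
time window are combined: every station pair contributes the intersection
of its two bearing rays, and the final position is the centre of gravity
(area centroid) of the convex hull of all mutual intersections.  A fix
seen by a single station still yields a position via the RSSI range
estimate along the bearing.  Post-processing summaries cover the 100 %
minimum convex polygon home range and a feeding/search activity budget.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .ranging import estimate_distance
from .types import ActivityBudget, BearingFix, PositionFix, RangeModel

__all__ = ["group_by_window", "bearing_intersections", "triangulate",
           "single_station_position", "mcp_100", "activity_budget"]

#: recommended triangulation window range (s)
WINDOW_RANGE_S = (15.0, 300.0)


def group_by_window(fixes: Iterable[BearingFix], window_s: float = 60.0):
    """Group fixes of one channel into tumbling time windows.

    Windows are non-overlapping, anchored at the epoch
    (window index = floor(t / window_s)).  Within a group at most one fix
    per station is kept — the latest.  Returns groups sorted by
    (channel, window), each a list of fixes.
    """
    if not WINDOW_RANGE_S[0] <= window_s <= WINDOW_RANGE_S[1]:
        warnings.warn(f"window_s={window_s} outside the recommended "
                      f"{WINDOW_RANGE_S[0]:.0f}-{WINDOW_RANGE_S[1]:.0f} s range")
    buckets: dict[tuple[float, int], dict[str, BearingFix]] = {}
    for f in fixes:
        key = (f.channel_khz, int(np.floor(f.time_s / window_s)))
        per_station = buckets.setdefault(key, {})
        prev = per_station.get(f.station_id)
        if prev is None or f.time_s > prev.time_s:
            per_station[f.station_id] = f
    return [sorted(b.values(), key=lambda f: (f.station_id, f.time_s))
            for _, b in sorted(buckets.items())]


def _ray_direction(bearing_deg: float) -> np.ndarray:
    b = np.deg2rad(bearing_deg)
    return np.array([np.sin(b), np.cos(b)])  # (east, north)


def bearing_intersections(group: Sequence[BearingFix],
                          station_positions: Mapping[str, tuple[float, float]],
                          parallel_eps: float = 1e-12):
    """All pairwise intersections of the group's forward bearing rays.

    Bearings are half-lines anchored at their stations: a pair whose rays
    are parallel, or whose crossing lies behind either station, yields no
    point.  Returns a list of (east, north) tuples (possibly empty).
    """
    pts = []
    group = list(group)
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            f1, f2 = group[i], group[j]
            p1 = np.asarray(station_positions[f1.station_id], dtype=float)
            p2 = np.asarray(station_positions[f2.station_id], dtype=float)
            u1 = _ray_direction(f1.bearing_deg)
            u2 = _ray_direction(f2.bearing_deg)
            det = u1[0] * (-u2[1]) - (-u2[0]) * u1[1]
            if abs(det) < parallel_eps:
                continue  # parallel rays never meet
            rhs = p2 - p1
            t1 = (rhs[0] * (-u2[1]) - (-u2[0]) * rhs[1]) / det
            t2 = (u1[0] * rhs[1] - rhs[0] * u1[1]) / det
            if t1 < 0 or t2 < 0:
                continue  # crossing lies behind a station
            q = p1 + t1 * u1
            pts.append((float(q[0]), float(q[1])))
    return pts


def triangulate(group: Sequence[BearingFix],
                station_positions: Mapping[str, tuple[float, float]]
                ) -> Optional[PositionFix]:
    """Centre of gravity of the convex hull of all mutual intersections.

    The hull degenerates gracefully: one intersection is returned as-is
    and collinear intersections yield the segment midpoint (the centroid
    of the degenerate hull).  Returns ``None`` when no pair of rays
    intersects forward — the caller may fall back to single-station
    positioning.
    """
    group = list(group)
    stations = {f.station_id for f in group}
    if len(stations) < 2:
        raise ValueError("triangulation needs fixes from at least 2 stations")
    pts = bearing_intersections(group, station_positions)
    if not pts:
        return None
    centroid = MultiPoint(pts).convex_hull.centroid
    return PositionFix(
        time_s=float(np.mean([f.time_s for f in group])),
        channel_khz=group[0].channel_khz,
        east_m=float(centroid.x), north_m=float(centroid.y),
        n_stations=len(stations), method="triangulated",
        contributing=tuple(sorted(stations)))


def single_station_position(fix: BearingFix,
                            station_position: tuple[float, float],
                            model: Optional[RangeModel] = None) -> PositionFix:
    """Project a lone bearing fix to a position along its ray.

    The range comes from the fix's ``distance_m`` when present, otherwise
    from the range model applied to RSSImax.
    """
    dist = fix.distance_m
    if dist is None:
        if model is None:
            raise ValueError("a range model is required when the fix has no distance")
        dist = estimate_distance(model, fix.rssi_max_dba)
    u = _ray_direction(fix.bearing_deg)
    east = station_position[0] + dist * u[0]
    north = station_position[1] + dist * u[1]
    return PositionFix(time_s=fix.time_s, channel_khz=fix.channel_khz,
                       east_m=float(east), north_m=float(north),
                       n_stations=1, method="single_station",
                       contributing=(fix.station_id,))


def mcp_100(positions) -> tuple[Polygon, float]:
    """100 % minimum convex polygon of a set of positions, with its area.

    Accepts PositionFix objects or (east, north) pairs; needs at least
    three non-collinear positions.
    """
    pts = [(p.east_m, p.north_m) if isinstance(p, PositionFix) else tuple(p)
           for p in positions]
    if len(pts) < 3:
        raise ValueError("at least 3 positions are required")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("positions are collinear: no polygon exists")
    return hull, float(hull.area)


def activity_budget(fixes: Sequence[PositionFix],
                    move_epsilon_m: float = 50.0) -> ActivityBudget:
    """Split a station's fix sequence into feeding and search time.

    Each interval between successive fixes is labelled *feeding* when the
    positions differ by at most ``move_epsilon_m`` (the animal stayed
    put, to within the system's positional noise) and *search*
    otherwise; interval durations are summed per label.  Fewer than two
    fixes give a zero budget.
    """
    fixes = sorted(fixes, key=lambda f: f.time_s)
    feeding = search = 0.0
    labels: list[str] = []
    for a, b in zip(fixes, fixes[1:]):
        dt = b.time_s - a.time_s
        moved = float(np.hypot(b.east_m - a.east_m, b.north_m - a.north_m))
        if moved <= move_epsilon_m:
            feeding += dt
            labels.append("feeding")
        else:
            search += dt
            labels.append("search")
    return ActivityBudget(feeding_time_s=feeding, search_time_s=search,
                          labels=tuple(labels))
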