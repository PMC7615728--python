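"""Bivariate bagplot flagging via Tukey halfspace depth.

The halfspace (Tukey) depth of a point is the minimum number of data
points in any closed halfplane whose boundary passes through it.  The
bagplot generalizes the boxplot to two dimensions: the "bag" is a
convex polygon around the deepest points holding at most half the
data, and the "fence" is the bag inflated (default factor 3) about the
depth median; points strictly outside the fence are flagged.

Depth is computed exactly by an angular sweep: for a query q, sort the
angles of the data points around q; the depth is n minus the largest
number of points inside an open half-circle, plus points coincident
with q.  Candidate half-circles start just after each data angle or
its antipode, so the sweep is O(n log n) per query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely import affinity
from shapely.geometry import Polygon

__all__ = ["Bagplot", "halfspace_depth", "halfspace_depths", "build_bagplot", "bagplot_flags"]


def _depth_one(q: np.ndarray, cloud: np.ndarray) -> int:
    v = cloud - q
    nonzero = (v[:, 0] != 0) | (v[:, 1] != 0)
    n0 = int(np.size(nonzero) - np.count_nonzero(nonzero))
    a = np.sort(np.arctan2(v[nonzero, 1], v[nonzero, 0]))
    m = a.size
    if m == 0:
        return n0
    # open half-circle starting just after each angle: (a_j, a_j + pi]
    c_hi = np.concatenate([a, a + 2 * np.pi])
    count1 = np.searchsorted(c_hi, a + np.pi, side="right") - np.searchsorted(c_hi, a, side="right")
    # ... and just after each antipode: (a_j - pi, a_j]
    c_lo = np.concatenate([a - 2 * np.pi, a])
    count2 = np.searchsorted(c_lo, a, side="right") - np.searchsorted(c_lo, a - np.pi, side="right")
    max_open = max(int(count1.max()), int(count2.max()))
    return n0 + m - max_open


def halfspace_depth(point, cloud) -> int:
    """Exact Tukey halfspace depth of one 2-D point w.r.t. a point cloud."""
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[1] != 2 or len(cloud) == 0:
        raise ValueError("cloud must be a nonempty (n, 2) array")
    return _depth_one(np.asarray(point, dtype=float), cloud)


def halfspace_depths(cloud, queries=None) -> np.ndarray:
    """Halfspace depth of each query point (default: every cloud point)."""
    cloud = np.asarray(cloud, dtype=float)
    qs = cloud if queries is None else np.asarray(queries, dtype=float)
    return np.fromiter((_depth_one(q, cloud) for q in qs), dtype=int, count=len(qs))


@dataclass(frozen=True)
class Bagplot:
    """Bag/fence geometry of a bivariate sample."""

    depth_median: np.ndarray
    bag: Polygon
    fence: Polygon
    inflation: float
    depths: np.ndarray = field(repr=False)


def _hull_polygon(points: np.ndarray) -> Polygon:
    hull = ConvexHull(points)
    return Polygon(points[hull.vertices])


def build_bagplot(xy, inflation: float = 3.0) -> Bagplot:
    """Construct the bagplot of an (n, 2) sample.

    The bag is the convex hull of the ceil(n/2) deepest points, shrunk
    (by raising the depth cutoff) while it covers more than floor(n/2)
    of the points; the fence is the bag scaled by ``inflation`` about
    the depth median (the average of the deepest points).
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < 10:
        raise ValueError("need at least 10 points")
    depths = halfspace_depths(xy)
    dmax = depths.max()
    depth_median = xy[depths == dmax].mean(axis=0)

    order = np.argsort(-depths, kind="stable")
    k = -(-n // 2)  # ceil(n/2)
    cutoff = depths[order[k - 1]]
    levels = np.sort(np.unique(depths[depths >= cutoff]))
    pts_geom = shapely.points(xy)
    bag = None
    for level in levels:
        sel = xy[depths >= level]
        if len(sel) < 3:
            break
        try:
            candidate = _hull_polygon(sel)
        except QhullError as exc:
            if bag is None and level == levels[-1]:
                raise ValueError("degenerate (collinear) data: bag undefined") from exc
            break
        bag = candidate
        covered = int(np.count_nonzero(shapely.covers(bag, pts_geom)))
        if covered <= n // 2:
            break
    if bag is None:
        raise ValueError("degenerate (collinear) data: bag undefined")
    fence = affinity.scale(bag, xfact=inflation, yfact=inflation,
                           origin=(depth_median[0], depth_median[1]))
    return Bagplot(depth_median=depth_median, bag=bag, fence=fence,
                   inflation=inflation, depths=depths)


def bagplot_flags(xy, bag: Bagplot) -> np.ndarray:
    """Flag points strictly outside the fence (boundary points are kept)."""
    xy = np.asarray(xy, dtype=float)
    return ~shapely.covers(bag.fence, shapely.points(xy))
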