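"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the code paths they certify: winding-number
membership vs. even-odd ray crossing, interval-arithmetic rectangle arc
fractions vs. angle sampling, gift-wrapping vs. Qhull, density-reachability
closure vs. the BFS labeller, O(n^2) sorts vs. vectorized neighbor queries.
"""

from __future__ import annotations

import math

import numpy as np


def haversine_m(lon1, lat1, lon2, lat2, radius=6_371_000.0) -> float:
    """Great-circle distance in meters."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


def winding_number_inside(x: float, y: float, ring: np.ndarray) -> bool:
    """Nonzero winding-number membership for a simple ring (open, (k,2))."""
    wn = 0
    k = len(ring)
    for i in range(k):
        x0, y0 = ring[i]
        x1, y1 = ring[(i + 1) % k]
        if y0 <= y:
            if y1 > y and (x1 - x0) * (y - y0) - (x - x0) * (y1 - y0) > 0:
                wn += 1
        else:
            if y1 <= y and (x1 - x0) * (y - y0) - (x - x0) * (y1 - y0) < 0:
                wn -= 1
    return wn != 0


def rect_circle_inside_fraction(cx, cy, r, xmin, ymin, xmax, ymax) -> float:
    """Exact fraction of a circle's circumference inside an axis rectangle.

    The outside region is the union of four arcs (one per violated edge),
    computed by closed-form interval arithmetic; valid whenever the circle
    center lies inside the rectangle.
    """
    intervals = []  # outside arcs as (start, end) angles, possibly wrapping

    def half_plane_arc(dist, center_angle):
        # arc where the circle leaves the half-plane at signed distance `dist`
        if r <= dist:
            return None
        half = math.acos(dist / r)
        return (center_angle - half, center_angle + half)

    for dist, ang in ((cx - xmin, math.pi),          # left edge, outward = pi
                      (xmax - cx, 0.0),              # right edge
                      (cy - ymin, 3 * math.pi / 2),  # bottom edge
                      (ymax - cy, math.pi / 2)):     # top edge
        arc = half_plane_arc(dist, ang)
        if arc is not None:
            intervals.append(arc)

    if not intervals:
        return 1.0
    # normalize to [0, 2pi) and split wrapping intervals
    norm = []
    for a, b in intervals:
        length = b - a
        a %= 2 * math.pi
        b = a + length
        if b > 2 * math.pi:
            norm.append((a, 2 * math.pi))
            norm.append((0.0, b - 2 * math.pi))
        else:
            norm.append((a, b))
    norm.sort()
    merged = [list(norm[0])]
    for a, b in norm[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    outside = sum(b - a for a, b in merged)
    return 1.0 - outside / (2 * math.pi)


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices by gift wrapping (Jarvis march), CCW order."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return pts
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % len(pts)
        for r in range(len(pts)):
            if r == p:
                continue
            cross = ((pts[q, 0] - pts[p, 0]) * (pts[r, 1] - pts[p, 1])
                     - (pts[q, 1] - pts[p, 1]) * (pts[r, 0] - pts[p, 0]))
            if cross < 0 or (cross == 0
                             and np.linalg.norm(pts[r] - pts[p])
                             > np.linalg.norm(pts[q] - pts[p])):
                q = r
        if q == start:
            break
        hull.append(q)
        if len(hull) > len(pts):
            raise RuntimeError("gift wrapping failed")
    return pts[hull]


def brute_knn_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Each point's k-th nearest-neighbor distance via full O(n^2) sort."""
    pts = np.asarray(points, dtype=float)
    out = []
    for i in range(len(pts)):
        d = sorted(math.hypot(*(pts[j] - pts[i])) for j in range(len(pts))
                   if j != i)
        out.append(d[k - 1])
    return np.array(sorted(out))


def dbscan_closure_oracle(points: np.ndarray, eps: float, min_pts: int):
    """DBSCAN semantics by explicit density-reachability closure.

    Returns (core mask, core partition as frozensets of core indices,
    noise mask) — border-point labels are order-dependent by design, so the
    oracle pins only the order-free parts.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts

    # union core points whose mutual distance <= eps (transitive closure)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    core_idx = np.nonzero(core)[0]
    for a in core_idx:
        for b in core_idx:
            if neigh[a, b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, set] = {}
    for a in core_idx:
        groups.setdefault(find(a), set()).add(int(a))
    partition = {frozenset(g) for g in groups.values()}

    reachable = neigh[:, core_idx].any(axis=1) if len(core_idx) else np.zeros(n, bool)
    noise = ~reachable
    return core, partition, noise


def quantile_sorted(values, q: float) -> float:
    """Linear-interpolation quantile computed directly from order statistics."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
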