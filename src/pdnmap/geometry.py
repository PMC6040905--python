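"""Planar projection and computational-geometry primitives.

Everything downstream works in a local Cartesian frame (meters east/north of
a reference lon/lat).  At city scale (< ~10 km extent) a single equirectangular
projection reproduces great-circle distances to within ~2 m, which is the
accuracy bound the rest of the pipeline assumes; a full geodesy stack is
deliberately out of scope.

Polygon membership uses the even-odd (ray-crossing) rule with points exactly
on the boundary counted as *inside* — a stable convention for clipping and
edge correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EARTH_RADIUS_M",
    "GeoPoint",
    "PlanarPoint",
    "PolygonWindow",
    "project_to_plane",
    "inverse_project",
    "point_in_polygon",
    "circle_inside_fraction",
    "convex_hull",
    "centroid",
    "sample_uniform_in_window",
    "load_boundary_geojson",
]

EARTH_RADIUS_M = 6_371_000.0

#: maximum angular offset (degrees) from the projection reference we accept;
#: beyond city scale the small-angle distance guarantee no longer holds.
PROJECTION_VALIDITY_DEG = 0.5


@dataclass(frozen=True)
class GeoPoint:
    """Geographic coordinate in decimal degrees (WGS84/NAD83 treated as one)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class PlanarPoint:
    """Projected coordinate in meters east/north of the projection reference."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("planar coordinates must be finite")


def _as_xy(points) -> np.ndarray:
    """Coerce a sequence of PlanarPoint / pairs / an (n,2) array to float array."""
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
    else:
        pts = list(points)
        if pts and isinstance(pts[0], PlanarPoint):
            arr = np.array([(p.x, p.y) for p in pts], dtype=float)
        else:
            arr = np.asarray(pts, dtype=float)
    if arr.ndim == 1 and arr.size == 2:
        arr = arr.reshape(1, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of planar coordinates")
    return arr


def _ring_area(ring: np.ndarray) -> float:
    """Signed shoelace area of a ring given as an (k,2) open array."""
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _close_ring(ring: np.ndarray) -> np.ndarray:
    if not np.array_equal(ring[0], ring[-1]):
        return np.vstack([ring, ring[0]])
    return ring


def _ring_self_intersects(ring: np.ndarray) -> bool:
    """O(k^2) segment-pair intersection check; rings here are tiny."""
    closed = _close_ring(ring)
    segs = [(closed[i], closed[i + 1]) for i in range(len(closed) - 1)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def intersects(p1, p2, p3, p4):
        d1 = cross(p3, p4, p1)
        d2 = cross(p3, p4, p2)
        d3 = cross(p1, p2, p3)
        d4 = cross(p1, p2, p4)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    n = len(segs)
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the closure
            if intersects(*segs[i], *segs[j]):
                return True
    return False


class PolygonWindow:
    """Observation window: an outer ring plus optional holes, planar meters.

    Parameters
    ----------
    shell : (k, 2) array-like
        Outer ring vertices (open or closed; stored open, CCW orientation).
    holes : iterable of (k, 2) array-like, optional
        Interior rings.
    reference : GeoPoint, optional
        Lon/lat used as origin of the local projection (metadata only).
    allow_degenerate : bool
        Permit zero-area windows (used for degenerate convex hulls).
    """

    def __init__(self, shell, holes: Iterable | None = None,
                 reference: GeoPoint | None = None,
                 allow_degenerate: bool = False) -> None:
        shell = _as_xy(shell)
        if np.array_equal(shell[0], shell[-1]) and len(shell) > 1:
            shell = shell[:-1]
        if _ring_area(shell) < 0:
            shell = shell[::-1].copy()
        self.shell = shell
        self.holes = [_as_xy(h) for h in (holes or [])]
        self.holes = [h[:-1] if len(h) > 1 and np.array_equal(h[0], h[-1]) else h
                      for h in self.holes]
        self.reference = reference
        self.degenerate = False

        if len(self.shell) >= 4 and _ring_self_intersects(self.shell):
            raise ValueError("outer ring is self-intersecting")
        area = _ring_area(self.shell) - sum(abs(_ring_area(h)) for h in self.holes)
        if area <= 0.0:
            if not allow_degenerate:
                raise ValueError("polygon window has non-positive area")
            self.degenerate = True
        self._area = max(area, 0.0)

        # flat edge arrays over all rings, for vectorized membership tests;
        # a single-vertex (degenerate) shell becomes one zero-length segment
        rings = [self.shell if len(self.shell) >= 2
                 else np.vstack([self.shell, self.shell])] + self.holes
        p0 = np.vstack([_close_ring(r)[:-1] for r in rings if len(r) >= 2])
        p1 = np.vstack([_close_ring(r)[1:] for r in rings if len(r) >= 2])
        self._ex0, self._ey0 = p0[:, 0], p0[:, 1]
        self._ex1, self._ey1 = p1[:, 0], p1[:, 1]

    @property
    def area(self) -> float:
        """Window area in m2 (shoelace of shell minus holes)."""
        return self._area

    @property
    def vertices(self) -> np.ndarray:
        return self.shell

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xs, ys = self.shell[:, 0], self.shell[:, 1]
        return float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max())

    # -- membership ---------------------------------------------------------

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized even-odd membership for many points.

        Boundary behaviour is unspecified here (measure-zero for the sampling
        uses this serves); use :func:`point_in_polygon` for the boundary-
        inclusive scalar contract.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shp = x.shape
        xf = x.ravel()[:, None]
        yf = y.ravel()[:, None]
        y0, y1 = self._ey0[None, :], self._ey1[None, :]
        x0, x1 = self._ex0[None, :], self._ex1[None, :]
        straddle = (y0 > yf) != (y1 > yf)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0 + (yf - y0) * (x1 - x0) / (y1 - y0)
        crossings = np.sum(straddle & (xf < xint), axis=1)
        return (crossings % 2 == 1).reshape(shp)

    def boundary_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest boundary segment."""
        from ._fast import HAVE_NUMBA, _boundary_distance_nb
        if HAVE_NUMBA:
            xf = np.ascontiguousarray(np.asarray(x, dtype=float).ravel())
            yf = np.ascontiguousarray(np.asarray(y, dtype=float).ravel())
            return _boundary_distance_nb(xf, yf, self._ex0, self._ey0,
                                         self._ex1, self._ey1)
        x = np.asarray(x, dtype=float).ravel()[:, None]
        y = np.asarray(y, dtype=float).ravel()[:, None]
        x0, y0 = self._ex0[None, :], self._ey0[None, :]
        dx = self._ex1[None, :] - x0
        dy = self._ey1[None, :] - y0
        seg_len2 = dx * dx + dy * dy
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((x - x0) * dx + (y - y0) * dy) / seg_len2
        t = np.clip(np.nan_to_num(t), 0.0, 1.0)
        px = x0 + t * dx
        py = y0 + t * dy
        d2 = (x - px) ** 2 + (y - py) ** 2
        return np.sqrt(d2.min(axis=1))

    def _on_boundary(self, x: float, y: float, tol: float = 1e-9) -> bool:
        scale = max(1.0, math.sqrt(abs(self._area)))
        return bool(self.boundary_distance(np.array([x]), np.array([y]))[0]
                    <= tol * scale)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PolygonWindow(area={self._area:.1f} m2, "
                f"{len(self.shell)} vertices, {len(self.holes)} holes)")


def project_to_plane(points: Sequence[GeoPoint], reference: GeoPoint,
                     radius: float = EARTH_RADIUS_M) -> list[PlanarPoint]:
    """Project lon/lat points to local planar meters about ``reference``.

    Equirectangular: x = R (lon-lon0) cos(lat0), y = R (lat-lat0), angles in
    radians.  Valid for points within ~0.5 degrees of the reference; distances
    between projected points then match great-circle distances to within ~2 m
    over a <= 10 km extent.

    Raises
    ------
    ValueError
        If any point falls outside the validity window.
    """
    out = []
    coslat = math.cos(math.radians(reference.lat))
    for p in points:
        if (abs(p.lon - reference.lon) > PROJECTION_VALIDITY_DEG
                or abs(p.lat - reference.lat) > PROJECTION_VALIDITY_DEG):
            raise ValueError(
                f"point ({p.lon}, {p.lat}) is more than "
                f"{PROJECTION_VALIDITY_DEG} deg from reference "
                f"({reference.lon}, {reference.lat})")
        x = radius * math.radians(p.lon - reference.lon) * coslat
        y = radius * math.radians(p.lat - reference.lat)
        out.append(PlanarPoint(x, y))
    return out


def inverse_project(points: Sequence[PlanarPoint], reference: GeoPoint,
                    radius: float = EARTH_RADIUS_M) -> list[GeoPoint]:
    """Exact inverse of :func:`project_to_plane`."""
    coslat = math.cos(math.radians(reference.lat))
    out = []
    for p in points:
        lon = reference.lon + math.degrees(p.x / (radius * coslat))
        lat = reference.lat + math.degrees(p.y / radius)
        out.append(GeoPoint(lon, lat))
    return out


def point_in_polygon(p: PlanarPoint | tuple[float, float],
                     w: PolygonWindow) -> bool:
    """Even-odd membership; points on the boundary count as inside."""
    if isinstance(p, PlanarPoint):
        x, y = p.x, p.y
    else:
        x, y = float(p[0]), float(p[1])
    if w._on_boundary(x, y):
        return True
    return bool(w.contains_xy(np.array([x]), np.array([y]))[0])


def circle_inside_fraction(center: PlanarPoint | tuple[float, float],
                           radius: float, w: PolygonWindow,
                           resolution: int = 720) -> float:
    """Fraction of a circle's circumference lying inside the window.

    Estimated by testing ``resolution`` equally spaced angles for membership;
    the error is at most ~1/resolution for windows whose boundary detail is
    coarse relative to the circle.  This fraction is the denominator of the
    isotropic edge-correction weight used by the K-function estimator.
    """
    if isinstance(center, PlanarPoint):
        cx, cy = center.x, center.y
    else:
        cx, cy = float(center[0]), float(center[1])
    if radius <= 0:
        raise ValueError("radius must be positive")
    if resolution < 64:
        raise ValueError("resolution must be >= 64")
    if not point_in_polygon((cx, cy), w):
        raise ValueError("circle center lies outside the window")
    theta = np.arange(resolution) * (2.0 * math.pi / resolution)
    xs = cx + radius * np.cos(theta)
    ys = cy + radius * np.sin(theta)
    return float(np.mean(w.contains_xy(xs, ys)))


def arc_inside_fractions(centers: np.ndarray, dists: np.ndarray,
                         w: PolygonWindow, resolution: int) -> np.ndarray:
    """Inside-circumference fractions for many (center, radius) pairs at once.

    Same angle-sampling estimate as :func:`circle_inside_fraction` (without
    the center-membership precondition check, which callers guarantee),
    batched for the K-function edge-correction hot path.
    """
    from ._fast import HAVE_NUMBA, _arc_fractions_nb
    centers = np.asarray(centers, dtype=float)
    dists = np.asarray(dists, dtype=float)
    if HAVE_NUMBA:
        return _arc_fractions_nb(
            np.ascontiguousarray(centers[:, 0]),
            np.ascontiguousarray(centers[:, 1]),
            np.ascontiguousarray(dists),
            w._ex0, w._ey0, w._ex1, w._ey1, resolution)
    theta = np.arange(resolution) * (2.0 * math.pi / resolution)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    out = np.empty(len(dists))
    per = max(200_000 // resolution, 1)
    for s in range(0, len(dists), per):
        cx = centers[s:s + per, 0][:, None] + dists[s:s + per][:, None] * cos_t
        cy = centers[s:s + per, 1][:, None] + dists[s:s + per][:, None] * sin_t
        out[s:s + per] = w.contains_xy(cx, cy).mean(axis=1)
    return out


def convex_hull(points) -> PolygonWindow:
    """Minimal convex polygon containing the points.

    Collinear or single-point inputs yield a degenerate window with area 0
    and ``degenerate=True`` rather than an error, so single-location clusters
    summarize cleanly.
    """
    xy = _as_xy(points)
    if len(xy) == 0:
        raise ValueError("convex hull of empty point set")
    uniq = np.unique(xy, axis=0)
    if len(uniq) >= 3:
        from scipy.spatial import ConvexHull, QhullError
        try:
            hull = ConvexHull(uniq)
            ring = uniq[hull.vertices]
            return PolygonWindow(ring, allow_degenerate=True)
        except QhullError:
            pass  # collinear input; fall through to degenerate handling
    # degenerate: point or segment — keep extreme vertices, area 0
    order = np.lexsort((uniq[:, 1], uniq[:, 0]))
    ring = uniq[order][[0, -1]] if len(uniq) > 1 else np.vstack([uniq, uniq])
    return PolygonWindow(ring, allow_degenerate=True)


def centroid(points) -> PlanarPoint:
    """Arithmetic mean of coordinates, with multiplicity (run-weighted)."""
    xy = _as_xy(points)
    if len(xy) == 0:
        raise ValueError("centroid of empty point set")
    m = xy.mean(axis=0)
    return PlanarPoint(float(m[0]), float(m[1]))


def sample_uniform_in_window(n: int, window: PolygonWindow,
                             rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. uniform points in the window, by bbox rejection sampling."""
    if n < 0:
        raise ValueError("n must be >= 0")
    xmin, ymin, xmax, ymax = window.bounds
    out = np.empty((n, 2))
    filled = 0
    # acceptance rate = area / bbox area; batch accordingly
    rate = max(window.area / max((xmax - xmin) * (ymax - ymin), 1e-300), 1e-3)
    while filled < n:
        m = max(int((n - filled) / rate * 1.2) + 16, 16)
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        ok = window.contains_xy(xs, ys)
        take = min(int(ok.sum()), n - filled)
        out[filled:filled + take, 0] = xs[ok][:take]
        out[filled:filled + take, 1] = ys[ok][:take]
        filled += take
    return out


# -- GeoJSON boundary I/O ----------------------------------------------------

def _extract_polygon_rings(geom: dict) -> list[list]:
    gtype = geom.get("type")
    if gtype == "Polygon":
        return geom["coordinates"]
    if gtype == "MultiPolygon":
        # use the largest part by shoelace area of the outer ring (in degrees)
        parts = geom["coordinates"]
        if len(parts) > 1:
            def deg_area(rings):
                return abs(_ring_area(np.asarray(rings[0], dtype=float)))
            parts = [max(parts, key=deg_area)]
        return parts[0]
    raise ValueError(f"unsupported GeoJSON geometry type: {gtype}")


def load_boundary_geojson(path_or_obj, reference: GeoPoint | None = None,
                          radius: float = EARTH_RADIUS_M) -> PolygonWindow:
    """Read a boundary polygon (WGS84 lon-lat GeoJSON) as a planar window.

    Accepts a Feature, FeatureCollection (first polygonal feature), or bare
    geometry.  ``reference`` defaults to the mean lon/lat of the outer ring;
    for a MultiPolygon only the largest part is kept.
    """
    if isinstance(path_or_obj, (str,)) or hasattr(path_or_obj, "__fspath__"):
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    else:
        obj = path_or_obj

    if obj.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in obj["features"]
                 if f.get("geometry", {}).get("type") in ("Polygon", "MultiPolygon")]
        if not geoms:
            raise ValueError("no polygonal feature in FeatureCollection")
        geom = geoms[0]
    elif obj.get("type") == "Feature":
        geom = obj["geometry"]
    else:
        geom = obj

    rings = _extract_polygon_rings(geom)
    outer = np.asarray(rings[0], dtype=float)
    if reference is None:
        ref_lonlat = outer.mean(axis=0)
        reference = GeoPoint(float(ref_lonlat[0]), float(ref_lonlat[1]))

    def proj_ring(ring_lonlat):
        geo = [GeoPoint(float(lon), float(lat)) for lon, lat in ring_lonlat]
        pl = project_to_plane(geo, reference, radius=radius)
        return np.array([(p.x, p.y) for p in pl])

    shell = proj_ring(outer)
    holes = [proj_ring(np.asarray(r, dtype=float)) for r in rings[1:]]
    return PolygonWindow(shell, holes=holes, reference=reference)


def window_to_geojson(window: PolygonWindow,
                      radius: float = EARTH_RADIUS_M) -> dict:
    """Serialize a window back to a lon-lat GeoJSON Polygon geometry."""
    if window.reference is None:
        raise ValueError("window has no projection reference")

    def ring_coords(ring):
        pts = [PlanarPoint(float(x), float(y)) for x, y in _close_ring(ring)]
        geo = inverse_project(pts, window.reference, radius=radius)
        return [[g.lon, g.lat] for g in geo]

    coords = [ring_coords(window.shell)] + [ring_coords(h) for h in window.holes]
    return {"type": "Polygon", "coordinates": coords}
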