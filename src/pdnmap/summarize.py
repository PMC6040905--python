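"""Per-cluster characterization and location-frequency profiling.

Summary columns mirror the reporting table: Runs, Locations, Area (convex
hull, m2), M-Dist (median run-to-centroid distance, m), N-200/P-200 (count
and percent of runs within the coverage radius of the centroid), M-Age
(median age, missing excluded) and P-Female (percent female, missing
excluded).

Geometry conventions: the hull/area uses unique locations so multiplicity
cannot inflate a polygon, while the centroid and distance distribution use
run-level points (they describe where demand is).  Both are switchable.
Quantiles use linear interpolation between order statistics throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import GeoPoint, PlanarPoint, PolygonWindow, _as_xy, centroid, convex_hull

__all__ = ["ClusterSummary", "summarize_cluster", "LocationProfile",
           "location_frequency_profile", "compare_subgroups", "GroupSummary"]


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    runs: int
    locations: int
    area: float                      # m2, convex hull of unique locations
    centroid: PlanarPoint
    centroid_geo: Optional[GeoPoint]
    m_dist: float                    # m, median run-to-centroid distance
    n_within: int                    # runs within `radius` of centroid
    radius: float
    m_age: Optional[float]
    p_female: Optional[float]        # percent, missing excluded
    hull: PolygonWindow

    @property
    def p_within(self) -> float:
        """Percent of the cluster's runs within `radius` of the centroid."""
        return round(100.0 * self.n_within / self.runs, 1)


def summarize_cluster(run_xy, location_xy=None,
                      ages: Optional[Sequence[Optional[float]]] = None,
                      sexes: Optional[Sequence[str]] = None,
                      radius: float = 200.0, cluster_id: int = 0,
                      centroid_mode: str = "runs",
                      reference: Optional[GeoPoint] = None) -> ClusterSummary:
    """Summarize one cluster from run-level points (and unique locations).

    ``location_xy`` defaults to the unique coordinates of ``run_xy``.  With
    ``centroid_mode='locations'`` the centroid averages unique locations
    instead of runs (sensitivity analysis).
    """
    xy = _as_xy(run_xy)
    if len(xy) == 0:
        raise ValueError("cannot summarize an empty cluster")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    loc_xy = np.unique(xy, axis=0) if location_xy is None else _as_xy(location_xy)

    if centroid_mode == "runs":
        cen = centroid(xy)
    elif centroid_mode == "locations":
        cen = centroid(loc_xy)
    else:
        raise ValueError("centroid_mode must be 'runs' or 'locations'")

    hull = convex_hull(loc_xy)
    dists = np.hypot(xy[:, 0] - cen.x, xy[:, 1] - cen.y)
    m_dist = float(np.median(dists))
    n_within = int(np.sum(dists <= radius))

    m_age = None
    if ages is not None:
        vals = np.array([a for a in ages if a is not None], dtype=float)
        if vals.size:
            m_age = float(np.median(vals))
    p_female = None
    if sexes is not None:
        known = [s for s in sexes if s in ("male", "female")]
        if known:
            p_female = round(100.0 * known.count("female") / len(known), 1)

    cen_geo = None
    if reference is not None:
        from .geometry import inverse_project
        cen_geo = inverse_project([cen], reference)[0]

    return ClusterSummary(cluster_id=cluster_id, runs=len(xy),
                          locations=len(loc_xy), area=hull.area, centroid=cen,
                          centroid_geo=cen_geo, m_dist=m_dist,
                          n_within=n_within, radius=radius, m_age=m_age,
                          p_female=p_female, hull=hull)


@dataclass(frozen=True)
class LocationProfile:
    """Histogram of runs-per-location plus the modal ('outlier') location."""

    histogram: dict[int, int]        # multiplicity -> number of locations
    top_location: str
    top_runs: int
    total_runs: int
    total_locations: int

    @property
    def top_share_pct(self) -> float:
        """The modal location's share of all runs, as a percent."""
        return round(100.0 * self.top_runs / self.total_runs, 1)

    def pct_with_multiplicity(self, m: int) -> float:
        return round(100.0 * self.histogram.get(m, 0) / self.total_locations, 1)


def location_frequency_profile(locations) -> LocationProfile:
    """Profile runs-per-location counts.

    Accepts a sequence of ingest.Location or of (location_id, n_runs) pairs.
    """
    pairs = []
    for loc in locations:
        if hasattr(loc, "location_id"):
            pairs.append((loc.location_id, loc.n_runs))
        else:
            lid, n = loc
            pairs.append((str(lid), int(n)))
    if not pairs:
        raise ValueError("no locations to profile")
    hist = Counter(n for _, n in pairs)
    top_id, top_n = max(pairs, key=lambda kv: kv[1])
    total = sum(n for _, n in pairs)
    return LocationProfile(histogram=dict(sorted(hist.items())),
                           top_location=top_id, top_runs=top_n,
                           total_runs=total, total_locations=len(pairs))


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median_age: Optional[float]
    age_iqr: Optional[tuple[float, float]]
    p_male: Optional[float]
    p_female: Optional[float]


def _group_summary(ages, sexes) -> GroupSummary:
    vals = np.array([a for a in ages if a is not None], dtype=float)
    median = float(np.median(vals)) if vals.size else None
    iqr = (tuple(float(q) for q in np.percentile(vals, [25, 75]))
           if vals.size else None)
    known = [s for s in sexes if s in ("male", "female")]
    p_male = round(100.0 * known.count("male") / len(known), 1) if known else None
    p_female = round(100.0 - p_male, 1) if p_male is not None else None
    return GroupSummary(n=len(list(ages)), median_age=median, age_iqr=iqr,
                        p_male=p_male, p_female=p_female)


def compare_subgroups(ages_a, sexes_a, ages_b, sexes_b
                      ) -> dict[str, GroupSummary]:
    """Descriptive comparison of a flagged group 'a' against the rest 'b'.

    Medians/IQRs use linear-interpolation quantiles; missing values are
    excluded.  Both groups must be nonempty.
    """
    ages_a, ages_b = list(ages_a), list(ages_b)
    if not ages_a or not ages_b:
        raise ValueError("both groups must be nonempty")
    return {"a": _group_summary(ages_a, list(sexes_a)),
            "b": _group_summary(ages_b, list(sexes_b))}
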