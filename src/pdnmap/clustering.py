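"""Local hotspot discovery: kNN-distance diagnostics, DBSCAN, minimum-size
filtering, and single- vs multi-location classification.

Conventions (these differ across DBSCAN implementations, so they are pinned
here): the eps-neighborhood is inclusive (d <= eps) and contains the point
itself, so a point is core iff it has >= min_pts points within eps counting
itself.  Clustering is run-level: coincident runs each count toward density,
because hotspots driven by one high-volume location are exactly what the
analysis must detect.  Border points attach to the first core cluster that
reaches them in input order, making the full labeling deterministic.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import _as_xy

__all__ = ["DbscanParams", "ClusterAssignment", "NOISE", "knn_distances",
           "dbscan", "cluster_size_threshold", "filter_clusters",
           "classify_cluster", "ClusterKind", "knee_epsilon"]

NOISE = -1


@dataclass(frozen=True)
class DbscanParams:
    eps: float
    min_pts: int = 3

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass
class ClusterAssignment:
    """Per-run labels (NOISE=-1 or 0..k-1) and core flags."""

    labels: np.ndarray
    core_flags: np.ndarray
    params: DbscanParams

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if np.any(self.labels >= 0) else 0

    def cluster_sizes(self) -> dict[int, int]:
        return {int(c): int(np.sum(self.labels == c))
                for c in range(self.n_clusters)}

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster_id)[0]


def knn_distances(points, k: int) -> np.ndarray:
    """Each point's distance to its k-th nearest neighbor, sorted ascending.

    Coincident points yield zeros.  These are the y-values of the kNN plot
    used to choose eps by visual inspection.
    """
    xy = _as_xy(points)
    n = len(xy)
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    d_sorted = np.sort(d, axis=1)       # column 0 is self-distance 0
    return np.sort(d_sorted[:, k])


def knee_epsilon(sorted_knn: np.ndarray) -> float:
    """Maximum-curvature heuristic on the sorted kNN curve (advisory only).

    Returns the distance at the point farthest from the chord joining the
    curve's endpoints.  Never auto-applied: eps selection stays manual.
    """
    y = np.asarray(sorted_knn, dtype=float)
    x = np.arange(len(y), dtype=float)
    if len(y) < 3:
        return float(y[-1])
    vx, vy = x[-1] - x[0], y[-1] - y[0]
    norm = math.hypot(vx, vy)
    dist = np.abs(vx * (y - y[0]) - vy * (x - x[0])) / norm
    return float(y[int(np.argmax(dist))])


def dbscan(points, params: DbscanParams) -> ClusterAssignment:
    """Standard DBSCAN on planar points (O(n^2); n is small here).

    Core iff |{q : d(p,q) <= eps}| >= min_pts (self included); clusters are
    density-connected components of core points plus reachable border points.
    """
    xy = _as_xy(points)
    n = len(xy)
    if n < 1:
        raise ValueError("dbscan needs at least one point")
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    neigh = d <= params.eps                     # inclusive, includes self
    core = neigh.sum(axis=1) >= params.min_pts

    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        labels[i] = cluster
        queue = deque([i])
        while queue:
            p = queue.popleft()
            for q in np.nonzero(neigh[p])[0]:
                if labels[q] == NOISE:
                    labels[q] = cluster
                    if core[q]:
                        queue.append(int(q))
        cluster += 1
    return ClusterAssignment(labels=labels, core_flags=core, params=params)


def cluster_size_threshold(total_runs: int, min_fraction: float) -> int:
    """Minimum cluster size under the retention rule: ceil(fraction * total)."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    return math.ceil(min_fraction * total_runs)


def filter_clusters(assignment: ClusterAssignment, total_runs: int,
                    min_fraction: float = 0.10
                    ) -> tuple[list[int], ClusterAssignment]:
    """Keep clusters with >= ceil(min_fraction * total_runs) runs.

    Returns (kept cluster ids, copy of the assignment with small clusters
    demoted to noise and their members' core flags cleared).
    """
    threshold = cluster_size_threshold(total_runs, min_fraction)
    sizes = assignment.cluster_sizes()
    kept = [c for c, s in sizes.items() if s >= threshold]
    labels = assignment.labels.copy()
    core = assignment.core_flags.copy()
    for c in sizes:
        if c not in kept:
            demoted = labels == c
            labels[demoted] = NOISE
            core[demoted] = False
    return kept, ClusterAssignment(labels=labels, core_flags=core,
                                   params=assignment.params)


@dataclass(frozen=True)
class ClusterKind:
    kind: str                     # 'single-location' | 'multi-location'
    modal_location: str
    modal_runs: int
    total_runs: int

    @property
    def modal_share(self) -> float:
        return self.modal_runs / self.total_runs

    @property
    def modal_share_pct(self) -> float:
        return round(100.0 * self.modal_share, 1)


def classify_cluster(run_location_ids: Sequence[str],
                     dominance: float = 0.5) -> ClusterKind:
    """Single-location iff the modal location's run share >= dominance.

    Multiplicity ties for the modal location break toward the id appearing
    first, but the kind depends only on the share; a share exactly at the
    threshold counts as single-location.
    """
    if len(run_location_ids) == 0:
        raise ValueError("cannot classify an empty cluster")
    counts = Counter(run_location_ids)
    modal_location, modal_runs = max(counts.items(), key=lambda kv: kv[1])
    total = len(run_location_ids)
    kind = ("single-location" if modal_runs / total >= dominance
            else "multi-location")
    return ClusterKind(kind=kind, modal_location=modal_location,
                       modal_runs=modal_runs, total_runs=total)
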