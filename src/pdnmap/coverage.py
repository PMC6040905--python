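"""Fixed-site naloxone coverage model.

Each kept cluster receives one site: multi-location clusters get a site at
the cluster centroid covering the cluster's runs within an accessibility
radius; single-location clusters get a site at the modal location covering
exactly the runs co-located there (within the dedupe tolerance).  The
modal-location convention matters: a centroid disc would also sweep in the
handful of nearby runs, overstating what a kit inside one building reaches.

Accounting is strictly per cluster — a site never claims noise or another
cluster's runs — so per-site counts sum without double counting.  A
``global_disc`` mode (any run within radius of any site) is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import PlanarPoint, _as_xy
from .ingest import DEFAULT_MERGE_TOLERANCE_M
from .clustering import ClusterKind
from .summarize import ClusterSummary

__all__ = ["PdnSite", "SiteCoverage", "CoverageResult", "site_clusters",
           "evaluate_coverage", "aggregate_coverage"]


@dataclass(frozen=True)
class PdnSite:
    site_id: str
    cluster_id: int
    position: PlanarPoint
    radius: float
    mode: str                     # 'centroid' | 'modal-location'

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("site radius must be > 0")
        if self.mode not in ("centroid", "modal-location"):
            raise ValueError(f"unknown site mode {self.mode!r}")


@dataclass(frozen=True)
class SiteCoverage:
    site_id: str
    cluster_id: int
    cluster_runs: int
    covered_runs: int

    @property
    def covered_pct_of_cluster(self) -> float:
        return round(100.0 * self.covered_runs / self.cluster_runs, 1)


@dataclass(frozen=True)
class CoverageResult:
    per_site: list[SiteCoverage]
    total_runs: int
    #: deduplicated union count; only set in global-disc mode, where one run
    #: can fall inside several site discs
    union_covered: Optional[int] = None

    @property
    def total_covered(self) -> int:
        if self.union_covered is not None:
            return self.union_covered
        return sum(s.covered_runs for s in self.per_site)

    @property
    def total_pct(self) -> float:
        """Percent of all geocoded runs potentially modifiable by the sites."""
        return round(100.0 * self.total_covered / self.total_runs, 1)


def site_clusters(summaries: Sequence[ClusterSummary],
                  kinds: Mapping[int, ClusterKind],
                  radius: float = 200.0,
                  modal_positions: Optional[Mapping[int, PlanarPoint]] = None
                  ) -> list[PdnSite]:
    """One site per kept cluster: centroid for multi-location clusters,
    the modal location for single-location clusters.

    ``modal_positions`` maps cluster_id -> modal location coordinate and is
    required for any single-location cluster.
    """
    sites = []
    for s in summaries:
        kind = kinds[s.cluster_id]
        if kind.kind == "single-location":
            if modal_positions is None or s.cluster_id not in modal_positions:
                raise ValueError(
                    f"cluster {s.cluster_id} is single-location but no modal "
                    f"position was provided")
            pos, mode = modal_positions[s.cluster_id], "modal-location"
        else:
            pos, mode = s.centroid, "centroid"
        sites.append(PdnSite(site_id=f"S{len(sites)}", cluster_id=s.cluster_id,
                             position=pos, radius=radius, mode=mode))
    return sites


def evaluate_coverage(sites: Sequence[PdnSite],
                      cluster_runs: Mapping[int, np.ndarray],
                      total_runs: int,
                      tolerance: float = DEFAULT_MERGE_TOLERANCE_M,
                      global_disc: bool = False) -> CoverageResult:
    """Count runs each site could reach.

    ``cluster_runs`` maps cluster_id -> (n, 2) run coordinates of that
    cluster.  Centroid sites cover their cluster's runs within ``site.radius``
    of the site; modal-location sites cover runs coincident with the site
    position (within ``tolerance``).  With ``global_disc=True`` every site
    instead covers any run (in any cluster) within its radius, and totals
    deduplicate runs covered by several sites.
    """
    if total_runs <= 0:
        raise ValueError("total_runs must be > 0")
    arrays = {cid: _as_xy(xy) for cid, xy in cluster_runs.items()}

    if global_disc:
        all_xy = np.vstack([a for a in arrays.values()]) if arrays else np.empty((0, 2))
        covered_any = np.zeros(len(all_xy), dtype=bool)
        per_site = []
        for site in sites:
            d = np.hypot(all_xy[:, 0] - site.position.x,
                         all_xy[:, 1] - site.position.y)
            hit = d <= site.radius
            covered_any |= hit
            per_site.append(SiteCoverage(
                site_id=site.site_id, cluster_id=site.cluster_id,
                cluster_runs=len(arrays.get(site.cluster_id, ())),
                covered_runs=int(hit.sum())))
        return CoverageResult(per_site=per_site, total_runs=total_runs,
                              union_covered=int(covered_any.sum()))

    per_site = []
    for site in sites:
        xy = arrays.get(site.cluster_id)
        if xy is None:
            raise ValueError(f"no runs supplied for cluster {site.cluster_id}")
        d = np.hypot(xy[:, 0] - site.position.x, xy[:, 1] - site.position.y)
        cutoff = site.radius if site.mode == "centroid" else tolerance
        per_site.append(SiteCoverage(site_id=site.site_id,
                                     cluster_id=site.cluster_id,
                                     cluster_runs=len(xy),
                                     covered_runs=int(np.sum(d <= cutoff))))
    return CoverageResult(per_site=per_site, total_runs=total_runs)


def aggregate_coverage(per_site_counts: Mapping[int, tuple[int, int]],
                       total_runs: int) -> CoverageResult:
    """Build a CoverageResult from per-cluster (covered, cluster_size) counts.

    Used when counts come from an external accounting rather than geometry.
    """
    per_site = [SiteCoverage(site_id=f"S{i}", cluster_id=cid,
                             cluster_runs=size, covered_runs=cov)
                for i, (cid, (cov, size)) in enumerate(per_site_counts.items())]
    return CoverageResult(per_site=per_site, total_runs=total_runs)
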