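"""End-to-end pipeline: ingest -> project -> dedupe -> clip -> K-function
envelope test -> DBSCAN -> size filter -> classification -> summaries ->
coverage, with all artifacts written as deterministic text files.

A single config seed fans out to fixed per-stage seeds so any stage can be
re-run in isolation and reproduce byte-identical output.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .clustering import (ClusterKind, DbscanParams, classify_cluster, dbscan,
                         filter_clusters, knn_distances)
from .coverage import CoverageResult, evaluate_coverage, site_clusters
from .geometry import (GeoPoint, PlanarPoint, load_boundary_geojson,
                       project_to_plane, window_to_geojson)
from .ingest import (attrition_report, clip_to_boundary, dedupe_locations,
                     load_lookup, load_runs)
from .ripley import EnvelopeResult, KEstimate, default_radii, global_envelope_test, k_estimate
from .summarize import ClusterSummary, location_frequency_profile, summarize_cluster

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "jitter_for_display"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults encode the reference settings
    (eps 200 m, min_pts 3, 10% size filter, 999 simulations, 200 m radius)."""

    runs_csv: str = "runs.csv"
    boundary_geojson: str = "boundary.geojson"
    out_dir: str = "out"
    lookup_csv: Optional[str] = None
    projection_reference: Optional[tuple[float, float]] = None  # lon, lat
    dedupe_tolerance: float = 0.5
    # ripley
    n_radii: int = 128
    nsim: int = 999
    seed: int = 0
    alternative: str = "two-sided"
    correction_resolution: int = 128
    # dbscan
    eps: float = 200.0
    min_pts: int = 3
    # filter / classify / coverage
    min_fraction: float = 0.10
    dominance: float = 0.5
    coverage_radius: float = 200.0
    modal_location_sites: bool = True
    # reporting
    jitter_sd: float = 0.0
    centroid_mode: str = "runs"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "projection_reference" in data and data["projection_reference"] is not None:
            data["projection_reference"] = tuple(data["projection_reference"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        if data["projection_reference"] is not None:
            data["projection_reference"] = list(data["projection_reference"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the config seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big")


@dataclass
class PipelineResult:
    attrition: object
    n_final_runs: int
    envelope: EnvelopeResult
    k_obs: KEstimate
    assignment: object
    kept_clusters: list[int]
    kinds: dict[int, ClusterKind]
    summaries: list[ClusterSummary]
    coverage: CoverageResult
    artifacts: dict[str, str]


def jitter_for_display(points, sd: float, seed: int = 0) -> np.ndarray:
    """Add isotropic Gaussian display jitter (sd meters); sd=0 is identity.

    For plotting only — analysis never consumes jittered coordinates, so
    jittered runs may fall outside their cluster's hull on maps.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    from .geometry import _as_xy
    xy = _as_xy(points).copy()
    if sd == 0 or len(xy) == 0:
        return xy
    rng = np.random.default_rng(seed)
    return xy + rng.normal(0.0, sd, size=xy.shape)


def _fmt(v, nd=6) -> str:
    return f"{v:.{nd}f}"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; write artifacts under ``config.out_dir``.

    Deterministic: identical config + inputs reproduce identical files.
    Stage failures propagate as ValueError with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # -- ingest --------------------------------------------------------------
    try:
        lookup = load_lookup(config.lookup_csv) if config.lookup_csv else None
        runs = load_runs(config.runs_csv, lookup=lookup)
    except ValueError as exc:
        raise ValueError(f"[ingest] {exc}") from exc
    attr = attrition_report(runs)
    logger.info("attrition: %d rows, %d geocoded runs (%.1f%%); %d addresses, "
                "%d geocoded (%.1f%%)", attr.n_rows, attr.n_runs_geocoded,
                attr.pct_runs_geocoded, attr.n_addresses,
                attr.n_addresses_geocoded, attr.pct_addresses_geocoded)

    # -- project -------------------------------------------------------------
    ref = (GeoPoint(*config.projection_reference)
           if config.projection_reference else None)
    try:
        window = load_boundary_geojson(config.boundary_geojson, reference=ref)
    except (OSError, ValueError, KeyError) as exc:
        raise ValueError(f"[boundary] {exc}") from exc
    ref = window.reference
    geocoded = [r for r in runs if r.coord is not None]
    try:
        planar = project_to_plane([r.coord for r in geocoded], ref)
    except ValueError as exc:
        raise ValueError(f"[project] {exc}") from exc
    xy_all = np.array([(p.x, p.y) for p in planar])

    # -- dedupe + clip -------------------------------------------------------
    locations = dedupe_locations(geocoded, xy_all, config.dedupe_tolerance)
    kept_locs, removed_locs = clip_to_boundary(locations, window)
    logger.info("%d locations (%d removed outside boundary)",
                len(kept_locs), len(removed_locs))

    loc_of_run = {rid: loc for loc in kept_locs for rid in loc.run_ids}
    final_runs = [r for r in geocoded if r.run_id in loc_of_run]
    xy = np.array([(loc_of_run[r.run_id].coord.x, loc_of_run[r.run_id].coord.y)
                   for r in final_runs])
    n_final = len(final_runs)
    if n_final < 2:
        raise ValueError("[clip] fewer than 2 runs remain inside the boundary")

    clip_path = out / "clip_report.csv"
    with open(clip_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["location_id", "x", "y", "n_runs", "kept"])
        for loc in kept_locs:
            w.writerow([loc.location_id, _fmt(loc.coord.x, 3),
                        _fmt(loc.coord.y, 3), loc.n_runs, 1])
        for loc in removed_locs:
            w.writerow([loc.location_id, _fmt(loc.coord.x, 3),
                        _fmt(loc.coord.y, 3), loc.n_runs, 0])
    artifacts["clip_report"] = str(clip_path)

    # -- ripley --------------------------------------------------------------
    radii = default_radii(window, config.n_radii)
    try:
        k_obs = k_estimate(xy, window, radii,
                           correction_resolution=config.correction_resolution)
        envelope = global_envelope_test(
            k_obs, window, nsim=config.nsim,
            seed=config.stage_seed("ripley"),
            alternative=config.alternative,
            correction_resolution=config.correction_resolution)
    except ValueError as exc:
        raise ValueError(f"[ripley] {exc}") from exc
    logger.info("global envelope test: T=%.2f p=%.4f (nsim=%d)",
                envelope.t_obs, envelope.p_global, envelope.nsim)

    env_path = out / "envelope.csv"
    with open(env_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["r", "k_hat", "k_theo", "lo", "hi"])
        for i in range(len(radii)):
            w.writerow([_fmt(radii[i], 3), _fmt(k_obs.k_hat[i], 3),
                        _fmt(k_obs.k_theo[i], 3), _fmt(envelope.lo[i], 3),
                        _fmt(envelope.hi[i], 3)])
    artifacts["envelope"] = str(env_path)

    # -- knn + dbscan + filter ----------------------------------------------
    knn = knn_distances(xy, config.min_pts)
    knn_path = out / "knn.csv"
    with open(knn_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "knn_distance"])
        for i, dval in enumerate(knn):
            w.writerow([i, _fmt(dval, 3)])
    artifacts["knn"] = str(knn_path)

    params = DbscanParams(eps=config.eps, min_pts=config.min_pts)
    assignment = dbscan(xy, params)
    kept_ids, filtered = filter_clusters(assignment, n_final,
                                         config.min_fraction)
    logger.info("dbscan: %d raw clusters, %d kept (>= %.0f%% of %d runs)",
                assignment.n_clusters, len(kept_ids),
                100 * config.min_fraction, n_final)

    assign_path = out / "assignment.csv"
    with open(assign_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["run_id", "location_id", "cluster_label", "is_core"])
        for i, r in enumerate(final_runs):
            w.writerow([r.run_id, loc_of_run[r.run_id].location_id,
                        int(filtered.labels[i]), int(filtered.core_flags[i])])
    artifacts["assignment"] = str(assign_path)

    # -- classify + summarize ------------------------------------------------
    kinds: dict[int, ClusterKind] = {}
    summaries: list[ClusterSummary] = []
    modal_positions: dict[int, PlanarPoint] = {}
    for cid in kept_ids:
        members = np.nonzero(filtered.labels == cid)[0]
        loc_ids = [loc_of_run[final_runs[i].run_id].location_id for i in members]
        kind = classify_cluster(loc_ids, config.dominance)
        kinds[cid] = kind
        loc_coords = {lid: loc_of_run_coord for lid, loc_of_run_coord in
                      ((loc.location_id, loc.coord) for loc in kept_locs)
                      if lid in set(loc_ids)}
        modal = loc_coords[kind.modal_location]
        modal_positions[cid] = modal
        loc_xy = np.array([(c.x, c.y) for c in loc_coords.values()])
        ages = [final_runs[i].age for i in members]
        sexes = [final_runs[i].sex for i in members]
        summaries.append(summarize_cluster(
            xy[members], loc_xy, ages, sexes,
            radius=config.coverage_radius, cluster_id=cid,
            centroid_mode=config.centroid_mode, reference=ref))

    table_path = out / "cluster_table.csv"
    with open(table_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cluster", "runs", "locations", "area_m2", "m_dist_m",
                    "n_within", "p_within", "m_age", "p_female", "kind"])
        for s in summaries:
            w.writerow([s.cluster_id, s.runs, s.locations, _fmt(s.area, 1),
                        _fmt(s.m_dist, 1), s.n_within, _fmt(s.p_within, 1),
                        "" if s.m_age is None else _fmt(s.m_age, 1),
                        "" if s.p_female is None else _fmt(s.p_female, 1),
                        kinds[s.cluster_id].kind])
    artifacts["cluster_table"] = str(table_path)

    profile = location_frequency_profile(kept_locs)
    profile_path = out / "location_profile.csv"
    with open(profile_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["runs_per_location", "n_locations"])
        for mult, cnt in profile.histogram.items():
            w.writerow([mult, cnt])
    artifacts["location_profile"] = str(profile_path)

    # -- coverage ------------------------------------------------------------
    sites = site_clusters(summaries, kinds, radius=config.coverage_radius,
                          modal_positions=modal_positions
                          if config.modal_location_sites else
                          {cid: s.centroid for cid, s in
                           zip(kept_ids, summaries)})
    if not config.modal_location_sites:
        sites = [dataclasses.replace(s, mode="centroid") for s in sites]
    cluster_runs = {cid: xy[filtered.labels == cid] for cid in kept_ids}
    coverage = evaluate_coverage(sites, cluster_runs, n_final,
                                 tolerance=config.dedupe_tolerance)
    logger.info("coverage: %d of %d runs (%.1f%%)", coverage.total_covered,
                n_final, coverage.total_pct)

    cov_path = out / "coverage.csv"
    with open(cov_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "cluster", "mode", "x", "y", "radius",
                    "cluster_runs", "covered_runs", "covered_pct"])
        for site, sc in zip(sites, coverage.per_site):
            w.writerow([site.site_id, site.cluster_id, site.mode,
                        _fmt(site.position.x, 3), _fmt(site.position.y, 3),
                        _fmt(site.radius, 1), sc.cluster_runs, sc.covered_runs,
                        _fmt(sc.covered_pct_of_cluster, 1)])
        w.writerow(["TOTAL", "", "", "", "", "", n_final,
                    coverage.total_covered, _fmt(coverage.total_pct, 1)])
    artifacts["coverage"] = str(cov_path)

    # -- geojson + manifest --------------------------------------------------
    from .geometry import inverse_project
    features = []
    for s in summaries:
        hull_geo = window_to_geojson(
            type(window)(s.hull.shell, reference=ref, allow_degenerate=True))
        features.append({"type": "Feature",
                         "properties": {"cluster": s.cluster_id,
                                        "role": "hull",
                                        "area_m2": round(s.area, 1)},
                         "geometry": hull_geo})
        cgeo = inverse_project([s.centroid], ref)[0]
        features.append({"type": "Feature",
                         "properties": {"cluster": s.cluster_id,
                                        "role": "centroid"},
                         "geometry": {"type": "Point",
                                      "coordinates": [cgeo.lon, cgeo.lat]}})
    for site in sites:
        sgeo = inverse_project([site.position], ref)[0]
        features.append({"type": "Feature",
                         "properties": {"site": site.site_id,
                                        "cluster": site.cluster_id,
                                        "mode": site.mode,
                                        "radius_m": site.radius,
                                        "role": "pdn-site"},
                         "geometry": {"type": "Point",
                                      "coordinates": [sgeo.lon, sgeo.lat]}})
    geo_path = out / "clusters.geojson"
    with open(geo_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  sort_keys=True)
    artifacts["clusters_geojson"] = str(geo_path)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {"ripley": config.stage_seed("ripley")},
        "counts": {
            "rows": attr.n_rows,
            "runs_geocoded": attr.n_runs_geocoded,
            "addresses": attr.n_addresses,
            "addresses_geocoded": attr.n_addresses_geocoded,
            "locations": len(locations),
            "locations_removed": len(removed_locs),
            "final_runs": n_final,
        },
        "p_global": envelope.p_global,
        "kept_clusters": [int(c) for c in kept_ids],
        "total_covered": coverage.total_covered,
        "total_pct": coverage.total_pct,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = str(manifest_path)

    return PipelineResult(attrition=attr, n_final_runs=n_final,
                          envelope=envelope, k_obs=k_obs,
                          assignment=filtered, kept_clusters=kept_ids,
                          kinds=kinds, summaries=summaries, coverage=coverage,
                          artifacts=artifacts)
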