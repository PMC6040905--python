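# pdnmap

Geospatial clustering analysis of emergency-response point data (e.g.
opioid-overdose EMS runs) and coverage modeling for fixed-site publicly
deployed naloxone (PDN) kits.

The pipeline: ingest run records (CSV) and a city boundary (GeoJSON) →
project to a local planar frame → collapse runs to unique physical locations
→ clip to the boundary → test for global clustering with Ripley's K-function
(isotropic edge correction, Monte-Carlo envelopes under complete spatial
randomness, global rank p-value) → find local hotspots with DBSCAN → filter
clusters by minimum size → characterize each cluster (runs, locations, hull
area, median distance to centroid, within-radius counts, demographics) →
model one PDN site per cluster (centroid for multi-location clusters, the
modal location for single-location spikes) and count potentially reachable
runs.

A synthetic-data module generates reproducible city datasets (uniform
background, two-level Gaussian clusters, a coincident-run spike, demographic
attributes) so the whole pipeline is testable without any external data.

## CLI

```sh
# generate a ~690-run synthetic city (3 clusters + one 76-run spike)
pdnmap synth --preset default --seed 1 --out-dir synth

# full pipeline with reference settings (eps 200 m, min_pts 3,
# 10% cluster-size filter, 999 CSR simulations, 200 m coverage radius)
pdnmap run --runs-csv synth/runs.csv --boundary-geojson synth/boundary.geojson \
           --out-dir out --seed 1

# individual stages
pdnmap ripley --runs-csv ... --boundary-geojson ... --nsim 999
pdnmap cluster --runs-csv ... --boundary-geojson ... --eps 200 --min-pts 3
pdnmap summarize --runs-csv ... --boundary-geojson ...
pdnmap coverage --runs-csv ... --boundary-geojson ...
pdnmap plot --runs-csv ... --boundary-geojson ... --out-dir out
```

Outputs under `--out-dir`: `envelope.csv` (r, K̂, πr², lo, hi),
`assignment.csv` (per-run cluster label + core flag), `cluster_table.csv`
(per-cluster summary row), `coverage.csv`, `clusters.geojson` (hulls,
centroids, sites in lon/lat), `knn.csv`, `location_profile.csv`,
`clip_report.csv`, and `manifest.json` (config hash, seeds, attrition
counts). Re-running with the same config and inputs reproduces byte-identical
files. A YAML config (`--config`) can replace the flags; see
`pdnmap.pipeline.PipelineConfig` for all keys.

## Conventions worth knowing

- Projection: a single local equirectangular projection (configurable Earth
  radius) — accurate to ~2 m over a city-scale (≤10 km) extent.
- Polygon membership is even-odd with boundary points counted inside.
- DBSCAN: `d <= eps` inclusive, `min_pts` counts the point itself, runs
  participate with multiplicity, border points attach in input order.
- The K-function counts coincident pairs with weight 1 at every radius; the
  global statistic is max |L̂(r) − r| (two-sided by default).
- Coverage: centroid sites cover cluster runs within the radius;
  modal-location sites cover only co-located runs.

## Tests

```sh
python -m pytest -q tests/
```

Unit + property tests per module plus `tests/test_acceptance.py` (oracle and
calibration criteria; the full suite takes a few minutes because it includes
a 999-simulation envelope test and a 200-replicate type-I-error calibration).

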