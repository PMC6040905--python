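"""Synthetic city datasets with the structure the analysis assumes.

A dataset is a superposition of
  * a uniform (CSR) background inside the city boundary,
  * several two-level clusters: location coordinates drawn from an isotropic
    Gaussian around a center (truncated to the window by resampling), with
    run multiplicities assigned multinomially across those locations — this
    mimics real hotspots, which mix a few locations with many runs,
  * optionally one single-location "spike" of many coincident runs,
plus demographic attributes (age from a shifted log-normal matched exactly
to a target median and IQR, sex Bernoulli, independent missingness).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtri

from .geometry import (
    GeoPoint,
    PlanarPoint,
    PolygonWindow,
    inverse_project,
    point_in_polygon,
    sample_uniform_in_window,
    window_to_geojson,
)
from .ingest import RunRecord

__all__ = [
    "ClusterSpec",
    "SpikeSpec",
    "Demographics",
    "SyntheticConfig",
    "default_boundary",
    "default_preset",
    "generate_csr",
    "generate_dataset",
    "write_dataset",
    "solve_shifted_lognormal",
]


@dataclass(frozen=True)
class ClusterSpec:
    """A planted multi-location cluster."""

    center: tuple[float, float]
    sigma: float            # m, isotropic Gaussian sd of location scatter
    n_runs: int
    n_locations: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_runs < self.n_locations or self.n_locations < 1:
            raise ValueError("need n_runs >= n_locations >= 1")


@dataclass(frozen=True)
class SpikeSpec:
    """A single location contributing many coincident runs."""

    location: tuple[float, float]
    n_runs: int
    age_median: Optional[float] = None       # override group age model
    age_iqr: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class Demographics:
    p_male: float = 0.618
    age_median: float = 36.0
    age_iqr: tuple[float, float] = (29.0, 49.0)
    missing_sex: float = 0.01
    missing_age: float = 0.02

    def __post_init__(self) -> None:
        for name in ("p_male", "missing_sex", "missing_age"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class SyntheticConfig:
    seed: int
    boundary: PolygonWindow
    n_background: int = 0
    clusters: list[ClusterSpec] = field(default_factory=list)
    spike: Optional[SpikeSpec] = None
    demographics: Demographics = field(default_factory=Demographics)
    start_date: str = "2021-01-01"
    n_days: int = 206

    @property
    def n_total(self) -> int:
        return (self.n_background + sum(c.n_runs for c in self.clusters)
                + (self.spike.n_runs if self.spike else 0))


def default_boundary(area_m2: float = 17.0e6,
                     reference: GeoPoint = GeoPoint(-71.0, 42.0)
                     ) -> PolygonWindow:
    """An irregular 12-gon scaled to the requested area (default ~17 km2)."""
    base = np.array([
        (0.00, 0.35), (0.25, 0.05), (0.62, 0.00), (1.00, 0.18),
        (1.28, 0.10), (1.45, 0.40), (1.30, 0.75), (1.05, 0.98),
        (0.70, 1.05), (0.42, 0.92), (0.15, 0.95), (-0.05, 0.65),
    ])
    from .geometry import _ring_area
    scale = math.sqrt(area_m2 / abs(_ring_area(base)))
    return PolygonWindow(base * scale, reference=reference)


def default_preset(seed: int = 0) -> SyntheticConfig:
    """A ~690-run city: 3 planted clusters, one 76-run spike, CSR background.

    Calibration: 86/42, 191/81 and 9/7 (+76 spike) runs/locations for the
    clusters, male share 0.618, age median 36 overall (35 off-spike, 43 at
    the spike), ~1% missing sex and ~2% missing age.
    """
    boundary = default_boundary()
    # cluster centers well inside the window, pairwise >= 1 km apart
    centers = [(1400.0, 2800.0), (2800.0, 1700.0), (3400.0, 3100.0)]
    clusters = [
        ClusterSpec(center=centers[0], sigma=110.0, n_runs=86, n_locations=42),
        ClusterSpec(center=centers[1], sigma=170.0, n_runs=191, n_locations=81),
        ClusterSpec(center=centers[2], sigma=50.0, n_runs=9, n_locations=7),
    ]
    spike = SpikeSpec(location=(3420.0, 3080.0), n_runs=76,
                      age_median=43.0, age_iqr=(36.5, 58.5))
    demo = Demographics(p_male=0.618, age_median=35.0, age_iqr=(28.0, 48.0),
                        missing_sex=7 / 690, missing_age=13 / 690)
    return SyntheticConfig(seed=seed, boundary=boundary, n_background=328,
                           clusters=clusters, spike=spike, demographics=demo)


def generate_csr(n: int, window: PolygonWindow, seed) -> np.ndarray:
    """n i.i.d. uniform points inside the window, as an (n, 2) array.

    ``seed`` may be an int or a numpy Generator (shared stream).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sample_uniform_in_window(n, window, rng)


def solve_shifted_lognormal(median: float, iqr: tuple[float, float]
                            ) -> tuple[float, float, float]:
    """Parameters (shift c, mu, sigma) of c + LogNormal(mu, sigma) matching
    the given median and quartiles exactly.

    With z = Phi^{-1}(0.75): q3-median = a(k-1), median-q1 = a(1-1/k) where
    a = exp(mu), k = exp(z*sigma); hence k = (q3-median)/(median-q1).
    """
    q1, q3 = iqr
    if not (q1 < median < q3):
        raise ValueError("need q1 < median < q3")
    z = float(ndtri(0.75))
    k = (q3 - median) / (median - q1)
    if k <= 1.0:
        # left-skewed target: mirror (negate) the variable and re-solve
        c, mu, sigma = solve_shifted_lognormal(-median, (-q3, -q1))
        return (-c, mu, -sigma)  # sigma<0 flags mirroring for the sampler
    sigma = math.log(k) / z
    a = (q3 - median) / (k - 1.0)
    c = median - a
    return (c, math.log(a), sigma)


def _sample_ages(n: int, median: float, iqr: tuple[float, float],
                 rng: np.random.Generator) -> np.ndarray:
    c, mu, sigma = solve_shifted_lognormal(median, iqr)
    draws = rng.standard_normal(n)
    if sigma >= 0:
        ages = c + np.exp(mu + sigma * draws)
    else:
        # mirrored (left-skewed) branch: X = c - exp(mu + |sigma| Z)
        ages = c - np.exp(mu + (-sigma) * draws)
    return np.clip(ages, 0.0, 130.0)


def _sample_truncated_gaussian(center: tuple[float, float], sigma: float,
                               n: int, window: PolygonWindow,
                               rng: np.random.Generator) -> np.ndarray:
    """n Gaussian points around center, resampled until inside the window."""
    out = np.empty((n, 2))
    filled = 0
    guard = 0
    while filled < n:
        m = max(2 * (n - filled), 8)
        pts = rng.normal(loc=center, scale=sigma, size=(m, 2))
        ok = window.contains_xy(pts[:, 0], pts[:, 1])
        take = min(int(ok.sum()), n - filled)
        out[filled:filled + take] = pts[ok][:take]
        filled += take
        guard += 1
        if guard > 1000:
            raise RuntimeError("truncated Gaussian sampling failed to converge")
    return out


def _multiplicities(n_runs: int, n_locations: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Assign n_runs across n_locations: one run each, remainder multinomial.

    The guaranteed minimum keeps the realized location count equal to
    n_locations (a plain multinomial would leave some locations empty).
    """
    counts = np.ones(n_locations, dtype=int)
    extra = n_runs - n_locations
    if extra > 0:
        counts += rng.multinomial(extra, np.full(n_locations, 1.0 / n_locations))
    return counts


def generate_dataset(config: SyntheticConfig
                     ) -> tuple[list[RunRecord], PolygonWindow, list[str]]:
    """Generate runs, the boundary window, and per-run truth labels.

    Truth labels are 'background', 'cluster-<i>' or 'spike' and partition the
    runs by generating component.  Spike runs share one exact coordinate.
    """
    rng = np.random.default_rng(config.seed)
    window = config.boundary
    for c in config.clusters:
        if not point_in_polygon(c.center, window):
            raise ValueError(f"cluster center {c.center} outside boundary")
    if config.spike and not point_in_polygon(config.spike.location, window):
        raise ValueError(f"spike location {config.spike.location} outside boundary")

    xy_parts: list[np.ndarray] = []
    labels: list[str] = []

    bg = sample_uniform_in_window(config.n_background, window, rng)
    xy_parts.append(bg)
    labels += ["background"] * config.n_background

    for ci, spec in enumerate(config.clusters):
        locs = _sample_truncated_gaussian(spec.center, spec.sigma,
                                          spec.n_locations, window, rng)
        mult = _multiplicities(spec.n_runs, spec.n_locations, rng)
        xy_parts.append(np.repeat(locs, mult, axis=0))
        labels += [f"cluster-{ci}"] * spec.n_runs

    if config.spike:
        sp = np.tile(np.asarray(config.spike.location, dtype=float),
                     (config.spike.n_runs, 1))
        xy_parts.append(sp)
        labels += ["spike"] * config.spike.n_runs

    xy = np.vstack(xy_parts) if xy_parts else np.empty((0, 2))
    n = len(xy)

    # demographics
    demo = config.demographics
    ages = _sample_ages(n, demo.age_median, demo.age_iqr, rng)
    if config.spike and config.spike.age_median is not None:
        mask = np.array([lab == "spike" for lab in labels])
        ages[mask] = _sample_ages(int(mask.sum()), config.spike.age_median,
                                  config.spike.age_iqr or demo.age_iqr, rng)
    male = rng.random(n) < demo.p_male
    miss_age = rng.random(n) < demo.missing_age
    miss_sex = rng.random(n) < demo.missing_sex
    day_offsets = rng.integers(0, max(config.n_days, 1), n)

    # synthetic address per distinct exact coordinate
    addr_of: dict[tuple[float, float], str] = {}
    ref = window.reference or GeoPoint(0.0, 0.0)
    geo = inverse_project([PlanarPoint(float(x), float(y)) for x, y in xy], ref)

    start = np.datetime64(config.start_date)
    records: list[RunRecord] = []
    for i in range(n):
        key = (float(xy[i, 0]), float(xy[i, 1]))
        addr = addr_of.setdefault(key, f"{len(addr_of) + 1} Synth St")
        records.append(RunRecord(
            run_id=f"R{i:05d}",
            address=addr,
            coord=geo[i],
            timestamp=str(start + day_offsets[i]),
            age=None if miss_age[i] else round(float(ages[i]), 1),
            sex="unknown" if miss_sex[i] else ("male" if male[i] else "female"),
        ))
    return records, window, labels


def write_dataset(records: Sequence[RunRecord], window: PolygonWindow,
                  labels: Sequence[str], out_dir) -> dict[str, str]:
    """Write runs CSV, boundary GeoJSON and truth-label CSV; return paths."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs_path = out / "runs.csv"
    with open(runs_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["run_id", "address", "lon", "lat", "timestamp", "age", "sex"])
        for r in records:
            w.writerow([
                r.run_id, r.address,
                f"{r.coord.lon:.8f}" if r.coord else "",
                f"{r.coord.lat:.8f}" if r.coord else "",
                r.timestamp or "",
                "" if r.age is None else f"{r.age:g}",
                "" if r.sex == "unknown" else r.sex,
            ])
    boundary_path = out / "boundary.geojson"
    with open(boundary_path, "w") as fh:
        json.dump({"type": "Feature", "properties": {},
                   "geometry": window_to_geojson(window)}, fh)
    truth_path = out / "truth.csv"
    with open(truth_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["run_id", "component"])
        for r, lab in zip(records, labels):
            w.writerow([r.run_id, lab])
    return {"runs": str(runs_path), "boundary": str(boundary_path),
            "truth": str(truth_path)}
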