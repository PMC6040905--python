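"""Run-record ingestion: CSV parsing, location dedupe, boundary clipping.

The preparation chain mirrors a typical EMS-data workflow: raw rows (some
without coordinates, i.e. geocoding failures) -> unique physical locations
(distinct addresses may share one coordinate, e.g. a multi-unit building)
-> locations clipped to the official city boundary.

Address-to-coordinate geocoding itself is out of scope: coordinates arrive
in the CSV, or via an optional address->coordinate lookup table.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import GeoPoint, PlanarPoint, PolygonWindow, point_in_polygon

logger = logging.getLogger(__name__)

__all__ = [
    "RunRecord",
    "Location",
    "AttritionReport",
    "load_runs",
    "load_lookup",
    "attrition_report",
    "dedupe_locations",
    "clip_to_boundary",
]

VALID_SEX = {"male", "female", "unknown"}

#: default coordinate-coincidence tolerance (m) for collapsing runs to one
#: physical location; below the ~2 m datum-equivalence bound so mixed-datum
#: inputs can still be merged by raising it to 2.0 in config.
DEFAULT_MERGE_TOLERANCE_M = 0.5


@dataclass
class RunRecord:
    """One EMS run. Missing fields stay absent (None); nothing is imputed."""

    run_id: str
    address: str = ""
    coord: Optional[GeoPoint] = None
    timestamp: Optional[str] = None
    age: Optional[float] = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.age is not None and not (0.0 <= self.age <= 130.0):
            raise ValueError(f"run {self.run_id}: age {self.age} outside [0, 130]")
        if self.sex not in VALID_SEX:
            raise ValueError(f"run {self.run_id}: sex must be one of {VALID_SEX}")


@dataclass
class Location:
    """A unique physical location aggregating one or more runs."""

    location_id: str
    coord: PlanarPoint
    addresses: set[str] = field(default_factory=set)
    run_ids: list[str] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)


@dataclass(frozen=True)
class AttritionReport:
    """Counts at each data-preparation step, with derived percentages."""

    n_rows: int
    n_runs_geocoded: int
    n_addresses: int
    n_addresses_geocoded: int

    @property
    def pct_runs_geocoded(self) -> float:
        return round(100.0 * self.n_runs_geocoded / self.n_rows, 1)

    @property
    def pct_addresses_geocoded(self) -> float:
        return round(100.0 * self.n_addresses_geocoded / self.n_addresses, 1)


def _parse_float(value: str) -> Optional[float]:
    value = (value or "").strip()
    if not value:
        return None
    return float(value)


def load_lookup(path) -> dict[str, GeoPoint]:
    """Read an address -> coordinate lookup CSV (columns address, lon, lat)."""
    table: dict[str, GeoPoint] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lon = _parse_float(row.get("lon", ""))
            lat = _parse_float(row.get("lat", ""))
            if lon is None or lat is None:
                continue
            table[row["address"].strip()] = GeoPoint(lon, lat)
    return table


def load_runs(path, lookup: dict[str, GeoPoint] | None = None) -> list[RunRecord]:
    """Parse the runs CSV (run_id, address, lon, lat, timestamp, age, sex).

    Rows with missing coordinates are kept (coord=None) unless the optional
    lookup table supplies one by address.  Malformed rows are skipped with a
    warning; duplicate run_ids raise.  A summary log line reports how many
    records carry coordinates.
    """
    path = Path(path)
    records: list[RunRecord] = []
    seen: set[str] = set()
    skipped = 0
    try:
        fh = open(path, newline="")
    except OSError as exc:
        raise ValueError(f"cannot read runs file {path}: {exc}") from exc
    with fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "run_id" not in reader.fieldnames:
            raise ValueError(f"runs file {path} has no usable header "
                             f"(need at least a run_id column)")
        for lineno, row in enumerate(reader, start=2):
            run_id = (row.get("run_id") or "").strip()
            if not run_id:
                skipped += 1
                logger.warning("%s line %d: missing run_id, skipped", path, lineno)
                continue
            if run_id in seen:
                raise ValueError(f"duplicate run_id {run_id!r} at line {lineno}")
            try:
                lon = _parse_float(row.get("lon", ""))
                lat = _parse_float(row.get("lat", ""))
                address = (row.get("address") or "").strip()
                coord = GeoPoint(lon, lat) if lon is not None and lat is not None else None
                if coord is None and lookup and address in lookup:
                    coord = lookup[address]
                sex = (row.get("sex") or "").strip().lower() or "unknown"
                rec = RunRecord(
                    run_id=run_id,
                    address=address,
                    coord=coord,
                    timestamp=(row.get("timestamp") or "").strip() or None,
                    age=_parse_float(row.get("age", "")),
                    sex=sex if sex in VALID_SEX else "unknown",
                )
            except (ValueError, TypeError) as exc:
                skipped += 1
                logger.warning("%s line %d: %s, skipped", path, lineno, exc)
                continue
            seen.add(run_id)
            records.append(rec)
    if not records:
        raise ValueError(f"runs file {path} contained no parseable records")
    n_coord = sum(1 for r in records if r.coord is not None)
    logger.info("loaded %d runs from %s (%d with coordinates, %d without, "
                "%d rows skipped)", len(records), path, n_coord,
                len(records) - n_coord, skipped)
    return records


def attrition_report(runs: Sequence[RunRecord]) -> AttritionReport:
    """Run- and address-level geocoding attrition counts."""
    addresses = {r.address for r in runs if r.address}
    geocoded_addresses = {r.address for r in runs if r.address and r.coord is not None}
    return AttritionReport(
        n_rows=len(runs),
        n_runs_geocoded=sum(1 for r in runs if r.coord is not None),
        n_addresses=len(addresses),
        n_addresses_geocoded=len(geocoded_addresses),
    )


def dedupe_locations(runs: Sequence[RunRecord], xy: np.ndarray,
                     tolerance: float = DEFAULT_MERGE_TOLERANCE_M) -> list[Location]:
    """Collapse runs to unique physical locations by coordinate coincidence.

    ``xy`` holds projected planar coordinates aligned with ``runs`` (all of
    which must carry coordinates).  Greedy in input order: a run within
    ``tolerance`` meters of an existing location's coordinate joins it;
    otherwise it founds a new location.  Distinct addresses at one coordinate
    collapse into a single location.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    xy = np.asarray(xy, dtype=float)
    if len(xy) != len(runs):
        raise ValueError("coordinate array does not align with runs")
    locations: list[Location] = []
    coords = np.empty((0, 2))
    for i, run in enumerate(runs):
        if run.coord is None:
            raise ValueError(f"run {run.run_id} has no coordinates")
        if len(locations):
            d = np.hypot(coords[:, 0] - xy[i, 0], coords[:, 1] - xy[i, 1])
            j = int(np.argmin(d))
            if d[j] <= tolerance:
                loc = locations[j]
                loc.run_ids.append(run.run_id)
                if run.address:
                    loc.addresses.add(run.address)
                continue
        loc = Location(
            location_id=f"L{len(locations):04d}",
            coord=PlanarPoint(float(xy[i, 0]), float(xy[i, 1])),
            addresses={run.address} if run.address else set(),
            run_ids=[run.run_id],
        )
        locations.append(loc)
        coords = np.vstack([coords, xy[i]])
    return locations


def clip_to_boundary(locations: Sequence[Location], window: PolygonWindow
                     ) -> tuple[list[Location], list[Location]]:
    """Split locations into (inside-or-on-boundary, outside) the window."""
    kept: list[Location] = []
    removed: list[Location] = []
    for loc in locations:
        if point_in_polygon(loc.coord, window):
            kept.append(loc)
        else:
            removed.append(loc)
            logger.info("location %s (%d runs) outside boundary, removed",
                        loc.location_id, loc.n_runs)
    return kept, removed
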