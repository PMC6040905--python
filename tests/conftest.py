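import numpy as np
import pytest

from pdnmap.geometry import GeoPoint, PolygonWindow


@pytest.fixture
def unit_square() -> PolygonWindow:
    return PolygonWindow([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def big_rectangle() -> PolygonWindow:
    """1000 x 800 m rectangle, large relative to test circles."""
    return PolygonWindow([(0, 0), (1000, 0), (1000, 800), (0, 800)])


@pytest.fixture
def irregular_window() -> PolygonWindow:
    return PolygonWindow([(0, 0), (400, -50), (700, 100), (800, 450),
                          (500, 700), (150, 600), (-100, 300)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def reference() -> GeoPoint:
    return GeoPoint(-71.0, 42.0)


def write_runs_csv(path, rows):
    """rows: iterable of dicts with any of the runs-CSV columns."""
    import csv
    cols = ["run_id", "address", "lon", "lat", "timestamp", "age", "sex"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for r in rows:
            w.writerow({c: r.get(c, "") for c in cols})
    return path
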