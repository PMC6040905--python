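import numpy as np
import pytest

from pdnmap.geometry import PolygonWindow
from pdnmap.ingest import (AttritionReport, Location, RunRecord,
                           attrition_report, clip_to_boundary,
                           dedupe_locations, load_lookup, load_runs)

from .conftest import write_runs_csv


def _mkrun(i, x=None, y=None, address=None, **kw):
    """RunRecord with planar-style lon/lat (tiny degrees ~ meters not needed
    for dedupe tests, which take a separate xy array)."""
    from pdnmap.geometry import GeoPoint
    coord = GeoPoint(x, y) if x is not None else None
    return RunRecord(run_id=f"r{i}", address=address or f"addr{i}",
                     coord=coord, **kw)


class TestLoadRuns:
    def test_basic_with_blank_age(self, tmp_path):
        path = write_runs_csv(tmp_path / "runs.csv", [
            {"run_id": "a", "address": "1 Main", "lon": "-71.0", "lat": "42.0",
             "age": "30", "sex": "male"},
            {"run_id": "b", "address": "2 Main", "lon": "-71.0", "lat": "42.1",
             "age": "", "sex": "female"},
            {"run_id": "c", "address": "3 Main", "lon": "-71.1", "lat": "42.0",
             "age": "41.5", "sex": "male"},
        ])
        runs = load_runs(path)
        assert len(runs) == 3
        assert sum(r.age is None for r in runs) == 1

    def test_duplicate_run_id_raises(self, tmp_path):
        path = write_runs_csv(tmp_path / "runs.csv", [
            {"run_id": "dup", "lon": "-71.0", "lat": "42.0"},
            {"run_id": "dup", "lon": "-71.0", "lat": "42.0"},
        ])
        with pytest.raises(ValueError, match="dup"):
            load_runs(path)

    def test_malformed_rows_skipped_with_warning(self, tmp_path, caplog):
        path = write_runs_csv(tmp_path / "runs.csv", [
            {"run_id": "ok", "lon": "-71.0", "lat": "42.0"},
            {"run_id": "bad", "lon": "not-a-number", "lat": "42.0"},
            {"run_id": "bad2", "lon": "-71.0", "lat": "42.0", "age": "999"},
        ])
        with caplog.at_level("WARNING"):
            runs = load_runs(path)
        assert [r.run_id for r in runs] == ["ok"]
        assert len(caplog.records) >= 2

    def test_unparseable_file_raises(self, tmp_path):
        path = tmp_path / "nope.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="run_id"):
            load_runs(path)
        with pytest.raises(ValueError):
            load_runs(tmp_path / "missing.csv")

    def test_empty_file_raises(self, tmp_path):
        path = write_runs_csv(tmp_path / "runs.csv", [])
        with pytest.raises(ValueError, match="no parseable"):
            load_runs(path)

    def test_lookup_table_fills_coordinates(self, tmp_path):
        lookup_path = tmp_path / "lookup.csv"
        lookup_path.write_text("address,lon,lat\n9 Side St,-71.05,42.02\n")
        path = write_runs_csv(tmp_path / "runs.csv", [
            {"run_id": "a", "address": "9 Side St"},
            {"run_id": "b", "address": "unknown"},
        ])
        runs = load_runs(path, lookup=load_lookup(lookup_path))
        assert runs[0].coord is not None
        assert runs[0].coord.lon == pytest.approx(-71.05)
        assert runs[1].coord is None

    def test_study_shaped_fixture_percentage(self, tmp_path):
        # 700 rows, 6 lacking coordinates -> 99.1% of runs geocoded
        rows = []
        for i in range(700):
            row = {"run_id": f"r{i}", "address": f"{i} Any St"}
            if i >= 6:
                row.update({"lon": f"{-71.0 + (i % 50) * 1e-3:.6f}",
                            "lat": f"{42.0 + (i // 50) * 1e-3:.6f}"})
            rows.append(row)
        runs = load_runs(write_runs_csv(tmp_path / "runs.csv", rows))
        attr = attrition_report(runs)
        assert attr.n_rows == 700
        assert attr.pct_runs_geocoded == 99.1


class TestAttrition:
    def test_address_level_counts(self):
        runs = ([_mkrun(i, -71.0 + i * 1e-4, 42.0, address=f"A{i}")
                 for i in range(353)]
                + [_mkrun(400 + i, address=f"B{i}") for i in range(6)])
        attr = attrition_report(runs)
        assert attr.n_addresses == 359
        assert attr.n_addresses_geocoded == 353
        assert attr.pct_addresses_geocoded == 98.3


class TestDedupe:
    def test_two_addresses_same_coordinates(self):
        runs = [_mkrun(0, -71.0, 42.0, address="Apt 1"),
                _mkrun(1, -71.0, 42.0, address="Apt 2")]
        xy = np.zeros((2, 2))
        locs = dedupe_locations(runs, xy)
        assert len(locs) == 1
        assert locs[0].addresses == {"Apt 1", "Apt 2"}
        assert locs[0].n_runs == 2

    def test_distant_runs_stay_separate(self):
        runs = [_mkrun(0, -71.0, 42.0), _mkrun(1, -71.0, 42.0)]
        xy = np.array([[0.0, 0.0], [100.0, 0.0]])
        assert len(dedupe_locations(runs, xy, tolerance=0.5)) == 2

    def test_matches_brute_force_grouping(self, rng):
        # coincident-or-far datasets: greedy merge must equal the exact
        # connected-component grouping
        for trial in range(25):
            n_sites = rng.integers(3, 12)
            sites = rng.uniform(0, 1000, size=(n_sites, 2))
            idx = rng.integers(0, n_sites, 60)
            xy = sites[idx] + rng.normal(0, 0.01, size=(60, 2))
            runs = [_mkrun(i, -71.0, 42.0) for i in range(60)]
            locs = dedupe_locations(runs, xy, tolerance=0.5)
            # oracle: union-find over all pairs within tolerance
            parent = list(range(60))

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for i in range(60):
                for j in range(i + 1, 60):
                    if np.hypot(*(xy[i] - xy[j])) <= 0.5:
                        ri, rj = find(i), find(j)
                        if ri != rj:
                            parent[ri] = rj
            oracle_groups = {}
            for i in range(60):
                oracle_groups.setdefault(find(i), set()).add(f"r{i}")
            mine = {frozenset(l.run_ids) for l in locs}
            assert mine == {frozenset(g) for g in oracle_groups.values()}

    def test_conservation(self, rng):
        xy = rng.uniform(0, 100, size=(40, 2))
        runs = [_mkrun(i, -71.0, 42.0) for i in range(40)]
        locs = dedupe_locations(runs, xy)
        assert sum(l.n_runs for l in locs) == 40
        all_ids = [rid for l in locs for rid in l.run_ids]
        assert sorted(all_ids) == sorted(f"r{i}" for i in range(40))

    def test_order_independent_when_well_separated(self, rng):
        sites = np.array([[0, 0], [10, 0], [0, 10], [50, 50]], dtype=float)
        idx = rng.integers(0, 4, 30)
        xy = sites[idx] + rng.normal(0, 0.05, size=(30, 2))
        runs = [_mkrun(i, -71.0, 42.0) for i in range(30)]
        locs1 = dedupe_locations(runs, xy, tolerance=0.5)
        perm = rng.permutation(30)
        locs2 = dedupe_locations([runs[i] for i in perm], xy[perm],
                                 tolerance=0.5)
        assert ({frozenset(l.run_ids) for l in locs1}
                == {frozenset(l.run_ids) for l in locs2})

    def test_run_without_coordinates_raises(self):
        with pytest.raises(ValueError, match="no coordinates"):
            dedupe_locations([_mkrun(0)], np.zeros((1, 2)))


class TestClip:
    @pytest.fixture
    def window(self):
        return PolygonWindow([(0, 0), (100, 0), (100, 100), (0, 100)])

    def _locs(self, coords):
        from pdnmap.geometry import PlanarPoint
        return [Location(location_id=f"L{i}", coord=PlanarPoint(*c),
                         run_ids=[f"r{i}"])
                for i, c in enumerate(coords)]

    def test_all_inside(self, window):
        kept, removed = clip_to_boundary(self._locs([(10, 10), (50, 50)]), window)
        assert len(kept) == 2 and removed == []

    def test_boundary_point_kept(self, window):
        kept, removed = clip_to_boundary(self._locs([(0.0, 50.0)]), window)
        assert len(kept) == 1

    def test_study_shaped_attrition(self, window, rng):
        # 349 locations carrying 693 runs, 3 single-run locations outside
        # -> 690 runs retained
        from pdnmap.geometry import PlanarPoint
        locs = []
        n_runs = 0
        for i in range(346):
            count = 1 if i < 345 else 345   # 345 singles + one 345-run site
            locs.append(Location(f"L{i}", PlanarPoint(*rng.uniform(1, 99, 2)),
                                 run_ids=[f"r{n_runs + k}" for k in range(count)]))
            n_runs += count
        # make total inside = 690 exactly
        assert sum(l.n_runs for l in locs) == 690
        for j in range(3):
            locs.append(Location(f"X{j}", PlanarPoint(200.0 + j, 200.0),
                                 run_ids=[f"out{j}"]))
        kept, removed = clip_to_boundary(locs, window)
        assert len(kept) == 346 and len(removed) == 3
        assert sum(l.n_runs for l in kept) == 690
        assert all(l.n_runs == 1 for l in removed)

    def test_partition_and_idempotence(self, window, rng):
        locs = self._locs([tuple(c) for c in rng.uniform(-50, 150, size=(40, 2))])
        kept, removed = clip_to_boundary(locs, window)
        assert len(kept) + len(removed) == 40
        assert set(id(l) for l in kept).isdisjoint(id(l) for l in removed)
        kept2, removed2 = clip_to_boundary(kept, window)
        assert kept2 == kept and removed2 == []
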