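import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdnmap.geometry import (GeoPoint, PlanarPoint, PolygonWindow,
                             arc_inside_fractions, centroid,
                             circle_inside_fraction, convex_hull,
                             inverse_project, load_boundary_geojson,
                             point_in_polygon, project_to_plane,
                             sample_uniform_in_window, window_to_geojson)

from .oracles import (gift_wrap_hull, haversine_m,
                      rect_circle_inside_fraction, winding_number_inside)


class TestProjection:
    def test_reference_maps_to_origin(self, reference):
        (p,) = project_to_plane([reference], reference)
        assert p.x == 0.0 and p.y == 0.0

    def test_latitude_step_matches_haversine(self, reference):
        a = GeoPoint(reference.lon, reference.lat)
        b = GeoPoint(reference.lon, reference.lat + 0.01)
        pa, pb = project_to_plane([a, b], reference)
        planar = math.hypot(pb.x - pa.x, pb.y - pa.y)
        true = haversine_m(a.lon, a.lat, b.lon, b.lat)
        assert planar == pytest.approx(1111.95, abs=1.0)
        assert abs(planar - true) < 2.0

    def test_city_scale_distances_within_2m(self, reference, rng):
        # random pairs within ~5 km of the reference
        lons = reference.lon + rng.uniform(-0.05, 0.05, 40)
        lats = reference.lat + rng.uniform(-0.04, 0.04, 40)
        geos = [GeoPoint(lon, lat) for lon, lat in zip(lons, lats)]
        pls = project_to_plane(geos, reference)
        for i in range(0, 40, 2):
            a, b = geos[i], geos[i + 1]
            pa, pb = pls[i], pls[i + 1]
            planar = math.hypot(pb.x - pa.x, pb.y - pa.y)
            true = haversine_m(a.lon, a.lat, b.lon, b.lat)
            assert abs(planar - true) < 2.0

    def test_outside_validity_window_rejected(self, reference):
        with pytest.raises(ValueError, match="reference"):
            project_to_plane([GeoPoint(reference.lon + 1.0, reference.lat)],
                             reference)

    @given(dlon=st.floats(-0.4, 0.4), dlat=st.floats(-0.4, 0.4))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, dlon, dlat):
        ref = GeoPoint(-71.0, 42.0)
        g = GeoPoint(ref.lon + dlon, ref.lat + dlat)
        (p,) = project_to_plane([g], ref)
        (back,) = inverse_project([p], ref)
        assert back.lon == pytest.approx(g.lon, abs=1e-9)
        assert back.lat == pytest.approx(g.lat, abs=1e-9)

    def test_geopoint_validation(self):
        with pytest.raises(ValueError):
            GeoPoint(200.0, 0.0)
        with pytest.raises(ValueError):
            GeoPoint(0.0, 91.0)


class TestPointInPolygon:
    def test_center_of_unit_square(self, unit_square):
        assert point_in_polygon(PlanarPoint(0.5, 0.5), unit_square)

    def test_outside(self, unit_square):
        assert not point_in_polygon(PlanarPoint(1.5, 0.5), unit_square)

    def test_boundary_counts_as_inside(self, unit_square):
        assert point_in_polygon(PlanarPoint(1.0, 0.5), unit_square)
        assert point_in_polygon(PlanarPoint(0.0, 0.0), unit_square)

    def test_against_winding_number_oracle(self, irregular_window, rng):
        ring = irregular_window.shell
        xs = rng.uniform(-200, 900, 1000)
        ys = rng.uniform(-150, 800, 1000)
        mine = irregular_window.contains_xy(xs, ys)
        oracle = np.array([winding_number_inside(x, y, ring)
                           for x, y in zip(xs, ys)])
        assert np.array_equal(mine, oracle)

    def test_hole_is_outside(self):
        w = PolygonWindow([(0, 0), (10, 0), (10, 10), (0, 10)],
                          holes=[[(4, 4), (6, 4), (6, 6), (4, 6)]])
        assert w.area == pytest.approx(100 - 4)
        assert not w.contains_xy(np.array([5.0]), np.array([5.0]))[0]
        assert w.contains_xy(np.array([2.0]), np.array([2.0]))[0]


class TestPolygonWindow:
    def test_area_is_shoelace(self, irregular_window):
        ring = irregular_window.shell
        x, y = ring[:, 0], ring[:, 1]
        shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert irregular_window.area == pytest.approx(shoelace)

    def test_self_intersecting_ring_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            PolygonWindow([(0, 0), (1, 1), (1, 0), (0, 1)])

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            PolygonWindow([(0, 0), (1, 0), (2, 0)])

    def test_boundary_distance(self, unit_square):
        d = unit_square.boundary_distance(np.array([0.5, 0.1]),
                                          np.array([0.5, 0.5]))
        assert d[0] == pytest.approx(0.5)
        assert d[1] == pytest.approx(0.1)


class TestCircleInsideFraction:
    def test_fully_interior_circle(self, big_rectangle):
        assert circle_inside_fraction(PlanarPoint(500, 400), 50.0,
                                      big_rectangle) == 1.0

    def test_half_plane_formula(self, big_rectangle):
        # center 5 m from one straight edge, radius 10: 1 - arccos(0.5)/pi
        frac = circle_inside_fraction(PlanarPoint(500, 5.0), 10.0,
                                      big_rectangle, resolution=7200)
        assert frac == pytest.approx(2.0 / 3.0, abs=2 / 7200)

    def test_center_outside_raises(self, big_rectangle):
        with pytest.raises(ValueError, match="outside"):
            circle_inside_fraction(PlanarPoint(-5, 400), 10.0, big_rectangle)

    def test_resolution_floor(self, big_rectangle):
        with pytest.raises(ValueError, match="resolution"):
            circle_inside_fraction(PlanarPoint(500, 400), 10.0, big_rectangle,
                                   resolution=10)

    def test_against_rectangle_closed_form(self, big_rectangle, rng):
        resolution = 720
        for _ in range(200):
            cx = rng.uniform(1, 999)
            cy = rng.uniform(1, 799)
            r = rng.uniform(1, 400)
            mine = circle_inside_fraction(PlanarPoint(cx, cy), r,
                                          big_rectangle, resolution=resolution)
            exact = rect_circle_inside_fraction(cx, cy, r, 0, 0, 1000, 800)
            assert abs(mine - exact) <= 2.0 / resolution

    def test_batched_matches_scalar(self, irregular_window, rng):
        centers = sample_uniform_in_window(50, irregular_window, rng)
        dists = rng.uniform(5, 150, 50)
        batched = arc_inside_fractions(centers, dists, irregular_window, 256)
        for i in range(50):
            scalar = circle_inside_fraction(
                PlanarPoint(*centers[i]), dists[i], irregular_window,
                resolution=256)
            assert batched[i] == pytest.approx(scalar, abs=1e-12)

    def test_monotone_in_radius_convex_window(self, big_rectangle):
        fracs = [circle_inside_fraction(PlanarPoint(300, 200), r,
                                        big_rectangle)
                 for r in (50, 150, 250, 350)]
        assert all(1.0 >= a >= b >= 0.0 for a, b in zip(fracs, fracs[1:]))

    def test_one_whenever_interior(self, irregular_window, rng):
        pts = sample_uniform_in_window(30, irregular_window, rng)
        bd = irregular_window.boundary_distance(pts[:, 0], pts[:, 1])
        for (x, y), d in zip(pts, bd):
            if d > 10.0:
                assert circle_inside_fraction(PlanarPoint(x, y), 0.9 * d,
                                              irregular_window) == 1.0


class TestConvexHull:
    def test_unit_square_with_center(self):
        hull = convex_hull([(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)])
        assert hull.area == pytest.approx(1.0)
        assert not hull.degenerate

    def test_collinear_degenerate(self):
        hull = convex_hull([(0, 0), (1, 1), (2, 2)])
        assert hull.degenerate
        assert hull.area == 0.0

    def test_single_point_degenerate(self):
        hull = convex_hull([(3.0, 4.0)])
        assert hull.degenerate and hull.area == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            convex_hull([])

    def test_matches_gift_wrapping_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(200, 2))
        hull = convex_hull(pts)
        oracle = gift_wrap_hull(pts)
        mine = {tuple(v) for v in hull.shell}
        theirs = {tuple(v) for v in oracle}
        assert mine == theirs

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_hull_contains_all_points(self, pts):
        hull = convex_hull(pts)
        if hull.degenerate:
            return
        for p in pts:
            assert point_in_polygon(PlanarPoint(*p), hull)
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        bbox = (max(xs) - min(xs)) * (max(ys) - min(ys))
        assert 0.0 <= hull.area <= bbox + 1e-9


class TestCentroid:
    def test_single_point(self):
        c = centroid([(3.0, -2.0)])
        assert (c.x, c.y) == (3.0, -2.0)

    def test_square_symmetry(self):
        c = centroid([(0, 0), (2, 0), (0, 2), (2, 2)])
        assert (c.x, c.y) == (1.0, 1.0)

    def test_multiplicity_weighting(self):
        # 76 coincident runs at A plus 9 at B=(85,0): mean x = 9*85/85 = 9
        pts = [(0.0, 0.0)] * 76 + [(85.0, 0.0)] * 9
        c = centroid(pts)
        assert c.x == pytest.approx(9.0)
        assert c.y == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            centroid([])

    def test_centroid_inside_hull(self, rng):
        pts = rng.uniform(-10, 10, size=(30, 2))
        hull = convex_hull(pts)
        assert point_in_polygon(centroid(pts), hull)


class TestGeoJson:
    def test_round_trip(self, tmp_path, reference):
        ring = [[-71.01, 41.99], [-70.98, 41.99], [-70.985, 42.01],
                [-71.005, 42.012], [-71.01, 41.99]]
        obj = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {},
             "geometry": {"type": "Polygon", "coordinates": [ring]}}]}
        path = tmp_path / "b.geojson"
        import json
        path.write_text(json.dumps(obj))
        w = load_boundary_geojson(path)
        assert w.area > 0
        out = window_to_geojson(w)
        back = np.asarray(out["coordinates"][0])
        orig = np.asarray(ring)
        assert np.allclose(back[:-1], orig[:-1], atol=1e-9)

    def test_multipolygon_keeps_largest(self):
        small = [[[0.0, 0.0], [0.001, 0.0], [0.001, 0.001], [0.0, 0.001], [0.0, 0.0]]]
        big = [[[0.0, 0.0], [0.01, 0.0], [0.01, 0.01], [0.0, 0.01], [0.0, 0.0]]]
        w = load_boundary_geojson({"type": "MultiPolygon",
                                   "coordinates": [small, big]})
        # ~1.11 km per 0.01 degrees at the equator
        assert w.area == pytest.approx(1.11e3 ** 2, rel=0.05)


class TestUniformSampling:
    def test_all_inside(self, irregular_window, rng):
        pts = sample_uniform_in_window(500, irregular_window, rng)
        assert irregular_window.contains_xy(pts[:, 0], pts[:, 1]).all()

    def test_zero_points(self, unit_square, rng):
        assert sample_uniform_in_window(0, unit_square, rng).shape == (0, 2)
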