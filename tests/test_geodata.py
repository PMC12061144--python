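import math

import numpy as np
import pandas as pd
import pytest
import tifffile

from nichetransfer.geodata import (
    EARTH_RADIUS_KM,
    GeoreferencingError,
    OccurrenceSet,
    PredictorStack,
    RasterGrid,
    align_stack,
    cell_area_km2,
    extract_values,
    read_occurrences,
    read_raster,
    write_occurrences,
    write_raster,
)

from conftest import make_grid


class TestRasterIO:
    def test_roundtrip_preserves_values_mask_and_georeferencing(self, tmp_path):
        values = np.arange(9.0).reshape(3, 3)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        values[1, 2] = np.nan
        grid = RasterGrid(values, mask, origin_lon=-10.0, origin_lat=50.0, cell_size=2.5 / 60)
        path = tmp_path / "g.tif"
        write_raster(grid, path)
        back = read_raster(path)
        assert np.array_equal(back.nodata_mask, mask)
        assert np.array_equal(back.values[~mask], values[~mask])
        assert back.origin_lon == -10.0 and back.origin_lat == 50.0
        assert abs(back.cell_size - 2.5 / 60) < 1e-12

    def test_pixel_is_area_cell_center_convention(self):
        grid = make_grid(np.zeros((4, 4)), origin_lon=0.0, origin_lat=10.0, cell_size=0.5)
        assert grid.lon_centers()[0] == pytest.approx(0.25)
        assert grid.lat_centers()[0] == pytest.approx(9.75)
        row, col = grid.cell_index(0.25, 9.75)
        assert (row, col) == (0, 0)

    def test_pixel_is_point_file_origin_shifted_half_cell(self, tmp_path):
        # the tiepoint of a point-convention file names the first cell CENTER
        path = tmp_path / "point.tif"
        geokeys = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 2, 2048, 0, 1, 4326)
        tifffile.imwrite(
            path,
            np.zeros((3, 3)),
            extratags=[
                (33550, "d", 3, (1.0, 1.0, 0.0)),
                (33922, "d", 6, (0.0, 0.0, 0.0, 100.0, 40.0, 0.0)),
                (34735, "H", len(geokeys), geokeys),
            ],
        )
        grid = read_raster(path)
        assert grid.origin_lon == pytest.approx(99.5)
        assert grid.origin_lat == pytest.approx(40.5)
        assert grid.lon_centers()[0] == pytest.approx(100.0)

    def test_projected_crs_rejected(self, tmp_path):
        path = tmp_path / "utm.tif"
        geokeys = (1, 1, 0, 2, 1024, 0, 1, 1, 1025, 0, 1, 1)
        tifffile.imwrite(
            path,
            np.zeros((3, 3)),
            extratags=[
                (33550, "d", 3, (100.0, 100.0, 0.0)),
                (33922, "d", 6, (0.0, 0.0, 0.0, 500000.0, 4000000.0, 0.0)),
                (34735, "H", len(geokeys), geokeys),
            ],
        )
        with pytest.raises(GeoreferencingError, match="[Rr]eproject"):
            read_raster(path)

    def test_plain_tiff_without_georeferencing_rejected(self, tmp_path):
        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((3, 3)))
        with pytest.raises(GeoreferencingError, match="georeferencing"):
            read_raster(path)


class TestAlign:
    def test_identity_resample_unchanged(self, small_stack):
        out = align_stack([small_stack], small_stack.template)
        for name in small_stack.names:
            a, b = out.grids[name], small_stack.grids[name]
            assert np.array_equal(a.nodata_mask, b.nodata_mask)
            assert np.array_equal(a.values[~a.nodata_mask], b.values[~b.nodata_mask])

    def test_constant_grid_resampled_stays_constant(self):
        src = make_grid(np.full((8, 8), 3.5), cell_size=0.5)
        template = make_grid(np.zeros((4, 4)), cell_size=1.0)
        stack = PredictorStack({"c": src}, {"c": "climate"})
        out = align_stack([stack], template)
        assert np.allclose(out.grids["c"].values, 3.5)

    def test_bilinear_center_of_2x2_checkerboard(self):
        # hand bilinear at the center of [[0,1],[0,1]]: 0.25*(0+1+0+1) = 0.5
        src = make_grid(np.array([[0.0, 1.0], [0.0, 1.0]]), origin_lon=0, origin_lat=2, cell_size=1.0)
        template = make_grid(np.zeros((1, 1)), origin_lon=0.5, origin_lat=1.5, cell_size=1.0)
        out = align_stack([PredictorStack({"c": src}, {"c": "climate"})], template)
        assert out.grids["c"].values[0, 0] == pytest.approx(0.5)

    def test_nearest_for_landuse_preserves_bounds(self):
        src = make_grid(np.array([[0.0, 1.0], [0.0, 1.0]]), origin_lon=0, origin_lat=2, cell_size=1.0)
        template = make_grid(np.zeros((1, 1)), origin_lon=0.4, origin_lat=1.5, cell_size=1.0)
        out = align_stack([PredictorStack({"lu": src}, {"lu": "landuse"})], template)
        assert out.grids["lu"].values[0, 0] in (0.0, 1.0)

    def test_non_overlapping_extent_raises_naming_layer(self, small_stack):
        far = make_grid(np.zeros((12, 12)), origin_lon=120.0, origin_lat=-40.0, cell_size=0.5)
        with pytest.raises(ValueError, match="bio1"):
            align_stack([small_stack], far)

    def test_idempotent_on_aligned_stack(self, small_stack):
        once = align_stack([small_stack], small_stack.template)
        twice = align_stack([once], small_stack.template)
        for name in once.names:
            a, b = once.grids[name], twice.grids[name]
            assert np.array_equal(a.nodata_mask, b.nodata_mask)
            assert np.array_equal(a.values[~a.nodata_mask], b.values[~b.nodata_mask])


class TestExtract:
    def test_point_at_cell_center_reads_that_cell(self, small_stack):
        tmpl = small_stack.template
        lon, lat = tmpl.lon_centers()[5], tmpl.lat_centers()[7]
        pts = pd.DataFrame({"population": ["a"], "lon": [lon], "lat": [lat]})
        X, report = extract_values(pts, small_stack)
        assert report.n_kept == 1
        for name in small_stack.names:
            assert X[name].iloc[0] == small_stack.grids[name].values[7, 5]

    def test_point_outside_extent_dropped_and_counted(self, small_stack):
        pts = pd.DataFrame(
            {"population": ["a", "a"], "lon": [1.0, 170.0], "lat": [9.0, 0.0]}
        )
        X, report = extract_values(pts, small_stack)
        assert report.n_outside == 1 and report.n_kept == 1

    def test_point_on_nodata_cell_dropped(self, small_stack):
        tmpl = small_stack.template
        lon, lat = tmpl.lon_centers()[4], tmpl.lat_centers()[3]  # masked in fixture
        pts = pd.DataFrame({"population": ["a", "a"], "lon": [lon, 1.0], "lat": [lat, 9.0]})
        X, report = extract_values(pts, small_stack)
        assert report.n_nodata == 1 and report.n_kept == 1

    def test_matches_per_point_brute_force(self, small_stack, rng):
        tmpl = small_stack.template
        n = 100
        lon = rng.uniform(tmpl.origin_lon, tmpl.origin_lon + 20 * 0.5, n)
        lat = rng.uniform(tmpl.origin_lat - 20 * 0.5, tmpl.origin_lat, n)
        pts = pd.DataFrame({"population": "a", "lon": lon, "lat": lat})
        X, report = extract_values(pts, small_stack)
        combined = small_stack.combined_nodata()
        for idx in X.index:
            # brute-force: scan every cell for the one containing the point
            px, py = lon[idx], lat[idx]
            hit = None
            for i in range(tmpl.n_rows):
                for j in range(tmpl.n_cols):
                    west = tmpl.origin_lon + j * tmpl.cell_size
                    north = tmpl.origin_lat - i * tmpl.cell_size
                    if west <= px < west + tmpl.cell_size and north - tmpl.cell_size < py <= north:
                        hit = (i, j)
            assert hit is not None and not combined[hit]
            for name in small_stack.names:
                assert X.loc[idx, name] == small_stack.grids[name].values[hit]

    def test_permutation_equivariant(self, small_stack, rng):
        tmpl = small_stack.template
        lon = rng.uniform(0.2, 9.8, 30)
        lat = rng.uniform(0.2, 9.8, 30)
        pts = pd.DataFrame({"population": "a", "lon": lon, "lat": lat})
        perm = rng.permutation(30)
        X1, _ = extract_values(pts, small_stack)
        X2, _ = extract_values(pts.iloc[perm].reset_index(drop=True), small_stack)
        merged = X2.assign(orig=perm[X2.index])
        for _, row in merged.iterrows():
            assert int(row["orig"]) in X1.index
            assert np.array_equal(
                row[small_stack.names].to_numpy(float),
                X1.loc[int(row["orig"]), small_stack.names].to_numpy(float),
            )

    def test_all_points_invalid_raises(self, small_stack):
        pts = pd.DataFrame({"population": ["a"], "lon": [170.0], "lat": [0.0]})
        with pytest.raises(ValueError):
            extract_values(pts, small_stack)


class TestCellArea:
    def test_constant_along_rows(self):
        grid = make_grid(np.zeros((5, 7)), origin_lat=60.0, cell_size=1.0)
        areas = cell_area_km2(grid).values
        assert np.all(areas == areas[:, :1])

    def test_global_grid_totals_sphere_surface(self):
        grid = make_grid(np.zeros((180, 360)), origin_lon=-180, origin_lat=90, cell_size=1.0)
        total = cell_area_km2(grid).values.sum()
        sphere = 4 * math.pi * EARTH_RADIUS_KM**2
        assert abs(total - sphere) / sphere < 1e-4

    def test_equatorial_one_degree_cell(self):
        # independent closed form: R^2 * (pi/180) * (sin 1 deg - sin 0)
        grid = make_grid(np.zeros((1, 1)), origin_lon=0, origin_lat=1.0, cell_size=1.0)
        expected = EARTH_RADIUS_KM**2 * (math.pi / 180) * math.sin(math.radians(1.0))
        assert cell_area_km2(grid).values[0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(12364, abs=1.0)

    def test_row_sums_shrink_toward_pole(self):
        grid = make_grid(np.zeros((80, 10)), origin_lat=85.0, cell_size=1.0)
        row_sums = cell_area_km2(grid).values.sum(axis=1)
        lat_tops = 85.0 - np.arange(80)
        # north of the equator rows get larger toward it, then shrink again
        northern = row_sums[lat_tops > 0]
        assert np.all(np.diff(northern) >= 0)


class TestOccurrences:
    def test_duplicate_triples_dropped_on_load(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text(
            "species,lon,lat\nmoth_eu,10.0,50.0\nmoth_eu,10.0,50.0\nmoth_as,100.0,40.0\n"
        )
        with pytest.warns(UserWarning, match="duplicate"):
            occ, n_dup = read_occurrences(path)
        assert n_dup == 1 and len(occ) == 2

    def test_roundtrip_csv(self, tmp_path, occurrences):
        path = tmp_path / "occ.csv"
        write_occurrences(occurrences, path)
        back, n_dup = read_occurrences(path)
        assert n_dup == 0
        assert back.counts() == occurrences.counts()

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            OccurrenceSet(
                pd.DataFrame({"population": ["a"], "lon": [10.0], "lat": [95.0]})
            )
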