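import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbniche.errors import GridFormatError, OutOfBoundsError
from herbniche.geodata import (
    EARTH_RADIUS_KM,
    EnvStack,
    OccurrenceSet,
    RasterGrid,
    cell_area_grid,
    cell_area_km2,
    extract_values,
    read_esri_ascii,
    read_occurrences,
    write_esri_ascii,
    write_occurrences,
)


def _write(tmp_path, text, name="g.asc"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestEsriAsciiIO:
    def test_read_simple_grid_northwest_cell_first(self, tmp_path):
        p = _write(
            tmp_path,
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\nNODATA_value -9999\n1 2\n3 4\n",
        )
        g = read_esri_ascii(p)
        assert g.values[0, 0] == 1  # northwest cell
        assert g.values[1, 1] == 4
        assert (g.nrows, g.ncols) == (2, 2)

    def test_center_dialect_converted_to_corner(self, tmp_path):
        p = _write(
            tmp_path,
            "ncols 1\nnrows 1\nxllcenter -0.5\nyllcenter -0.5\ncellsize 1\nNODATA_value -9999\n5\n",
        )
        g = read_esri_ascii(p)
        assert g.xll == pytest.approx(-1.0)
        assert g.yll == pytest.approx(-1.0)

    def test_header_keys_case_insensitive(self, tmp_path):
        p = _write(
            tmp_path,
            "NCOLS 1\nNROWS 1\nXLLCORNER 0\nYLLCORNER 0\nCELLSIZE 1\nnodata_VALUE -1\n2\n",
        )
        assert read_esri_ascii(p).values[0, 0] == 2

    def test_malformed_header_names_line(self, tmp_path):
        p = _write(tmp_path, "ncols 1 1\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 1\nNODATA_value -1\n2\n")
        with pytest.raises(GridFormatError, match="line 1"):
            read_esri_ascii(p)

    def test_row_length_mismatch_names_row(self, tmp_path):
        p = _write(
            tmp_path,
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\nNODATA_value -1\n1 2\n3\n",
        )
        with pytest.raises(GridFormatError, match="row 1"):
            read_esri_ascii(p)

    def test_nodata_only_grid_written_as_sentinel(self, tmp_path, small_grid):
        g = small_grid.copy_with(np.full((3, 3), -9999.0))
        p = tmp_path / "nd.asc"
        write_esri_ascii(g, p)
        data = p.read_text().splitlines()[6:]
        assert all(tok == "-9999" for row in data for tok in row.split())

    def test_single_value_token(self, tmp_path):
        g = RasterGrid("x", 0, 0, 1.0, -9999.0, np.array([[0.04]]))
        p = tmp_path / "one.asc"
        write_esri_ascii(g, p)
        assert p.read_text().splitlines()[6].strip() == "0.04"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        nrows=st.integers(1, 5),
        ncols=st.integers(1, 5),
        seed=st.integers(0, 10_000),
        frac_nodata=st.floats(0, 0.5),
    )
    def test_roundtrip_identity(self, tmp_path_factory, nrows, ncols, seed, frac_nodata):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.uniform(-100, 100, (nrows, ncols)), 4)
        vals[rng.random((nrows, ncols)) < frac_nodata] = -9999.0
        g = RasterGrid(
            "r",
            round(float(rng.uniform(-10, 10)), 4),
            round(float(rng.uniform(-10, 10)), 4),
            0.25,
            -9999.0,
            vals,
        )
        p = tmp_path_factory.mktemp("rt") / "g.asc"
        write_esri_ascii(g, p, decimals=6)
        back = read_esri_ascii(p)
        np.testing.assert_array_equal(back.values, g.values)
        assert (back.xll, back.yll, back.cellsize, back.nodata) == (g.xll, g.yll, g.cellsize, g.nodata)


def test_geotiff_roundtrip(tmp_path):
    tifffile = pytest.importorskip("tifffile")
    vals = np.arange(6, dtype=np.float32).reshape(2, 3)
    p = tmp_path / "g.tif"
    # ModelPixelScale (33550) and ModelTiepoint (33922): top-left at (10, 50)
    tifffile.imwrite(
        p,
        vals,
        extratags=[
            (33550, "d", 3, (0.5, 0.5, 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, 10.0, 50.0, 0.0)),
        ],
    )
    from herbniche.geodata import read_geotiff

    g = read_geotiff(p)
    np.testing.assert_allclose(g.values, vals)
    assert g.xll == pytest.approx(10.0)
    assert g.yll == pytest.approx(50.0 - 2 * 0.5)
    assert g.cellsize == pytest.approx(0.5)


class TestExtractValues:
    def test_nearest_at_cell_centers_equals_indexing(self, tiny_stack):
        g = tiny_stack.grid
        lons, lats = np.meshgrid(g.lon_centers(), g.lat_centers())
        pts = np.column_stack([lons.ravel(), lats.ravel()])
        df = extract_values(tiny_stack, pts, method="nearest")
        for name in tiny_stack.names:
            np.testing.assert_allclose(
                df[name].to_numpy(), tiny_stack[name].values.ravel()
            )

    def test_bilinear_midpoint_of_four_cells(self):
        vals = np.array([[0.0, 0.0], [10.0, 10.0]])
        g = RasterGrid("v", 0, 0, 1.0, -9999.0, vals)
        stack = EnvStack([g])
        df = extract_values(stack, [(1.0, 1.0)], method="bilinear")
        assert df["v"].iloc[0] == pytest.approx(5.0)

    def test_point_outside_extent_raises(self, tiny_stack):
        with pytest.raises(OutOfBoundsError):
            extract_values(tiny_stack, [(0.0, 30.5)], method="nearest")

    def test_nodata_hit_is_flagged_not_dropped(self, small_grid):
        stack = EnvStack([small_grid])
        df = extract_values(stack, [(1.5, 1.5), (0.5, 2.5)], method="nearest")
        assert len(df) == 2
        assert bool(df["has_nodata"].iloc[0]) is True
        assert bool(df["has_nodata"].iloc[1]) is False


class TestCellArea:
    def test_equatorial_one_degree_cell(self):
        g = RasterGrid("e", 0, -0.5, 1.0, -9999.0, np.zeros((1, 1)))
        assert cell_area_km2(g, 0) == pytest.approx(111.1949**2, rel=1e-4)

    def test_cos_latitude_halves_at_60(self):
        g = RasterGrid("e", 0, -0.5, 1.0, -9999.0, np.zeros((1, 1)))
        g60 = RasterGrid("e", 0, 59.5, 1.0, -9999.0, np.zeros((1, 1)))
        assert cell_area_km2(g60, 0) == pytest.approx(cell_area_km2(g, 0) / 2, rel=1e-9)

    def test_row_out_of_range(self, small_grid):
        with pytest.raises(IndexError):
            cell_area_km2(small_grid, 3)

    def test_zero_cellsize_rejected(self):
        with pytest.raises(ValueError):
            RasterGrid("z", 0, 0, 0.0, -9999.0, np.zeros((1, 1)))

    def test_hemisphere_sum_approaches_half_sphere(self):
        g = RasterGrid("h", -180, 0, 1.0, -9999.0, np.zeros((90, 360)))
        total = cell_area_grid(g).sum()
        assert total == pytest.approx(2 * np.pi * EARTH_RADIUS_KM**2, rel=0.005)


class TestOccurrences:
    def test_csv_roundtrip(self, tmp_path):
        occ = OccurrenceSet("sp", [(110.5, 32.1), (111.0, 30.0)])
        p = tmp_path / "occ.csv"
        write_occurrences(occ, p)
        back = read_occurrences(p)
        np.testing.assert_allclose(back.points, occ.points)
        assert back.species == "sp"

    def test_duplicates_flagged_not_removed(self):
        occ = OccurrenceSet("sp", [(1.0, 1.0), (1.0, 1.0), (2.0, 2.0)])
        assert len(occ) == 3
        assert occ.duplicates_flagged.tolist() == [True, True, False]

    def test_coordinates_validated(self):
        with pytest.raises(ValueError):
            OccurrenceSet("sp", [(181.0, 0.0)])


def test_envstack_mask_is_intersection(small_grid):
    other = small_grid.copy_with(np.ones((3, 3)), name="b")
    other.values[0, 0] = -9999.0
    stack = EnvStack([small_grid, other])
    assert stack.mask.sum() == 7  # 9 cells minus one nodata in each layer
    with pytest.raises(ValueError):
        EnvStack([small_grid, small_grid])  # duplicate names
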