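"""Raster model, file round-trips, alignment geometry and point extraction."""

import numpy as np
import pandas as pd
import pytest

from aridrange.grid_core import (
    CoverageError,
    GridSpec,
    RasterFormatError,
    RasterLayer,
    RasterStack,
    align_to_grid,
    extract_at_points,
    read_raster,
    validate_occurrences,
    write_raster,
)

from conftest import unit_grid


class TestGridSpec:
    def test_alignment_is_exact_field_equality(self):
        g = unit_grid(4)
        assert g.is_aligned(unit_grid(4))
        assert not g.is_aligned(unit_grid(5))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 3, 0, 3, 1, 1)
        with pytest.raises(ValueError):
            GridSpec(3, 3, 0, 3, -1, 1)

    def test_point_on_shared_edge_maps_to_larger_index_cell(self):
        g = unit_grid(2)  # 2x2, origin (0, 2)
        row, col, inside = g.point_to_cell(np.array([1.0]), np.array([1.0]))
        assert inside[0] and (row[0], col[0]) == (1, 1)

    def test_outer_max_boundary_belongs_to_last_cell(self):
        g = unit_grid(2)
        row, col, inside = g.point_to_cell(np.array([2.0, 0.0]), np.array([0.0, 2.0]))
        assert inside.all()
        assert (row[0], col[0]) == (1, 1)  # max-x / min-y corner
        assert (row[1], col[1]) == (0, 0)  # min-x / max-y corner

    def test_layer_shape_and_finiteness_validated(self, grid3):
        with pytest.raises(ValueError):
            RasterLayer("bad", grid3, np.zeros((2, 2)))
        vals = np.zeros((3, 3))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError):
            RasterLayer("bad", grid3, vals)


class TestRasterIO:
    def test_esri_ascii_nodata_cells_masked(self, tmp_path):
        text = (
            "ncols 3\nnrows 3\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n"
            "1 2 3\n4 -9999 6\n7 8 9\n"
        )
        p = tmp_path / "g.asc"
        p.write_text(text)
        layer = read_raster(p)
        assert layer.mask.sum() == 1 and layer.mask[1, 1]
        assert layer.values[0, 2] == 3.0
        assert layer.grid.y_origin == 3.0

    def test_ascii_roundtrip_within_decimal_quantization(self, tmp_path, rng):
        grid = unit_grid(10)
        layer = RasterLayer("x", grid, rng.uniform(-5, 5, (10, 10)))
        back = read_raster(write_raster(layer, tmp_path / "x.asc"))
        assert back.grid == layer.grid
        # 6 printed decimals quantize by at most half an ulp of 1e-6
        assert np.abs(back.values - layer.values).max() <= 5e-7

    def test_ascii_header_body_disagreement_raises(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text(
            "ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1 2 3\n4 5\n"
        )
        with pytest.raises(RasterFormatError, match="ncols"):
            read_raster(p)

    def test_ascii_missing_header_field_raises(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nnrows 2\n1 2\n3 4\n")
        with pytest.raises(RasterFormatError, match="xllcorner"):
            read_raster(p)

    def test_all_masked_layer_roundtrips(self, tmp_path, grid3):
        layer = RasterLayer("m", grid3, np.zeros((3, 3)), np.ones((3, 3), bool))
        back = read_raster(write_raster(layer, tmp_path / "m.asc"))
        assert back.mask.all()

    def test_constant_layer_roundtrip(self, tmp_path, grid3):
        layer = RasterLayer("c", grid3, np.full((3, 3), 5.0))
        back = read_raster(write_raster(layer, tmp_path / "c.asc"))
        assert (back.values == 5.0).all()

    def test_geotiff_roundtrip_preserves_grid_and_mask(self, tmp_path, rng):
        grid = GridSpec(6, 4, 500000.0, 4_800_000.0, 1000.0, 500.0)
        mask = np.zeros((6, 4), bool)
        mask[2, 3] = True
        vals = np.where(mask, 0, rng.uniform(0, 1, (6, 4)))
        layer = RasterLayer("t", grid, vals, mask)
        back = read_raster(write_raster(layer, tmp_path / "t.tif"))
        assert back.grid == layer.grid
        assert np.array_equal(back.mask, layer.mask)
        assert np.abs(back.values - layer.values).max() < 1e-6  # float32 storage


class TestAlign:
    def test_identity(self, small_stack):
        layer = small_stack["C"]
        out = align_to_grid(layer, layer.grid)
        assert out.equals(layer)

    def test_upsample_2x2_to_4x4_blocks(self):
        src_grid = GridSpec(2, 2, 0, 2, 1, 1)
        layer = RasterLayer("s", src_grid, np.array([[1.0, 2.0], [3.0, 4.0]]))
        target = GridSpec(4, 4, 0, 2, 0.5, 0.5)
        out = align_to_grid(layer, target)
        expected = np.array(
            [[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]], dtype=float
        )
        assert np.array_equal(out.values, expected)

    def test_downsample_hits_coinciding_centres(self, rng):
        src = RasterLayer("s", unit_grid(4), rng.normal(size=(4, 4)))
        # target centres coincide with source cells (0,0),(0,2),(2,0),(2,2)
        target = GridSpec(2, 2, -0.5, 4.5, 2.0, 2.0)
        out = align_to_grid(src, target)
        assert np.array_equal(out.values, src.values[np.ix_([0, 2], [0, 2])])

    def test_value_set_preservation(self, rng):
        src = RasterLayer("s", unit_grid(5), rng.integers(0, 4, (5, 5)).astype(float))
        target = GridSpec(9, 7, 0.3, 4.8, 0.51, 0.49)
        out = align_to_grid(src, target)
        assert set(np.unique(out.values[~out.mask])) <= set(np.unique(src.values))

    def test_idempotent(self, rng):
        src = RasterLayer("s", unit_grid(5), rng.normal(size=(5, 5)))
        target = GridSpec(3, 3, 0.2, 4.7, 1.4, 1.5)
        once = align_to_grid(src, target)
        twice = align_to_grid(once, target)
        assert twice.equals(once)

    def test_disjoint_extents_raise(self, grid3):
        layer = RasterLayer("s", grid3, np.zeros((3, 3)))
        far = GridSpec(3, 3, 100.0, 103.0, 1, 1)
        with pytest.raises(CoverageError):
            align_to_grid(layer, far)


class TestExtract:
    @staticmethod
    def occ(x, y):
        return pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(len(x))],
                "x": x,
                "y": y,
                "species": "sp",
                "presence": [i % 2 for i in range(len(x))],
            }
        )

    def test_site_at_cell_centre_gets_cell_values(self, small_stack):
        # centre of cell (2, 4): x=4.5, y=10-2.5=7.5; A=row idx, B=col idx
        design, n_exc = extract_at_points(small_stack, self.occ([4.5], [7.5]))
        assert n_exc == 0
        assert design.loc[0, "A"] == 2.0 and design.loc[0, "B"] == 4.0

    def test_nodata_site_excluded_with_count(self, small_stack):
        # cell (7,7) is masked; its centre is (7.5, 2.5)
        design, n_exc = extract_at_points(small_stack, self.occ([7.5, 1.5], [2.5, 8.5]))
        assert n_exc == 1 and len(design) == 1

    def test_outside_site_excluded_not_fatal(self, small_stack):
        design, n_exc = extract_at_points(small_stack, self.occ([-5.0], [5.0]))
        assert n_exc == 1 and len(design) == 0

    def test_order_and_shape_preserved(self, small_stack):
        xs, ys = [0.5, 3.5, 9.5], [9.5, 6.5, 0.5]
        design, n_exc = extract_at_points(small_stack, self.occ(xs, ys))
        assert list(design["site_id"]) == ["s0", "s1", "s2"]
        assert design[["A", "B", "C"]].shape == (3, 3)
        assert len(design) + n_exc == 3

    def test_row_count_conservation(self, small_stack, rng):
        xs = rng.uniform(-2, 12, 50)
        ys = rng.uniform(-2, 12, 50)
        design, n_exc = extract_at_points(small_stack, self.occ(xs, ys))
        assert len(design) + n_exc == 50

    def test_occurrence_validation(self):
        bad = self.occ([1.0], [1.0])
        bad["presence"] = 2
        with pytest.raises(ValueError, match="binary"):
            validate_occurrences(bad)


def test_stack_requires_alignment_and_unique_names(grid3):
    a = RasterLayer("A", grid3, np.zeros((3, 3)))
    with pytest.raises(ValueError, match="duplicate"):
        RasterStack([a, a.copy()])
    other = RasterLayer("B", unit_grid(4), np.zeros((4, 4)))
    with pytest.raises(Exception):
        RasterStack([a, other])
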