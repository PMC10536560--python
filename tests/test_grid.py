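"""Raster container, resampling, compositing and ASCII-grid round trips."""

import itertools

import numpy as np
import pytest

from eqiscope import (Grid, GridStack, GridTransform, assert_aligned,
                      max_value_composite, read_ascii_grid, resample_nearest,
                      resample_to, write_ascii_grid)

from conftest import NODATA, make_grid


def brute_force_nearest(source, target_transform, target_shape):
    """Exhaustive nearest-center search over all source cells (oracle)."""
    out = np.full(target_shape, source.nodata)
    st = source.transform
    for r in range(target_shape[0]):
        for c in range(target_shape[1]):
            x, y = target_transform.cell_center(r, c)
            best, best_idx = None, None
            for sr in range(source.shape[0]):
                for scol in range(source.shape[1]):
                    sx, sy = st.cell_center(sr, scol)
                    d = (x - sx) ** 2 + (y - sy) ** 2
                    if best is None or d < best - 1e-12:
                        best, best_idx = d, (sr, scol)
                    # ties resolve to smaller row, then column: earlier
                    # iteration order already visits those first
            # outside extent -> nodata
            inside = (st.x0 <= x <= st.x0 + source.shape[1] * st.dx and
                      st.y0 - source.shape[0] * st.dy <= y <= st.y0)
            if inside:
                out[r, c] = source.values[best_idx]
    return out


class TestResampleNearest:
    def test_constant_field_invariant(self):
        src = make_grid(np.full((4, 4), 2.5), cell=500.0)
        tgt = GridTransform(x0=0.0, y0=2000.0, dx=1000.0, dy=1000.0)
        out = resample_nearest(src, tgt, (2, 2))
        assert np.all(out.values == 2.5)

    def test_matches_exhaustive_nearest_center_oracle(self):
        src = make_grid(np.arange(16, dtype=float).reshape(4, 4), cell=500.0)
        tgt = GridTransform(x0=0.0, y0=2000.0, dx=1000.0, dy=1000.0)
        out = resample_nearest(src, tgt, (2, 2))
        expected = brute_force_nearest(src, tgt, (2, 2))
        np.testing.assert_array_equal(out.values, expected)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_geometry_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        src = make_grid(rng.uniform(0, 10, size=(5, 7)), cell=300.0)
        tgt = GridTransform(x0=rng.uniform(-200, 200), y0=1500.0 + rng.uniform(-200, 200),
                            dx=450.0, dy=450.0)
        out = resample_nearest(src, tgt, (4, 5))
        expected = brute_force_nearest(src, tgt, (4, 5))
        np.testing.assert_array_equal(out.values, expected)

    def test_all_nodata_propagates(self):
        src = make_grid(np.full((4, 4), NODATA), cell=500.0)
        out = resample_nearest(src, GridTransform(0.0, 2000.0, 1000.0, 1000.0), (2, 2))
        assert np.all(out.values == NODATA)

    def test_no_new_values(self, rng):
        src = make_grid(rng.uniform(0, 5, size=(6, 6)), cell=500.0)
        out = resample_nearest(src, GridTransform(100.0, 2900.0, 700.0, 700.0), (4, 4))
        src_vals = set(src.values.ravel()) | {src.nodata}
        assert set(out.values.ravel()) <= src_vals

    def test_non_overlapping_extent_errors(self):
        src = make_grid(np.ones((4, 4)), cell=500.0)
        with pytest.raises(ValueError, match="overlap"):
            resample_nearest(src, GridTransform(1e6, 1e6, 1000.0, 1000.0), (2, 2))

    def test_crs_mismatch_errors(self):
        src = make_grid(np.ones((4, 4)), cell=500.0, crs="A")
        ref = make_grid(np.ones((2, 2)), cell=1000.0, crs="B")
        with pytest.raises(ValueError, match="CRS"):
            resample_to(src, ref)


class TestMaxValueComposite:
    def _stack(self, layers):
        return GridStack(slices=[make_grid(l) for l in layers])

    def test_single_slice_identity(self):
        g = make_grid([[1.0, 2.0], [3.0, 4.0]])
        out = max_value_composite(GridStack(slices=[g]))
        np.testing.assert_array_equal(out.values, g.values)

    def test_pixelwise_maximum_and_nodata(self):
        stack = self._stack([[[1.0, NODATA]], [[3.0, 0.4]], [[2.0, NODATA]]])
        out = max_value_composite(stack)
        np.testing.assert_array_equal(out.values, [[3.0, 0.4]])

    def test_all_nodata_pixel_stays_nodata(self):
        stack = self._stack([[[NODATA]], [[NODATA]]])
        assert max_value_composite(stack).values[0, 0] == NODATA

    def test_empty_stack_errors(self):
        with pytest.raises(ValueError, match="empty"):
            max_value_composite(GridStack(slices=[]))

    def test_permutation_invariant_and_idempotent(self, rng):
        layers = rng.uniform(0, 5, size=(4, 3, 3))
        layers[rng.random(layers.shape) < 0.3] = NODATA
        base = max_value_composite(self._stack(list(layers)))
        for perm in itertools.permutations(range(4)):
            out = max_value_composite(self._stack([layers[i] for i in perm]))
            np.testing.assert_array_equal(out.values, base.values)
        again = max_value_composite(GridStack(slices=[base]))
        np.testing.assert_array_equal(again.values, base.values)


class TestAlignment:
    def test_same_geometry_true(self):
        a, b = make_grid(np.ones((3, 3))), make_grid(np.zeros((3, 3)))
        assert assert_aligned([a, b])

    def test_shape_mismatch_false(self):
        assert not assert_aligned([make_grid(np.ones((3, 3))), make_grid(np.ones((4, 3)))])

    def test_tiny_transform_difference_tolerated(self):
        a = make_grid(np.ones((3, 3)))
        b = Grid(values=np.ones((3, 3)),
                 transform=GridTransform(1e-12, 3000.0, 1000.0, 1000.0),
                 crs="SYNTH:TEST", nodata=NODATA)
        assert assert_aligned([a, b])
        c = Grid(values=np.ones((3, 3)),
                 transform=GridTransform(1e-3, 3000.0, 1000.0, 1000.0),
                 crs="SYNTH:TEST", nodata=NODATA)
        assert not assert_aligned([a, c])


def test_ascii_round_trip_bit_exact(tmp_path, rng):
    vals = rng.standard_normal((7, 5)) * 1e3
    vals[rng.random(vals.shape) < 0.2] = NODATA
    g = make_grid(vals, cell=927.67, crs="SYNTH:ROUNDTRIP")
    write_ascii_grid(g, tmp_path / "g.asc")
    back = read_ascii_grid(tmp_path / "g.asc")
    np.testing.assert_array_equal(back.values, g.values)
    assert back.crs == g.crs
    assert back.nodata == g.nodata
    assert back.transform.approx_equal(g.transform)
    np.testing.assert_array_equal(back.valid_mask(), g.valid_mask())


def test_positive_cell_size_enforced():
    with pytest.raises(ValueError, match="positive"):
        GridTransform(0.0, 0.0, -1.0, 1.0)
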