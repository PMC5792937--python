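"""Raster I/O, cell assignment, deduplication and variable pruning."""

import numpy as np
import pandas as pd
import pytest

from nichephylo.errors import DataError, GeometryError
from nichephylo.geodata import (CATEGORICAL, CONTINUOUS, EnvStack, RasterGrid,
                                assign_cells, deduplicate,
                                filter_min_localities, read_ascii_grid,
                                read_env_stack, select_variables,
                                write_ascii_grid)

from conftest import make_occurrences


class TestAsciiGrid:
    def test_roundtrip(self, tmp_path, small_grid):
        path = tmp_path / "g.asc"
        write_ascii_grid(small_grid, path)
        back = read_ascii_grid(path)
        assert back.same_geometry(small_grid)
        np.testing.assert_allclose(back.values, small_grid.values)

    def test_nodata_roundtrip(self, tmp_path):
        vals = np.arange(9, dtype=float).reshape(3, 3)
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        grid = RasterGrid(np.where(mask, np.nan, vals), mask, 0, 0, 0.5)
        path = tmp_path / "g.asc"
        write_ascii_grid(grid, path)
        back = read_ascii_grid(path)
        assert back.nodata_mask[0, 0] and back.nodata_mask.sum() == 1

    def test_missing_header_key(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows 2\n1 2\n3 4\n")
        with pytest.raises(DataError, match="cellsize"):
            read_ascii_grid(path)


class TestEnvStack:
    def test_union_mask(self, tmp_path):
        a = RasterGrid(np.ones((3, 3)), np.eye(3, dtype=bool), 0, 0, 1)
        b_mask = np.zeros((3, 3), bool)
        b_mask[0, 2] = True
        b = RasterGrid(np.ones((3, 3)), b_mask, 0, 0, 1)
        stack = EnvStack([a, b], [CONTINUOUS, CONTINUOUS])
        assert stack.mask.sum() == 4  # 3 diagonal + 1 distinct corner

    def test_geometry_mismatch_names_layer(self, tmp_path):
        a = RasterGrid(np.ones((3, 3)), np.zeros((3, 3), bool), 0, 0, 1, name="a")
        b = RasterGrid(np.ones((3, 3)), np.zeros((3, 3), bool), 0, 0, 2, name="b")
        with pytest.raises(GeometryError, match="'b'"):
            EnvStack([a, b], [CONTINUOUS, CONTINUOUS])

    def test_all_nodata_is_empty_domain(self):
        g = RasterGrid(np.full((3, 3), np.nan), np.ones((3, 3), bool), 0, 0, 1)
        with pytest.raises(DataError, match="empty domain"):
            EnvStack([g], [CONTINUOUS])

    def test_read_env_stack(self, tmp_path, small_grid):
        write_ascii_grid(small_grid, tmp_path / "a.asc")
        write_ascii_grid(small_grid, tmp_path / "b.asc")
        stack = read_env_stack([tmp_path / "a.asc", tmp_path / "b.asc"],
                               [CONTINUOUS, CONTINUOUS])
        assert stack.n_layers == 2
        assert stack.n_valid_cells == 25


class TestAssignCells:
    def test_cell_center_maps_to_cell(self, small_grid):
        occ = make_occurrences([("sp", *small_grid.cell_center(2, 3))])
        out = assign_cells(occ, small_grid)
        assert (out.records.loc[0, "row"], out.records.loc[0, "col"]) == (2, 3)

    def test_center_reassignment_roundtrip(self, small_grid):
        # every cell's center re-assigns to that cell
        pts = [("sp", *small_grid.cell_center(r, c))
               for r in range(5) for c in range(5)]
        out = assign_cells(make_occurrences(pts), small_grid)
        expect = [(r, c) for r in range(5) for c in range(5)]
        got = list(zip(out.records["row"], out.records["col"]))
        assert got == expect

    def test_boundary_goes_to_higher_index(self, small_grid):
        # x=2.0 sits on the shared edge of columns 1 and 2 -> column 2
        occ = make_occurrences([("sp", 2.0, 0.5)])
        out = assign_cells(occ, small_grid)
        assert out.records.loc[0, "col"] == 2

    def test_outside_extent_dropped(self, small_grid):
        occ = make_occurrences([("sp", -1.0, 0.5), ("sp", 0.5, 0.5)])
        out = assign_cells(occ, small_grid)
        assert len(out) == 1 and out.n_dropped == 1

    def test_masked_cell_dropped(self, small_grid):
        mask = np.zeros((5, 5), bool)
        mask[4, 0] = True  # cell containing (0.5, 0.5)
        occ = make_occurrences([("sp", 0.5, 0.5)])
        out = assign_cells(occ, small_grid, mask=mask)
        assert len(out) == 0 and out.n_dropped == 1


class TestDeduplicate:
    def test_shared_cell_collapsed(self, small_grid):
        occ = assign_cells(make_occurrences([
            ("sp", 0.5, 0.5), ("sp", 0.6, 0.6),  # same cell
            ("sp", 1.5, 0.5), ("sp", 2.5, 0.5), ("sp", 3.5, 0.5)]), small_grid)
        out = deduplicate(occ)
        assert len(out) == 4

    def test_idempotent(self, small_grid):
        occ = assign_cells(make_occurrences(
            [("sp", 0.5, 0.5), ("sp", 0.6, 0.6), ("b", 0.5, 0.5)]), small_grid)
        once = deduplicate(occ)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_two_species_share_cell_both_kept(self, small_grid):
        occ = assign_cells(make_occurrences(
            [("a", 0.5, 0.5), ("b", 0.5, 0.5)]), small_grid)
        assert len(deduplicate(occ)) == 2

    def test_requires_cells(self):
        with pytest.raises(DataError, match="cell"):
            deduplicate(make_occurrences([("a", 0.5, 0.5)]))


class TestFilterMinLocalities:
    @pytest.mark.parametrize("n_cells,expected_retained", [(4, True), (3, False)])
    def test_threshold_of_four(self, small_grid, n_cells, expected_retained):
        pts = [("sp", 0.5 + i, 0.5) for i in range(n_cells)]
        occ = deduplicate(assign_cells(make_occurrences(pts), small_grid))
        retained, excluded = filter_min_localities(occ, 4)
        assert (["sp"] == retained) is expected_retained
        assert (["sp"] == excluded) is not expected_retained

    def test_min_one_retains_all(self, small_grid):
        occ = deduplicate(assign_cells(make_occurrences(
            [("a", 0.5, 0.5), ("b", 1.5, 0.5)]), small_grid))
        retained, excluded = filter_min_localities(occ, 1)
        assert retained == ["a", "b"] and excluded == []


class TestSelectVariables:
    def _stack(self, arrays, names):
        grids = [RasterGrid(a, np.zeros(a.shape, bool), 0, 0, 1, name=n)
                 for a, n in zip(arrays, names)]
        return EnvStack(grids, [CONTINUOUS] * len(grids))

    def test_exact_copy_removed(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(5, 5))
        stack = self._stack([a, a.copy()], ["a", "b"])
        reduced, log = select_variables(stack, 0.7)
        assert reduced.names == ["a"]
        assert log.loc[0, "removed"] == "b" and abs(log.loc[0, "r"] - 1) < 1e-12

    def test_uncorrelated_unchanged(self):
        rng = np.random.default_rng(1)
        arrays = [rng.uniform(size=(6, 6)) for _ in range(3)]
        stack = self._stack(arrays, list("abc"))
        reduced, log = select_variables(stack, 0.7)
        assert reduced.names == ["a", "b", "c"] and log.empty

    def test_against_bruteforce_pearson_oracle(self):
        """Survivors match a brute-force greedy pruning on a 5x5 toy grid."""
        rng = np.random.default_rng(5)
        base = rng.uniform(size=(5, 5))
        arrays = [base,
                  base * 0.9 + 0.1 * rng.uniform(size=(5, 5)),
                  rng.uniform(size=(5, 5))]
        stack = self._stack(arrays, list("abc"))
        flat = [a.ravel() for a in arrays]

        def pearson(u, v):
            u = u - u.mean()
            v = v - v.mean()
            return float((u @ v) / np.sqrt((u @ u) * (v @ v)))

        thr = 0.7
        pairs = sorted(((abs(pearson(flat[i], flat[j])), i, j)
                        for i in range(3) for j in range(i + 1, 3)
                        if abs(pearson(flat[i], flat[j])) >= thr),
                       key=lambda t: -t[0])
        dropped = set()
        for _, i, j in pairs:
            if i not in dropped and j not in dropped:
                dropped.add(j)
        expected = [n for k, n in enumerate("abc") if k not in dropped]
        reduced, _ = select_variables(stack, thr)
        assert reduced.names == expected

    def test_no_surviving_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(size=(8, 8))
        arrays = [base + 0.1 * k * rng.uniform(size=(8, 8)) for k in range(5)]
        stack = self._stack(arrays, [f"l{k}" for k in range(5)])
        reduced, _ = select_variables(stack, 0.7)
        vals = reduced.valid_values()
        corr = np.atleast_2d(np.corrcoef(vals.T))
        off = corr[~np.eye(reduced.n_layers, dtype=bool)]
        assert np.all(np.abs(off) < 0.7)

    def test_zero_variance_removed_with_warning(self):
        rng = np.random.default_rng(4)
        stack = self._stack([np.full((5, 5), 2.0), rng.uniform(size=(5, 5))],
                            ["const", "ok"])
        with pytest.warns(UserWarning, match="zero variance"):
            reduced, log = select_variables(stack, 0.7)
        assert reduced.names == ["ok"]
        assert "zero variance" in log["reason"].tolist()
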