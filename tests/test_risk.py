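"""Risk-cell tessellation, ERI computation and five-level classing."""

import numpy as np
import pandas as pd
import pytest

from landrisk import (
    ERIField,
    LandUseRaster,
    RiskClassing,
    build_grid,
    class_metrics,
    classify_risk,
    compute_eri,
    jenks_breaks,
    level_areas,
    local_loss_indices,
    overall_risk,
)


def brute_force_eri(raster, grid, metrics):
    """Oracle: re-sum R over individual pixels of each cell."""
    out = []
    r_of_code = {
        code: (metrics.loc[name, "R"] if name in metrics.index else 0.0)
        for code, name in raster.codebook.items()
    }
    for cell in grid.cells.itertuples():
        window = raster.codes[cell.row0:cell.row1, cell.col0:cell.col1]
        vals = [r_of_code[int(c)] for c in window.reshape(-1)
                if c != raster.nodata_code]
        out.append(sum(vals) / len(vals))
    return np.array(out)


class TestBuildGrid:
    def test_exact_tiling(self):
        r = LandUseRaster(np.full((100, 100), 3), 10.0)
        grid = build_grid(r, 100.0)
        assert grid.n_cells == 100
        assert np.allclose(grid.cells["area_km2"], 0.01)
        assert grid.total_area_km2 == pytest.approx(r.total_area_km2)

    def test_single_cell_covers_all(self, toy_raster):
        grid = build_grid(toy_raster, 2000.0)
        assert grid.n_cells == 1
        assert grid.cells.loc[0, "area_km2"] == pytest.approx(4.0)

    def test_nodata_corner_cells_dropped(self):
        codes = np.full((40, 40), 3)
        codes[:16, :16] = -9999  # nodata block over the top-left cells
        r = LandUseRaster(codes, 10.0)
        grid = build_grid(r, 100.0, min_coverage=0.5)
        # cell (0,0) fully nodata; (0,1)/(1,0) 40% valid -> dropped
        kept = set(zip(grid.cells["grid_row"], grid.cells["grid_col"]))
        assert (0, 0) not in kept and (0, 1) not in kept and (1, 0) not in kept
        assert (1, 1) in kept  # 64% valid
        valid_area_kept = sum(
            (codes[c.row0:c.row1, c.col0:c.col1] != -9999).sum() * r.pixel_area_km2
            for c in grid.cells.itertuples()
        )
        assert grid.total_area_km2 == pytest.approx(valid_area_kept)

    def test_per_class_areas_sum_to_cell_area(self):
        rng = np.random.default_rng(0)
        r = LandUseRaster(rng.choice([1, 2, 3, 4, 5], size=(50, 50)), 100.0)
        grid = build_grid(r, 700.0)
        sums = grid.cells[grid.class_area_columns()].sum(axis=1)
        assert np.allclose(sums, grid.cells["area_km2"])

    def test_invalid_cell_side(self, toy_raster):
        with pytest.raises(ValueError):
            build_grid(toy_raster, -5.0)
        with pytest.raises(ValueError):
            build_grid(toy_raster, 100.0)  # below pixel size


class TestERI:
    def test_uniform_landscape_eri_equals_r(self):
        r = LandUseRaster(np.full((20, 20), 5), 100.0)  # all water
        grid = build_grid(r, 500.0)
        cm = class_metrics(r, grid)
        field = compute_eri(grid, cm)
        assert np.allclose(field.values, cm.loc["water", "R"])

    def test_worked_fixture_value(self, toy_raster, toy_grid):
        cm = class_metrics(toy_raster, toy_grid)
        field = compute_eri(toy_grid, cm)
        assert field.values[0] == pytest.approx(0.38125, abs=1e-12)

    def test_matches_pixel_resummation_oracle(self):
        rng = np.random.default_rng(11)
        r = LandUseRaster(rng.choice([1, 2, 3, 4, 5], size=(64, 64)), 100.0)
        grid = build_grid(r, 800.0)
        cm = class_metrics(r, grid)
        field = compute_eri(grid, cm)
        np.testing.assert_allclose(field.values, brute_force_eri(r, grid, cm),
                                   atol=1e-12)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(12)
        r = LandUseRaster(rng.choice([1, 2, 3, 4, 5], size=(40, 40)), 100.0)
        grid = build_grid(r, 400.0)
        cm = class_metrics(r, grid)
        field = compute_eri(grid, cm)
        assert field.values.min() >= cm["R"].min() - 1e-12
        assert field.values.max() <= cm["R"].max() + 1e-12

    def test_local_scope_uses_cell_metrics(self, toy_raster):
        grid = build_grid(toy_raster, 1000.0)  # four 2x2-pixel cells
        cm = class_metrics(toy_raster, grid)
        local_r = local_loss_indices(toy_raster, grid)
        field = compute_eri(grid, cm, local_r)
        # water-only top-left cell: single 1 km² patch in a 1 km² cell;
        # C=1, N=(1/2)·sqrt(1/1)=0.5; global D_water over the 4-cell grid:
        # Q=1/4, M=1/2, L=1/4 -> D=0.3125; E=0.5+0.15+0.0625=0.7125, F=1
        assert field.values[0] == pytest.approx(0.7125)


class TestClassing:
    @pytest.mark.parametrize(
        "value,level",
        [(0.05, "lowest"), (0.10, "lowest"), (0.12, "low"), (0.15, "low"),
         (0.2, "medium"), (0.38125, "high"), (0.45, "high"), (0.46, "highest")],
    )
    def test_fixed_breaks_right_closed(self, value, level):
        field = ERIField(pd.DataFrame({"cell_id": [0], "eri": [value]}))
        assert classify_risk(field).table.loc[0, "level"] == level

    def test_every_value_gets_exactly_one_level(self):
        rng = np.random.default_rng(1)
        field = ERIField(pd.DataFrame(
            {"cell_id": range(200), "eri": rng.random(200)}
        ))
        out = classify_risk(field)
        assert out.table["level"].notna().all()

    def test_jenks_recovers_separated_clusters(self):
        vals = np.concatenate([
            np.full(10, 0.1), np.full(10, 0.5), np.full(10, 1.0),
            np.full(10, 3.0), np.full(10, 9.0),
        ])
        breaks = jenks_breaks(vals, 5)
        assert breaks == (0.1, 0.5, 1.0, 3.0)

    def test_jenks_needs_enough_values(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 2.0], 5)

    def test_jenks_scheme_end_to_end(self):
        rng = np.random.default_rng(2)
        field = ERIField(pd.DataFrame(
            {"cell_id": range(50), "eri": rng.random(50)}
        ))
        out = classify_risk(field, RiskClassing(scheme="jenks"))
        assert out.classing.scheme == "jenks"
        assert set(out.table["level"].unique()) <= set(
            ("lowest", "low", "medium", "high", "highest")
        )


class TestAggregates:
    def test_overall_risk_sum_and_mean_identity(self):
        rng = np.random.default_rng(5)
        vals = rng.random(137)
        field = ERIField(pd.DataFrame({"cell_id": range(137), "eri": vals}))
        assert overall_risk(field) == pytest.approx(vals.sum())
        assert overall_risk(field) == pytest.approx(vals.mean() * 137, abs=1e-12)

    def test_constant_cells(self):
        field = ERIField(pd.DataFrame(
            {"cell_id": range(1378), "eri": np.full(1378, 0.1)}
        ))
        assert overall_risk(field) == pytest.approx(137.8)

    def test_level_areas_conservation(self):
        rng = np.random.default_rng(6)
        r = LandUseRaster(rng.choice([1, 2, 3, 4, 5], size=(40, 40)), 100.0)
        grid = build_grid(r, 400.0)
        field = classify_risk(compute_eri(grid, class_metrics(r, grid)))
        la = level_areas(field, grid)
        assert set(la.index) == {"lowest", "low", "medium", "high", "highest"}
        assert la.sum() == pytest.approx(grid.total_area_km2)

    def test_worked_fixture_level_areas(self, toy_raster, toy_grid):
        field = classify_risk(compute_eri(toy_grid, class_metrics(toy_raster, toy_grid)))
        la = level_areas(field, toy_grid)
        assert la["high"] == pytest.approx(4.0)
        assert la.drop("high").sum() == 0.0
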