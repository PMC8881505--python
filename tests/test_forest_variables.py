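"""Plot-level variable derivation, climate extraction and variable screening."""

import math

import numpy as np
import pandas as pd
import pytest

from forestsdm.errors import DataError, InterfaceError
from forestsdm.forest_variables import (
    PLOT_AREA_M2,
    DEFAULT_CATALOG,
    compute_plot_variables,
    extract_climate_to_plots,
    rank_by_single_variable_gain,
    screen_correlated,
)
from forestsdm.rasters import Raster


def _tree(dbh, height=10.0, species="Pnig", status="alive", wood="soft", dens=0.52):
    return {
        "plot_id": 0,
        "species_code": species,
        "dbh_mm": dbh,
        "height_m": height,
        "status": status,
        "wood": wood,
        "wood_density_g_cm3": dens,
    }


def _frame(trees):
    return pd.DataFrame(
        trees,
        columns=["plot_id", "species_code", "dbh_mm", "height_m", "status", "wood", "wood_density_g_cm3"],
    )


class TestComputePlotVariables:
    def test_empty_plot_is_all_zero(self):
        out = compute_plot_variables(_frame([]), plot_id=7)
        assert out["tree_density"] == 0.0
        assert out["tree_richness"] == 0
        assert out["dominant_species"] == "none"
        assert out["basal_area"] == 0.0

    def test_per_hectare_scaling_three_trees(self):
        out = compute_plot_variables(_frame([_tree(100), _tree(150), _tree(200)]), 0)
        assert out["tree_density"] == pytest.approx(3 * 10_000 / PLOT_AREA_M2, abs=0.01)
        assert out["tree_density"] == pytest.approx(61.12, abs=0.01)

    def test_single_large_softwood_tree(self):
        out = compute_plot_variables(_frame([_tree(450, wood="soft")]), 0)
        assert out["large_tree_density"] == pytest.approx(20.37, abs=0.01)
        assert out["softwood_large_density"] == out["large_tree_density"]

    def test_negative_dbh_names_the_plot(self):
        with pytest.raises(DataError, match="plot 13"):
            compute_plot_variables(_frame([_tree(-5)]), 13)

    def test_dominant_species_by_basal_area_with_tie_break(self):
        # equal basal areas: lexicographically smallest code wins
        out = compute_plot_variables(
            _frame([_tree(200, species="Qile"), _tree(200, species="Pnig")]), 0
        )
        assert out["dominant_species"] == "Pnig"
        # larger basal area wins regardless of count
        out = compute_plot_variables(
            _frame([_tree(400, species="Qile"), _tree(150, species="Pnig"), _tree(150, species="Pnig")]), 0
        )
        assert out["dominant_species"] == "Qile"

    def test_brute_force_oracle_on_random_plots(self, rng):
        species = ["Pnig", "Qile", "Phal"]
        for _ in range(25):
            n = int(rng.integers(1, 15))
            trees = [
                _tree(
                    float(rng.uniform(76, 800)),
                    height=float(rng.uniform(2, 30)),
                    species=str(rng.choice(species)),
                    status=str(rng.choice(["alive", "dead"])),
                    wood=str(rng.choice(["soft", "hard"])),
                    dens=float(rng.uniform(0.4, 0.9)),
                )
                for _ in range(n)
            ]
            df = _frame(trees)
            out = compute_plot_variables(df, 0)
            live = df[df.status == "alive"]
            per_ha = 10_000 / PLOT_AREA_M2
            assert out["dead_tree_density"] == pytest.approx((df.status == "dead").sum() * per_ha)
            if len(live):
                ba = np.pi * (live.dbh_mm / 2000.0) ** 2
                assert out["basal_area"] == pytest.approx(float(ba.sum() * per_ha))
                assert out["tree_dbh_mean"] == pytest.approx(live.dbh_mm.mean())
                assert out["dbh_range"] == pytest.approx(live.dbh_mm.max() - live.dbh_mm.min())
                assert out["wood_density_mean"] == pytest.approx(
                    float(np.average(live.wood_density_g_cm3, weights=ba))
                )
                assert out["softwood_large_density"] <= out["large_tree_density"] <= out["tree_density"]
                assert out["tree_richness"] == live.species_code.nunique()

    def test_doubling_trees_doubles_densities(self, rng):
        trees = [_tree(float(rng.uniform(76, 700))) for _ in range(6)]
        a = compute_plot_variables(_frame(trees), 0)
        b = compute_plot_variables(_frame(trees + trees), 0)
        for key in ("tree_density", "large_tree_density", "basal_area", "dead_tree_density"):
            assert b[key] == pytest.approx(2 * a[key])


class TestClimateExtraction:
    def _plots(self):
        return pd.DataFrame({"plot_id": [0, 1], "x_m": [500.0, 1500.0], "y_m": [500.0, 1500.0]})

    def test_constant_raster(self):
        r = Raster(np.full((4, 4), 42.0), xll=0, yll=0, cellsize=1000.0)
        out = extract_climate_to_plots(self._plots(), {"v": r})
        assert (out["v"] == 42.0).all()

    def test_exact_cell_centre_hit(self):
        vals = np.arange(4.0).reshape(2, 2)  # row 0 is the top row
        r = Raster(vals, xll=0, yll=0, cellsize=1000.0)
        plots = pd.DataFrame({"plot_id": [0], "x_m": [500.0], "y_m": [500.0]})
        out = extract_climate_to_plots(plots, {"v": r})
        assert out["v"].iloc[0] == vals[1, 0]  # bottom-left cell

    def test_nearest_neighbour_oracle(self):
        vals = np.array([[2.0, 3.0], [0.0, 1.0]])
        r = Raster(vals, xll=0, yll=0, cellsize=1.0)
        plots = pd.DataFrame({"plot_id": [0], "x_m": [0.4], "y_m": [0.3]})
        out = extract_climate_to_plots(plots, {"v": r})
        assert out["v"].iloc[0] == 0.0  # nearer cell (bottom-left)

    def test_out_of_extent_is_nan_but_total_mismatch_raises(self):
        r = Raster(np.zeros((2, 2)), xll=0, yll=0, cellsize=1000.0)
        plots = pd.DataFrame({"plot_id": [0, 1], "x_m": [500.0, 9e6], "y_m": [500.0, 9e6]})
        out = extract_climate_to_plots(plots, {"v": r})
        assert np.isnan(out["v"].iloc[1]) and out["v"].iloc[0] == 0.0
        bad = pd.DataFrame({"plot_id": [0], "x_m": [9e6], "y_m": [9e6]})
        with pytest.raises(InterfaceError):
            extract_climate_to_plots(bad, {"v": r})


class TestScreening:
    def test_perfectly_correlated_pair_keeps_higher_ranked(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=200)})
        assert screen_correlated(df, ["a", "b", "c"]) == ["a", "c"]

    def test_independent_variables_all_retained(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        assert screen_correlated(df, list("abcd")) == list("abcd")

    def test_greedy_trace_three_variables(self, rng):
        # A-B and B-C strongly correlated, A-C weakly; ranking A>B>C:
        # B is dropped against A, C is compared only against retained A -> {A, C}
        cov = np.array([[1.0, 0.8, 0.3], [0.8, 1.0, 0.8], [0.3, 0.8, 1.0]])
        xyz = rng.multivariate_normal(np.zeros(3), cov, size=6000)
        df = pd.DataFrame(xyz, columns=["A", "B", "C"])
        r = df.corr()
        assert abs(r.loc["A", "B"]) >= 0.70 and abs(r.loc["B", "C"]) >= 0.70
        assert abs(r.loc["A", "C"]) < 0.70
        assert screen_correlated(df, ["A", "B", "C"]) == ["A", "C"]

    def test_constant_variable_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            out = screen_correlated(df, ["a", "b"])
        assert out == ["b"]

    def test_screened_set_has_low_pairwise_correlation(self, rng):
        base = rng.normal(size=(400, 3))
        df = pd.DataFrame(
            {
                "v0": base[:, 0],
                "v1": base[:, 0] * 0.95 + 0.1 * rng.normal(size=400),
                "v2": base[:, 1],
                "v3": base[:, 1] - base[:, 2],
                "v4": base[:, 2],
            }
        )
        kept = screen_correlated(df, list(df.columns))
        corr = df[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.70

    def test_categorical_passes_through(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50)})
        out = screen_correlated(df.assign(cat=["x"] * 50), ["a"], categorical=("cat",))
        assert out == ["a", "cat"]


class TestSingleVariableRanking:
    def test_generative_variable_ranks_first_and_copies_tie(self, rng):
        n_b = 300
        bg = pd.DataFrame(
            {
                "signal": rng.normal(size=n_b),
                "noise": rng.normal(size=n_b),
            }
        )
        bg["copy"] = bg["signal"]
        pres = bg.sample(n=80, weights=np.exp(1.8 * bg["signal"]), random_state=1).reset_index(drop=True)
        ranked = rank_by_single_variable_gain(pres, bg, ["signal", "noise", "copy"])
        names = [v for v, _ in ranked]
        gains = dict(ranked)
        assert names[0] in ("signal", "copy")
        assert gains["signal"] == pytest.approx(gains["copy"], abs=1e-6)
        assert gains["noise"] == min(g for g in gains.values())

    def test_uninformative_variable_has_near_zero_gain(self, rng):
        bg = pd.DataFrame({"flat": rng.normal(size=200)})
        pres = bg.sample(n=60, random_state=0).reset_index(drop=True)
        ranked = rank_by_single_variable_gain(pres, bg, ["flat"])
        assert ranked[0][1] < 0.05


def test_default_catalog_structure():
    roost = DEFAULT_CATALOG.variables_in_group("roost_availability")
    assert sorted(roost) == sorted(
        [
            "tree_dbh_mean",
            "tree_height_mean",
            "dead_tree_density",
            "large_tree_density",
            "softwood_large_density",
            "development_stage",
            "wood_density_mean",
        ]
    )
    for var, meta in DEFAULT_CATALOG.entries.items():
        assert meta["group"] in DEFAULT_CATALOG.GROUPS


def test_catalog_yaml_roundtrip(tmp_path):
    path = tmp_path / "catalog.yaml"
    DEFAULT_CATALOG.to_yaml(path)
    from forestsdm.forest_variables import VariableCatalog

    loaded = VariableCatalog.from_yaml(path)
    assert loaded.entries == DEFAULT_CATALOG.entries
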