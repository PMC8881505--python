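"""Per-plot structural and compositional forest variables.

Turns raw tree records (one row per stem above the 75-mm DBH inclusion
limit) into plot-level variables: stem densities on a per-hectare basis,
size structure, basal area, basal-area-weighted wood density, species
richness and the dominant species by basal area. Climate raster values are
attached by nearest-cell extraction, and variable screening (pairwise
correlation and single-variable model gain) prepares the modelling set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, InterfaceError
from .rasters import Raster

__all__ = [
    "PLOT_AREA_M2",
    "QUANTITATIVE_VARIABLES",
    "CATEGORICAL_VARIABLES",
    "VariableCatalog",
    "DEFAULT_CATALOG",
    "compute_plot_variables",
    "plot_variables_table",
    "extract_climate_to_plots",
    "screen_correlated",
    "rank_by_single_variable_gain",
]

#: Area of a 25-m-diameter circular inventory plot.
PLOT_AREA_M2 = math.pi * 12.5**2  # 490.874 m^2

LARGE_DBH_MM = 425.0

QUANTITATIVE_VARIABLES = [
    "tree_dbh_mean",
    "tree_height_mean",
    "dbh_range",
    "height_range",
    "tree_density",
    "large_tree_density",
    "softwood_large_density",
    "dead_tree_density",
    "tree_richness",
    "basal_area",
    "wood_density_mean",
    "tree_cover",
    "understory_cover",
    "plantation_pct",
]

CATEGORICAL_VARIABLES = ["dominant_species", "development_stage"]

CLIMATE_VARIABLES = ["elevation", "annual_precip", "tmax_warmest", "temp_seasonality"]


@dataclass
class VariableCatalog:
    """Maps each modelled variable to its type and mechanistic group.

    Groups follow the four mechanistic classes of forest variables (roost
    availability, structural heterogeneity, clutter, composition) plus the
    climate set and the landscape forest-proportion layer.
    """

    entries: dict[str, dict[str, str]] = field(default_factory=dict)

    GROUPS = (
        "roost_availability",
        "heterogeneity",
        "clutter",
        "composition",
        "climate",
        "forest_proportion",
    )

    def __post_init__(self):
        for name, meta in self.entries.items():
            if meta.get("group") not in self.GROUPS:
                raise DataError(f"variable {name!r} has unknown group {meta.get('group')!r}")
            if meta.get("type") not in ("quantitative", "categorical"):
                raise DataError(f"variable {name!r} has unknown type {meta.get('type')!r}")

    def group_of(self, variable: str) -> str:
        try:
            return self.entries[variable]["group"]
        except KeyError:
            raise DataError(f"variable {variable!r} is not in the catalog") from None

    @property
    def quantitative(self) -> list[str]:
        return [v for v, m in self.entries.items() if m["type"] == "quantitative"]

    @property
    def categorical(self) -> list[str]:
        return [v for v, m in self.entries.items() if m["type"] == "categorical"]

    def variables_in_group(self, group: str) -> list[str]:
        return [v for v, m in self.entries.items() if m["group"] == group]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.entries, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "VariableCatalog":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _default_catalog() -> VariableCatalog:
    q = "quantitative"
    c = "categorical"
    entries = {
        # roost availability: size/age of trees and dead wood
        "tree_dbh_mean": {"type": q, "group": "roost_availability"},
        "tree_height_mean": {"type": q, "group": "roost_availability"},
        "dead_tree_density": {"type": q, "group": "roost_availability"},
        "large_tree_density": {"type": q, "group": "roost_availability"},
        "softwood_large_density": {"type": q, "group": "roost_availability"},
        "development_stage": {"type": c, "group": "roost_availability"},
        "wood_density_mean": {"type": q, "group": "roost_availability"},
        # structural heterogeneity
        "dbh_range": {"type": q, "group": "heterogeneity"},
        "height_range": {"type": q, "group": "heterogeneity"},
        "basal_area": {"type": q, "group": "heterogeneity"},
        # clutter
        "tree_density": {"type": q, "group": "clutter"},
        "tree_cover": {"type": q, "group": "clutter"},
        "understory_cover": {"type": q, "group": "clutter"},
        # composition
        "dominant_species": {"type": c, "group": "composition"},
        "tree_richness": {"type": q, "group": "composition"},
        "plantation_pct": {"type": q, "group": "composition"},
        # climate
        "elevation": {"type": q, "group": "climate"},
        "annual_precip": {"type": q, "group": "climate"},
        "tmax_warmest": {"type": q, "group": "climate"},
        "temp_seasonality": {"type": q, "group": "climate"},
        # landscape forest proportion
        "forest_proportion": {"type": q, "group": "forest_proportion"},
    }
    return VariableCatalog(entries)


DEFAULT_CATALOG = _default_catalog()


def compute_plot_variables(
    trees: pd.DataFrame,
    plot_id,
    plot_diameter_m: float = 25.0,
) -> dict:
    """Derive the structural/compositional variable vector for one plot.

    Densities are live-stem counts scaled to per-hectare using the circular
    plot area; dead stems are counted separately. Basal area is computed from
    live stems; wood density is the basal-area-weighted mean; the dominant
    species is the one with the largest summed basal area (ties broken by the
    lexicographically smallest species code). An empty plot yields zero
    densities, richness 0 and dominant species ``"none"``.
    """
    area_m2 = math.pi * (plot_diameter_m / 2.0) ** 2
    per_ha = 10_000.0 / area_m2
    out = {
        "plot_id": plot_id,
        "tree_dbh_mean": 0.0,
        "tree_height_mean": 0.0,
        "dbh_range": 0.0,
        "height_range": 0.0,
        "tree_density": 0.0,
        "large_tree_density": 0.0,
        "softwood_large_density": 0.0,
        "dead_tree_density": 0.0,
        "tree_richness": 0,
        "basal_area": 0.0,
        "wood_density_mean": 0.0,
        "dominant_species": "none",
    }
    if len(trees) == 0:
        return out

    dbh = trees["dbh_mm"].to_numpy(dtype=float)
    height = trees["height_m"].to_numpy(dtype=float)
    if np.any(dbh < 0) or np.any(height < 0):
        raise DataError(f"plot {plot_id}: negative DBH or height in tree records")

    alive = trees["status"].to_numpy() == "alive"
    out["dead_tree_density"] = float((~alive).sum() * per_ha)
    live = trees[alive]
    if len(live) == 0:
        return out

    dbh = live["dbh_mm"].to_numpy(dtype=float)
    height = live["height_m"].to_numpy(dtype=float)
    ba_m2 = math.pi * (dbh / 2000.0) ** 2  # stem basal area, DBH mm -> radius m

    out["tree_dbh_mean"] = float(dbh.mean())
    out["tree_height_mean"] = float(height.mean())
    out["dbh_range"] = float(dbh.max() - dbh.min())
    out["height_range"] = float(height.max() - height.min())
    out["tree_density"] = float(len(live) * per_ha)
    large = dbh > LARGE_DBH_MM
    out["large_tree_density"] = float(large.sum() * per_ha)
    soft = live["wood"].to_numpy() == "soft"
    out["softwood_large_density"] = float((large & soft).sum() * per_ha)
    out["tree_richness"] = int(live["species_code"].nunique())
    out["basal_area"] = float(ba_m2.sum() * per_ha)
    out["wood_density_mean"] = float(
        np.average(live["wood_density_g_cm3"].to_numpy(dtype=float), weights=ba_m2)
    )
    ba_by_species = live.assign(_ba=ba_m2).groupby("species_code")["_ba"].sum()
    best = ba_by_species.max()
    out["dominant_species"] = sorted(ba_by_species.index[ba_by_species == best])[0]
    return out


def plot_variables_table(landscape) -> pd.DataFrame:
    """All-plot variable table: tree-derived variables + carried plot fields
    + climate values extracted at plot locations."""
    trees_by_plot = dict(tuple(landscape.trees.groupby("plot_id"))) if len(landscape.trees) else {}
    empty = landscape.trees.iloc[0:0]
    rows = [
        compute_plot_variables(
            trees_by_plot.get(pid, empty), pid, landscape.config.plot_diameter_m
        )
        for pid in landscape.plots["plot_id"]
    ]
    derived = pd.DataFrame(rows)
    carried = landscape.plots[
        ["plot_id", "x_m", "y_m", "tree_cover", "understory_cover", "plantation_pct", "development_stage"]
    ]
    table = carried.merge(derived, on="plot_id", how="left")
    return extract_climate_to_plots(table, landscape.climate)


def extract_climate_to_plots(plots: pd.DataFrame, rasters: dict[str, Raster]) -> pd.DataFrame:
    """Attach nearest-cell raster values at plot coordinates.

    Plots outside a raster's extent get NaN (flagged for downstream
    exclusion). A raster whose extent does not overlap the plots at all is a
    coordinate-scale mismatch and raises :class:`InterfaceError`.
    """
    out = plots.copy()
    x = plots["x_m"].to_numpy(dtype=float)
    y = plots["y_m"].to_numpy(dtype=float)
    for name, raster in rasters.items():
        vals = raster.extract(x, y)
        if len(vals) and np.all(np.isnan(vals)):
            raise InterfaceError(
                f"raster {name!r} does not overlap any plot: check coordinate units/extent"
            )
        out[name] = vals
    return out


def screen_correlated(
    table: pd.DataFrame,
    ranking: list[str],
    threshold: float = 0.70,
    categorical: tuple[str, ...] = (),
) -> list[str]:
    """Greedy correlation screening of quantitative variables.

    Walk the candidates in ranking order; retain a variable unless its
    absolute pairwise-complete Pearson correlation with an already retained
    variable reaches ``threshold``. Constant (zero-variance) variables are
    dropped with a warning; categorical variables pass through untouched.
    """
    retained: list[str] = []
    for var in ranking:
        col = table[var].astype(float)
        if col.dropna().nunique() <= 1:
            warnings.warn(f"variable {var!r} is constant; dropped from screening")
            continue
        ok = True
        for kept in retained:
            r = col.corr(table[kept].astype(float))  # pairwise-complete Pearson
            if np.isfinite(r) and abs(r) >= threshold:
                ok = False
                break
        if ok:
            retained.append(var)
    return retained + [c for c in categorical if c in table.columns]


def rank_by_single_variable_gain(
    presences: pd.DataFrame,
    backgrounds: pd.DataFrame,
    variables: list[str],
    categorical: tuple[str, ...] = (),
    classes: str = "LQ",
    rm: float = 1.0,
) -> list[tuple[str, float]]:
    """Rank variables by the training gain of their single-variable model.

    Fits one presence-background maximum-entropy model per variable and sorts
    by decreasing training gain; variables whose fit fails rank last with a
    NaN gain.
    """
    from . import maxent  # local import: maxent is a heavier module

    results: list[tuple[str, float]] = []
    failed: list[tuple[str, float]] = []
    for var in variables:
        quant = [] if var in categorical else [var]
        cat = [var] if var in categorical else []
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Xp, Xb, fs = maxent.expand_features(
                    presences, backgrounds, quant, cat, classes=classes
                )
                model = maxent.fit(Xp, Xb, feature_set=fs, rm=rm)
            results.append((var, model.gain))
        except Exception:
            failed.append((var, float("nan")))
    results.sort(key=lambda t: -t[1])
    return results + failed
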