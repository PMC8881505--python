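"""Spatial operations: un-clustering, home-range-scaled interpolation,
background generation and the coarse forest-proportion layer.

All coordinates are planar metres in a projected frame; distances are
Euclidean. The interpolation step summarises the forest-inventory plots
around a point at the scale of the species' home range: the nearest
``k_min``..``k_max`` plots within ``d_max_km`` are averaged (mean for
quantitative variables, mode for categorical ones); points with fewer than
``k_min`` plots in range are dropped rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DataError, PipelineError
from .rasters import Raster

__all__ = [
    "SpeciesSpatialParams",
    "MOBILITY_DEFAULTS",
    "thin_points",
    "interpolate_to_point",
    "interpolate_points",
    "generate_background",
    "forest_proportion_layer",
]

log = logging.getLogger(__name__)

#: Home-range-class defaults: (k_min, k_max, d_max_km, thin_presence_m,
#: thin_background_km, exclusion_km).
MOBILITY_DEFAULTS: dict[str, tuple] = {
    "less-mobile": (2, 5, 3.0, 500.0, 4.0, 4.0),
    "intermediate": (4, 8, 5.0, 1000.0, 4.0, 4.0),
    "mobile": (8, 16, 7.0, 2000.0, 5.0, 5.0),
}


@dataclass(frozen=True)
class SpeciesSpatialParams:
    """Interpolation and thinning parameters scaled to a species' home range."""

    species: str
    k_min: int
    k_max: int
    d_max_km: float
    thin_presence_m: float
    thin_background_km: float = 4.0
    exclusion_km: float = 4.0

    def __post_init__(self):
        if not (1 <= self.k_min <= self.k_max):
            raise ConfigurationError("need 1 <= k_min <= k_max")
        if self.d_max_km <= 0:
            raise ConfigurationError("d_max_km must be positive")

    @classmethod
    def for_mobility(cls, species: str, mobility: str) -> "SpeciesSpatialParams":
        try:
            k_min, k_max, d_max, thin_p, thin_b, excl = MOBILITY_DEFAULTS[mobility]
        except KeyError:
            raise ConfigurationError(f"unknown mobility class {mobility!r}") from None
        return cls(species, k_min, k_max, d_max, thin_p, thin_b, excl)


def thin_points(points: np.ndarray, min_dist: float, seed: int = 0) -> np.ndarray:
    """Un-cluster points so every pairwise distance is >= ``min_dist``.

    Greedy max-neighbour elimination: repeatedly delete the point with the
    most remaining neighbours closer than ``min_dist`` (ties broken at random
    under ``seed``) until no violating pair remains. Returns the retained
    rows in their original order; the output is always a subset of the input.
    """
    if min_dist <= 0:
        raise ConfigurationError("min_dist must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n <= 1:
        return points.copy()
    tree = cKDTree(points)
    pairs = tree.query_pairs(min_dist, output_type="ndarray")
    if len(pairs):  # keep pairs at exactly min_dist (they already satisfy >=)
        d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        pairs = pairs[d < min_dist]
    neighbours: list[set[int]] = [set() for _ in range(n)]
    for i, j in pairs:
        neighbours[i].add(j)
        neighbours[j].add(i)
    alive = np.ones(n, dtype=bool)
    counts = np.array([len(s) for s in neighbours])
    rng = np.random.default_rng(seed)
    while True:
        live_counts = np.where(alive, counts, -1)
        worst = live_counts.max()
        if worst <= 0:
            break
        candidates = np.flatnonzero(live_counts == worst)
        victim = int(rng.choice(candidates))
        alive[victim] = False
        counts[victim] = 0
        for j in neighbours[victim]:
            if alive[j]:
                counts[j] -= 1
            neighbours[j].discard(victim)
        neighbours[victim] = set()
    return points[alive]


def _mode_with_nearest_tiebreak(values: np.ndarray, order_by_distance: np.ndarray):
    """Most frequent value; ties go to the value of the nearest plot holding it."""
    vals, counts = np.unique(values, return_counts=True)
    top = counts.max()
    tied = set(vals[counts == top])
    if len(tied) == 1:
        return tied.pop()
    for idx in order_by_distance:
        if values[idx] in tied:
            return values[idx]
    return sorted(tied)[0]  # unreachable; deterministic fallback


def interpolate_to_point(
    point_xy,
    plot_vars: pd.DataFrame,
    params: SpeciesSpatialParams,
    quantitative: list[str],
    categorical: list[str],
    _tree: cKDTree | None = None,
) -> dict | None:
    """Summarise plot variables around one point, or ``None`` if dropped.

    Selects the nearest up to ``k_max`` plots within ``d_max_km``; if fewer
    than ``k_min`` qualify the point is dropped. Quantitative variables are
    averaged; categorical ones take the mode with ties broken by the nearest
    plot's value.
    """
    xy = np.asarray(point_xy, dtype=float)
    tree = _tree if _tree is not None else cKDTree(plot_vars[["x_m", "y_m"]].to_numpy())
    k = min(params.k_max, len(plot_vars))
    if k == 0:
        return None
    dist, idx = tree.query(xy, k=k)
    dist = np.atleast_1d(dist)
    idx = np.atleast_1d(idx)
    within = dist <= params.d_max_km * 1000.0
    dist, idx = dist[within], idx[within]
    if len(idx) < params.k_min:
        return None
    sel = plot_vars.iloc[idx]
    out: dict = {
        "x_m": float(xy[0]),
        "y_m": float(xy[1]),
        "n_plots_used": int(len(idx)),
        "mean_plot_distance_m": float(dist.mean()),
    }
    for var in quantitative:
        out[var] = float(sel[var].to_numpy(dtype=float).mean())
    order = np.argsort(dist, kind="stable")
    for var in categorical:
        out[var] = _mode_with_nearest_tiebreak(sel[var].to_numpy(), order)
    return out


def interpolate_points(
    points: np.ndarray,
    plot_vars: pd.DataFrame,
    params: SpeciesSpatialParams,
    quantitative: list[str],
    categorical: list[str],
    label: str = "presence",
) -> pd.DataFrame:
    """Interpolate a set of points; dropped points are logged, not imputed.

    Vectorised equivalent of mapping :func:`interpolate_to_point` over the
    rows (the per-point function remains the reference implementation).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cols = ["label", "x_m", "y_m", "n_plots_used", "mean_plot_distance_m"] + quantitative + categorical
    if len(plot_vars) == 0 or len(points) == 0:
        return pd.DataFrame(columns=cols)
    tree = cKDTree(plot_vars[["x_m", "y_m"]].to_numpy())
    k = min(params.k_max, len(plot_vars))
    dist, idx = tree.query(points, k=k)
    dist = np.atleast_2d(dist.reshape(len(points), -1))
    idx = np.atleast_2d(idx.reshape(len(points), -1))
    within = dist <= params.d_max_km * 1000.0
    counts = within.sum(axis=1)
    keep = counts >= params.k_min
    n_dropped = int((~keep).sum())

    rows = []
    Q = plot_vars[quantitative].to_numpy(dtype=float) if quantitative else None
    cat_arrays = {v: plot_vars[v].to_numpy() for v in categorical}
    for i in np.flatnonzero(keep):
        sel = idx[i][within[i]]
        d = dist[i][within[i]]
        rec = {
            "label": label,
            "x_m": float(points[i, 0]),
            "y_m": float(points[i, 1]),
            "n_plots_used": int(len(sel)),
            "mean_plot_distance_m": float(d.mean()),
        }
        if Q is not None:
            rec.update(zip(quantitative, Q[sel].mean(axis=0)))
        if categorical:
            order = np.argsort(d, kind="stable")
            for var, arr in cat_arrays.items():
                rec[var] = _mode_with_nearest_tiebreak(arr[sel], order)
        rows.append(rec)
    if n_dropped:
        log.info(
            "%s: dropped %d/%d %s points with < %d plots within %.1f km",
            params.species, n_dropped, len(points), label, params.k_min, params.d_max_km,
        )
    return pd.DataFrame(rows, columns=cols)


def generate_background(
    region_bounds: tuple[float, float, float, float],
    presences: np.ndarray,
    plot_vars: pd.DataFrame,
    params: SpeciesSpatialParams,
    quantitative: list[str],
    categorical: list[str],
    n_init: int = 10_000,
    seed: int = 0,
    max_n: int | None = None,
) -> pd.DataFrame:
    """Background (pseudoabsence) samples for one species.

    Draws ``n_init`` uniform points in the region, thins them at
    ``thin_background_km``, removes from the *interpolation pool* every plot
    closer than ``exclusion_km`` to any presence, then interpolates the
    surviving points with the species' parameters. ``max_n`` optionally
    subsamples the interpolated background to a fixed size (seeded).
    """
    xmin, xmax, ymin, ymax = region_bounds
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n_init), rng.uniform(ymin, ymax, n_init)]
    )
    pts = thin_points(pts, params.thin_background_km * 1000.0, seed=seed)

    presences = np.asarray(presences, dtype=float).reshape(-1, 2)
    pool = plot_vars
    if len(presences):
        ptree = cKDTree(presences)
        d, _ = ptree.query(plot_vars[["x_m", "y_m"]].to_numpy(), k=1)
        pool = plot_vars[d > params.exclusion_km * 1000.0]

    bg = interpolate_points(pts, pool, params, quantitative, categorical, label="background")
    if len(bg) == 0:
        raise PipelineError(
            f"{params.species}: no background points survived thinning/exclusion/interpolation"
        )
    if max_n is not None and len(bg) > max_n:
        keep = np.sort(rng.choice(len(bg), size=max_n, replace=False))
        bg = bg.iloc[keep].reset_index(drop=True)
    return bg


def forest_proportion_layer(landcover: Raster, factor: int = 25) -> Raster:
    """Aggregate a fine binary forest mask to a coarse proportion raster.

    Each coarse cell is the mean of its ``factor`` × ``factor`` block of fine
    cells (partial edge blocks use the cells available). 100-m input with the
    default factor gives the 2.5-km proportion-of-forest layer.
    """
    vals = landcover.values
    finite = vals[np.isfinite(vals)]
    if not np.all(np.isin(finite, (0.0, 1.0))):
        raise DataError("landcover raster must be binary (0/1)")
    nr, nc = vals.shape
    nr_c = -(-nr // factor)
    nc_c = -(-nc // factor)
    padded = np.full((nr_c * factor, nc_c * factor), np.nan)
    padded[:nr, :nc] = vals
    blocks = padded.reshape(nr_c, factor, nc_c, factor).transpose(0, 2, 1, 3)
    with np.errstate(invalid="ignore"):
        coarse = np.nanmean(blocks.reshape(nr_c, nc_c, -1), axis=2)
    # coarse grid is aligned to the *top-left* corner of the fine grid
    top = landcover.yll + nr * landcover.cellsize
    cell = factor * landcover.cellsize
    return Raster(values=coarse, xll=landcover.xll, yll=top - nr_c * cell, cellsize=cell)
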