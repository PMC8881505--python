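"""Null-model calibration of model discrimination.

A species' cross-validated test AUC is compared against the AUCs obtained
when the same number of presences is drawn at random in the region and pushed
through the identical downstream procedure (background generation,
interpolation, modelling). A model is regarded as performing better than
random when its observed test AUC exceeds the 95th percentile of the null
AUC distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .rasters import Raster

__all__ = ["NullModelReport", "draw_random_presences", "run_null_models"]

log = logging.getLogger(__name__)


@dataclass
class NullModelReport:
    """Result of one null-model calibration run."""

    observed_auc: float
    null_aucs: list[float]
    n_reps_requested: int
    ci_lower: float  # 5th percentile of null AUCs
    ci_upper: float  # 95th percentile
    better_than_random: bool
    n_failed: int = 0
    rep_seeds: list[int] = field(default_factory=list)

    @property
    def n_completed(self) -> int:
        return len(self.null_aucs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rep": range(self.n_completed), "auc_test": self.null_aucs})

    def summary(self) -> dict:
        return {
            "observed_auc": self.observed_auc,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "better_than_random": self.better_than_random,
            "n_completed": self.n_completed,
            "n_failed": self.n_failed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def draw_random_presences(
    n: int,
    region_bounds: tuple[float, float, float, float],
    rng: np.random.Generator,
    forest_mask: Raster | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform random points in the region, optionally restricted to forest."""
    xmin, xmax, ymin, ymax = region_bounds
    if forest_mask is None:
        return np.column_stack([rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)])
    out = np.empty((0, 2))
    for _ in range(max_tries):
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, 4 * n), rng.uniform(ymin, ymax, 4 * n)]
        )
        keep = forest_mask.extract(cand[:, 0], cand[:, 1]) > 0.5
        out = np.vstack([out, cand[keep]])
        if len(out) >= n:
            return out[:n]
    raise RuntimeError("could not place random presences inside forest")


def run_null_models(
    pipeline_fn: Callable[[np.ndarray, int], float],
    n_presences: int,
    region_bounds: tuple[float, float, float, float],
    observed_auc: float,
    n_reps: int = 100,
    seed: int = 0,
    forest_mask: Raster | None = None,
) -> NullModelReport:
    """Calibrate an observed test AUC against random-presence null models.

    ``pipeline_fn(presence_xy, seed)`` must run the full downstream procedure
    on a presence set and return its test AUC. Each replicate draws
    ``n_presences`` uniform random points (replicate ``i`` is seeded
    ``seed + i`` for reproducibility) and failures are logged and skipped.
    Percentiles are empirical (linear/type-7 interpolation).
    """
    null_aucs: list[float] = []
    seeds: list[int] = []
    n_failed = 0
    for rep in range(n_reps):
        rep_seed = seed + rep
        rng = np.random.default_rng(rep_seed)
        xy = draw_random_presences(n_presences, region_bounds, rng, forest_mask)
        try:
            null_aucs.append(float(pipeline_fn(xy, rep_seed)))
            seeds.append(rep_seed)
        except Exception as exc:  # replicate failure: log and continue
            n_failed += 1
            log.warning("null replicate %d failed: %s", rep, exc)
    if not null_aucs:
        raise RuntimeError("every null replicate failed")
    lo, hi = np.percentile(null_aucs, [5.0, 95.0])
    return NullModelReport(
        observed_auc=float(observed_auc),
        null_aucs=null_aucs,
        n_reps_requested=n_reps,
        ci_lower=float(lo),
        ci_upper=float(hi),
        better_than_random=bool(observed_auc > hi),
        n_failed=n_failed,
        rep_seeds=seeds,
    )
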