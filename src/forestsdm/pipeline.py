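"""End-to-end orchestration: landscape → variables → thinning →
interpolation → background → model tuning/fit → evaluation → null models →
gain profiles → trait tests.

The master seed fans out to per-stage, per-species seeds through a stable
hash, so adding or removing one species never perturbs another's results;
re-running a config reproduces every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import maxent
from .errors import ConfigurationError, PipelineError
from .evaluation import NullModelReport, run_null_models
from .forest_variables import (
    DEFAULT_CATALOG,
    VariableCatalog,
    plot_variables_table,
    screen_correlated,
    rank_by_single_variable_gain,
)
from .geospatial import (
    SpeciesSpatialParams,
    forest_proportion_layer,
    generate_background,
    interpolate_points,
    thin_points,
)
from .synthetic import (
    Landscape,
    LandscapeConfig,
    VirtualSpecies,
    generate_landscape,
    sample_occurrences,
    study_species,
)

__all__ = [
    "ModelSettings",
    "BackgroundSettings",
    "NullSettings",
    "PipelineConfig",
    "SpeciesResult",
    "PipelineResult",
    "stage_seed",
    "model_point_set",
    "run_pipeline",
    "default_config",
]

log = logging.getLogger(__name__)

STAGES = ("simulate", "variables", "interpolate", "fit", "nulls", "traits")


def stage_seed(master_seed: int, stage: str, species: str = "") -> int:
    """Stable sub-seed (< 2^31) for a stage/species pair."""
    digest = hashlib.sha256(f"{master_seed}|{stage}|{species}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ModelSettings:
    """Maxent tuning/fitting settings for the pipeline."""

    tune: bool = True
    feature_grid: tuple[str, ...] = ("L", "LQ", "H", "LQH")
    rms: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    classes: str = "LQ"  # used when tune=False
    rm: float = 1.0
    n_hinge_knots: int = 50
    n_folds: int = 6
    tol: float = 1e-7


@dataclass(frozen=True)
class BackgroundSettings:
    n_init: int = 10_000
    max_n: int | None = None


@dataclass(frozen=True)
class NullSettings:
    run: bool = True
    n_reps: int = 100
    forest_restricted: bool = False  # draw null presences in forest only


@dataclass
class PipelineConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    species: list[VirtualSpecies] = field(default_factory=study_species)
    spatial: dict[str, SpeciesSpatialParams] = field(default_factory=dict)
    catalog: VariableCatalog = field(default_factory=lambda: DEFAULT_CATALOG)
    model: ModelSettings = field(default_factory=ModelSettings)
    background: BackgroundSettings = field(default_factory=BackgroundSettings)
    nulls: NullSettings = field(default_factory=NullSettings)
    screen_threshold: float | None = None  # e.g. 0.70 to screen per species
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        self.landscape.validate()
        for sp in self.species:
            params = self.spatial.get(sp.name)
            if params is None and sp.mobility not in ("less-mobile", "intermediate", "mobile"):
                raise ConfigurationError(f"species {sp.name}: no spatial params and unknown mobility")

    def spatial_params(self, sp: VirtualSpecies) -> SpeciesSpatialParams:
        if sp.name in self.spatial:
            return self.spatial[sp.name]
        return SpeciesSpatialParams.for_mobility(sp.name, sp.mobility)


@dataclass
class SpeciesResult:
    name: str
    params: SpeciesSpatialParams
    n_records: int  # un-clustered presences actually modelled
    presence_env: pd.DataFrame
    background_env: pd.DataFrame
    model: maxent.MaxentModel
    classes: str
    rm: float
    aicc: float
    auc_train: float
    auc_test_folds: list[float]
    gain: float
    contributions: dict[str, float]
    grid_report: pd.DataFrame | None = None
    null_report: NullModelReport | None = None

    @property
    def auc_test_mean(self) -> float:
        return float(np.mean(self.auc_test_folds))


@dataclass
class PipelineResult:
    config: PipelineConfig
    landscape: Landscape
    plot_vars: pd.DataFrame
    forest_proportion: object  # Raster
    species_results: list[SpeciesResult] = field(default_factory=list)
    gain_profiles: pd.DataFrame | None = None
    trait_tests: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _attach_forest_proportion(env: pd.DataFrame, raster) -> pd.DataFrame:
    env = env.copy()
    vals = raster.extract(env["x_m"].to_numpy(), env["y_m"].to_numpy())
    env["forest_proportion"] = np.nan_to_num(vals, nan=0.0)
    return env


def model_point_set(
    presence_xy: np.ndarray,
    plot_vars: pd.DataFrame,
    region_bounds: tuple[float, float, float, float],
    params: SpeciesSpatialParams,
    settings: ModelSettings,
    quantitative: list[str],
    categorical: list[str],
    forest_prop_raster,
    background_settings: BackgroundSettings,
    seed: int,
) -> dict:
    """The downstream procedure shared by observed and null runs.

    Thin the presences, interpolate them, generate and interpolate the
    background, attach the forest-proportion layer, fit (or tune) the model
    and evaluate it by cross-validated AUC.
    """
    thinned = thin_points(np.asarray(presence_xy, float), params.thin_presence_m, seed=seed)
    pres = interpolate_points(thinned, plot_vars, params, quantitative, categorical, "presence")
    if len(pres) < 6:
        raise PipelineError(f"{params.species}: only {len(pres)} usable presences after interpolation")
    bg = generate_background(
        region_bounds,
        thinned,
        plot_vars,
        params,
        quantitative,
        categorical,
        n_init=background_settings.n_init,
        seed=seed + 1,
        max_n=background_settings.max_n,
    )
    pres = _attach_forest_proportion(pres, forest_prop_raster)
    bg = _attach_forest_proportion(bg, forest_prop_raster)
    quant_model = quantitative + ["forest_proportion"]

    if settings.tune:
        tr = maxent.tune(
            pres,
            bg,
            quant_model,
            categorical,
            feature_grid=settings.feature_grid,
            rms=settings.rms,
            n_hinge_knots=settings.n_hinge_knots,
            n_folds=settings.n_folds,
            seed=seed + 2,
            tol=settings.tol,
        )
        model, classes, rm = tr.model, tr.classes, tr.rm
        aicc_score, report = tr.aicc, tr.report
        auc_train, folds = tr.auc_train, tr.auc_test_folds
    else:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            Xp, Xb, fs = maxent.expand_features(
                pres, bg, quant_model, categorical, settings.classes, settings.n_hinge_knots
            )
            model = maxent.fit(
                Xp, Xb, feature_set=fs, rm=settings.rm, classes=settings.classes,
                tol=settings.tol, path_seed=seed + 3,
            )
        classes, rm = settings.classes, settings.rm
        aicc_score = maxent.aicc(model, Xp)
        report = None
        auc_train = maxent.auc(model.linear_predictor(Xp), model.linear_predictor(Xb))
        folds = maxent.cross_validated_auc(
            pres, bg, quant_model, categorical, classes, rm,
            n_folds=settings.n_folds, seed=seed + 2,
            n_hinge_knots=settings.n_hinge_knots, tol=settings.tol,
        )
    return {
        "presence_env": pres,
        "background_env": bg,
        "model": model,
        "classes": classes,
        "rm": rm,
        "aicc": aicc_score,
        "grid_report": report,
        "auc_train": auc_train,
        "auc_test_folds": folds,
        "gain": model.gain,
        "contributions": maxent.variable_contribution(model),
        "n_records": len(pres),
    }


def run_pipeline(config: PipelineConfig, stop_after: str = "traits") -> PipelineResult:
    """Run the full analysis; ``stop_after`` truncates at a named stage."""
    if stop_after not in STAGES:
        raise ConfigurationError(f"unknown stage {stop_after!r}")
    config.validate()
    stage_idx = STAGES.index(stop_after)

    landscape = generate_landscape(
        dataclasses.replace(config.landscape, seed=stage_seed(config.seed, "simulate"))
    )
    extent = landscape.extent_m
    region_bounds = (0.0, extent, 0.0, extent)
    result = PipelineResult(config, landscape, pd.DataFrame(), None)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        landscape.plots.to_csv(outdir / "plots.csv", index=False)
        landscape.trees.to_csv(outdir / "trees.csv", index=False)
    if stage_idx < 1:
        return result

    plot_vars = plot_variables_table(landscape)
    plot_vars = plot_vars.dropna().reset_index(drop=True)
    factor = max(1, int(round(2500.0 / landscape.config.landcover_cellsize_m)))
    forest_prop = forest_proportion_layer(landscape.forest_mask, factor=factor)
    result.plot_vars = plot_vars
    result.forest_proportion = forest_prop
    if outdir:
        plot_vars.to_csv(outdir / "plot_variables.csv", index=False)
    if stage_idx < 2:
        return result

    quantitative = [v for v in config.catalog.quantitative if v in plot_vars.columns]
    categorical = [v for v in config.catalog.categorical if v in plot_vars.columns]

    manifest: dict = {
        "seed": config.seed,
        "n_plots": int(len(plot_vars)),
        "species": {},
        "stages": STAGES[: stage_idx + 1],
    }
    species_payload: list[dict] = []
    species_vars: dict[str, list[str]] = {}
    for sp in config.species:
        params = config.spatial_params(sp)
        occ_seed = stage_seed(config.seed, "occurrences", sp.name)
        occ = sample_occurrences(sp, plot_vars, seed=occ_seed)
        pres_xy = occ[["x_m", "y_m"]].to_numpy()
        quant_sp, cat_sp = quantitative, categorical
        if config.screen_threshold is not None:
            # per-species screening: rank by single-variable gain, then greedy
            thin_seed = stage_seed(config.seed, "screen", sp.name)
            thinned = thin_points(pres_xy, params.thin_presence_m, seed=thin_seed)
            pres_env = interpolate_points(thinned, plot_vars, params, quantitative, categorical)
            bg_env = generate_background(
                region_bounds, thinned, plot_vars, params, quantitative, categorical,
                n_init=config.background.n_init, seed=thin_seed + 1, max_n=config.background.max_n,
            )
            ranked = rank_by_single_variable_gain(pres_env, bg_env, quantitative)
            ranking = [v for v, _ in ranked]
            quant_sp = screen_correlated(plot_vars, ranking, config.screen_threshold)
        species_vars[sp.name] = quant_sp
        model_seed = stage_seed(config.seed, "fit", sp.name)
        try:
            out = model_point_set(
                pres_xy, plot_vars, region_bounds, params, config.model,
                quant_sp, cat_sp, forest_prop, config.background, model_seed,
            )
        except PipelineError as exc:
            raise PipelineError(f"stage=fit species={sp.name}: {exc}") from exc
        sr = SpeciesResult(
            name=sp.name,
            params=params,
            n_records=out["n_records"],
            presence_env=out["presence_env"],
            background_env=out["background_env"],
            model=out["model"],
            classes=out["classes"],
            rm=out["rm"],
            aicc=out["aicc"],
            auc_train=out["auc_train"],
            auc_test_folds=out["auc_test_folds"],
            gain=out["gain"],
            contributions=out["contributions"],
            grid_report=out["grid_report"],
        )
        result.species_results.append(sr)
        manifest["species"][sp.name] = {
            "n_occurrences_raw": int(len(occ)),
            "n_presences_modelled": sr.n_records,
            "n_background": int(len(sr.background_env)),
            "classes": sr.classes,
            "rm": sr.rm,
            "gain": sr.gain,
            "auc_test_mean": sr.auc_test_mean,
        }
        species_payload.append(
            {
                "name": sp.name,
                "roosting": sp.roosting,
                "wing_loading": sp.wing_loading,
                "aspect_ratio": sp.aspect_ratio,
                "forager_class": sp.forager_class,
                "n_records": sr.n_records,
                "gain": sr.gain,
                "contributions": sr.contributions,
            }
        )
        if outdir:
            sp_dir = outdir / sp.name
            sp_dir.mkdir(exist_ok=True)
            env = pd.concat([sr.presence_env, sr.background_env], ignore_index=True)
            cols = ["label"] + [c for c in env.columns if c != "label"]
            env[cols].to_csv(sp_dir / "env_samples.csv", index=False)
            sr.model.to_json(sp_dir / "model.json")
            if sr.grid_report is not None:
                sr.grid_report.to_csv(sp_dir / "tuning_grid.csv", index=False)
    if stage_idx < 4:
        result.manifest = manifest
        _write_manifest(outdir, manifest)
        return result

    if config.nulls.run:
        for sp, sr in zip(config.species, result.species_results):
            null_seed = stage_seed(config.seed, "nulls", sp.name)

            def _null_auc(
                xy: np.ndarray,
                rep_seed: int,
                _params=sr.params,
                _quant=species_vars[sp.name],
            ) -> float:
                out = model_point_set(
                    xy, plot_vars, region_bounds, _params, config.model,
                    _quant, categorical, forest_prop, config.background, rep_seed,
                )
                return float(np.mean(out["auc_test_folds"]))

            sr.null_report = run_null_models(
                _null_auc,
                n_presences=sr.n_records,
                region_bounds=region_bounds,
                observed_auc=sr.auc_test_mean,
                n_reps=config.nulls.n_reps,
                seed=null_seed,
                forest_mask=landscape.forest_mask if config.nulls.forest_restricted else None,
            )
            manifest["species"][sp.name]["null"] = sr.null_report.summary()
            if outdir:
                sr.null_report.to_frame().to_csv(outdir / sp.name / "null_aucs.csv", index=False)
                sr.null_report.to_json(outdir / sp.name / "null_summary.json")
    if stage_idx < 5:
        result.manifest = manifest
        _write_manifest(outdir, manifest)
        return result

    from .traits import build_gain_profiles, trait_test_table

    profiles = build_gain_profiles(species_payload, config.catalog)
    result.gain_profiles = profiles
    if len(profiles["roosting"].unique()) == 2 and profiles["roosting"].value_counts().min() >= 2:
        result.trait_tests = trait_test_table(profiles, config.catalog)
    if outdir:
        profiles.to_csv(outdir / "gain_profiles.csv", index=False)
        if result.trait_tests is not None:
            result.trait_tests.to_csv(outdir / "trait_tests.csv", index=False)
    result.manifest = manifest
    _write_manifest(outdir, manifest)
    return result


def _write_manifest(outdir: Path | None, manifest: dict) -> None:
    if outdir:
        from . import __version__

        manifest = {"forestsdm_version": __version__, **manifest}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)


def scaled_spatial_params(
    species: VirtualSpecies,
    distance_scale: float = 1.0,
    background_scale: float | None = None,
    exclusion_km: float | None = None,
) -> SpeciesSpatialParams:
    """Home-range spatial params with all distances scaled down, for
    landscapes much smaller than a full region: interpolation radius,
    presence un-clustering and background thinning shrink together so home
    ranges keep a sensible proportion to the landscape (plot counts are
    unchanged; the plot grid is still 1 km, so the scaled radii must stay
    above it).

    The presence-background exclusion buffer scales differently: its purpose
    is only to keep the plots at presence locations out of the background
    pool, and in a small landscape a home-range-sized buffer around every
    record would swallow entire habitat strata and manufacture artificial
    presence/background separation. Default: half the plot spacing (0.5 km),
    which covers the record-coordinate jitter.
    """
    if background_scale is None:
        background_scale = distance_scale
    base = SpeciesSpatialParams.for_mobility(species.name, species.mobility)
    return dataclasses.replace(
        base,
        d_max_km=max(1.2, base.d_max_km * distance_scale),
        thin_presence_m=base.thin_presence_m * distance_scale,
        thin_background_km=base.thin_background_km * background_scale,
        exclusion_km=0.5 if exclusion_km is None else exclusion_km,
    )


def default_config(seed: int = 0, outdir: str | None = None) -> PipelineConfig:
    """The bundled synthetic demo configuration (laptop-scale).

    A 40-km landscape is ~1/60 the area of a full administrative region, so
    home-range distances (interpolation radius, presence un-clustering) are
    scaled to 60% and background thinning to 25%, keeping a ~500-point
    background; interpolation plot counts are unchanged because the plot grid
    spacing is unchanged.
    """
    species = study_species(n_scale=1.0)
    return PipelineConfig(
        landscape=LandscapeConfig(extent_km=40.0, forest_fraction=0.65, seed=seed),
        species=species,
        spatial={sp.name: scaled_spatial_params(sp, 0.6, background_scale=0.25) for sp in species},
        model=ModelSettings(tune=False, classes="LQ", rm=1.0, n_folds=6),
        background=BackgroundSettings(n_init=4000, max_n=500),
        nulls=NullSettings(run=False),
        outdir=outdir,
        seed=seed,
    )
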