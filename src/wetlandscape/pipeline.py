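"""Configuration-driven orchestration of the full analysis chain.

simulate → seasonal composites → feature stack → RF classification →
fragment labeling/counting → WFPI → carbon accounting, with every artifact
written to the output directory and hashed into a run manifest.  Stage
outputs are pure functions of (inputs, config, master seed): a rerun with
the same config and seed reproduces every artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as cl
from . import fragmentation as fr
from . import wfpi as wf
from .carbon_accounting import (
    FactorTable,
    area_shares,
    area_table_from_map,
    carbon_stock,
    emissions_ipcc,
    emissions_wtl,
)
from .grids_io import CLIMATE_ZONES, RasterLayer, make_grid, write_raster
from .indices import ZONE_COMPOSITE_STATISTIC, build_feature_stack, seasonal_composite
from .synthetic_data import (
    PopulationModel,
    default_scene_model,
    generate_control_points,
    generate_population,
    generate_scene,
    generate_truth_map,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

_EXAMPLE_FACTORS = Path(__file__).parent / "data" / "example_factors_synthetic.csv"

DEFAULT_VARIABLES = [
    "NDVI_wet", "NDWI_wet", "MNDWI_wet", "TCWI_wet", "Ndiff_wet", "Nratio_wet",
    "B8_wet", "B11_wet",
    "NDVI_dry", "NDWI_dry", "Ndiff_dry", "B8_dry",
]

_STAGES = ("truth", "scenes", "population", "points", "split", "importance", "train")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Every knob of the chain in one declarative object.

    Defaults are the package's synthetic study conditions: a 200x200 truth
    raster at 50 m, population at 1 km, a 2 km analysis grid, 5 wetland
    classes plus background with wide band separation, 200 control points
    per class split 50/50, and a 500-tree random forest.
    """

    shape: tuple[int, int] = (200, 200)
    fine_cell_size: float = 50.0
    pop_cell_size: float = 1000.0
    grid_cell_size: float = 2000.0
    zone: str = "TW"
    n_scenes_per_season: int = 3
    composite_statistic: str | None = None  # None → per-zone default policy
    variables: list[str] = field(default_factory=lambda: list(DEFAULT_VARIABLES))
    n_points_per_class: int = 200
    split_fraction: float = 0.5
    label_noise: float = 0.0
    ntree: int = 500
    mtry: int | str = "auto"
    n_importance_runs: int = 5
    k_variables: int = 8
    connectivity: int = 4
    merge_classes: bool = False
    membership_bounds: str = "auto"
    thresholds: tuple[float, float] = (0.3, 0.5)
    wtl_code: int = -2
    factor_table: str | None = None  # None → packaged example table
    separation_sd: float = 8.0
    prevalence: float = 0.09
    cities: list[tuple[float, float, float]] | None = None
    pop_background: float = 20.0
    pop_noise_sd: float = 5.0
    seed: int = 0
    outdir: str = "wetlandscape_run"

    def __post_init__(self) -> None:
        if self.zone not in CLIMATE_ZONES:
            raise ValueError(f"unknown climate zone {self.zone!r}")
        lo, hi = self.thresholds
        if not (0 <= lo < hi <= 1):
            raise ValueError("WFPI thresholds must be strictly increasing within [0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.factor_table is not None and not os.path.exists(self.factor_table):
            raise FileNotFoundError(f"factor table not found: {self.factor_table}")

    @property
    def statistic(self) -> str:
        return self.composite_statistic or ZONE_COMPOSITE_STATISTIC[self.zone]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        if "cities" in raw and raw["cities"] is not None:
            raw["cities"] = [tuple(c) for c in raw["cities"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(d["shape"])
        d["thresholds"] = list(d["thresholds"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_cities(shape_pop: tuple[int, int]) -> list[tuple[float, float, float]]:
    nr, nc = shape_pop
    return [
        (nr * 0.25, nc * 0.25, 50_000.0),
        (nr * 0.70, nc * 0.60, 30_000.0),
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and return the run manifest (also written to disk).

    The manifest records the config, the master seed, every artifact path
    with its SHA-256 hash, and the headline metrics of each stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "artifacts": {}, "metrics": {}}

    def save_raster(layer: RasterLayer, name: str) -> None:
        path = outdir / name
        write_raster(layer, path)
        manifest["artifacts"][name] = _sha256(path)

    def save_text(text: str, name: str) -> None:
        path = outdir / name
        path.write_text(text)
        manifest["artifacts"][name] = _sha256(path)

    # --- simulate -----------------------------------------------------------
    model = default_scene_model(separation_sd=config.separation_sd,
                                prevalence=config.prevalence,
                                cell_size=config.fine_cell_size)
    truth, inventory = generate_truth_map(model, config.shape,
                                          seed=stage_seed(config.seed, "truth"),
                                          connectivity=config.connectivity)
    save_raster(truth, "truth.tif")

    scenes = {}
    for season in ("wet", "dry"):
        season_scenes = [
            generate_scene(truth, model, season=season,
                           seed=stage_seed(config.seed, f"scene:{season}:{i}"), zone=config.zone)
            for i in range(config.n_scenes_per_season)
        ]
        scenes[season] = seasonal_composite(season_scenes, statistic=config.statistic)

    extent_m = config.shape[0] * config.fine_cell_size
    pop_shape = (int(extent_m // config.pop_cell_size), int(config.shape[1] * config.fine_cell_size // config.pop_cell_size))
    cities = config.cities if config.cities is not None else _default_cities(pop_shape)
    pop_model = PopulationModel(centers=[tuple(c) for c in cities],
                                kernel_scale=max(pop_shape) / 8.0,
                                background=config.pop_background,
                                noise_sd=config.pop_noise_sd)
    population = generate_population(pop_model, pop_shape, cell_size=config.pop_cell_size,
                                     seed=stage_seed(config.seed, "population"))
    save_raster(population, "population.tif")

    points = generate_control_points(truth, config.n_points_per_class,
                                     seed=stage_seed(config.seed, "points"),
                                     zone=config.zone, label_noise=config.label_noise)
    # --- classify -----------------------------------------------------------
    points = cl.split_control_points(points, config.split_fraction,
                                     seed=stage_seed(config.seed, "split"))
    save_text(points.frame.to_csv(index=False), "control_points.csv")

    stack = build_feature_stack(scenes, config.variables)
    train = points.subset("train")
    test = points.subset("test")
    report = cl.variable_importance(stack, train, n_runs=config.n_importance_runs,
                                    ntree=config.ntree, seed=stage_seed(config.seed, "importance"))
    selected = cl.select_variables(report, min(config.k_variables, len(config.variables)))
    stack_sel = build_feature_stack(scenes, selected)
    model_fit = cl.train_classifier(stack_sel, train, ntree=config.ntree, mtry=config.mtry,
                                    seed=stage_seed(config.seed, "train"))
    predicted_map = cl.predict_map(model_fit, stack_sel)
    save_raster(predicted_map, "classified.tif")

    pred, ref = cl.predict_points(model_fit, stack_sel, test)
    acc = cl.accuracy_report(pred, ref)
    save_text(acc.confusion.to_csv(), "confusion_matrix.csv")
    save_text(json.dumps(acc.to_json_dict(), indent=2), "accuracy.json")
    manifest["metrics"]["overall_accuracy"] = acc.overall_accuracy
    manifest["metrics"]["kappa"] = acc.kappa
    manifest["metrics"]["selected_variables"] = selected
    manifest["metrics"]["importance_mean"] = report.mean_scores.to_dict()

    # --- fragmentation ------------------------------------------------------
    labels = fr.label_fragments(predicted_map, connectivity=config.connectivity,
                                merge_classes=config.merge_classes)
    grid = make_grid(truth, config.grid_cell_size)
    frag_grid = fr.fragments_per_cell(labels, grid)
    save_raster(labels.labels, "fragments.tif")
    save_raster(frag_grid, "fragment_grid.tif")
    manifest["metrics"]["n_fragments"] = labels.n_fragments
    manifest["metrics"]["oracle_n_fragments"] = inventory.n_fragments

    # --- WFPI ---------------------------------------------------------------
    pop_grid = wf.aggregate_population(population, grid, method="sum")
    mem_pop = wf.fuzzy_linear_membership(pop_grid, bounds=config.membership_bounds, source="population")
    mem_frag = wf.fuzzy_linear_membership(frag_grid, bounds=config.membership_bounds, source="fragmentation")
    wfpi_layer = wf.fuzzy_and_overlay(mem_frag, mem_pop)
    save_raster(wfpi_layer, "wfpi.tif")
    area_grid = wf.wetland_area_per_cell(predicted_map, grid)
    summary = wf.threat_summary(wfpi_layer, area_grid, population=pop_grid,
                                fragments=frag_grid, thresholds=config.thresholds)
    save_text(json.dumps(summary.to_json_dict(), indent=2), "threat_summary.json")
    manifest["metrics"]["wfpi_heavy_km2"] = summary.heavy_km2
    manifest["metrics"]["wfpi_moderate_km2"] = summary.moderate_km2

    # --- carbon -------------------------------------------------------------
    zone_code = CLIMATE_ZONES.index(config.zone) + 1
    zones = truth.like(np.full(truth.shape, zone_code, dtype=np.int16), nodata=None)
    class_names = {code: name for name, code in cl.CLASS_CODES.items()}
    zone_names = {i + 1: z for i, z in enumerate(CLIMATE_ZONES)}
    areas = area_table_from_map(predicted_map, zones, class_names, zone_names)
    save_text(areas.frame.to_csv(index=False), "area_table.csv")
    shares = area_shares(areas)
    save_text(shares.to_csv(index=False), "area_shares.csv")

    factors = FactorTable.from_csv(config.factor_table or _EXAMPLE_FACTORS)
    stock = carbon_stock(areas, factors)
    drained = emissions_ipcc(areas, factors, "drained")
    pristine = emissions_ipcc(areas, factors, "pristine")
    wtl = emissions_wtl(areas, factors, config.wtl_code)
    carbon = {
        "stock_tC": stock.total,
        "drained_tC_yr": drained.total,
        "drained_tCO2e_yr": drained.total_co2e,
        "pristine_tC_yr": pristine.total,
        "pristine_tCO2e_yr": pristine.total_co2e,
        f"wtl{config.wtl_code}_t_yr": wtl.total,
    }
    save_text(json.dumps(carbon, indent=2), "carbon_report.json")
    manifest["metrics"].update(carbon)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
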