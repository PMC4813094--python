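"""Readers, writers, run configuration and the pipeline orchestrator.

Tabular interchange is CSV throughout; rasters use a headered CSV-grid
dialect (``x,y,value``, one row per pixel, row-major); zones are GeoJSON
polygons.  Every output file carries a metadata block (version, seed,
config hash) — as leading ``#`` comment lines for CSV, as a ``_meta`` key
for JSON.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import Grid
from .synthetic import SEASONS

CLUSTER_COLUMNS = (
    "cluster_id",
    "x_km",
    "y_km",
    "year",
    "season",
    "n_examined",
    "n_wasted",
)
_SEASON_LOOKUP = {s.lower(): s for s in SEASONS}


def _meta_block(seed=None, config_hash=None) -> dict:
    from . import __version__

    return {
        "package": "wastingmap",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash,
    }


def read_clusters_csv(path) -> pd.DataFrame:
    """Schema-validated cluster records.

    Seasons match the four canonical names case-insensitively; counts are
    checked row by row (``n_wasted <= n_examined``) with the offending
    1-based data row named in the error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    seasons = []
    for i, s in enumerate(df["season"]):
        key = str(s).strip().lower()
        if key not in _SEASON_LOOKUP:
            raise ValueError(f"{path}: unknown season {s!r} at row {i + 1}")
        seasons.append(_SEASON_LOOKUP[key])
    df["season"] = seasons
    for i, (w, n) in enumerate(zip(df["n_wasted"], df["n_examined"])):
        if w < 0 or n < 0 or w > n:
            raise ValueError(
                f"{path}: invalid counts (n_wasted={w}, n_examined={n}) "
                f"at row {i + 1}"
            )
    df["year"] = df["year"].astype(int)
    return df


def write_clusters_csv(df: pd.DataFrame, path, seed=None, config_hash=None):
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# meta: {json.dumps(_meta_block(seed, config_hash))}\n")
        df.to_csv(f, index=False)


def write_raster(grid: Grid, path, seed=None, config_hash=None):
    """CSV-grid dialect: header ``x,y,value``, one row per pixel, row-major."""
    X, Y = grid.centers()
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# meta: {json.dumps(_meta_block(seed, config_hash))}\n")
        f.write("x,y,value\n")
        for x, y, v in zip(X, Y, grid.values.ravel()):
            f.write(f"{x:.10g},{y:.10g},{v:.12g}\n")


def read_raster(path) -> Grid:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != ["x", "y", "value"]:
        raise ValueError(f"{path}: expected header x,y,value")
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    if len(xs) > 1:
        dx = np.diff(xs)
        if not np.allclose(dx, dx[0], rtol=1e-6):
            raise ValueError(f"{path}: non-uniform x spacing")
        res = float(dx[0])
    elif len(ys) > 1:
        res = float(np.diff(ys)[0])
    else:
        res = 1.0
    values = (
        df.pivot(index="y", columns="x", values="value")
        .sort_index()
        .to_numpy()
    )
    return Grid(
        x0=float(xs[0] - res / 2), y0=float(ys[0] - res / 2),
        resolution=res, values=values,
    )


def write_zones_geojson(zones: dict, path):
    from shapely.geometry import mapping

    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": mapping(poly),
            }
            for name, poly in zones.items()
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_zones_geojson(path) -> dict:
    from shapely.geometry import shape

    fc = json.loads(Path(path).read_text())
    return {
        feat["properties"]["name"]: shape(feat["geometry"])
        for feat in fc["features"]
    }


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see `run_pipeline`)."""

    out_dir: str = "run"
    seed: int = 0
    model: int = 1
    # synthetic-study conditions
    region_width_km: float = 300.0
    region_height_km: float = 300.0
    resolution_km: float = 10.0
    n_clusters: int = 1066
    years: tuple = (2007, 2008, 2009, 2010)
    total_under5: int = 1_500_000
    # selection / fit settings
    candidates: tuple = ("rainfall", "evi", "temperature", "dist_water", "urban")
    gamma: float = 1.0
    mesh_edge_km: float = 60.0
    mesh_buffer_km: float = 80.0
    basis: str = "intercept"
    outer_maxiter: int = 80
    holdout_fraction: float = 0.10
    clusters_csv: str | None = None  # fit existing data instead of simulating

    _KNOWN = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        if "candidates" in raw:
            raw["candidates"] = tuple(raw["candidates"])
        cfg = cls(**raw)
        if cfg.clusters_csv and not Path(cfg.clusters_csv).exists():
            raise FileNotFoundError(cfg.clusters_csv)
        if not isinstance(cfg.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        return cfg

    def hash(self) -> str:
        # out_dir is a path, not a scientific setting
        payload = {
            k: v
            for k, v in asdict(self).items()
            if not k.startswith("_") and k != "out_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


class _StageLogger:
    def __init__(self, path):
        self.path = Path(path)

    def log(self, stage, **kwargs):
        rec = {"time": time.time(), "stage": stage, **kwargs}
        with open(self.path, "a") as f:
            f.write(json.dumps(rec, default=str) + "\n")


def _write_json(path, payload, seed, config_hash):
    payload = dict(payload)
    payload["_meta"] = _meta_block(seed, config_hash)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(config: RunConfig) -> Path:
    """Simulate (or load) -> select -> fit -> predict -> classify -> validate.

    Deterministic given the config seed; each stage logs to
    ``log.jsonl`` and leaves a resumable ``STAGE`` marker.  Returns the run
    directory.
    """
    from . import inference, riskmap, selection, synthetic, validation

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLogger(out / "log.jsonl")
    chash = config.hash()
    marker = out / "STAGE"

    def stage(name):
        marker.write_text(name)
        log.log(name, seed=config.seed, config_hash=chash)

    try:
        stage("simulate")
        region = synthetic.make_study_region(
            config.region_width_km, config.region_height_km, config.resolution_km
        )
        covs = synthetic.simulate_covariate_surfaces(region, seed=config.seed)
        if config.clusters_csv:
            clusters = read_clusters_csv(config.clusters_csv)
        else:
            locs = synthetic.sample_cluster_locations(
                region, config.n_clusters, seed=config.seed + 1
            )
            clusters = synthetic.simulate_wasting_data(
                region, locs, covs, synthetic.TrueParameters(),
                years=config.years, seed=config.seed + 2,
            )
        write_clusters_csv(clusters, out / "clusters.csv", config.seed, chash)
        pop = synthetic.simulate_population_grid(
            region, config.total_under5, seed=config.seed + 3
        )
        write_raster(pop, out / "population.csv", config.seed, chash)
        write_zones_geojson(region.zones, out / "zones.geojson")

        stage("select")
        sel = selection.select_best_subset(
            clusters, config.candidates, gamma=config.gamma
        )
        _write_json(
            out / "selection.json",
            {
                "chosen": list(sel.chosen),
                "gamma": sel.gamma,
                "table": sel.table.assign(
                    subset=sel.table["subset"].apply(list)
                ).to_dict(orient="records"),
            },
            config.seed,
            chash,
        )

        stage("holdout")
        train, test = validation.spatiotemporal_holdout(
            clusters, config.holdout_fraction, seed=config.seed + 4
        )

        stage("fit")
        mcfg = inference.ModelConfig(
            model=config.model,
            years=config.years,
            covariates=tuple(sel.chosen),
            mesh_edge_km=config.mesh_edge_km,
            mesh_buffer_km=config.mesh_buffer_km,
            basis=config.basis,
        )
        fit = inference.laplace_fit(
            train, mcfg,
            optimizer_config={"maxiter": config.outer_maxiter, "restarts": 0},
            seed=config.seed + 5,
        )
        _write_json(
            out / "fit_summary.json",
            {
                "fixed_effects": fit.fixed_summary.to_dict(orient="records"),
                "hyperparameters": fit.hyperparameters(),
                "converged": fit.converged,
                "log_posterior": fit.log_posterior,
            },
            config.seed,
            chash,
        )

        stage("predict")
        which = [(y, s) for y in config.years for s in synthetic.SEASONS]
        pred = inference.predict_prevalence(
            fit, region.empty_grid(), covs, which, with_sd=False
        )
        for (y, s), grid in pred.grids.items():
            write_raster(grid, out / f"prevalence_{y}_{s}.csv", config.seed, chash)

        stage("classify")
        risk = riskmap.wasted_children_counts(pred.grids, pop, region.zones)
        risk.table.to_csv(out / "risk.csv", index=False)
        risk.formatted().to_csv(out / "risk_formatted.csv", index=False)

        if config.model == 2:
            stage("seasonal")
            seas = inference.seasonal_effect_estimates(fit)
            _write_json(
                out / "seasonal_effects.json",
                {"effects": seas.to_dict(orient="records")},
                config.seed,
                chash,
            )

        stage("validate")
        test_pred = inference.predict_prevalence_at_points(fit, test, covs)
        report = validation.validation_metrics(
            (test["n_wasted"] / test["n_examined"]).to_numpy(),
            test_pred,
            split_metadata=test.attrs.get("split", {}),
        )
        _write_json(out / "validation.json", report.to_dict(), config.seed, chash)

        stage("done")
    except Exception as err:  # re-raise with the failed stage named
        failed = marker.read_text() if marker.exists() else "unknown"
        log.log("error", failed_stage=failed, error=str(err))
        raise RuntimeError(f"pipeline failed at stage '{failed}': {err}") from err
    return out
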