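"""Config-driven orchestration of the full analysis.

Stages run in dependency order: data (read or simulate) -> baselines ->
calibration -> isoscapes -> mixing -> trophic position.  Every stage writes
plain-text artifacts (CSV / JSON / ASCII grid) into the output directory,
and a manifest records the config digest, per-stage status and timings, and
the master seed, so a run can be re-executed bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import PheCalibrationModel, apply_calibration
from .isoscape import GridSpec, compute_region_baseline, idw_interpolate
from .mixing import (
    MixingConfig,
    MixingSourceSet,
    Source,
    TwoSourceMixingModel,
    summarize_posterior,
)
from .presets import get_tdf, get_tef
from .records import (
    AnalyticalPrecision,
    Region,
    read_consumer_table,
    read_station_table,
)
from .simulate import ScenarioSpec, write_scenario
from .trophic import (
    BayesianTPConfig,
    TwoBaselineTPModel,
    tp_bulk_records,
    tp_csia_records,
)

log = logging.getLogger("isotroph")

_STAGES = ("data", "baselines", "calibration", "isoscape", "mixing", "tp")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    out_dir: str = "isotroph_run"
    seed: int = 0
    # either simulate a scenario ...
    simulate: bool = True
    scenario: dict = field(default_factory=dict)
    # ... or read input tables
    consumers_path: str | None = None
    stations_path: str | None = None
    consumer_columns: dict | None = None
    station_columns: dict | None = None
    # analysis settings
    tissue: str = "muscle"
    tef_preset: str = "madigan-muscle"
    tef_preset_bayes: str = "madigan-muscle-bayes-c"
    tdf_preset: str = "bradley-tuna"
    grid: dict = field(default_factory=dict)
    isoscape_variables: tuple = ("d15N", "d13C", "d15N_phe")
    mixing: dict = field(default_factory=dict)
    tp: dict = field(default_factory=dict)
    stages: tuple = _STAGES
    run_csia: bool = True

    def __post_init__(self):
        bad = set(self.stages) - set(_STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s): {sorted(bad)}")
        for preset, getter in (
            (self.tef_preset, get_tef),
            (self.tef_preset_bayes, get_tef),
            (self.tdf_preset, get_tdf),
        ):
            try:
                getter(preset)
            except KeyError as e:
                raise ConfigError(str(e))
        if not self.simulate and not (self.consumers_path and self.stations_path):
            raise ConfigError(
                "either enable 'simulate' or provide consumers_path and stations_path"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config key(s): {sorted(bad)}")
        for k in ("stages", "isoscape_variables"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _setup_logging(out: pathlib.Path):
    log.setLevel(logging.INFO)
    log.handlers = [logging.StreamHandler(), logging.FileHandler(out / "run.log")]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest.

    Any stage failure aborts the run; the manifest then marks the failed
    stage and labels downstream outputs incomplete.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest = {
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
        "complete": False,
    }
    state: dict = {}
    try:
        for stage in _STAGES:
            if stage not in config.stages:
                manifest["stages"][stage] = {"status": "skipped"}
                continue
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            _RUNNERS[stage](config, state, out)
            dt = time.perf_counter() - t0
            manifest["stages"][stage] = {"status": "complete", "seconds": round(dt, 3)}
            log.info("stage %s: done in %.3f s", stage, dt)
        manifest["complete"] = True
    except Exception as e:
        stage = next(
            (s for s in config.stages if s not in manifest["stages"]), "unknown"
        )
        manifest["stages"][stage] = {"status": "failed", "error": str(e)}
        manifest["error_stage"] = stage
        log.error("stage %s failed: %s", stage, e)
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest


def _stage_data(config: RunConfig, state: dict, out: pathlib.Path):
    if config.simulate:
        spec = ScenarioSpec(**{"seed": config.seed, **config.scenario})
        write_scenario(spec, out)
        state["consumers"] = read_consumer_table(out / "consumers.csv")
        state["stations"] = read_station_table(out / "stations.csv")
        state["scenario"] = spec
    else:
        state["consumers"] = read_consumer_table(
            config.consumers_path, config.consumer_columns
        )
        state["stations"] = read_station_table(
            config.stations_path, config.station_columns
        )
    log.info(
        "data: %d consumers, %d stations",
        len(state["consumers"]), len(state["stations"]),
    )


def _stage_baselines(config: RunConfig, state: dict, out: pathlib.Path):
    baselines = {}
    for region in (Region.NORTH, Region.CENTRAL_SOUTH):
        b = compute_region_baseline(state["stations"], region)
        baselines[region.value] = b
        log.info(
            "baseline %s: n=%d d15N=%.3f+/-%.3f d13C=%.3f+/-%.3f",
            region.value, b.n, b.d15N_mean, b.d15N_sd, b.d13C_mean, b.d13C_sd,
        )
    state["baselines"] = baselines
    payload = {
        k: {f.name: getattr(b, f.name) for f in dataclasses.fields(b)}
        for k, b in baselines.items()
    }
    for k in payload:
        payload[k]["region"] = k
    with open(out / "baselines.json", "w") as fh:
        json.dump(payload, fh, indent=2)


def _stage_calibration(config: RunConfig, state: dict, out: pathlib.Path):
    try:
        model = PheCalibrationModel.from_stations(state["stations"]).fit()
    except ValueError as e:
        log.info("calibration skipped: %s", e)
        state["calibration"] = None
        return
    state["calibration"] = model
    state["stations"] = apply_calibration(state["stations"], model)
    model.to_json(out / "calibration.json")
    log.info("calibration: %s", model.summary())


def _stage_isoscape(config: RunConfig, state: dict, out: pathlib.Path):
    stations = state["stations"]
    lons = [s.lon for s in stations]
    lats = [s.lat for s in stations]
    grid = GridSpec(
        **{
            "lon_min": min(lons), "lon_max": max(lons) + 1e-6,
            "lat_min": min(lats), "lat_max": max(lats) + 1e-6,
            **config.grid,
        }
    )
    for var in config.isoscape_variables:
        try:
            raster = idw_interpolate(stations, var, grid)
        except ValueError as e:
            log.info("isoscape %s skipped: %s", var, e)
            continue
        raster.to_ascii(out / f"isoscape_{var}.asc")
        log.info(
            "isoscape %s: %dx%d cells, %d masked",
            var, grid.nrows, grid.ncols, int(raster.values.mask.sum()),
        )


def _stage_mixing(config: RunConfig, state: dict, out: pathlib.Path):
    b = state["baselines"]
    n, s = b["north"], b["central_south"]
    source_set = MixingSourceSet(
        sources=(
            Source("north", n.d13C_mean, n.d13C_sd, n.d15N_mean, n.d15N_sd),
            Source("central_south", s.d13C_mean, s.d13C_sd, s.d15N_mean, s.d15N_sd),
        ),
        tef=get_tef(config.tef_preset),
    )
    consumers = [
        c for c in state["consumers"] if c.tissue.value == config.tissue
    ]
    cfg = MixingConfig(**{"seed": config.seed, **config.mixing})
    post = TwoSourceMixingModel(consumers, source_set, cfg).fit()
    state["mixing"] = post
    pd.DataFrame(
        {
            "chain": np.repeat(np.arange(post.samples_p.shape[0]),
                               post.samples_p.shape[1]),
            "p_north": post.samples_p.reshape(-1),
            "eps_d13C": post.samples_resid["d13C"].reshape(-1),
            "eps_d15N": post.samples_resid["d15N"].reshape(-1),
        }
    ).to_csv(out / f"mixing_{config.tissue}_draws.csv", index=False)
    summary = summarize_posterior(post)
    summary["rhat"] = post.rhat
    summary["warnings"] = post.warnings
    with open(out / f"mixing_{config.tissue}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("mixing:\n%s", post.summary())


def _stage_tp(config: RunConfig, state: dict, out: pathlib.Path):
    b = state["baselines"]
    consumers = [c for c in state["consumers"] if c.tissue.value == config.tissue]
    tef = get_tef(config.tef_preset)
    precision = AnalyticalPrecision()
    frames = []
    for region in ("north", "central_south"):
        df = tp_bulk_records(consumers, b[region], tef, precision)
        df["method"] = "bulk"
        df["baseline"] = region
        frames.append(df)
    has_csia = any(
        c.d15N_glu is not None and c.d15N_phe is not None for c in consumers
    )
    if config.run_csia and has_csia:
        df = tp_csia_records(consumers, get_tdf(config.tdf_preset), precision)
        df["method"] = "csia"
        df["baseline"] = ""
        frames.append(df)
    per_fish = pd.concat(frames, ignore_index=True)
    per_fish.to_csv(out / "tp_per_fish.csv", index=False)

    cfg = BayesianTPConfig(**{"seed": config.seed, **config.tp})
    res = TwoBaselineTPModel(
        consumers, b["north"], b["central_south"],
        get_tef(config.tef_preset_bayes), cfg,
    ).fit()
    state["tp_bayesian"] = res
    summary = {
        "bulk": {
            region: {
                "mean": float(g["tp"].mean()),
                "sd_between_fish": float(g["tp"].std(ddof=1)),
                "mean_propagated_sd": float(g["sd"].mean()),
            }
            for region, g in per_fish[per_fish.method == "bulk"].groupby("baseline")
        },
        "bayesian": {
            "median": res.median_tp,
            "ci95": list(res.ci95),
            "alpha_median": res.median_alpha,
            "rhat": res.rhat,
            "warnings": res.warnings,
        },
    }
    if config.run_csia and has_csia:
        g = per_fish[per_fish.method == "csia"]
        summary["csia"] = {
            "mean": float(g["tp"].mean()),
            "sd_between_fish": float(g["tp"].std(ddof=1)),
            "mean_propagated_sd": float(g["sd"].mean()),
        }
    with open(out / "tp_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("tp: %s", json.dumps(summary["bayesian"]))


_RUNNERS = {
    "data": _stage_data,
    "baselines": _stage_baselines,
    "calibration": _stage_calibration,
    "isoscape": _stage_isoscape,
    "mixing": _stage_mixing,
    "tp": _stage_tp,
}
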