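"""End-to-end experiment orchestration: sample -> climate -> simulate ->
sensitivity -> uncertainty, with deterministic seeding and a JSON manifest.

The full published experiment (1000 parameter sets x 10 scenarios on the
0.5-degree pan-Arctic grid with a thousand-year spin-up) is cluster-scale;
this pipeline runs the identical code path at a configurable desk scale
(coarse grid, fewer samples, shorter spin-up).

Seeding: every stage draws its seed from the master seed through
``stage_seed(master, stage, index)`` — a SeedSequence over (master, stage
code, index) reduced below 2^31 — so each stage is independently
reproducible and the Latin hypercube draw does not depend on the scenario
list.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .climate_synth import (
    GridSpec,
    builtin_scenarios,
    generate_scenario,
    generate_spinup,
    get_scenario,
    save_cube,
)
from .dgvm_core import (
    SimConfig,
    SimulationResult,
    default_pft_table,
    run_grid,
)
from .parameter_space import (
    SampleMatrix,
    default_parameter_table,
    lhs_sample,
    save_sample_matrix,
    standard_values,
)
from .sensitivity import prcc, rank_importance
from .uncertainty import (
    EnsembleSummary,
    coverage_series,
    decompose_uncertainty,
    ensemble_band,
    summary_frame,
)

logger = logging.getLogger(__name__)

_STAGE_CODES = {"sample": 1, "climate": 2, "simulate": 3}


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([master, _STAGE_CODES[stage], index])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    """Desk-scale experiment configuration (full scale is the same schema)."""

    n_samples: int = 20
    scenarios: list[str] = field(
        default_factory=lambda: [s.name for s in builtin_scenarios()]
    )
    grid_resolution: float = 10.0
    lat_bounds: tuple[float, float] = (45.0, 90.0)
    years: tuple[int, int] = (1971, 2100)   # transient span fed to the model
    analysis_years: tuple[int, int] = (2001, 2100)
    spinup_years: int = 100
    master_seed: int = 0
    out_dir: str = "experiment_out"
    pft_config: str | None = None            # path; None = shipped defaults
    k_mort1_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        known = {s.name for s in builtin_scenarios()}
        unknown = set(self.scenarios) - known
        if unknown:
            raise ValueError(
                f"unknown scenarios {sorted(unknown)}; built-ins: {sorted(known)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("lat_bounds", "years", "analysis_years", "k_mort1_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _forcing_cube(
    scenario_name: str, grid: GridSpec, config: ExperimentConfig
) -> xr.Dataset:
    """Spin-up + transient forcing for one scenario."""
    spec = get_scenario(scenario_name)
    cube = generate_scenario(
        spec,
        grid,
        range(config.years[0], config.years[1] + 1),
        seed=stage_seed(config.master_seed, "climate", _scenario_index(scenario_name)),
    )
    spin = generate_spinup(cube, config.spinup_years)
    return xr.concat([spin, cube], dim="year")


def _scenario_index(name: str) -> int:
    return [s.name for s in builtin_scenarios()].index(name)


def run_scenario_ensemble(
    scenario_name: str,
    samples: SampleMatrix,
    grid: GridSpec,
    config: ExperimentConfig,
    sim_config: SimConfig | None = None,
) -> tuple[SimulationResult, np.ndarray, np.ndarray]:
    """Simulate every parameter set under one scenario.

    Returns the last member's :class:`SimulationResult` (for schema/coords),
    the (sample, year, pft) coverage array over the analysis years, and the
    (sample, cell, pft) mean FPC over the analysis years.
    """
    sim_config = sim_config or SimConfig(spinup_years=config.spinup_years)
    pfts = default_pft_table(config.pft_config)
    cube = _forcing_cube(scenario_name, grid, config)
    y0, y1 = config.analysis_years
    result = None
    coverage = None
    mean_fpc = None
    for i in range(samples.n_samples):
        result = run_grid(samples.row_dict(i), cube, pfts, sim_config)
        sel = (result.years >= y0) & (result.years <= y1)
        if coverage is None:
            n_years = int(sel.sum())
            coverage = np.zeros((samples.n_samples, n_years, len(pfts)))
            mean_fpc = np.zeros(
                (samples.n_samples, result.fpc.shape[1], len(pfts))
            )
        for j in range(len(pfts)):
            coverage[i, :, j] = coverage_series(
                result.fpc[sel, :, j], result.cell_area_km2
            )
        mean_fpc[i] = result.fpc[sel].mean(axis=0)
    return result, coverage, mean_fpc


def run_control(
    config: ExperimentConfig, scenario_name: str
) -> SimulationResult:
    """Single simulation at the standard (control) parameter values."""
    grid = GridSpec.regular(config.grid_resolution, config.lat_bounds)
    cube = _forcing_cube(scenario_name, grid, config)
    pfts = default_pft_table(config.pft_config)
    specs = default_parameter_table(config.k_mort1_range)
    result = run_grid(
        standard_values(specs), cube, pfts, SimConfig(spinup_years=config.spinup_years)
    )
    result.diagnostics["tag"] = "control"
    return result


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full scaled experiment and write all artifacts.

    Produces, under ``config.out_dir``: the shared LHS sample CSV, one
    forcing NetCDF and one ensemble-result NetCDF per scenario, a
    Table-3-style importance CSV per scenario, tidy ensemble-band and
    decomposition CSVs, and a JSON manifest.  Fully deterministic given
    the config (including its master seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {"sample": stage_seed(config.master_seed, "sample")},
        "artifacts": [],
    }

    specs = default_parameter_table(config.k_mort1_range)
    samples = lhs_sample(specs, config.n_samples, manifest["seeds"]["sample"])
    sample_path = out / "lhs_samples.csv"
    save_sample_matrix(samples, sample_path)
    manifest["artifacts"].append(sample_path.name)

    grid = GridSpec.regular(config.grid_resolution, config.lat_bounds)
    pft_ids = [p.id for p in default_pft_table(config.pft_config)]
    y0, y1 = config.analysis_years
    years = np.arange(y0, y1 + 1)

    summaries: dict[tuple[str, str], EnsembleSummary] = {}
    for name in config.scenarios:
        logger.info("scenario %s: simulating %d members", name, config.n_samples)
        cube = _forcing_cube(name, grid, config)
        cube_path = out / f"climate_{name}.nc"
        save_cube(cube.sel(year=slice(config.years[0], None)), cube_path)
        manifest["artifacts"].append(cube_path.name)
        manifest["seeds"][f"climate_{name}"] = stage_seed(
            config.master_seed, "climate", _scenario_index(name)
        )

        result, coverage, mean_fpc = run_scenario_ensemble(
            name, samples, grid, config
        )
        ens_path = out / f"ensemble_{name}.nc"
        xr.Dataset(
            {
                "coverage_km2": (("sample", "year", "pft"), coverage),
                "mean_fpc": (("sample", "cell", "pft"), mean_fpc),
            },
            coords={
                "sample": samples.sample_ids,
                "year": years,
                "pft": pft_ids,
                "cell_lat": ("cell", result.cell_lat),
                "cell_lon": ("cell", result.cell_lon),
            },
        ).to_netcdf(ens_path, engine="scipy")
        manifest["artifacts"].append(ens_path.name)

        # Table-3-style importance ranking: PRCC of century-mean coverage
        rows = []
        for j, pid in enumerate(pft_ids):
            response = coverage[:, :, j].mean(axis=1)
            if np.ptp(response) == 0 or samples.n_samples <= len(specs) + 1:
                continue
            table = rank_importance(
                prcc(samples, response, output_name=f"mean coverage {pid}")
            )
            for rank, pname, value in table.rows:
                rows.append(
                    {"pft": pid, "rank": rank, "parameter": pname, "prcc": value}
                )
        if rows:
            prcc_path = out / f"importance_{name}.csv"
            pd.DataFrame(rows).to_csv(prcc_path, index=False)
            manifest["artifacts"].append(prcc_path.name)

        if config.n_samples >= 2:
            for j, pid in enumerate(pft_ids):
                summaries[(name, pid)] = ensemble_band(coverage[:, :, j], years)

    if summaries:
        band_path = out / "ensemble_bands.csv"
        summary_frame(summaries).to_csv(band_path, index=False)
        manifest["artifacts"].append(band_path.name)

        rows = []
        for pid in pft_ids:
            per_scn = {
                scn: s for (scn, p), s in summaries.items() if p == pid
            }
            try:
                comp = decompose_uncertainty(per_scn)
            except KeyError:
                continue
            for yidx, year in enumerate(years):
                rec = {
                    "pft": pid,
                    "year": int(year),
                    "parameter_width": float(comp.parameter_width[yidx]),
                }
                if comp.climate_width is not None:
                    rec["climate_width"] = float(comp.climate_width[yidx])
                    rec["emission_width"] = float(comp.emission_width[yidx])
                rows.append(rec)
        if rows:
            unc_path = out / "uncertainty_components.csv"
            pd.DataFrame(rows).to_csv(unc_path, index=False)
            manifest["artifacts"].append(unc_path.name)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
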