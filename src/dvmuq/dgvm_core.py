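"""Reduced-form six-PFT dynamic vegetation simulator.

Per grid cell and year the simulator runs: bioclimatic gating ->
light-use-efficiency production -> carbon allocation and allometry ->
mortality -> establishment -> foliage-cover constraint enforcement.  Each
plant functional type (PFT) is represented by an average individual
(carbon pools, crown geometry) and a population density; its foliage
projective cover (FPC) is density x crown area x individual cover, with
individual cover from the Lambert-Beer law, 1 - exp(-k_beer * LAI).

This is deliberately a structural surrogate of a full process model: it
honors the competition rules (woody dominance over grass, establishment
attenuation near canopy closure, growth-efficiency mortality, bioclimatic
limits, CO2 fertilization of C3 photosynthesis) without Farquhar
photosynthesis, soil hydrology, soil carbon pools or fire.  All surrogate
equations live in this one module.

Structural guarantees, enforced by construction every step:
  * per-PFT FPC in [0, 1] and the cell sum of FPCs in [0, 1];
  * the establishment step never decreases any PFT's FPC;
  * the mortality step never increases any PFT's FPC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import xarray as xr
import yaml

PFT_IDS = ("TNE", "TBE", "TBS", "BNE", "BSW", "CPG")
TEMPERATE_PFTS = ("TNE", "TBE", "TBS")
BOREAL_PFTS = ("BNE", "BSW")

#: CO2 mixing ratio (ppmv) at which the fertilization factor equals 1.
CO2_REFERENCE_PPMV = 370.0
#: Half-saturation constant of the saturating CO2 response (ppmv).
CO2_HALF_SAT_PPMV = 300.0
_DAYS_PER_MONTH = 30.42


class DataError(ValueError):
    """Invalid climate input (e.g. NaN) with cell/year context."""


@dataclass(frozen=True)
class PFTConfig:
    """Static (unsampled) traits and bioclimatic limits of one PFT."""

    id: str
    name: str
    woody: bool
    phenology: str
    tc_min_est: float
    tc_max_est: float
    gdd5_min: float
    tw_max: float
    tc_min_surv: float
    k_allom2: float
    sla: float
    wood_density: float
    maint_resp: float

    def __post_init__(self) -> None:
        if math.isfinite(self.tc_min_est) and math.isfinite(self.tc_max_est):
            if not self.tc_min_est < self.tc_max_est:
                raise ValueError(f"{self.id}: tc_min_est must be < tc_max_est")
        if self.sla <= 0:
            raise ValueError(f"{self.id}: sla must be positive")


def default_pft_table(path: str | Path | None = None) -> list[PFTConfig]:
    """Load the six shipped PFT configurations (or a same-schema file)."""
    if path is None:
        with resources.as_file(
            resources.files("dvmuq.data").joinpath("pfts.yml")
        ) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    configs = [PFTConfig(**block) for block in raw]
    ids = [c.id for c in configs]
    if len(configs) != 6 or len(set(ids)) != 6:
        raise ValueError("expected exactly 6 uniquely-named PFT configs")
    return configs


@dataclass(frozen=True)
class SimConfig:
    """Tunable simulator constants (everything not sampled and not per-PFT)."""

    spinup_years: int = 200
    bioclim_window: int = 20       # years averaged for establishment/survival
    heat_mort_rate: float = 0.3    # extra mortality when warmest month > tw_max
    # sapling / grass-patch initial pools, kgC per individual (patch)
    sapling_leaf: float = 0.2
    sapling_sapwood: float = 0.3
    sapling_root: float = 0.2
    grass_leaf: float = 0.05
    grass_root: float = 0.05
    # turnover fractions per year
    leaf_turnover: float = 0.3
    root_turnover: float = 0.3
    sapwood_turnover: float = 0.05
    # NPP allocation fractions (woody: leaf/sapwood/root; grass: leaf/root)
    alloc_leaf_woody: float = 0.35
    alloc_sap_woody: float = 0.35
    alloc_leaf_grass: float = 0.6
    # production scheme constants
    par_scale: float = 6.0         # peak monthly absorbed-light scale
    jc_capacity: float = 0.5       # carboxylation-proxy capacity per month
    precip_demand_mm: float = 300.0  # half-saturation of the water scalar
    # equilibrium diagnostic
    equil_window: int = 30
    equil_tol: float = 1e-3


@dataclass
class GridCellState:
    """Vegetation state of a batch of grid cells (arrays are cell x PFT)."""

    density: np.ndarray      # individuals (grass: patches) per m2
    leaf: np.ndarray         # kgC per individual
    sapwood: np.ndarray
    heartwood: np.ndarray
    root: np.ndarray
    crown_area: np.ndarray   # m2 per individual
    height: np.ndarray       # m
    diameter: np.ndarray     # m
    lai: np.ndarray          # individual leaf-area index
    fpc: np.ndarray          # population foliage projective cover, [0, 1]
    greff: np.ndarray        # growth efficiency, kgC per m2 leaf per yr

    @classmethod
    def bare(cls, n_cells: int, n_pft: int = 6) -> "GridCellState":
        z = lambda: np.zeros((n_cells, n_pft))
        return cls(z(), z(), z(), z(), z(), z(), z(), z(), z(), z(), z())

    @property
    def present(self) -> np.ndarray:
        return self.density > 0

    @property
    def bare_fraction(self) -> np.ndarray:
        return 1.0 - self.fpc.sum(axis=1)

    def copy(self) -> "GridCellState":
        return GridCellState(
            **{k: np.array(v, copy=True) for k, v in vars(self).items()}
        )

    def check_invariants(self, atol: float = 1e-9) -> None:
        for name in ("density", "leaf", "sapwood", "heartwood", "root"):
            if np.any(getattr(self, name) < -atol):
                raise AssertionError(f"negative {name}")
        if np.any(self.fpc < -atol) or np.any(self.fpc > 1 + atol):
            raise AssertionError("per-PFT FPC outside [0, 1]")
        if np.any(self.fpc.sum(axis=1) > 1 + atol):
            raise AssertionError("FPC sum exceeds 1")


@dataclass(frozen=True)
class SimulationResult:
    """Per-year per-cell per-PFT FPC trajectory plus diagnostics."""

    fpc: np.ndarray                  # (year, cell, pft)
    years: np.ndarray
    pft_ids: tuple[str, ...]
    cell_lat: np.ndarray             # latitude of each land cell
    cell_lon: np.ndarray
    cell_area_km2: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def mean_fpc(self, year_range: tuple[int, int] | None = None) -> np.ndarray:
        """(cell, pft) mean FPC over a year span (inclusive; default all)."""
        if year_range is None:
            sel = slice(None)
        else:
            sel = (self.years >= year_range[0]) & (self.years <= year_range[1])
        return self.fpc[sel].mean(axis=0)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"fpc": (("year", "cell", "pft"), self.fpc)},
            coords={
                "year": self.years,
                "pft": list(self.pft_ids),
                "cell_lat": ("cell", self.cell_lat),
                "cell_lon": ("cell", self.cell_lon),
                "cell_area_km2": ("cell", self.cell_area_km2),
            },
        )


# ---------------------------------------------------------------------------
# elementary relations

def lambert_beer_fpc(lai, k_beer: float):
    """Individual foliage projective cover, 1 - exp(-k_beer * LAI)."""
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be non-negative")
    if k_beer <= 0:
        raise ValueError("k_beer must be positive")
    return 1.0 - np.exp(-k_beer * lai)


def co2_fertilization(co2_ppmv: float) -> float:
    """Saturating CO2 response, normalized to 1 at the reference 370 ppmv."""
    if co2_ppmv <= 0:
        raise ValueError("CO2 must be positive")
    ref = CO2_REFERENCE_PPMV / (CO2_REFERENCE_PPMV + CO2_HALF_SAT_PPMV)
    return (co2_ppmv / (co2_ppmv + CO2_HALF_SAT_PPMV)) / ref


def colimitation_root(je, jc, theta: float):
    """Smaller root of theta*x^2 - (je + jc)*x + je*jc = 0.

    The non-rectangular hyperbola colimiting the light- and
    capacity-limited rates; approaches min(je, jc) as theta -> 1 and the
    harmonic form je*jc/(je+jc) as theta -> 0.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    je = np.asarray(je, dtype=float)
    jc = np.asarray(jc, dtype=float)
    b = je + jc
    disc = np.maximum(b * b - 4.0 * theta * je * jc, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        root = (b - np.sqrt(disc)) / (2.0 * theta)
    return np.where(b > 0, root, 0.0)


# ---------------------------------------------------------------------------
# climate summaries and bioclimatic gating

def annual_climate_metrics(tas_monthly: np.ndarray) -> tuple[np.ndarray, ...]:
    """(coldest-month T, warmest-month T, GDD5) from (12, cell) monthly T."""
    tc = tas_monthly.min(axis=0)
    tw = tas_monthly.max(axis=0)
    gdd5 = np.maximum(tas_monthly - 5.0, 0.0).sum(axis=0) * _DAYS_PER_MONTH
    return tc, tw, gdd5


def bioclim_allows(
    pft: PFTConfig, tc: np.ndarray, tw: np.ndarray, gdd5: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Establishment and survival gates from multi-year mean climate.

    ``tc``/``tw`` are means of the coldest/warmest month over the bioclim
    window, ``gdd5`` the mean growing degree-days above 5 degC.
    """
    establish = (tc >= pft.tc_min_est) & (tc <= pft.tc_max_est) & (
        gdd5 >= pft.gdd5_min
    )
    survive = (tw <= pft.tw_max) & (tc >= pft.tc_min_surv)
    return establish, survive


# ---------------------------------------------------------------------------
# production

def _insolation(lat_deg: np.ndarray, month: np.ndarray) -> np.ndarray:
    """Relative top-of-atmosphere light proxy, (month, cell)."""
    decl = 23.4 * np.cos(2.0 * np.pi * (month[:, None] - 6) / 12.0)
    return np.maximum(np.cos(np.radians(lat_deg[None, :] - decl)), 0.0)


def _temperature_response(tas: np.ndarray) -> np.ndarray:
    """Photosynthetic temperature scalar: 0 at 0 degC, 1 from 12-30, 0 at 38."""
    up = np.clip(tas / 12.0, 0.0, 1.0)
    down = np.clip((38.0 - tas) / 8.0, 0.0, 1.0)
    return up * down


def annual_production(
    tas: np.ndarray,
    pr: np.ndarray,
    clt: np.ndarray,
    co2: float,
    params: dict[str, float],
    pft: PFTConfig,
    fpc: np.ndarray,
    lat: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """Net primary production per m2 of ground, kgC/m2/yr, per cell.

    GPP is a light-use-efficiency colimitation scheme: the light-limited
    rate J_E = alpha_C3 * f(T) * APAR (APAR = insolation x cloud x cover)
    and the capacity-limited rate J_C = capacity * f(CO2) * w(P) are
    combined through the non-rectangular hyperbola with shape ``theta``,
    scaled leaf-to-canopy by ``alpha_a``.  NPP = max(0, GPP - R_maint) *
    (1 - r_growth); maintenance respiration is charged by the caller
    (it depends on standing biomass), so here R_maint enters via the
    ``maint`` term passed through ``params['_maint']`` if present.

    ``tas``/``pr``/``clt`` are (12, cell) monthly fields.
    """
    fpc = np.asarray(fpc, dtype=float)
    if np.any((fpc < 0) | (fpc > 1)):
        raise ValueError("fpc must lie in [0, 1]")
    par = config.par_scale * _insolation(lat, np.arange(12)) * (1.0 - 0.5 * clt)
    je = params["alpha_C3"] * _temperature_response(tas) * par * fpc[None, :]
    p_annual = pr.sum(axis=0)
    water = p_annual / (p_annual + config.precip_demand_mm)
    jc_month = config.jc_capacity * co2_fertilization(co2) * water
    jc = np.broadcast_to(jc_month[None, :], je.shape)
    phi = colimitation_root(je, jc, params["theta"])
    gpp = params["alpha_a"] * phi.sum(axis=0)
    maint = params.get("_maint", 0.0)
    return np.maximum(gpp - maint, 0.0) * (1.0 - params["r_growth"])


# ---------------------------------------------------------------------------
# allometry

def update_allometry(
    leaf: np.ndarray,
    sapwood: np.ndarray,
    heartwood: np.ndarray,
    params: dict[str, float],
    pft: PFTConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(height, crown_area, diameter, LAI) of the average individual.

    Woody PFTs: stem diameter from a cylinder of total stem carbon at the
    configured wood density, height = k_allom2 * d^k_allom3, crown area =
    min(k_allom1 * height^k_rp, CA_max), leaf area capped by the leaf-to-
    sapwood-area ratio.  Grasses: unit patch (crown area 1 m2), LAI =
    leaf mass x SLA.
    """
    leaf = np.asarray(leaf, dtype=float)
    if np.any(leaf < 0) or np.any(sapwood < 0) or np.any(heartwood < 0):
        raise ValueError("carbon pools must be non-negative")
    if not pft.woody:
        height = np.zeros_like(leaf)
        diameter = np.zeros_like(leaf)
        crown = np.ones_like(leaf)
        lai = leaf * pft.sla
        return height, crown, diameter, lai
    stem = sapwood + heartwood
    volume = stem / pft.wood_density
    diameter = (4.0 * volume / (np.pi * pft.k_allom2)) ** (
        1.0 / (2.0 + params["k_allom3"])
    )
    height = pft.k_allom2 * diameter ** params["k_allom3"]
    crown = np.minimum(params["k_allom1"] * height ** params["k_rp"], params["CA_max"])
    with np.errstate(divide="ignore", invalid="ignore"):
        sap_cross = np.where(height > 0, sapwood / (pft.wood_density * height), 0.0)
    leaf_area = np.minimum(leaf * pft.sla, params["k_la_sa"] * sap_cross)
    if np.any((crown == 0) & (leaf_area > 0)):
        raise FloatingPointError("positive leaf area with zero crown area")
    with np.errstate(divide="ignore", invalid="ignore"):
        lai = np.where(crown > 0, leaf_area / crown, 0.0)
    return height, crown, diameter, lai


# ---------------------------------------------------------------------------
# demographic steps (each preserves its directionality guarantee exactly)

WOODY_CLOSURE = 0.95  # establishment attenuates above this woody cover


def establishment(
    state: GridCellState,
    params: dict[str, float],
    establish_ok: np.ndarray,
    pfts: Sequence[PFTConfig],
    config: SimConfig,
) -> GridCellState:
    """Add saplings (grass patches) to permitted PFTs; FPC never decreases.

    Woody establishment per PFT is est_max x (1 - woody cover), attenuated
    linearly to zero as woody cover closes from 0.95 to 1.  Grass
    establishes into the space not occupied by any PFT.  Sapling pools are
    merged into the average individual by density weighting; the FPC
    contribution of the new saplings is added explicitly, so the step is
    monotone by construction.
    """
    state = state.copy()
    woody = np.array([p.woody for p in pfts])
    # free-space terms are snapshot at entry so the order PFTs are
    # processed in does not change anyone's establishment rate
    fpc_woody = state.fpc[:, woody].sum(axis=1)
    fpc_total = state.fpc.sum(axis=1)
    atten = np.clip((1.0 - fpc_woody) / (1.0 - WOODY_CLOSURE), 0.0, 1.0)
    k_beer = params["k_beer"]
    est_flux = np.zeros(state.density.shape[0])
    for j, pft in enumerate(pfts):
        ok = np.asarray(establish_ok[:, j], dtype=bool)
        if pft.woody:
            d_new = params["est_max"] * (1.0 - fpc_woody) * atten * ok
            pools = {
                "leaf": config.sapling_leaf,
                "sapwood": config.sapling_sapwood,
                "heartwood": 0.0,
                "root": config.sapling_root,
            }
            sap_h, sap_ca, sap_d, sap_lai = update_allometry(
                np.array([pools["leaf"]]),
                np.array([pools["sapwood"]]),
                np.array([0.0]),
                params,
                pft,
            )
            crown_new, lai_new = float(sap_ca[0]), float(sap_lai[0])
        else:
            free = np.clip(1.0 - fpc_total, 0.0, 1.0)
            d_new = params["est_max"] * free * ok
            pools = {
                "leaf": config.grass_leaf,
                "sapwood": 0.0,
                "heartwood": 0.0,
                "root": config.grass_root,
            }
            crown_new, lai_new = 1.0, config.grass_leaf * pft.sla
        if not np.any(d_new > 0):
            continue
        d_old = state.density[:, j]
        d_tot = d_old + d_new
        with np.errstate(divide="ignore", invalid="ignore"):
            for pool, init in pools.items():
                merged = np.where(
                    d_tot > 0,
                    (getattr(state, pool)[:, j] * d_old + init * d_new) / d_tot,
                    0.0,
                )
                getattr(state, pool)[:, j] = merged
        state.density[:, j] = d_tot
        dfpc = d_new * crown_new * (1.0 - np.exp(-k_beer * lai_new))
        state.fpc[:, j] = np.minimum(state.fpc[:, j] + dfpc, 1.0)
        est_flux += d_new
    return state


def mortality_rate(
    greff: np.ndarray, k_mort1: float, k_mort2: float
) -> np.ndarray:
    """Background mortality, k_mort1 / (1 + k_mort2 * greff).

    Approaches the asymptotic maximum k_mort1 as growth efficiency
    vanishes and zero as it grows large.
    """
    return k_mort1 / (1.0 + k_mort2 * np.asarray(greff, dtype=float))


def mortality(
    state: GridCellState,
    params: dict[str, float],
    heat_stressed: np.ndarray,
    survive_ok: np.ndarray,
    config: SimConfig,
) -> GridCellState:
    """Thin populations; FPC never increases in this step.

    Density (and FPC proportionally) is reduced by the growth-efficiency
    rate, plus an extra heat-stress rate where the warmest month exceeded
    the PFT's limit this year; PFTs whose bioclimatic survival window has
    been exceeded over the averaging window are removed outright.
    """
    state = state.copy()
    rate = mortality_rate(state.greff, params["k_mort1"], params["k_mort2"])
    rate = rate + config.heat_mort_rate * np.asarray(heat_stressed, dtype=float)
    rate = np.clip(rate, 0.0, 1.0)
    keep = 1.0 - rate
    state.density *= keep
    state.fpc *= keep
    dead = ~np.asarray(survive_ok, dtype=bool) | (state.density <= 1e-12)
    for name in ("density", "leaf", "sapwood", "heartwood", "root",
                 "crown_area", "height", "diameter", "lai", "fpc", "greff"):
        arr = getattr(state, name)
        arr[dead] = 0.0
    return state


def enforce_fpc_constraints(state: GridCellState, pfts: Sequence[PFTConfig]) -> GridCellState:
    """Cap the cell FPC sum at 1: herbaceous cover yields first, then woody
    cover is rescaled proportionally (with proportional density reduction)."""
    state = state.copy()
    woody = np.array([p.woody for p in pfts])
    fw = state.fpc[:, woody].sum(axis=1)
    scale_w = np.where(fw > 1.0, 1.0 / np.maximum(fw, 1e-300), 1.0)
    state.fpc[:, woody] *= scale_w[:, None]
    state.density[:, woody] *= scale_w[:, None]
    fw = state.fpc[:, woody].sum(axis=1)
    grass_cols = np.nonzero(~woody)[0]
    fg = state.fpc[:, grass_cols].sum(axis=1)
    allowed = np.where(fw >= 1.0 - 1e-12, 0.0, 1.0 - fw)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale_g = np.where(fg > allowed, allowed / np.maximum(fg, 1e-300), 1.0)
    state.fpc[:, grass_cols] *= scale_g[:, None]
    state.density[:, grass_cols] *= scale_g[:, None]
    return state


# ---------------------------------------------------------------------------
# annual loop

def _validate_climate(tas, pr, clt, co2, years) -> None:
    for name, arr in (("tas", tas), ("pr", pr), ("clt", clt)):
        bad = np.isnan(arr)
        if bad.any():
            y, m, c = np.argwhere(bad)[0]
            raise DataError(
                f"NaN in {name} at year {int(years[y])}, month {m + 1}, cell {c}"
            )
    if np.isnan(co2).any():
        y = int(np.argwhere(np.isnan(co2))[0][0])
        raise DataError(f"NaN in co2 at year {int(years[y])}")


def run_grid(
    params: dict[str, float],
    cube: xr.Dataset,
    pfts: Sequence[PFTConfig] | None = None,
    config: SimConfig | None = None,
    seed: int = 0,
    record_steps: bool = False,
) -> SimulationResult:
    """Simulate every land cell of a climate cube from bare ground.

    ``params`` maps the 13 sampled parameter names to values.  The run is
    deterministic (``seed`` is accepted for interface symmetry; the
    surrogate has no stochastic process).  With ``record_steps`` the
    per-step FPC snapshots needed to audit the establishment/mortality
    directionality guarantees are stored in ``diagnostics``.
    """
    pfts = list(pfts) if pfts is not None else default_pft_table()
    config = config or SimConfig()
    mask = cube.land_mask.values
    lat_grid, lon_grid = np.meshgrid(cube.lat.values, cube.lon.values, indexing="ij")
    cell_lat = lat_grid[mask]
    cell_lon = lon_grid[mask]
    areas = cube.cell_area_km2.values[mask]
    years = cube.year.values
    # (year, month, cell)
    tas = cube.tas.values[:, :, mask]
    pr = cube.pr.values[:, :, mask]
    clt = cube.clt.values[:, :, mask]
    co2 = cube.co2.values
    _validate_climate(tas, pr, clt, co2, years)

    n_years, _, n_cells = tas.shape
    n_pft = len(pfts)
    state = GridCellState.bare(n_cells, n_pft)
    fpc_out = np.zeros((n_years, n_cells, n_pft))
    window: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    diag: dict[str, list] = {
        "est_fpc_delta_min": [], "mort_fpc_delta_max": [], "fpc_sum_max": []
    }

    woody_idx = [j for j, p in enumerate(pfts) if p.woody]

    for y in range(n_years):
        tc_y, tw_y, gdd5_y = annual_climate_metrics(tas[y])
        window.append((tc_y, tw_y, gdd5_y))
        if len(window) > config.bioclim_window:
            window.pop(0)
        tc = np.mean([wdw[0] for wdw in window], axis=0)
        tw = np.mean([wdw[1] for wdw in window], axis=0)
        gdd5 = np.mean([wdw[2] for wdw in window], axis=0)

        establish_ok = np.zeros((n_cells, n_pft), dtype=bool)
        survive_ok = np.zeros((n_cells, n_pft), dtype=bool)
        heat = np.zeros((n_cells, n_pft), dtype=bool)
        for j, pft in enumerate(pfts):
            est, surv = bioclim_allows(pft, tc, tw, gdd5)
            establish_ok[:, j] = est
            survive_ok[:, j] = surv
            heat[:, j] = tw_y > pft.tw_max

        # production and allocation
        for j, pft in enumerate(pfts):
            dens = state.density[:, j]
            living = (
                state.leaf[:, j] + state.sapwood[:, j] + state.root[:, j]
            ) * dens
            p = dict(params)
            p["_maint"] = pft.maint_resp * living
            npp_cell = annual_production(
                tas[y], pr[y], clt[y], float(co2[y]), p, pft,
                state.fpc[:, j], cell_lat, config,
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                npp_ind = np.where(dens > 0, npp_cell / np.maximum(dens, 1e-300), 0.0)
            # turnover
            state.leaf[:, j] *= 1.0 - config.leaf_turnover
            state.root[:, j] *= 1.0 - config.root_turnover
            if pft.woody:
                moved = state.sapwood[:, j] * config.sapwood_turnover
                state.sapwood[:, j] -= moved
                state.heartwood[:, j] += moved
                fl = config.alloc_leaf_woody
                fs = config.alloc_sap_woody
                state.leaf[:, j] += fl * npp_ind
                state.sapwood[:, j] += fs * npp_ind
                state.root[:, j] += (1.0 - fl - fs) * npp_ind
            else:
                fl = config.alloc_leaf_grass
                state.leaf[:, j] += fl * npp_ind
                state.root[:, j] += (1.0 - fl) * npp_ind
            h, ca, d, lai = update_allometry(
                state.leaf[:, j], state.sapwood[:, j], state.heartwood[:, j],
                params, pft,
            )
            state.height[:, j] = h
            state.crown_area[:, j] = ca
            state.diameter[:, j] = d
            state.lai[:, j] = lai
            leaf_area = lai * ca
            with np.errstate(divide="ignore", invalid="ignore"):
                state.greff[:, j] = np.where(
                    leaf_area > 0, npp_ind / np.maximum(leaf_area, 1e-300), 0.0
                )
            ind_cover = 1.0 - np.exp(-params["k_beer"] * lai)
            state.fpc[:, j] = np.minimum(dens * ca * ind_cover, 1.0)

        state = enforce_fpc_constraints(state, pfts)

        pre_mort = state.fpc.copy()
        state = mortality(state, params, heat, survive_ok, config)
        if record_steps:
            diag["mort_fpc_delta_max"].append(float((state.fpc - pre_mort).max()))

        pre_est = state.fpc.copy()
        state = establishment(state, params, establish_ok, pfts, config)
        if record_steps:
            diag["est_fpc_delta_min"].append(float((state.fpc - pre_est).min()))

        state = enforce_fpc_constraints(state, pfts)
        if record_steps:
            diag["fpc_sum_max"].append(float(state.fpc.sum(axis=1).max()))
            state.check_invariants()
        fpc_out[y] = state.fpc

    return SimulationResult(
        fpc=fpc_out,
        years=np.asarray(years),
        pft_ids=tuple(p.id for p in pfts),
        cell_lat=cell_lat,
        cell_lon=cell_lon,
        cell_area_km2=areas,
        diagnostics={k: np.asarray(v) for k, v in diag.items()} if record_steps else {},
    )


def run_gridcell(
    params: dict[str, float],
    cube: xr.Dataset,
    pfts: Sequence[PFTConfig] | None = None,
    config: SimConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Single-cell convenience wrapper: (year, pft) FPC trajectory for the
    first (or only) land cell of ``cube``."""
    result = run_grid(params, cube, pfts, config, seed)
    return result.fpc[:, 0, :]


def save_result(result: SimulationResult, path: str | Path) -> None:
    result.to_dataset().to_netcdf(path, engine="scipy")


def load_result(path: str | Path) -> SimulationResult:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    return SimulationResult(
        fpc=ds.fpc.values,
        years=ds.year.values,
        pft_ids=tuple(str(p) for p in ds.pft.values),
        cell_lat=ds.cell_lat.values,
        cell_lon=ds.cell_lon.values,
        cell_area_km2=ds.cell_area_km2.values,
    )
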