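"""Synthetic gridded climate scenarios for the northern high latitudes.

Real simulations of this kind are forced with 0.5-degree gridded monthly
observations (1901-2000) and GCM scenario climates (2001-2100).  Neither is
bundled here; instead this module generates synthetic monthly temperature,
precipitation and cloud-fraction fields over 45-90N whose *statistical
structure* matches the ten built-in scenarios: an exact configured linear
trend of the area-weighted domain-mean annual series, per-scenario CO2
trajectories between the published 2001/2100 endpoints, interannual noise
calibrated so the fitted-trend R^2 matches the published regression, a
latitude-amplified warming gradient for the IGSM-family scenarios, and a
cyclic 30-year baseline climatology for model spin-up.

The baseline climatology is a smooth idealization (sinusoidal seasonal
cycle, latitude-dependent mean and amplitude); no attempt is made to
reproduce observed spatial fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

EARTH_RADIUS_KM = 6371.0
#: Reference year at which scenario trends are anchored (trend = 0 here).
TREND_ANCHOR_YEAR = 2001
#: Approximate global CO2 concentration at the start of the historical period.
CO2_1901_PPMV = 296.0
#: Population variance of t = 0..99, used to convert printed trend R^2 into
#: an interannual noise standard deviation for 100-year series.
_VAR_T_100 = (100.0**2 - 1.0) / 12.0

# Baseline climatology constants (idealized; latitude phi in degrees north).
_T_MEAN_45N = 8.0          # degC mean annual temperature at 45N
_T_LAPSE = 0.55            # degC per degree latitude
_T_AMPL_45N = 16.0         # degC seasonal half-amplitude at 45N
_T_AMPL_SLOPE = 0.08       # amplitude decrease per degree latitude
_P_MEAN_45N = 45.0         # mm/month at 45N
_P_LAPSE = 0.40            # mm/month per degree latitude
_P_FLOOR = 10.0            # mm/month minimum of the baseline mean
_P_SEASONAL = 10.0         # mm/month seasonal half-amplitude
_CLT_MEAN = 0.6
_CLT_SEASONAL = 0.1
_LOCAL_T_NOISE = 1.5       # degC per-cell-month noise
_LOCAL_P_NOISE = 8.0       # mm/month per-cell-month noise
_LOCAL_CLT_NOISE = 0.05
#: Relative latitudinal amplification gradient for IGSM-family warming
#: (fractional change of the local warming rate per degree latitude).
DEFAULT_AMPLIFICATION = 0.015


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration of one synthetic climate-change scenario."""

    name: str
    temp_slope: float              # degC/yr, domain-mean annual
    precip_slope: float            # mm/yr, domain-mean annual total
    co2_start: float               # ppmv at 2001
    co2_end: float                 # ppmv at 2100
    family: str                    # "IPCC-smooth" | "IGSM-latitude-amplified"
    emission_group: str            # "ipcc" | "reference" | "stabilization"
    response_class: str            # "median" | "low" | "high" | "n/a"
    temp_noise: float = 0.0        # degC, interannual sd of the domain mean
    precip_noise: float = 0.0      # mm, interannual sd of the annual total
    amplification: float = 0.0     # IGSM latitude gradient coefficient

    def __post_init__(self) -> None:
        if not self.co2_start < self.co2_end:
            raise ValueError(f"{self.name}: co2_start must be below co2_end")
        if self.temp_noise < 0 or self.precip_noise < 0:
            raise ValueError(f"{self.name}: noise must be non-negative")

    def with_noise_scale(self, scale: float) -> "ScenarioSpec":
        """Copy of this spec with both noise levels multiplied by ``scale``."""
        return replace(
            self,
            temp_noise=self.temp_noise * scale,
            precip_noise=self.precip_noise * scale,
        )


@dataclass(frozen=True)
class GridSpec:
    """Regular latitude-longitude grid with a land mask."""

    lats: np.ndarray   # cell-center latitudes, degrees north
    lons: np.ndarray   # cell-center longitudes, degrees east
    resolution: float  # degrees
    land_mask: np.ndarray  # (lat, lon) boolean

    @classmethod
    def regular(
        cls,
        resolution: float = 10.0,
        lat_bounds: tuple[float, float] = (45.0, 90.0),
        lon_bounds: tuple[float, float] = (-180.0, 180.0),
        land_mask: np.ndarray | None = None,
    ) -> "GridSpec":
        lats = np.arange(lat_bounds[0] + resolution / 2, lat_bounds[1], resolution)
        lons = np.arange(lon_bounds[0] + resolution / 2, lon_bounds[1], resolution)
        if land_mask is None:
            land_mask = np.ones((lats.size, lons.size), dtype=bool)
        if not np.any(land_mask):
            raise ValueError("grid must contain at least one land cell")
        return cls(lats=lats, lons=lons, resolution=resolution, land_mask=land_mask)

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    def cell_areas_km2(self) -> np.ndarray:
        """(lat, lon) spherical cell areas, km^2."""
        half = self.resolution / 2.0
        phi1 = np.radians(self.lats - half)
        phi2 = np.radians(self.lats + half)
        dlam = math.radians(self.resolution)
        band = EARTH_RADIUS_KM**2 * dlam * (np.sin(phi2) - np.sin(phi1))
        return np.broadcast_to(band[:, None], self.land_mask.shape).copy()

    def area_weights(self) -> np.ndarray:
        """(lat, lon) normalized area weights; zero on ocean cells."""
        w = self.cell_areas_km2() * self.land_mask
        return w / w.sum()


def builtin_scenarios() -> list[ScenarioSpec]:
    """The ten built-in scenarios with published slopes and CO2 endpoints.

    Interannual noise defaults are chosen so that the R^2 of a fitted
    100-year trend matches the published per-scenario regression R^2:
    for a series y_t = s*t + eps with var(eps) = sigma^2,
    R^2 = s^2 var(t) / (s^2 var(t) + sigma^2), hence
    sigma = s * sqrt(var(t) * (1/R^2 - 1)).
    """
    with resources.as_file(
        resources.files("dvmuq.data").joinpath("scenarios.csv")
    ) as p:
        table = pd.read_csv(p, comment="#")
    specs = []
    for row in table.itertuples(index=False):
        t_sd = row.temp_slope * math.sqrt(_VAR_T_100 * (1.0 / row.temp_r2 - 1.0))
        p_sd = row.precip_slope * math.sqrt(_VAR_T_100 * (1.0 / row.precip_r2 - 1.0))
        specs.append(
            ScenarioSpec(
                name=row.name,
                temp_slope=row.temp_slope,
                precip_slope=row.precip_slope,
                co2_start=row.co2_start,
                co2_end=row.co2_end,
                family=row.family,
                emission_group=row.emission_group,
                response_class=row.response_class,
                temp_noise=t_sd,
                precip_noise=p_sd,
                amplification=(
                    DEFAULT_AMPLIFICATION
                    if row.family == "IGSM-latitude-amplified"
                    else 0.0
                ),
            )
        )
    return specs


def get_scenario(name: str) -> ScenarioSpec:
    for spec in builtin_scenarios():
        if spec.name == name:
            return spec
    names = ", ".join(s.name for s in builtin_scenarios())
    raise KeyError(f"unknown scenario {name!r}; built-ins are: {names}")


# ---------------------------------------------------------------------------
# field construction

def _seasonal(month: np.ndarray, amplitude: float | np.ndarray) -> np.ndarray:
    """Seasonal cycle peaking in July (month index 6)."""
    return amplitude * np.cos(2.0 * np.pi * (month - 6) / 12.0)


def baseline_climatology(grid: GridSpec) -> dict[str, np.ndarray]:
    """Idealized (month, lat) monthly climatology of T, P and cloud."""
    months = np.arange(12)[:, None]
    lat = grid.lats[None, :]
    t_mean = _T_MEAN_45N - _T_LAPSE * (lat - 45.0)
    t_ampl = np.maximum(_T_AMPL_45N - _T_AMPL_SLOPE * (lat - 45.0), 0.0)
    tas = t_mean + _seasonal(months, t_ampl)
    p_mean = np.maximum(_P_MEAN_45N - _P_LAPSE * (lat - 45.0), _P_FLOOR)
    pr = np.maximum(p_mean + _seasonal(months, _P_SEASONAL), 0.0)
    clt = np.clip(
        _CLT_MEAN - _seasonal(months, _CLT_SEASONAL) * np.ones_like(lat), 0.0, 1.0
    )
    return {"tas": tas, "pr": pr, "clt": clt}


def _co2_trajectory(spec: ScenarioSpec, years: np.ndarray) -> np.ndarray:
    """Annual CO2: linear 2001->2100 between the scenario endpoints,
    linear 1901->2001 between the preindustrial-era level and co2_start."""
    co2 = np.empty(years.size)
    future = years >= TREND_ANCHOR_YEAR
    frac = (years[future] - TREND_ANCHOR_YEAR) / (2100 - TREND_ANCHOR_YEAR)
    co2[future] = spec.co2_start + frac * (spec.co2_end - spec.co2_start)
    past = ~future
    fracp = (years[past] - 1901) / (TREND_ANCHOR_YEAR - 1901)
    co2[past] = CO2_1901_PPMV + fracp * (spec.co2_start - CO2_1901_PPMV)
    return co2


def generate_scenario(
    spec: ScenarioSpec,
    grid: GridSpec,
    years: range,
    seed: int,
) -> xr.Dataset:
    """Generate one scenario's monthly climate cube.

    The trend term ``slope * (year - 2001)`` (zero before 2001) is imposed on
    the area-weighted domain mean exactly; for IGSM-family scenarios the
    local warming rate is additionally modulated by a latitude gradient that
    is zero-mean under the area weights, so the domain-mean trend is
    unaffected.  Interannual noise is a domain-wide annual anomaly plus
    small independent per-cell-month noise.  Deterministic given ``seed``.

    Returns an :class:`xarray.Dataset` with variables ``tas`` (degC), ``pr``
    (mm/month), ``clt`` (fraction) on dims (year, month, lat, lon), annual
    ``co2`` (ppmv), and the land mask / cell areas as coordinates.
    """
    years_arr = np.asarray(list(years))
    if years_arr.size == 0:
        raise ValueError("empty year range")
    if years_arr.min() < 1901 or years_arr.max() > 2100:
        raise ValueError("supported years are 1901-2100")
    if not np.any(grid.land_mask):
        raise ValueError("grid has no land cells")

    rng = np.random.default_rng(seed)
    clim = baseline_climatology(grid)
    n_y, n_lat, n_lon = years_arr.size, grid.lats.size, grid.lons.size

    # latitude modulation of the warming rate; area-weighted mean is exactly 1
    w = grid.area_weights()
    wlat = w.sum(axis=1)  # weight per latitude band
    lat_bar = float(np.sum(wlat * grid.lats))
    g = 1.0 + spec.amplification * (grid.lats - lat_bar)

    elapsed = np.maximum(years_arr - TREND_ANCHOR_YEAR, 0.0)

    # temperature: clim + trend * g(lat) + domain anomaly + local noise
    tas = np.empty((n_y, 12, n_lat, n_lon))
    tas[:] = clim["tas"][None, :, :, None]
    tas += (elapsed[:, None] * spec.temp_slope * g[None, :])[:, None, :, None]
    if spec.temp_noise > 0:
        tas += rng.normal(0.0, spec.temp_noise, n_y)[:, None, None, None]
        tas += rng.normal(0.0, _LOCAL_T_NOISE, tas.shape)

    # precipitation: annual-total trend spread evenly over months
    pr = np.empty_like(tas)
    pr[:] = clim["pr"][None, :, :, None]
    pr += (elapsed * spec.precip_slope / 12.0)[:, None, None, None]
    if spec.precip_noise > 0:
        pr += rng.normal(0.0, spec.precip_noise / 12.0, n_y)[:, None, None, None]
        pr += rng.normal(0.0, _LOCAL_P_NOISE, pr.shape)
    pr = np.maximum(pr, 0.0)

    clt = np.empty_like(tas)
    clt[:] = clim["clt"][None, :, :, None]
    if spec.temp_noise > 0:
        clt += rng.normal(0.0, _LOCAL_CLT_NOISE, clt.shape)
    clt = np.clip(clt, 0.0, 1.0)

    co2 = _co2_trajectory(spec, years_arr)

    return xr.Dataset(
        data_vars={
            "tas": (("year", "month", "lat", "lon"), tas),
            "pr": (("year", "month", "lat", "lon"), pr),
            "clt": (("year", "month", "lat", "lon"), clt),
            "co2": (("year",), co2),
        },
        coords={
            "year": years_arr,
            "month": np.arange(1, 13),
            "lat": grid.lats,
            "lon": grid.lons,
            "land_mask": (("lat", "lon"), grid.land_mask),
            "cell_area_km2": (("lat", "lon"), grid.cell_areas_km2()),
        },
        attrs={"scenario": spec.name, "seed": seed, "resolution": grid.resolution},
    )


def generate_spinup(cube: xr.Dataset, n_years: int) -> xr.Dataset:
    """Cyclic replication of the cube's first 30 years for model spin-up.

    The first 30 years of monthly climate are tiled to cover ``n_years``
    (truncating the final cycle); CO2 is held at the first year's value.
    """
    if cube.sizes["year"] < 30:
        raise ValueError("spin-up requires a cube covering at least 30 years")
    base = cube.isel(year=slice(0, 30))
    reps = int(np.ceil(n_years / 30))
    idx = np.tile(np.arange(30), reps)[:n_years]
    spin = base.isel(year=idx)
    first_year = int(cube.year.values[0])
    spin = spin.assign_coords(year=np.arange(first_year - n_years, first_year))
    spin["co2"] = ("year", np.full(n_years, float(cube.co2.values[0])))
    return spin


def domain_mean_annual(cube: xr.Dataset, var: str) -> np.ndarray:
    """Area-weighted land-only domain mean annual series.

    Temperature (`tas`) is averaged over months; precipitation (`pr`) is the
    annual total (mm/yr); cloud is averaged.
    """
    w = cube.cell_area_km2.values * cube.land_mask.values
    w = w / w.sum()
    monthly = cube[var].values  # (year, month, lat, lon)
    annual = monthly.sum(axis=1) if var == "pr" else monthly.mean(axis=1)
    return np.einsum("yij,ij->y", annual, w)


# ---------------------------------------------------------------------------
# trend fitting

@dataclass(frozen=True)
class TrendEstimate:
    """OLS linear trend of an annual series."""

    slope: float
    intercept: float
    ci95: tuple[float, float]
    r_squared: float
    p_value: float
    n_years: int


def fit_trend(series: np.ndarray, years: np.ndarray | range) -> TrendEstimate:
    """Ordinary least-squares linear trend with a t-distribution 95% CI.

    A constant series is reported with slope 0 and (by convention) R^2 = 0,
    p = 1.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(list(years) if isinstance(years, range) else years, dtype=float)
    if y.size != t.size:
        raise ValueError("series and years must have equal length")
    if y.size < 3:
        raise ValueError("trend fit needs at least 3 points")
    if np.ptp(t) == 0:
        raise ValueError("years have zero variance")
    if np.ptp(y) == 0:
        return TrendEstimate(0.0, float(y[0]), (0.0, 0.0), 0.0, 1.0, y.size)
    res = stats.linregress(t, y)
    tcrit = stats.t.ppf(0.975, y.size - 2)
    return TrendEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci95=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_years=y.size,
    )


# ---------------------------------------------------------------------------
# persistence (plain netCDF3 via the scipy engine; same schema accepted back)

def save_cube(cube: xr.Dataset, path: str | Path) -> None:
    cube = cube.copy()
    # netCDF3 has no bool type
    cube["land_mask"] = cube.land_mask.astype("i1")
    cube.to_netcdf(path, engine="scipy")


def load_cube(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        cube = ds.load()
    cube["land_mask"] = cube.land_mask.astype(bool)
    return cube.set_coords(["land_mask", "cell_area_km2"])
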