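"""Ensemble summarization and uncertainty decomposition.

Coverage of a PFT is its FPC-weighted area (km^2) over the spherical grid.
Per scenario, the Monte Carlo ensemble over parameter sets is summarized
by the mean, variance and 10%/90% quantiles of coverage per year
("parameter-induced" uncertainty band).  Across the six IGSM scenarios,
which pair two emission pathways with low/median/high climate response,
the spread of ensemble means within an emission group measures
climate-response-induced uncertainty, and the difference between
emission-group means measures emission-induced uncertainty.

Quantiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate_synth import TrendEstimate, fit_trend

#: IGSM scenario names by emission group, ordered (median, low, high).
IGSM_GROUPS = {
    "reference": ("X901M", "X902L", "X903H"),
    "stabilization": ("X904M", "X905L", "X906H"),
}


class MissingGroupError(KeyError):
    """A required scenario is absent from the decomposition input."""


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-year ensemble statistics of one PFT's coverage under one scenario."""

    years: np.ndarray
    mean: np.ndarray       # km^2
    variance: np.ndarray
    q10: np.ndarray
    q90: np.ndarray
    n_samples: int

    def band_width(self) -> np.ndarray:
        return self.q90 - self.q10


@dataclass(frozen=True)
class UncertaintyComponents:
    """Per-year widths (km^2) of the three uncertainty sources."""

    years: np.ndarray
    parameter_width: np.ndarray          # mean over scenarios of q90 - q10
    parameter_width_by_scenario: dict[str, np.ndarray]
    climate_width: np.ndarray | None     # max |high/low - median| over groups
    emission_width: np.ndarray | None    # |reference mean - stabilization mean|


def coverage_area(fpc: np.ndarray, cell_area_km2: np.ndarray) -> float:
    """FPC-weighted area (km^2) of one PFT over the land cells."""
    fpc = np.asarray(fpc, dtype=float)
    if np.any((fpc < 0) | (fpc > 1)):
        raise ValueError("fpc must lie in [0, 1]")
    return float(np.sum(fpc * np.asarray(cell_area_km2, dtype=float)))


def coverage_series(fpc_traj: np.ndarray, cell_area_km2: np.ndarray) -> np.ndarray:
    """Per-year coverage (km^2) from a (year, cell) FPC trajectory."""
    return np.asarray(fpc_traj, dtype=float) @ np.asarray(cell_area_km2, dtype=float)


def ensemble_band(
    areas: np.ndarray,
    years: np.ndarray | None = None,
    q_low: float = 0.10,
    q_high: float = 0.90,
) -> EnsembleSummary:
    """Mean/variance/quantile band of a (sample, year) coverage matrix."""
    areas = np.asarray(areas, dtype=float)
    if areas.ndim != 2 or areas.shape[0] < 2:
        raise ValueError("need a (sample, year) matrix with at least 2 samples")
    if years is None:
        years = np.arange(areas.shape[1])
    return EnsembleSummary(
        years=np.asarray(years),
        mean=areas.mean(axis=0),
        variance=areas.var(axis=0, ddof=1),
        q10=np.quantile(areas, q_low, axis=0),
        q90=np.quantile(areas, q_high, axis=0),
        n_samples=areas.shape[0],
    )


def decompose_uncertainty(
    summaries: dict[str, EnsembleSummary],
) -> UncertaintyComponents:
    """Split projection spread into parameter, climate and emission parts.

    * parameter: the within-scenario q90-q10 band (per scenario, and
      averaged over the provided scenarios);
    * climate: within each IGSM emission group, the larger of
      |high-response mean - median mean| and |low-response mean - median
      mean|, maximized over the two groups (requires all 6 IGSM runs);
    * emission: |mean over the reference group - mean over the
      stabilization group| of the ensemble means.

    Components whose required scenarios are absent are returned as None;
    asking for them with a partially missing group raises
    :class:`MissingGroupError` only when *some but not all* of a group is
    present.
    """
    if not summaries:
        raise ValueError("no scenario summaries given")
    years = next(iter(summaries.values())).years
    widths = {name: s.band_width() for name, s in summaries.items()}
    parameter_width = np.mean(list(widths.values()), axis=0)

    igsm_needed = [n for grp in IGSM_GROUPS.values() for n in grp]
    have = [n for n in igsm_needed if n in summaries]
    climate_width = None
    emission_width = None
    if have:
        missing = sorted(set(igsm_needed) - set(have))
        if missing:
            raise MissingGroupError(
                "climate/emission decomposition needs all six IGSM scenarios; "
                f"missing: {', '.join(missing)}"
            )
        group_means = {}
        climate_parts = []
        for group, (median, low, high) in IGSM_GROUPS.items():
            m = summaries[median].mean
            climate_parts.append(
                np.maximum(
                    np.abs(summaries[high].mean - m),
                    np.abs(summaries[low].mean - m),
                )
            )
            group_means[group] = np.mean(
                [summaries[n].mean for n in IGSM_GROUPS[group]], axis=0
            )
        climate_width = np.maximum(*climate_parts)
        emission_width = np.abs(
            group_means["reference"] - group_means["stabilization"]
        )
    return UncertaintyComponents(
        years=years,
        parameter_width=parameter_width,
        parameter_width_by_scenario=widths,
        climate_width=climate_width,
        emission_width=emission_width,
    )


def regress_fpc_climate(
    per_cell_fpc: np.ndarray, per_cell_climate_stat: np.ndarray
) -> TrendEstimate:
    """OLS of mean FPC on a per-cell climate statistic (mean or trend of
    temperature or precipitation) across grid cells."""
    y = np.asarray(per_cell_fpc, dtype=float)
    x = np.asarray(per_cell_climate_stat, dtype=float)
    if y.size != x.size:
        raise ValueError("cell vectors must align")
    if y.size < 3:
        raise ValueError("regression needs at least 3 cells")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance regressor")
    return fit_trend(y, x)


def summary_frame(
    summaries: dict[tuple[str, str], EnsembleSummary]
) -> pd.DataFrame:
    """Tidy (year, pft, scenario, statistic, value) table of ensemble bands.

    Keys of ``summaries`` are (scenario, pft_id) pairs.
    """
    records = []
    for (scenario, pft), s in summaries.items():
        for stat in ("mean", "variance", "q10", "q90"):
            values = getattr(s, stat)
            for year, value in zip(s.years, values):
                records.append(
                    {
                        "year": int(year),
                        "pft": pft,
                        "scenario": scenario,
                        "statistic": stat,
                        "value": float(value),
                    }
                )
    return pd.DataFrame.from_records(records)
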