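# Methods

This note documents the models, defaults and numerical choices behind
`dvmuq`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Parameter space and Latin hypercube sampling

Thirteen vegetation-model parameters are treated as independent uniform
random variables on published ranges (shipped in
`src/dvmuq/data/parameters.csv`). Sampling follows the classic
three-step Latin hypercube procedure: split each range into *n*
equal-width (hence equal-probability) strata, draw one value uniformly
inside every stratum, and pair the per-parameter draws by independent
uniform random permutations. We deliberately use a *uniform draw within
each stratum* (not stratum midpoints) and *pure random pairing* (no
correlation-reduction optimization). Strata are half-open `[a, b)` with
the final stratum closed, which makes occupancy counting unambiguous;
`check_stratification` verifies exactly one sample per stratum per
column. Sampling is driven by `numpy.random.default_rng(seed)` and is
bitwise reproducible.

The shipped table prints a degenerate range `[0.01, 0.01]` for
`k_mort1`, the asymptotic maximum mortality rate. A degenerate range
would make the parameter unsampleable even though it carries nonzero
importance in published rankings, so we treat it as a typographical
error: the loader repairs it to `[0.01, 0.1]` — bracketing the standard
value 0.05 — emits a prominent warning, and accepts an alternative range
as an argument. `k_rp`'s standard value 1.6 sits on its range boundary
`[1.33, 1.6]`; it is accepted as printed.

## Synthetic climate scenarios

No observational or GCM archives ship with the package. The generator
emulates only the statistical structure the analysis depends on:

* **Trends.** Each scenario imposes its configured linear trend
  (anchored at 2001; zero before) on the *area-weighted domain mean* of
  the annual temperature and precipitation series. Area weighting uses
  spherical cell areas `R²·Δλ·(sin φ₂ − sin φ₁)` with R = 6371 km.
  With noise off, an OLS fit of the domain-mean series returns the
  configured slope to round-off — this exactness is a tested contract.
* **Latitude amplification.** The six IGSM-family scenarios warm faster
  at higher latitudes. The local warming rate is
  `slope · (1 + a·(φ − φ̄))` with `a = 0.015 /degree` and `φ̄` the
  area-weighted mean latitude, so the modulation is zero-mean under the
  area weights and the domain-mean trend is unchanged. The four
  IPCC-family scenarios warm uniformly.
* **Interannual noise.** A domain-wide annual anomaly (shared across
  cells, so it behaves like large-scale variability) plus small
  independent per-cell-month noise. The anomaly standard deviation is
  derived per scenario from the published regression R² of its 100-year
  trend: for y = s·t + ε, R² = s²·var(t)/(s²·var(t) + σ²), hence
  σ = s·√(var(t)·(1/R² − 1)). The one printed "1.00 (rounded)" R² is
  taken as 0.995. Precipitation is clipped at zero and cloud fraction at
  [0, 1] after noise (with noise off no clipping ever binds, preserving
  trend exactness).
* **CO₂.** Linear interpolation between the scenario's 2001 and 2100
  endpoints; before 2001, linear from 296 ppmv (1901). Exponential
  alternatives were considered and rejected for transparency — only the
  endpoints are constrained anyway.
* **Baseline climatology.** Idealized smooth fields: mean annual
  temperature 8 °C at 45°N falling 0.55 °C per degree latitude; a
  sinusoidal seasonal cycle peaking in July with half-amplitude 16 °C at
  45°N decreasing by 0.08 °C per degree; monthly precipitation
  45 mm/month at 45°N decreasing to a 10 mm floor with a ±10 mm seasonal
  cycle; cloud fraction 0.6 ± 0.1. These values were chosen once to put
  boreal, temperate and tundra bioclimates in their observed latitudinal
  order over the domain; they are emulation constants, not calibrated
  quantities.
* **Spin-up forcing.** Cyclic replication of the cube's first 30 years
  of monthly climate (CO₂ held at the first year's value), mirroring the
  standard practice of recycling an early-period climatology until the
  vegetation reaches quasi-equilibrium.

What the generator does *not* emulate: realistic spatial covariance,
land–sea geometry, daily weather, humidity/radiation physics. Tests that
pass on these synthetic fields demonstrate correctness of the pipeline's
statistics and the simulator's structural behaviour, not predictive
skill on real climate data.

## The reduced-form vegetation simulator

The simulator keeps the published structural rules of large dynamic
global vegetation models while replacing the process physics
(biochemical photosynthesis, soil hydrology, soil carbon, fire) with a
compact surrogate; every surrogate equation lives in
`src/dvmuq/dgvm_core.py`.

**State.** Each of six PFTs (three temperate tree types TNE/TBE/TBS, two
boreal types BNE/BSW, and C3 perennial grass CPG) is an average
individual — carbon pools (leaf, sapwood, heartwood, root; grasses leaf
and root only), height, crown area, LAI — plus a population density per
m². Population FPC is `density · crown_area · (1 − e^(−k_beer·LAI))`,
capped at 1.

**Annual loop** (per cell): bioclimatic gating → production →
allocation/allometry → mortality → establishment → cover-constraint
enforcement.

* *Bioclimatic gating.* Establishment requires the coldest-month mean
  temperature within `[tc_min_est, tc_max_est]` and GDD₅ ≥ `gdd5_min`;
  survival fails when the warmest-month mean exceeds `tw_max` or the
  coldest month falls below `tc_min_surv`. Means are over a rolling
  20-year window. Limit values (in `src/dvmuq/data/pfts.yml`) are
  idealized representatives of each strategy chosen once so that the
  baseline climatology produces boreal forest at mid latitudes, tundra
  grass polewards, and temperate trees only after substantial warming.
  Heat stress (current-year warmest month above `tw_max`) adds a
  configurable extra mortality rate (default 0.3/yr).
* *Production.* Monthly light-limited rate
  J_E = α_C3 · f(T) · PAR(φ, month, cloud) · FPC and capacity-limited
  rate J_C = c · f(CO₂) · w(P) are colimited by the smaller root of
  θx² − (J_E+J_C)x + J_E·J_C = 0 and summed over months;
  GPP = α_a · Σφ; NPP = max(0, GPP − R_maint)·(1 − r_growth), with
  maintenance respiration proportional to living biomass. The CO₂
  factor is a saturating Michaelis form normalized to 1 at 370 ppmv
  (monotone by construction, so more CO₂ never lowers NPP); the water
  scalar is w = P/(P + 300 mm) on annual precipitation. The quadratic
  uses the stable smaller-root form with the θ → 0 harmonic limit.
* *Allometry.* Stem diameter from a cylinder of stem carbon at the
  configured wood density; height = k_allom2·d^k_allom3
  (k_allom2 = 40); crown area = min(k_allom1·height^k_rp, CA_max);
  leaf area capped at k_la:sa times the sapwood cross-section; LAI =
  leaf area / crown area. Grasses occupy unit patches with LAI =
  leaf·SLA.
* *Mortality.* Fractional density loss k_mort1/(1 + k_mort2·greff),
  greff being NPP per unit leaf area — the simplest form consistent
  with an "asymptotic maximum" scaled down by growth efficiency — plus
  the heat-stress increment; bioclim-failing PFTs are removed outright.
* *Establishment.* Permitted woody PFTs gain est_max·(1 − woody FPC)
  saplings/m², attenuated linearly from 1 at woody cover 0.95 to 0 at
  1.0 (canopy closure); grass establishes into space free of any cover.
  Sapling pools merge into the average individual by density weighting.
* *Competition constraint.* If woody cover alone exceeds 1 it is
  rescaled proportionally (density with it); grass cover then yields to
  whatever space remains — herbaceous biomass is reduced first,
  reflecting woody competitive dominance.

**Directionality by construction.** The establishment step adds the
saplings' FPC contribution explicitly and the mortality step scales FPC
down with density, so "establishment never decreases FPC" and
"mortality never increases FPC" hold to machine precision and are
asserted per step in tests; allometry is the only step that recomputes
FPC from pools.

**Scale and spin-up.** The annual step is vectorized across cells;
a 100-cell, 150-year, six-PFT run takes well under a second. Runs start
from bare ground with a default 200-year spin-up (100 in most tests) —
chosen as the desk-scale point where FPC trajectories flatten under the
cyclic climatology (full-scale studies use a thousand years); the
equilibrium tolerance knobs sit in `SimConfig`. The simulator is
deterministic; the `seed` argument exists for interface symmetry.

## Sensitivity statistics

Pearson correlation, partial correlation and PRCC are implemented
directly from their definitions rather than wrapped from a statistics
package: the partial correlation of x_j with y is the correlation of the
two residual vectors after regressing each (with intercept — without it
the construction is ill-defined for uncentered ranks) on the remaining
inputs; PRCC applies this to average-rank-transformed data, which makes
it exactly invariant under strictly monotone transforms. Zero variance
raises an explicit error rather than returning 0; constant columns yield
NaN ("missing") and are dropped from the control design so the remaining
coefficients stay defined; rank-deficient designs raise unless a
pseudo-inverse fallback is requested. Tests verify equivalence to an
independent normal-equation oracle (|Δ| < 10⁻¹⁰) and to
`pingouin.partial_corr(method="spearman")`.

Importance ranking orders by |PRCC| descending; ties break positive
first, then input order (cosmetic, matching how published tables order
equal-magnitude pairs). Per-cell PRCC maps mask cells where the PFT
never appears in any ensemble member (NaN, not 0); cells where it
appears in only some members are retained, variance permitting.

## Uncertainty summarization and decomposition

Coverage is FPC-weighted area (km²) — not presence-thresholded — because
the target quantity is a continuous trajectory; quantiles use linear
interpolation between order statistics (NumPy's default), frozen in
tests. Per scenario, the 10–90 % band of the Monte Carlo ensemble is the
parameter-induced uncertainty. Across the six IGSM scenarios the
climate component is max(|high − median|, |low − median|) of
*ensemble-mean* coverage within each emission group (parameter spread is
averaged out first so components are not double-counted), and the
emission component is the absolute difference of the two emission-group
means. Identical inputs across scenarios give exactly zero climate and
emission components. A normalized "band width ÷ ensemble mean" per year
is computable from the tidy outputs; we report absolute widths because
the normalization convention (per year vs. century-averaged) is
ambiguous in the literature this design follows.

## Pipeline determinism

Every stage seed derives from the master seed via
`SeedSequence([master, stage_code, index])` reduced below 2³¹, so the
Latin hypercube draw is independent of the scenario list and each stage
can be reproduced in isolation. Re-running a config reproduces every
artifact byte for byte; the manifest records seeds, a config hash and
the package version. Desk-scale defaults (coarse grid, tens of samples)
run in minutes; the full-scale configuration (0.5° grid, 1000 samples ×
10 scenarios) uses the identical code path.

## Known limitations

* The simulator omits fire, permafrost, nitrogen limitation, land use
  and migration lags; its bioclimatic limits and allocation constants
  are illustrative, so absolute coverages are not comparable to
  observations — only structural and ordinal behaviour is meaningful.
* PRCC assumes monotone input–output relations and near-independent
  inputs; no significance tests or bootstrap intervals are attached.
* NetCDF output uses the classic (netCDF3, via the scipy engine) format.
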