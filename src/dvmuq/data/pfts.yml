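# Six plant functional types (PFTs) competing in the northern high latitudes.
#
# Bioclimatic limits (degC / degree-days) gate establishment and survival:
#   tc_min_est / tc_max_est : coldest-month 20-yr mean window for establishment
#   gdd5_min                : minimum growing degree-days above 5 degC
#   tw_max                  : warmest-month survival limit (heat stress above it)
#   tc_min_surv             : coldest-month survival floor
# Fixed (unsampled) constants:
#   k_allom2      : height-diameter allometry coefficient (height = k2 * d^k3)
#   sla           : specific leaf area, m2 per kgC
#   wood_density  : stem carbon density, kgC/m3
#   maint_resp    : maintenance respiration per kgC living biomass per year
# Values are idealized representatives of each strategy, not a calibration.
- id: TNE
  name: temperate needleleaved evergreen
  woody: true
  phenology: evergreen
  tc_min_est: -2.0
  tc_max_est: 22.0
  gdd5_min: 900.0
  tw_max: .inf
  tc_min_surv: -7.0
  k_allom2: 40.0
  sla: 10.0
  wood_density: 200.0
  maint_resp: 0.03
- id: TBE
  name: temperate broadleaved evergreen
  woody: true
  phenology: evergreen
  tc_min_est: 3.0
  tc_max_est: 18.8
  gdd5_min: 1200.0
  tw_max: .inf
  tc_min_surv: -1.0
  k_allom2: 40.0
  sla: 12.0
  wood_density: 200.0
  maint_resp: 0.03
- id: TBS
  name: temperate broadleaved summergreen
  woody: true
  phenology: summergreen
  tc_min_est: -17.0
  tc_max_est: 15.5
  gdd5_min: 1200.0
  tw_max: .inf
  tc_min_surv: -22.0
  k_allom2: 40.0
  sla: 22.0
  wood_density: 200.0
  maint_resp: 0.035
- id: BNE
  name: boreal needleleaved evergreen
  woody: true
  phenology: evergreen
  tc_min_est: -32.5
  tc_max_est: -2.0
  gdd5_min: 600.0
  tw_max: 23.0
  tc_min_surv: -37.5
  k_allom2: 40.0
  sla: 9.0
  wood_density: 200.0
  maint_resp: 0.025
- id: BSW
  name: boreal summergreen woody
  woody: true
  phenology: summergreen
  tc_min_est: -40.0
  tc_max_est: -2.0
  gdd5_min: 350.0
  tw_max: 23.0
  tc_min_surv: -45.0
  k_allom2: 40.0
  sla: 20.0
  wood_density: 200.0
  maint_resp: 0.025
- id: CPG
  name: C3 perennial grass
  woody: false
  phenology: grass
  tc_min_est: -45.0
  tc_max_est: 15.5
  gdd5_min: 50.0
  tw_max: .inf
  tc_min_surv: -50.0
  k_allom2: 0.0
  sla: 30.0
  wood_density: 0.0
  maint_resp: 0.05
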