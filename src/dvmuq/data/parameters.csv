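# Key sampled vegetation-model parameters: standard value and uniform range.
# The k_mort1 range is degenerate as printed in the source table; the loader
# repairs it (see parameter_space.default_parameter_table).
name,standard,lower,upper,description
k_beer,0.5,0.4,0.7,Light extinction coefficient
theta,0.7,0.2,0.996,Photosynthesis colimitation shape parameter
k_mort1,0.05,0.01,0.01,Asymptotic maximum mortality rate (1/yr)
k_mort2,0.5,0.2,0.5,Growth efficiency mortality scalar
alpha_a,0.5,0.3,0.7,Photosynthesis scaling parameter (leaf to canopy)
alpha_C3,0.08,0.02,0.125,Intrinsic quantum efficiency of CO2 uptake in C3 plants
k_allom1,100,75,125,Crown area allometry coefficient (crown = k_allom1 * height^k_rp)
k_allom3,0.67,0.5,0.8,Height allometry exponent (height = k_allom2 * diameter^k_allom3)
k_rp,1.6,1.33,1.6,Crown area allometry exponent
k_la_sa,4000,2000,8000,Leaf to sapwood area ratio
CA_max,15.0,7.5,30.0,Maximum woody PFT crown area (m2)
r_growth,0.25,0.15,0.4,Growth respiration per unit NPP
est_max,0.12,0.05,0.3,Maximum sapling establishment rate (1/m2/yr)
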