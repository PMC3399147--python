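# Built-in climate-change scenarios, 2001-2100: least-squares trend slopes of the
# domain-mean (45-90N) annual air temperature and precipitation, printed regression
# R^2, and CO2 endpoints. IGSM scenarios pair an emission pathway (reference /
# stabilization) with a low/median/high climate-system response.
name,family,emission_group,response_class,temp_slope,temp_r2,precip_slope,precip_r2,co2_start,co2_end
A1FI,IPCC-smooth,ipcc,n/a,0.136,0.98,0.166,0.98,368.448,925.531
A2,IPCC-smooth,ipcc,n/a,0.106,0.98,0.127,0.98,368.949,818.891
B1,IPCC-smooth,ipcc,n/a,0.056,0.99,0.073,0.99,368.936,531.371
B2,IPCC-smooth,ipcc,n/a,0.069,0.995,0.086,0.995,368.903,603.702
X901M,IGSM-latitude-amplified,reference,median,0.073,0.97,0.117,0.97,370.957,911.319
X902L,IGSM-latitude-amplified,reference,low,0.057,0.98,0.087,0.97,371.228,947.953
X903H,IGSM-latitude-amplified,reference,high,0.094,0.96,0.148,0.95,371.281,905.128
X904M,IGSM-latitude-amplified,stabilization,median,0.019,0.92,0.035,0.87,370.957,476.506
X905L,IGSM-latitude-amplified,stabilization,low,0.013,0.85,0.023,0.80,371.228,490.717
X906H,IGSM-latitude-amplified,stabilization,high,0.027,0.96,0.047,0.93,371.281,472.149
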