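# Cefazolin delivery study: 1 g IV infusion (infusion time not reported in
# the source study; 30 min assumed) in 31-year-old subjects at 39 weeks GA,
# default body weight for a typical 31-year-old female at 39 GA.
name: cz_39wk_1g
drug: cefazolin
subject: {age: 31, weight: 78, height: 165, gestational_age_weeks: 39, sex: female}
regimen: {dose_mg: 1000, times_h: [0.0], infusion_duration_h: 0.5}
t_end_h: 24
provenance: "printed study description: 1 g IV infusion (30 min assumed), 39 weeks GA"
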