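# Cefazolin pregnant arm: 0.5 g IV bolus in a 25-year-old, 62 kg female at
# 25 weeks GA (weight gain ~6 kg per the implemented curve).
name: cz_25wk
drug: cefazolin
subject: {age: 25, weight: 62, height: 160, gestational_age_weeks: 25, sex: female}
regimen: {dose_mg: 500, times_h: [0.0], infusion_duration_h: 0.0}
t_end_h: 24
provenance: "printed study description: 0.5 g IV bolus at 25 weeks GA, 62 kg, +6 kg weight gain"
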