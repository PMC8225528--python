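# Postpartum (non-pregnant reference) study: 0.75 g IV bolus in a
# 30-year-old, 61.7 kg female; MRP4 Vmax reduced five-fold to match the
# observed urinary excretion.
name: cfx_postpartum
drug: cefuroxime
subject: {age: 30, weight: 61.7, height: 163, gestational_age_weeks: 0, sex: female}
regimen: {dose_mg: 750, times_h: [0.0], infusion_duration_h: 0.0}
postpartum: true
t_end_h: 24
provenance: "printed study description: 0.75 g IV bolus, postpartum"
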