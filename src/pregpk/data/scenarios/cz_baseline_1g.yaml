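# Cefazolin baseline model development: 1 g IV bolus in a 32-year-old,
# 79 kg male subject.
name: cz_baseline_1g
drug: cefazolin
subject: {age: 32, weight: 79, height: 178, gestational_age_weeks: 0, sex: male}
regimen: {dose_mg: 1000, times_h: [0.0], infusion_duration_h: 0.0}
t_end_h: 24
provenance: "printed study description: 1 g IV bolus, healthy male"
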