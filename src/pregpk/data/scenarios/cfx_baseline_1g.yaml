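# Baseline healthy-volunteer model development study: 1 g IV infusion over
# 3 min in 30-year-old, 70 kg fasted male subjects (0.25 and 0.5 g arms are
# the same scenario with dose_mg changed).
name: cfx_baseline_1g
drug: cefuroxime
subject: {age: 30, weight: 70, height: 178, gestational_age_weeks: 0, sex: male}
regimen: {dose_mg: 1000, times_h: [0.0], infusion_duration_h: 0.05}
t_end_h: 48
provenance: "printed study description: healthy fasted volunteers, 0.25/0.5/1 g IV infusion 3 min"
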