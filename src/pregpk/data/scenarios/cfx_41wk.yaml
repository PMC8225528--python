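# Delivery study at 41 weeks GA: 0.75 g IV bolus; fetal plasma and amniotic
# fluid sampled at delivery.  Placental PStc values were calibrated at this
# GA (maternal 15.9 mL/s, fetal 32,400 mL/s).
name: cfx_41wk
drug: cefuroxime
subject: {age: 30, weight: 61.7, height: 163, gestational_age_weeks: 41, sex: female}
regimen: {dose_mg: 750, times_h: [0.0], infusion_duration_h: 0.0}
# the postpartum-calibrated MRP4 Vmax adjustment carries over to the
# pregnant simulations of this cohort
postpartum: true
t_end_h: 24
provenance: "printed study description: 0.75 g IV bolus at 41 weeks GA, cord blood + amniotic fluid"
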