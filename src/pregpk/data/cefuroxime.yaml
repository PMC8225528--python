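# Cefuroxime (CFX) model inputs.  Every numeric leaf carries a provenance
# tag: printed (stated in the source text), literature (standard reference
# value), fitted (output of this package's calibration workbench), assumed
# (documented modeling assumption), calibrated (tuned to profile shape).
name: cefuroxime
molecular_weight: {value: 424.39, tag: literature}
logp: {value: -0.16, tag: literature}
pka_list:
  - {value: 2.45, tag: literature, type: acid}
fup: {value: 0.67, tag: literature}
blood_plasma_ratio: {value: 0.55, tag: literature}
fup_fetal: {value: 0.75, tag: assumed}   # lower fetal albumin -> higher free fraction
transporters:
  - name: OAT3
    location: kidney basolateral
    direction: influx
    km_um: {value: 65.0, tag: literature}
    vmax_ug_h: {value: 665000.0, tag: fitted}
    vmax_cv: {value: 1.0, tag: printed}     # 100% CV from kidney protein abundance
  - name: MRP4
    location: kidney apical
    direction: efflux
    km_um: {value: 65.0, tag: assumed}      # set equal to OAT3 (no measured affinity)
    vmax_ug_h: {value: 1330000.0, tag: fitted}
    vmax_cv: {value: 1.0, tag: printed}
# Postpartum refinement: MRP4 Vmax reduced five-fold to match urinary data.
postpartum_mrp4_factor: {value: 0.2, tag: printed}
tissue_model_map:
  kidney: permeability
  placenta: permeability
pstc_map:
  kidney_capillary: {value: 1.0, tag: assumed, units: mL/s/mL}
  kidney_cell: {value: 0.05, tag: assumed, units: mL/s/mL}
  placenta_maternal: {value: 15.9, tag: printed, units: mL/s}
  placenta_fetal: {value: 32400.0, tag: printed, units: mL/s}
# GA at which the absolute placental PStc values were calibrated; they are
# rescaled with placental sub-tissue volume at other GAs.
pstc_reference_ga: 41
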