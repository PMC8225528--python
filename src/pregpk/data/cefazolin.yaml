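# Cefazolin (CZ) model inputs.  Provenance tags as in cefuroxime.yaml.
name: cefazolin
molecular_weight: {value: 454.51, tag: literature}
logp: {value: -0.58, tag: literature}
pka_list:
  - {value: 2.22, tag: literature, type: acid}
# Average compromise value for the saturable plasma protein binding (the
# binding model itself is out of scope).
fup: {value: 0.09, tag: printed}
blood_plasma_ratio: {value: 0.55, tag: assumed}
fup_fetal: {value: 0.25, tag: assumed}
transporters:
  - name: OAT3
    location: kidney basolateral
    direction: influx
    km_um: {value: 117.0, tag: printed}     # Ki for estrone-sulfate uptake inhibition
    vmax_ug_h: {value: 958000.0, tag: fitted}
    vmax_cv: {value: 1.0, tag: printed}
  - name: MRP4
    location: kidney apical
    direction: efflux
    km_um: {value: 80.9, tag: printed}      # membrane-vesicle measurement
    vmax_ug_h: {value: 1916000.0, tag: fitted}
    vmax_cv: {value: 1.0, tag: printed}
tissue_model_map:
  kidney: permeability
  placenta: permeability
pstc_map:
  # One specific PStc fitted on fetal cord-blood data; also applied to the
  # kidney capillary barrier.
  kidney_capillary: {value: 1.0, tag: printed, units: mL/s/mL}
  kidney_cell: {value: 0.05, tag: assumed, units: mL/s/mL}
  placenta_maternal: {value: 1.0, tag: printed, units: mL/s/mL}
  placenta_fetal: {value: 1.0, tag: printed, units: mL/s/mL}
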