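"""Unit conventions and conversion factors.

Repo-wide conventions: volumes L, flows L/h, amounts ug, concentrations
ug/mL (== mg/L), time h, gestational age weeks.  GFR is reported in
mL/min at the interface and converted to L/h internally.  Permeability-
surface area products (PStc) are quoted in mL/s and converted to L/h.
Amniotic pathway rates are quoted in L/day and converted to L/h.
"""

ML_MIN_TO_L_H = 0.06        # 1 mL/min = 0.06 L/h
ML_S_TO_L_H = 3.6           # 1 mL/s   = 3.6  L/h
L_DAY_TO_L_H = 1.0 / 24.0   # 1 L/day
MG_TO_UG = 1000.0


def km_um_to_ug_ml(km_um: float, mw: float) -> float:
    """Convert a Michaelis constant from uM to ug/mL given MW in g/mol."""
    return km_um * mw / 1000.0
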