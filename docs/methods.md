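# Methods

This note documents the science implemented in `pregpk`: the model
equations, the parameter defaults and their units, the synthetic-data
machinery used for testing, and the design choices made where the design
was genuinely open.

Units are fixed repo-wide: volumes L, flows L/h, amounts µg,
concentrations µg/mL (≡ mg/L), time h, gestational age (GA) weeks. GFR is
expressed in mL/min at interfaces and converted internally; permeability–
surface area products (PStc) are quoted in mL/s (×3.6 → L/h); amniotic
pathway rates in L/day (÷24 → L/h).

## 1. Non-pregnant baseline physiology

The baseline generator produces a reference adult from age, body weight,
height and sex. Organ masses are fixed fractions of body weight (heart
0.47%, spleen 0.26%, liver 2.4%, lung 0.76%, kidney 0.44%, skin 4.7%,
muscle 29% female / 40% male, adipose 32.5% / 21%), brain is a fixed mass
(1.30 / 1.45 kg), the non-pregnant uterus is 80 g. Plasma volume is
40 mL/kg (female) / 45 mL/kg (male); hematocrit 0.40 / 0.44. Cardiac
output is allometric, CO = 15·BW^0.75 L/h of blood; regional blood flows
are standard fractions of CO (kidney 19%, brain 12%, muscle 17%, liver
arterial 6.5%, …) with the rest-of-body compartment absorbing the
remainder, so parallel plasma flows sum exactly to CO·(1 − hct). Baseline
GFR is 110 (female) / 125 (male) mL/min at the reference weight, scaled by
(BW/ref)^0.75. These are standard reference-human values; they replace a
proprietary population-physiology generator and are locked by regression
tests.

## 2. Gestational-age dependence

The exact coefficient tables behind published pregnancy physiology
polynomials are not reproduced here; each GA-dependent quantity is instead
a smooth anchored fit through the landmark values those publications
encode. Two functional families are used, chosen so that every increment
evaluates to exactly 0.0 at GA = 0 (the non-pregnant reduction is bitwise,
not approximate):

* saturating ramps `f(GA) = Δ·(1 − exp(−(GA/τ)²))` for plasma volume
  (Δ = +47%, τ = 20), hematocrit (−15%, τ = 20), GFR (+50%, τ = 15),
  albumin (−22%, τ = 25) and α1-acid glycoprotein (−15%, τ = 25), brain
  volume (−3%, τ = 25);
* polynomial growth for weight gain
  (`0.0285·GA + 0.0084615·GA²` kg — ≈1.8 kg at 13 wk, 6.0 kg at 25 wk,
  14.7 kg at 40 wk, the averaged non-obese gestational weight-gain
  trajectory), uterus (`0.08 + 0.0006375·GA²` kg → 1.10 kg at term),
  whole placenta (`0.65·(GA/40)²` L, split 50/50 into maternal- and
  fetal-facing sub-tissues), kidney (linear, +30% at 40 wk).

Skin, adipose and cardiac output are recomputed from the *current* body
weight (pre-pregnancy + gain) with the baseline allometric rules. The
plasma free fraction of albumin-bound drugs rises with gestation through
the albumin dilution, fup′ = fup / (fup + (1 − fup)·albumin_ratio).

Fetal curves: weight is a rescaled exponential-quadratic growth curve
pinned to 0 at GA 0 and 3.32 kg at 40 wk (the reference birth weight used
throughout for rate normalization); blood volume is 80 mL/kg; hematocrit
rises 0.30 → 0.47 and fetal GFR 0 → ~4 mL/min (1.2 mL/min/kg at term)
linearly between the urine-production onset at 9 weeks and term — fetal
GFR is identically zero before 9 weeks. Amniotic fluid volume follows a
gamma-shaped curve `3.473e-5·GA⁴·exp(−GA/8.5)` L (peak 0.85 L at ~34 wk,
0.80 L at 40 wk). Fetal quantities below 12 weeks are downward
extrapolations of these same smooth forms, floored at zero.

## 3. Amniotic fluid exchange

Four active pathways and one passive pathway connect the amniotic pool:
fetal urine (fetal blood → amniotic fluid), lung/oral secretion (fetal
tissue → AF), swallowing (AF → fetal tissue), the intramembranous pathway
(AF → fetal blood), and passive transmembranous exchange with the uterine
wall driven by the free-concentration difference. Homeostasis is imposed
by construction: active inflow equals active outflow at every GA.

The term reference turnover is 1.46 L/day at 3.32 kg. The split between
pathways is not uniquely determined by the printed total; the defaults —
urinary 1.00, secretion 0.46, swallowing 0.80, intramembranous
0.66 L/day — are the averaged ovine literature values rebalanced to close
the budget exactly, and are overridable per scenario. (The printed total
1.46 is itself not the arithmetic mean of the two published sums 1.26 and
1.51; the total is treated as the authoritative constraint.) The passive
transmembranous constant has no printed value; the default 0.24 L/day at
reference weight is calibrated to the shape of the term amniotic-fluid
profile and tagged `calibrated`. All rates scale linearly with fetal
weight and the four active rates are zero before 9 weeks, leaving
transmembranous exchange as the only early-gestation pathway.

Drug transport convention: bulk-fluid pathways (urine, swallowing,
secretion) entrain drug at the total concentration of their source
compartment; the membrane-mediated intramembranous and transmembranous
pathways act on free concentrations. Drug in fetal urine enters the
amniotic fluid at the fetal renal clearance, fetal fup × fetal GFR.
Amniotic fluid is a single well-mixed compartment whose volume is imposed
by the physiology curve (not integrated from the fluid fluxes, avoiding
drift against the published volume curve); fluid and drug simulations are
run at a fixed GA, which is appropriate for the hours-scale dosing studies
modeled here.

## 4. Tissue partitioning

Perfusion-limited tissues use a Rodgers–Rowland-family equation for acids/
neutrals/very weak bases:

    Kpu = f_EW + f_IW·(X/Y) + [P·f_NL + (0.3P + 0.7)·f_NP]/Y
          + Ka_alb·(tissue/plasma albumin ratio)
    Kp  = Kpu · fup

with P = 10^logP, X and Y the ionization factors at intracellular pH 7.0
and plasma pH 7.4, and the albumin association constant derived from fup
itself, Ka_alb = max(1/fup − 1 − plasma lipid term, 0) — i.e. residual
plasma binding is projected into the tissue interstitium instead of
requiring a measured tissue-binding input. Permeability-limited tissues
use an extracellular partition: free drug in extracellular water plus
binding to interstitial albumin at half the plasma level,
`Kp_ec = fup·f_EW + 0.5·(1 − fup)`. The tissue composition table
(`data/tissue_composition.csv`) carries approximate standard human
compositions and is versioned; lumped rows (uterus, placenta, rest,
fetal tissue) are assembled from the muscle/spleen entries.

Both methods are positive and continuous in logP and fup; for the two
shipped polar acids all perfusion Kp values fall in 0.05–5.

## 5. The compartment engine

The engine integrates amounts (µg) over a graph of well-stirred
compartments. All convective, permeability, clearance and amniotic
transfers are linear in the source amount and assembled into a constant
matrix; transporters contribute Michaelis–Menten terms
`v = Vmax·Cu/(Km + Cu)` on the unbound source concentration (Km converted
from µM via the molecular weight). Each compartment carries a free-factor
φ mapping total to unbound concentration: fup for plasma spaces, fup/Kp
for tissues, 1 for protein-free fluids (filtrate, amniotic fluid).

Integration is piecewise BDF (SciPy `solve_ivp`) with an analytic
Jacobian, relative tolerance 1e-8 and absolute tolerance 1e-10 µg, with
breakpoints at every dose and infusion boundary. Boluses are instantaneous
state increments; samples at a dose time are post-dose, consistent with
the cumulative-administration convention. Elimination sinks (urine) are
amount-only compartments, so mass balance is an emergent property that is
checked (≤1e-6 relative, typically ~1e-14) rather than imposed.
Negative undershoot beyond −1e-6 µg raises a diagnostic error with a state
dump; smaller undershoot is clipped to zero in the outputs. Degenerate
one- and two-compartment graphs match the closed-form solutions to better
than 0.1% (regression-tested).

## 6. Maternal–fetal model assembly

The kidney is permeability-limited with vascular (15%), extracellular
(25%), intracellular (59%) and filtrate (1%) sub-spaces. A porous-capillary
PS (1 mL/s/mL tissue, non-limiting) joins vascular and extracellular
space; a passive basolateral PS of 0.05 mL/s/mL joins extracellular space
and cell. OAT3 moves drug vascular → cell, MRP4 cell → filtrate;
filtration (fup × GFR on kidney plasma) feeds the filtrate, which drains
to urine at the filtration flow. The basolateral PS default was chosen
between the two transporters' intrinsic clearances so that *both* carry
identifiable leverage on net secretion — with a negligible leak the MRP4
step has no effect, with a very large one OAT3 has none; the value is
tagged `assumed` and the cefazolin placental fit (1 mL/s/mL) bounds it
from above. Transporter Vmax values are defined at the 0.308 L reference
kidney and scale linearly with kidney volume (constant expression per gram
of tissue) — this is the mechanism by which pregnancy increases active
secretion. Vmax values themselves are calibration outputs, fitted with the
package's own workbench to literature clearance targets (cefuroxime
11.4 L/h at 70 kg; cefazolin 3.6 L/h at 79 kg) and stored in the fixtures
tagged `fitted`. The cefuroxime model additionally carries the
postpartum-calibrated five-fold MRP4 Vmax reduction, applied to both the
postpartum and the pregnant simulations of that cohort.

The placenta is split into maternal- and fetal-facing sub-tissues, each
perfused from its own circulation, coupled by their PStc values in series.
Absolute PStc values (cefuroxime: 15.9 mL/s maternal, 32,400 mL/s fetal,
calibrated at 41 weeks) rescale with sub-tissue volume at other GAs;
specific values (cefazolin: 1 mL/s/mL) multiply the sub-tissue volume
directly. At 32,400 mL/s the fetal-side barrier is effectively
non-limiting, and 15.9 mL/s (57 L/h) exceeds the maternal placental plasma
flow, so for cefuroxime the transplacental transfer is close to
flow-limited; this is why the parameter-recovery experiments for PStc are
run in the genuinely permeability-limited regime (~1 mL/s). The fetus has
venous/arterial plasma (⅔/⅓ of fetal plasma volume), a lumped
perfusion-limited tissue, and the fetal placenta, in a single
cardiac-output loop (CO_fetal = 20·w^0.75 L/h blood, 40% umbilical).
Observed "fetal venous return" and cord-blood data both map onto the fetal
venous compartment. GA = 0 builds contain no fetal machinery at all and
are bitwise identical to a directly constructed non-pregnant model.

## 7. Fitting, population simulation, synthetic data

Parameter estimation is bounded trust-region least squares on
log-concentration residuals with log-transformed parameters (scale-free,
positivity guaranteed); approximate CVs come from the Gauss–Newton
covariance and parameters with numerically flat residual columns trigger a
non-identifiability warning. Virtual populations draw height/weight from a
bivariate lognormal (correlation 0.5 on the log scale — the distribution
family is named in the source literature but not parameterized there),
GA uniformly over the study range, and mean-1 lognormal multipliers for
GFR, plasma volume and cardiac output (CV 15% each, the documented
10–20% assumption band, editable) and for each transporter Vmax (CV 100%,
from kidney protein-abundance variability). CVs are natural-scale
(σ² = ln(1 + CV²)); CV = 0 reproduces the mean subject exactly. Percentile
bands (5/25/50/75/95) are computed pointwise and are monotone by
construction; a fixed seed reproduces cohorts and bands bitwise.

Observed clinical profiles exist in the source studies only as figures, so
the repository ships no digitized ground truth. The workbench instead
synthesizes observations by perturbing simulated truth with multiplicative
lognormal noise at a stated CV on a stated schedule — this is what the
parameter-recovery tests consume, and it also mimics the delivery-study
design (one cord-blood/amniotic sample per subject). What passing recovery
tests show is that the estimation machinery can find known parameters from
data of realistic sparsity and noise; they cannot show that the fixture
values are the true human values, which were calibrated to aggregate
clearance targets. Fit quality against user-supplied digitized data is
summarized by AAFE (geometric-mean fold error) and the fraction of
predictions within two-fold (boundary inclusive), with predictions
interpolated to observed times linearly in log-concentration.

## 8. Numerical and scope notes

* Simulation problem sizes: packaged scenarios use ≤28 state variables and
  481 output points over 24–48 h; a single simulation takes ~0.1 s, a
  200-subject population run ~30 s.
* Dynamics run on plasma flows and plasma-equivalent compartments; the
  blood:plasma ratio is carried in the drug files but not used by the
  dynamics (both shipped drugs are plasma-restricted acids).
* Saturable plasma protein binding is out of scope; cefazolin uses the 9%
  compromise free fraction, which is known to under-describe the first
  hours after high doses.
* No oral/IM absorption, no metabolism, no fetal kidney transporters (no
  expression data exist), no multi-organ fetus, no twin pregnancies or
  disease states. Early-gestation (<13 wk) fetal predictions are
  extrapolations and should be treated as exploratory.
* The amniotic-fluid compartment volume is floored at 5 mL so that
  early-GA builds remain integrable.
* Spleen drains directly to venous blood (no portal sub-circulation);
  irrelevant for renally cleared compounds.
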