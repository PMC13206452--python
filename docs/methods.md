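# Methods

## Scope and intent

`pbpkddi` is a reduced whole-body PBPK engine for one question: how much does
a perpetrator drug that induces and inhibits intestinal/renal efflux
transporters (rifampin) change the exposure of a victim substrate
(linezolid), at standard and high perpetrator doses? It re-derives the
whole-body context (anatomy, expression, absorption geometry) from textbook
physiology and documented calibration anchors rather than reproducing any
proprietary platform, so simulated exposures carry a documented tolerance
band (±15%) rather than platform-exact agreement.

## Body structure

Nine flow-limited compartments: gut lumen, gut tissue, portal vein plasma,
liver, kidney, lung, arterial plasma, venous plasma, and a lumped
rest-of-body; three cumulative sinks (urine, feces, metabolised). All
concentrations are plasma-referenced (blood:plasma ratio 1 by convention)
and all flows are plasma flows. The default adult weighs 73 kg with a
cardiac plasma output of 3.0 L/min (gut 0.55, hepatic artery 0.25, kidney
0.60, rest 1.60 L/min) and GFR 0.12 L/min.

Tissue:plasma partition coefficients use the Rodgers–Rowland mechanistic
equations for neutrals, acids and weak bases (pKa < 7): tissue water with
intracellular ionisation at pH 7.0, neutral lipid and neutral phospholipid
partitioning, and extracellular protein binding back-calculated from the
plasma unbound fraction. Moderate-to-strong bases would need
acidic-phospholipid data and are rejected explicitly — supply Kp values
directly for such compounds. For the victim drug (logP 0.55, essentially
un-ionised at physiological pH, fu 0.69) this yields Kp ≈ 0.60–0.71 across
organs and Vss ≈ 41 L, consistent with the 40–50 L literature range.

Oral absorption is first-order from a single lumen compartment,
`ka = P_int · A_eff / V_lumen`, with the effective (villi-amplified) surface
area `A_eff` a one-time calibration constant of the reduced geometry.
Un-absorbed drug leaves the lumen to feces at a first-order transit rate.
Apical efflux returns drug from gut tissue to the lumen, where it competes
again between absorption and transit.

## Elimination

* **Hepatic**: linear clearance applied to the plasma-referenced liver
  concentration. The configured value is a *plasma* clearance (the quantity
  drug labels report), so it is applied as stated rather than multiplied by
  fu again; mechanistically this equals an unbound-concentration clearance
  of CL/fu. A single-dose/multiple-dose switch (0.65 → 0.5 mL/min/kg for the
  victim) captures the reduced steady-state clearance seen on repeated
  dosing; the multiple-dose value applies to any regimen with more than one
  administration. The mechanistic origin of that reduction is out of scope —
  only the clearance switch is modelled.
* **Renal**: filtration `gfr_fraction · GFR · fu · C_kidney` plus
  Michaelis–Menten tubular secretion by ABCB1/ABCG2 on the unbound kidney
  concentration, both into the urine sink. The victim sets
  `gfr_fraction = 0`: its renal plasma clearance (~30–50 mL/min) is far
  below fu·GFR (~83 mL/min), implying extensive passive reabsorption, and
  its renal route is described through the transporters; net
  filtration–reabsorption is assumed to cancel. Other compounds default to
  `gfr_fraction = 1` (rifampin keeps full filtration).
* **Biliary**: none. Hepatic ABCB1/ABCG2 expression is zero in the default
  physiology because the victim is not excreted unchanged in feces.

## Transporter and interaction kinetics

Efflux flux is `V = Kcat · E · S/(Km,app + S)` with `E` the transporter
amount in the organ: reference concentration (µmol/L) × relative expression
× organ volume. In-vitro assay scaling: `Vmax = CLint · Km` (µL/min/mg ×
µmol/L → pmol/min/mg) and `Kcat = Vmax/abundance`.

A perpetrator acts through three mechanisms, simultaneously where
configured:

1. **Induction** (turnover model): normalised expression follows
   `dE/dt = Kdeg·(1 + Emax·I/(EC50+I)) − Kdeg·E`, steady state
   `1 + Emax·I/(EC50+I)`. `I` is the free perpetrator concentration in the
   organ housing the transporter (gut tissue for intestinal, kidney for
   renal, liver for hepatic pathways). Kdeg defaults to a 36-h turnover
   half-life (platform-typical intestinal ABCB1 turnover); the canonical
   7-day pre-treatment spans >4 half-lives, so induction is >94%
   equilibrated at read-out.
2. **Competitive inhibition**: `Km,app = Km·(1 + I/Ki)`, leaving Vmax
   untouched.
3. **Static fold**: a fixed expression multiplier active from the first
   perpetrator dose onward. ABCG2 induction is represented this way
   (1.5-fold average) rather than through the turnover model, because it was
   characterised only as an average fold-change and the perpetrator's ABCG2
   entries otherwise specify inhibition only.

The built-in rifampin model carries: ABCB1 induction (Emax 2.5, EC50
0.34 µmol/L), ABCB1 inhibition (Ki 9.1 µmol/L), ABCG2 inhibition (Ki
14 µmol/L — the explicitly stated model value; a narrative 9 µM figure
exists in the source literature and was not used), ABCG2 static 1.5-fold,
and auto-induction of its own clearance pathways (OATP1B1 Emax 0.383, AADAC
Emax 0.985, EC50 0.34 µmol/L) which multiplies its hepatic clearance.
Sensitivity parameter sets substitute published alternatives for the ABCB1
constants (Nilles: Emax 5.1 [96-h, default] or 7 [120-h], EC50 1 µM, Ki
12.9 µM; Asaumi: Emax 4, EC50 0.0639 µM, Ki 0.488 µM).

The coupled problem is solved sequentially: the perpetrator system
(amounts + expression states) integrates first with dense output; the victim
system then reads local free perpetrator concentrations and expression
states through an interpolating provider. The victim does not affect the
perpetrator, so this is exact up to interpolation error, and a
co-administration run with every mechanism disabled is bit-for-bit identical
to monotherapy.

## Default parameter choices and calibration

Fixed by the source parameterisation (not calibrated here): victim
physicochemistry (MW 337.35, logP 0.55, pKa 1.7, fu 0.69, solubility 3 g/L),
hepatic clearance switch 0.65/0.5 mL/min/kg, transporter kinetics (ABCB1
Kcat 72 min⁻¹ / Km 51 µM, ABCG2 Kcat 720 min⁻¹ / Km 53 µM, reference
concentrations 0.077 / 0.025 µmol/L), intestinal permeability
9×10⁻⁶ cm/min, and all interaction constants above. The printed assay
pipeline values (ABCG2: CLint 16 µL/min/mg, Km 100 µM, abundance
13.18 pmol/mg → Kcat 121.4 → 120 min⁻¹ at 2 s.f.) document provenance; the
final optimised Kcat values are what the built-in model uses. For ABCB1 the
analogous arithmetic gives 20.4 min⁻¹, not the 200 min⁻¹ sometimes quoted —
the derivation functions report full-precision arithmetic and that figure is
not used anywhere.

Calibrated once against monotherapy anchors and then frozen (the re-derived
physiology's free constants):

* effective intestinal area 1.9×10⁶ cm² → ka ≈ 0.025 min⁻¹ for the victim,
  giving tmax ≈ 1.2 h (anchor: 1–2 h);
* lumen transit 1/k = 5 h, the effective absorption window of the
  one-segment gut (small intestine plus colonic tail). A strict 3-h
  small-intestinal residence in a single-segment gut would force oral
  bioavailability toward 0.78 at the calibrated ka; 5 h yields F ≈ 0.85,
  consistent with the victim's near-complete absorption;
* relative transporter expression — gut {ABCB1 0.6, ABCG2 0.04}, kidney
  {ABCB1 1.8, ABCG2 0.10}, liver {0, 0} — set so that a single oral 600 mg
  victim dose excretes ~36% unchanged in urine (anchor band 30–40%) and the
  600 mg twice-daily control arm reaches a steady-state AUCinf of
  ~161 µg·h/mL. ABCB1 carries ~85% of the secretion capacity, consistent
  with its dominant role in one-at-a-time Kcat sensitivity.

Interaction outcomes were then taken as predictions and not re-tuned. The
combined-mechanism standard-dose scenario predicts a day-14 AUC0–12 ratio of
0.674 and Cmax ratio 0.784 — a somewhat stronger interaction than the
0.77/0.85 predicted by the original platform (within the documented ±15%
band, and close to the clinically observed AUC ratio of 0.667). The
discrepancy is the expected consequence of the reduced physiology: with a
one-segment gut, more of the interaction is carried by renal secretion
induction, whose concentration-desaturation feedback amplifies the
clearance increase. The high-dose sweep reproduces the flattening
dose–response: most of the interaction is already present at 10 mg/kg
because intestinal induction approaches its ceiling while rising perpetrator
concentrations add competitive inhibition that partially offsets further
induction.

Rifampin's own disposition (not printed in the source) uses literature-
typical defaults: MW 822.94, fu 0.17, effective logP 2.0 for partitioning
(an effective lipophilicity giving Vss ≈ 44 L), baseline hepatic plasma
clearance 1.5 mL/min/kg with auto-induction, intestinal permeability
4×10⁻⁶ cm/min. At 600 mg once daily this produces steady-state Cmax
6.6 µg/mL, AUC24 42 µg·h/mL and t½ 3.8 h — low-normal relative to clinical
ranges. All values are user-overridable through compound configs.

## Non-compartmental metrics

AUC uses the linear-up/log-down trapezoid over the final dosing interval.
The terminal slope λz comes from a log-linear regression over the best
adjusted-R² window (≥3 points) of the post-dose data; when no negative slope
is estimable, AUCinf is reported missing (NaN), never fabricated. Reported
steady-state AUCinf is the final-interval AUC plus the terminal
extrapolation C(τ)/λz after the last dose — a superposition-consistent
quantity; the plain interval AUC0–τ is always reported alongside, since
multiple-dose "AUCinf" is ambiguous between the two conventions. Urinary
recovery is the urine-sink increment over the read-out interval referenced
to one dose.

## Synthetic studies

The generator emulates the statistical structure the evaluation metrics
assume: per subject, body weight uniform over the study range with
physiology rescaled allometrically (volumes ∝ W, flows and GFR ∝ W^0.75);
mean-one lognormal between-subject variability (default CV 25%) on hepatic
clearance, lumped rest-of-body Kp and absorption rate — the three parameters
a development workflow optimises; and proportional lognormal residual error
(default sd 0.2 on the log scale) on each sampled concentration. A fixed
seed makes output bit-reproducible. It does *not* emulate covariate
physiology, assay-specific error, or real sparse-design heterogeneity — a
green recovery test establishes engine self-consistency, not fidelity to any
particular clinical dataset. Parameter recovery refits the hepatic clearance
by bounded scalar least squares on pooled log concentrations.

## Numerics

LSODA (stiff-capable, adaptive) with rtol 10⁻⁸ and atol 10⁻¹⁰ µmol;
integration restarts at every dose event and infusion boundary, with bolus
amounts applied as state jumps; output on a 5-min grid by default. Mass
balance (dosed = in-system + sinks) holds to <10⁻⁶ relative error at all
output times and is asserted in tests. Michaelis–Menten terms clamp the
substrate concentration at zero to tolerate solver-scale negative
excursions; a compartment amount below −10⁻⁶ µmol aborts with an integrity
error. Degenerate configurations (one effective compartment) reproduce the
closed-form mono-exponential solution to <0.1%.

## Known limitations

* One-segment gut: no longitudinal transporter-expression gradient, so the
  intestinal contribution to the interaction is understated relative to a
  multi-segment model, and the renal contribution correspondingly
  overstated (see calibration note above).
* Flow-limited tissues only; no permeability-limited organs, lymph, or
  enterohepatic recirculation; solubility is used only for a lumen
  sub-saturation sanity check.
* The victim's steady-state clearance switch is phenomenological.
* Rifampin pharmacokinetics are linear in dose; the mild supra-proportional
  exposure of high-dose rifampin is not represented, so high-dose
  interaction predictions are conservative on perpetrator exposure.
* Between-subject variability is a three-parameter lognormal stand-in, not a
  virtual population with covariate physiology.
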