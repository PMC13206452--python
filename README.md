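# pbpkddi

A desk-scale, reduced whole-body physiologically-based pharmacokinetic (PBPK)
engine for predicting transporter-mediated drug–drug interactions, built
around the rifampin–linezolid pair.

Linezolid, an oxazolidinone used against multidrug-resistant tuberculosis, is
a substrate of the efflux transporters ABCB1 (P-glycoprotein) and ABCG2
(BCRP) in the intestine and kidney. Rifampin, a first-line TB drug, induces
ABCB1 expression, inhibits both transporters competitively, and modestly
raises ABCG2 expression — so co-administration lowers linezolid exposure.
Because high-dose rifampin (20–40 mg/kg) is being evaluated for tuberculous
meningitis alongside linezolid, the dose dependence of this interaction
matters clinically. This package lets a modeller simulate those regimens,
quantify the interaction, and qualify the model with the standard PBPK
statistics — with no proprietary platform and no external data downloads.

## Model core

* **Disposition** — a flow-limited 9-compartment body (gut lumen + gut
  tissue, portal vein, liver, kidney, lung, arterial/venous plasma, lumped
  rest-of-body) with urine, feces and metabolite sinks. Tissue:plasma
  partition coefficients come from the Rodgers–Rowland tissue-composition
  equations; hepatic elimination is a linear plasma clearance with a
  single-dose/steady-state switch; renal elimination combines glomerular
  filtration (GFR · fu) with active tubular secretion.
* **Transporter kinetics** — Michaelis–Menten efflux,
  `V = Kcat · [E] · S / (Km,app + S)`, with in-vitro scaling
  `Vmax = CLint · Km` and `Kcat = Vmax / abundance`.
* **Interaction mechanisms** — induction through a turnover model,
  `dE/dt = Rsyn·(1 + Emax·I/(EC50+I)) − Kdeg·E`, competitive inhibition
  through `Km,app = Km·(1 + I/Ki)`, and a static expression fold during
  co-dosing; all driven by the free perpetrator concentration local to the
  organ housing the transporter.
* **Qualification statistics** — MRD, GMFE, DDI AUC/Cmax ratios, AFE, RMSE
  and 1.5-/2-fold classification, computed in log space on paired
  predicted/observed values.
* **Synthetic studies** — lognormal between-subject variability on the
  optimised parameters plus proportional residual error, for metric and
  parameter-recovery testing without clinical data.

## Worked example

Run the standard-dose interaction scenario — rifampin 600 mg once daily for
14 days with linezolid 600 mg twice daily added on day 8, against the
matched linezolid-only control — and read out day-14 exposure:

```sh
$ pbpkddi ddi --scenario ddi_combined --out ddi.csv
ddi_combined: AUC ratio 0.674, Cmax ratio 0.784
```

The ratios are steady-state exposure with rifampin divided by without: the
model predicts that rifampin strips about a third of linezolid's AUC0–12
(net induction dominating inhibition). The output CSV holds the per-arm
metrics; the control arm, for example:

```
arm      auc_tau  auc_inf  cmax   tmax  ae_fraction_urine
control  117.0    161.2    14.7   1.0   0.389
```

i.e. monotherapy steady-state AUC0–12 117 µg·h/mL, AUCinf 161 µg·h/mL,
Cmax 14.7 µg/mL, with 39% of each dose excreted unchanged in urine. The
same run from Python:

```python
from pbpkddi import get_scenario, run_scenario
res = run_scenario(get_scenario("ddi_combined"))
print(res.ddi_auc_ratio)        # 0.674...
print(res.without_perpetrator)  # control-arm PKMetrics
```

`pbpkddi scenario list` shows all shipped arms, including the high-dose
rifampin sweep (`highdose_10` … `highdose_40`) and the sensitivity re-runs
with alternative published interaction constants.

## Acceptance script

`scripts/acceptance.py` recomputes the headline quantities from scratch by
running the package: the ABCG2 catalytic-rate derivation from in-vitro
assay values, the monotherapy steady-state AUCinf of the high-dose sweep's
control arm, and the combined-mechanism DDI AUC ratio at standard rifampin
dose. Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(about half a minute on one CPU; the simulations are deterministic).

## Layout

| module | contents |
| --- | --- |
| `pbpkddi.compound` | drug parameter sets, in-vitro-to-in-vivo derivations |
| `pbpkddi.physiology` | organ volumes, flows, GFR, transporter expression |
| `pbpkddi.partition` | Rodgers–Rowland tissue:plasma coefficients |
| `pbpkddi.core` | flow-limited ODE right-hand side |
| `pbpkddi.interaction` | induction turnover, competitive inhibition, folds |
| `pbpkddi.simulate` | dose events, integration driver, NCA metrics |
| `pbpkddi.evaluation` | MRD/GMFE/AFE/RMSE/ratio qualification suite |
| `pbpkddi.scenarios` | pre-registered simulation arms |
| `pbpkddi.synthetic` | synthetic observed-data generator, recovery fits |
| `pbpkddi.io`, `pbpkddi.cli` | configs, tidy CSVs, command line |

See `docs/methods.md` for the model equations, default parameters, numerical
choices and known limitations.
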