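# oxalipk

Population pharmacokinetics of **intact oxaliplatin** in rats with acute
kidney injury (AKI): a complete, tested re-implementation of the analysis
workflow — synthetic study generation, non-compartmental analysis (NCA),
FOCE-ELS estimation of a two-compartment mixed-effects model,
bootstrap/pcVPC model qualification, and Monte Carlo simulation of drug
exposure as a function of plasma creatinine.

Oxaliplatin is eliminated renally, yet the *intact* (parent) drug is an
almost negligible fraction of urinary platinum, so how AKI changes intact
drug exposure is not obvious. The workflow here quantifies that question
end to end: a two-compartment IV-bolus model

    C(t) = A e^(-αt) + B e^(-βt),      A/α + B/β = D/CL

with lognormal inter-individual variability on V1, CL, CL2
(`P_i = θ_P e^{η_P}`, `η ~ N(0, ω²)`) and proportional residual error
(`y = f(1 + ε)`, `ε ~ N(0, σ²)`), estimated by first-order conditional
estimation with extended least squares (FOCE-ELS, with interaction);
individual (post hoc) clearances regressed on plasma creatinine,
`CL = a + b·Cr`; and exposure `AUC(0–∞) = D/CL_i` simulated across the
creatinine range of AKI (0.3–2.5 mg/dL).

Written for pharmacometricians and method developers who want the full
machinery inspectable and testable: every stage is a plain Python
function over NONMEM-convention event tables, with the estimator built
from scratch (batched empirical-Bayes Newton solver, linearised marginal
likelihood, finite-difference curvature) and cross-checked against
independent oracles (stiff ODE integration, adaptive Gauss–Hermite
quadrature).

## Worked example

```python
import oxalipk as ox

# a complete synthetic study at the real design: 30 rats, 3 renal groups,
# 3 or 8 mg/kg IV bolus, 9 plasma samples to 2 h, urine in the 8 mg/kg arms
study = ox.generate_study(seed=1)

fit = ox.fit_foce(study)
print(fit.parameter_table())
```

```
parameter   unit  estimate  cv_percent
        V   L/kg     0.416        6.26
       V2   L/kg      1.69        9.47
       CL L/h/kg      1.91        4.91
      CL2 L/h/kg      0.98        7.11
  omega_V      %      31.7        14.7
 omega_CL      %      24.6        14
omega_CL2      %      33.5        14.5
    sigma      %      14.5        5.54
```

The generating truth was V1 0.44, V2 2.26 L/kg, CL 1.76, CL2 1.0 L/h/kg,
IIV 37.5/30.5/31.5 %, σ 14.9 % — one 30-rat study recovers the typical
clearance within ~8 % and the residual SD almost exactly; averaging over
20 replicate studies the estimator is unbiased to well under 1 %.

Exposure versus renal function, using the creatinine→clearance line
anchored at the extreme creatinine levels:

```python
summary = ox.monte_carlo_exposure(
    ox.default_pop_model(), ox.anchor_regression(),
    cr_levels=[0.3, 0.5, 1.0, 1.5, 2.5], dose=8.0, n=1000, seed=11)
print(summary.table().round(2))
```

```
 cr_mg_dl  auc_median  auc_p5  auc_p95
      0.3        3.33    2.07     5.54
      0.5        3.62    2.23     6.13
      1.0        4.60    2.76     7.62
      1.5        6.34    3.81    10.35
      2.5       21.37   13.25    34.74
```

Median AUC(0–∞) in µg·h/mL per creatinine level: exposure roughly doubles
by Cr 1.5 mg/dL and rises ~6–7× at Cr 2.5 — severe AKI matters, mild AKI
barely does, which is the analysis' central pharmacological conclusion.

The same stages run from the shell:

```sh
oxalipk run --seed 1 --out runs/demo        # generate → NCA → fit → bootstrap → pcVPC → simulate
oxalipk generate --seed 1 --out runs/demo   # any stage standalone
oxalipk fit --data runs/demo/dataset.csv --out runs/demo
```

Each run directory holds delimited-text tables (per-subject NCA, the fit
report, empirical-Bayes estimates, GOF/CWRES, bootstrap and VPC
summaries, the exposure table) plus a `manifest.json` recording seed,
configuration and hash — the pipeline is bit-reproducible for a fixed
seed.

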