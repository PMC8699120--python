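# Methods

## The model

Intact oxaliplatin given as an intravenous bolus to rats is described by a
two-compartment disposition model with linear elimination. On a per-kg
basis the parameters are the central volume `V1` (L/kg), peripheral volume
`V2` (L/kg), elimination clearance `CL` (L/h/kg) and inter-compartmental
clearance `CL2` (L/h/kg). The plasma concentration after a bolus of `D`
mg/kg is the bi-exponential

    C(t) = A e^(-alpha t) + B e^(-beta t)

with `alpha > beta > 0` the roots of `s^2 - (k10 + k12 + k21) s + k10 k21`,
`k10 = CL/V1`, `k12 = CL2/V1`, `k21 = CL2/V2`, `A + B = D/V1` and the AUC
identity `A/alpha + B/beta = D/CL`. Working per kilogram of body weight
means a mg/kg dose yields ug/mL concentrations with no body-weight field;
time is hours everywhere (sampling minutes are converted at ingest). The
repeated-root case `alpha = beta` is rejected rather than handled with the
`t e^(-alpha t)` limiting form: it has probability zero under continuous
parameters and would complicate every downstream derivative.

The population model places lognormal inter-individual variability on
`V1`, `CL` and `CL2` (`P_i = theta_P exp(eta_P)`, `eta ~ N(0, omega^2)`,
diagonal) and none on `V2`, matching the variability structure actually
reported for this model (`V`, `CL`, `CL2` only, with `V` read as the
central volume). Residual error is proportional:
`y = f (1 + eps)`, `eps ~ N(0, sigma^2)`. Reported variability
percentages are `100 sqrt(omega^2)` (so `omega_CL = 0.305` for 30.5%),
the Phoenix-style convention; the alternative
`100 sqrt(exp(omega^2) - 1)` differs by under 3% at these magnitudes.

### Default parameter values

| parameter | default | unit | role |
|---|---|---|---|
| V1 | 0.44 | L/kg | central volume |
| V2 | 2.26 | L/kg | peripheral volume |
| CL | 1.76 | L/h/kg | elimination clearance |
| CL2 | 1.0 | L/h/kg | inter-compartmental clearance |
| omega (V1, CL, CL2) | 37.5, 30.5, 31.5 | % | lognormal IIV |
| sigma | 14.9 | % | proportional residual SD |

These are the final-model estimates for this system and serve as both the
generator truth and the sanity anchor for estimation tests. The derived
composites are `CLtot = CL + CL2 = 2.76` L/h/kg and `Vd = V1 + V2 = 2.70`
L/kg.

## Synthetic studies

The generator (`oxalipk.simulate`) reproduces the study design the model
was developed on: 30 rats in three renal groups (normal, mild, severe —
acute kidney injury by 30/60 min renal ischemia-reperfusion), 3 or 8 mg/kg
IV bolus with five rats per dose per group, plasma samples at 3, 5, 10,
20, 30, 45 min, 1, 1.5, 2 h, and urine collections over 0-0.5 ... 3-4 h in
the 8 mg/kg arms only (the assay cannot quantify urine drug at the low
dose). Choices the data do not pin down:

- **Markers.** BUN, plasma creatinine and creatinine clearance are drawn
  per group from the observed means/SDs (normal Cr 0.27 +/- 0.02, mild
  0.54 +/- 0.21, severe 0.95 +/- 0.17 mg/dL, etc.) as zero-truncated
  normals. No joint distribution was reported; BUN and CCr are coupled to
  Cr through a Gaussian copula (r = +0.8 and -0.8, conditionally
  independent given Cr) so that all marker-clearance correlations are
  non-trivial.
- **Renal effect.** When active, the typical clearance of a subject is
  `CL_typ(Cr) = a + b Cr` using the anchored regression line (below),
  clipped to the line's valid creatinine range, before the lognormal
  random effect applies. This builds in the negative Cr-clearance
  correlation (measured Pearson r ~ -0.37 across seeds; the attainable
  r^2 of the post hoc regression is ~0.2 because the full 30.5% IIV sits
  on top of the covariate trend). Parameter-recovery experiments switch
  the renal effect off so the generating typical CL is the uniform 1.76.
- **Residual draws** yielding non-positive concentrations are redrawn;
  truncation at zero would bias the mean upward more. Values below the
  default quantification limit of 0.01 ug/mL are flagged, never dropped;
  flagged values are excluded from the likelihood with a logged count.
- **Urine.** Cumulative excreted amount follows plasma exposure,
  `Ae(t) = fe * D_total * AUC(0,t)/AUC(0,4h)` with `D_total` the absolute
  dose for the 0.3 kg reference rat (2400 ug at 8 mg/kg), so `Ae(4h) =
  fe * D_total` exactly; `fe = 5e-4` for normal function reproduces the
  observed 1.2 ug, and the dysfunction groups scale it by 0.635 (mild)
  and 0.377 (severe). One mean-one lognormal factor with CV 0.2/1.2 ~ 17%
  (matching the observed 1.2 +/- 0.2 ug) perturbs the whole curve,
  preserving monotonicity. Whether real urinary excretion tracks plasma
  AUC this way is unknown; the model is a stand-in consistent with the
  printed cumulative fractions only.
- **Seeds.** One master seed; subject `i` uses the substream
  `SeedSequence([seed, i])`, so any subject regenerates identically in
  isolation.

Passing tests on these studies therefore demonstrates correctness of the
machinery under the stated stochastic model — lognormal IIV, proportional
error, normal markers — not robustness to features of real data the
generator does not emulate (assay drift, model misspecification,
correlated random effects, drop-out).

## Non-compartmental analysis

Linear trapezoidal AUC with terminal extrapolation `C_last/ke`; `ke` from
an OLS fit of `ln C` on `t` over the last 3 points by default (an `auto`
option picks the 3-5 point window with the best adjusted R^2 — the window
the original analysts used is not recoverable). For a bolus, `C(0)` is
back-extrapolated as the exponential of the log-linear intercept through
the first two samples so the 0-3 min segment is not undercounted. Then
`t1/2 = ln 2/ke`, `CLtot = dose/AUC(0-inf)`, `Vd = CLtot/ke`. Profiles
with an extrapolated fraction above 20% are flagged, not rejected: with
sampling truncated at 2 h the terminal slope over-estimates `beta`, the
tail is under-counted, and NCA clearance is biased high relative to the
model value — visible in this package's tests and consistent with the
dose-dependent half-life pattern in the source data.

## FOCE-ELS estimation

First-order conditional estimation with interaction. Per subject the
empirical Bayes mode minimises

    sum_j [ (y_j - f_j(eta))^2 / (sigma^2 f_j(eta)^2) + ln(sigma^2 f_j(eta)^2) ]
      + eta' Omega^-1 eta

solved for all subjects simultaneously by a damped (Levenberg) Newton
with Gauss-Newton Hessian, gradient tolerance 1e-8 (relative to the
objective scale), step components bounded at 5, `|eta|` bounded at 30.
The marginal -2 log-likelihood is approximated subject-wise by

    n_i ln(2 pi) + ln|V_i| + r_i' V_i^-1 r_i,
    V_i = G_i Omega G_i' + diag(sigma^2 f_i(eta_hat)^2),
    r_i = y_i - f_i(eta_hat) + G_i eta_hat,

with `G_i = d f_i / d eta` at the mode by central differences (step 1e-5).
The outer problem minimises the summed objective over log-transformed
`(theta, omega, sigma)` with L-BFGS-B (finite-difference step 1e-5 on the
log scale; modes warm-started between evaluations, which keeps a full fit
near two seconds). Initial values are NCA-informed: `CL` from a shrunken
median `dose/AUC(0-inf)`, `V1` from the median `dose/C(0)`, `V2` and
`CL2` from crude fractions of the NCA volume and clearance; the fit is
deterministic given data and initial values. A numerically singular
`V_i` receives a 1e-10 ridge.

Standard errors come from the central-difference Hessian of the -2LL at
the optimum on the log scale (step 1e-3): `cov = 2 H^-1`, and by the
delta method the CV% of a lognormally parameterised estimate equals
100 x the SE of its log. A sandwich estimator (`H^-1 B H^-1` with `B` the
per-subject score cross-products) is available via
`FitOptions(se_method="sandwich")`; which flavour the original software
reported is unknown, so both are provided and the choice is logged in the
fit options.

Two properties worth noting. First, with proportional error the
interaction term `ln(sigma^2 f^2)` shifts the conditional mode of a
noise-free typical subject by O(sigma^2) (about 0.01 at sigma = 0.149);
`eta_hat -> 0` holds only as `sigma -> 0`, and the tests assert exactly
that limit. Second, against an adaptive Gauss-Hermite quadrature oracle
the linearised -2LL of single-random-effect toys agrees to ~0.2 per
subject at sigma = 0.1 with eight observations, tightening to well under
0.1 at small sigma — the expected accuracy envelope of FOCE.

`PRED` is the prediction at `eta = 0`, `IPRED` at the mode, and CWRES
decorrelates `r_i` by the symmetric inverse square root of `V_i`; under
the true model CWRES is approximately standard normal, which the tests
check at the study size (270 observations).

## Qualification

**Bootstrap.** Subjects are resampled with replacement, stratified by
renal group x dose arm so every replicate keeps the 6-arm design
(unstratified resampling is an option). Replicates refit from the
original estimates — fast, and noted as potentially optimistic about
convergence rates; non-converged replicates are excluded and counted,
with a hard warning above 20% failures. Summaries are the median and
2.5th-97.5th percentiles per parameter. Tests run 200 replicates; the
conventional 1000 is a parameter away (`bootstrap_n`).

**pcVPC.** Simulated datasets reuse the original design matrix. Both
observed and simulated values are corrected by
`pcY = Y * median(PRED in bin)/PRED`, removing dose and covariate
heterogeneity; bins are the nine nominal sampling times (natural for this
fixed schedule), with under-filled bins merged into a neighbour and
logged. Observed 5th/50th/95th percentiles are overlaid on 2.5-97.5%
bands of the corresponding simulated percentiles. Calibration: with data
simulated from the fitted model itself the observed median falls inside
its band in essentially all bins; a deliberately misspecified model
(halved clearance) escapes the bands in most bins.

## Renal-impairment exposure simulation

Individual (post hoc) clearances are regressed on plasma creatinine by
ordinary least squares, `CL = a + b Cr`. The functional form is the one
consistent with the printed exposure summaries: fixing the line by the
median AUCs at the two extreme creatinine levels —
`a + 0.3 b = 8/3.4`, `a + 2.5 b = 8/21.7`, giving `a ~ 2.6235` L/h/kg,
`b ~ -0.9019` L/h/kg per mg/dL (`anchor_regression()`) — reproduces the
three intermediate printed medians (3.7, 4.6, 6.3 ug h/mL at Cr 0.5,
1.0, 1.5) to printed rounding, and lands at 1.77 L/h/kg at the severe
group's mean creatinine, inside the observed severe-group clearance
band. The line refuses evaluation outside its creatinine range
(0.3-2.5 mg/dL); a line fitted from data additionally trims its range to
where predicted clearance stays above 0.05 L/h/kg so a noisy slope can
never yield a non-positive clearance inside its own domain.

Monte Carlo exposure per creatinine level: `CL_i = CL_typ(Cr) exp(eta)`,
`eta ~ N(0, omega_CL^2)`, and AUC is the analytic `dose/CL_i` — residual
error does not enter an exposure summary, and the analytic route
reproduces the printed medians; an NCA-on-simulated-curves route would
add assay noise whose original mechanics are not recoverable. Medians
and empirical 5th/95th percentiles (linear-interpolation quantiles) are
reported per level, plus per-time concentration percentiles from the
individual bi-exponential profiles for profile plots. The printed
5th-95th intervals are slightly narrower than the pure-lognormal
prediction `exp(+/-1.645 omega_CL)`; since their generating mechanism is
unknown they are reported but not used as anchors.

## Problem sizes

Defaults used by the test-suite and the acceptance script, chosen to keep
a full run on one CPU in minutes while leaving every conclusion
statistically meaningful: 20 synthetic studies for parameter-recovery
averages, 200 bootstrap replicates, 400-1000 pcVPC simulations, 1000
Monte Carlo exposure draws. All are parameters; the conventional 1000
replicates for bootstrap/pcVPC run unchanged through the same code.

## Known limitations

- Diagonal `Omega` only; correlated random effects are out of scope, as
  is covariate-model building (renal function enters post hoc, as in the
  source analysis).
- FOCE linearisation error grows with `sigma` and data sparsity; the
  quadrature oracle quantifies it only for single-random-effect models.
- The urine model is exposure-proportional by construction; it encodes
  the printed cumulative fractions, not urinary physiology.
- NCA on the truncated 2-h schedule is intrinsically biased (documented
  above); the package reports the bias rather than correcting it.
- No infusion or absorption models: bolus input only.
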