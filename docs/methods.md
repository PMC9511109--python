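# Methods

## Model structure

The analysis is a cohort-level partitioned-survival model with three
health states — progression-free disease (PFD), progressed disease (PD)
and death — on a grid of 21-day cycles over a 10-year horizon
(`ceil(10 × 365.25 / 21) = 174` cycles).  State membership is read
directly off the two marginal survival curves rather than from a
transition matrix: `PFD(t) = min(S_PFS(t), S_OS(t))`,
`PD(t) = S_OS(t) − PFD(t)`, `dead(t) = 1 − S_OS(t)`.  The `min` clamps
the progressed fraction at zero wherever a fitted PFS curve crosses
above the OS curve — a structural artifact of modelling the two
endpoints marginally, which the engine tolerates by design.  The source
analysis describes a "Markov model" but prints only the two survival
curves and no transition probabilities, so partitioned survival is the
only reconstruction its inputs support.

Survival curves are Weibull in the *rate* parameterization
`S(t) = exp(−λ t^γ)` with time in cycles:

| endpoint / arm | shape γ | rate λ (cycle⁻γ) |
|---|---|---|
| OS, sugemalimab | 1.15 | 0.017 |
| OS, chemotherapy | 1.36 | 0.015 |
| PFS, sugemalimab | 1.16 | 0.047 |
| PFS, chemotherapy | 1.29 | 0.059 |

**Time unit.** The published parameter table does not state its time
unit.  Cycles (21 days) is the only consistent reading: the
chemotherapy OS mean is then `λ^(−1/γ) Γ(1+1/γ) ≈ 20.1` cycles
(≈ 13.9 months) giving discounted life expectancy ≈ 1.08 years against
the printed 1.03, and the chemotherapy PFS median is 6.75 cycles
(≈ 4.7 months) against the trial's 4.8; a months reading misses both by
large factors.  The implied OS medians (≈ 17.3 / 11.6 months) sit below
the trial's 22.8 / 17.7 months; this discrepancy is inherent to the
published parameters and is noted, not corrected.  A further artifact:
the two OS curves cross near t = 1.8 cycles (the comparator briefly
higher), so curve dominance of the intervention holds only from cycle 2
onward.

Six families are supported for curve fitting and AIC/BIC selection
(Weibull, exponential, gamma, log-normal, log-logistic, Gompertz).
Their parameterizations are stated in `psmcea.distributions`; Gompertz
uses `S(t) = exp(−(b/a)(e^{at} − 1))` with positive shape, and
log-logistic `S(t) = 1/(1 + (t/α)^β)`.  Fitting offers two routes,
matching the two ways published curves are reconstructed in practice:
maximum likelihood on (pseudo) individual-patient data with right
censoring, and least squares on digitized curve coordinates (squared
error on the survival scale by default; complementary log-log
optional).  The MLE optimizes in log-parameter space from three
perturbed moment-based starts (Nelder–Mead, objective tolerance 1e-8);
information criteria from curve fits are Gaussian pseudo-values and are
never mixed with likelihood-based ones in model selection.  Which route
produced the published parameters is unknowable; both are first-class.

## Economic inputs

All inputs are bundled in `src/psmcea/data/sugemalimab_nsclc.yaml`, the
single in-package source of these numbers.  Key values (USD, 2022
prices; utilities on [0, 1]):

* drug prices per mg: sugemalimab 3.08, pemetrexed 1.672, carboplatin
  0.041; dosing from a reference patient (BSA 1.72 m², weight 65 kg,
  CrCl 70 ml/min): sugemalimab 1,200 mg flat, pemetrexed 500 mg/m² →
  860 mg, carboplatin by the Calvert formula `AUC 5 × (70 + 25)` →
  475 mg.  The Calvert computation is the standard clinical rule; the
  source prints only the AUC target and CrCl, so its use is an
  assumption.  No vial rounding or wastage: doses are priced per mg.
* combination therapy for the first 4 cycles, then maintenance
  (pemetrexed ± sugemalimab) until progression.
* grade ≥3 adverse events (anemia, white-blood-cell decrease, platelet
  decrease): per-cycle management costs 531.7 / 461.5 / 3,551.7 with
  arm-specific incidences (0.13/0.14/0.11 intervention,
  0.69/0.17/0.10 comparator) and disutilities 0.073 / 0.2 / 0.108.
* follow-up 55.60 per PFD cycle; after progression, 44% (intervention)
  or 62% (comparator) of patients receive subsequent therapy at 854.05
  per cycle, the rest best supportive care at 337.50.
* utilities 0.71 (PFD), 0.67 (PD), 0 (death); discounting 5%/year as
  `(1.05)^(−t_years)`; WTP 37,663.26 USD/QALY.

## Structural toggles and their defaults

Several accumulation rules are not reported in the source analysis.
Each is an explicit configuration toggle; the defaults below were fixed
by two internal-consistency arguments, and every alternative remains
available:

* `eval_point = cycle-end`, `half_cycle_correction = false`.  Under
  these defaults the comparator arm's discounted total cost reproduces
  the printed value to 0.01% (24,905 vs 24,903) and its life-years to
  +4.6%, the strongest available evidence for the original engine's
  convention.  Half-cycle correction (average of adjacent cycle
  boundaries, mid-cycle discounting) is second-order accurate under
  grid refinement and is the recommended choice for new analyses.
* `ae_cost_mode = per-treatment-cycle`: the price list labels AE costs
  "per cycle", and the comparator total is only reproduced when the
  expected AE cost is charged every on-treatment cycle.  A one-off
  charge at cycle 1 (`once`) is the common field convention and is
  retained as an option.
* `ae_disutility_mode = once`: the expected disutility burden
  `Σ incidence × disutility` is subtracted once, in full QALY units
  (equivalent to the decrement persisting about one year).  The printed
  tables force this reading: the comparator's QALY/life-year ratio
  (0.66/1.03 = 0.64) is *below* the smallest state utility (0.67),
  which is impossible unless the decrement is of order 0.095 QALYs —
  exactly `Σ incidence × disutility` for that arm.  A per-cycle-scaled
  decrement (≈ 0.005 QALYs) is available as the alternative.
* `followup_state = pfd` (PD cycles already carry subsequent/BSC
  costs); `all-alive` available.
* `treatment_duration_rule = until-progression` (drug cost weighted by
  PFD occupancy, combination capped at 4 cycles).  The published
  sensitivity result at half the sugemalimab price implies ≈ 13.6
  discounted sugemalimab cycles, which matches the PFS-occupancy
  integral (12.3–13.3 depending on evaluation point) and not the
  trial's 7.2-month median treatment duration (10.5 cycles); a
  `capped-at-median` rule is provided for comparison.

## Known residual vs the published base case

With the defaults above the model reproduces, against the published
values: comparator cost −0.01%, life-years +4.6% / −1.2%
(comparator/intervention), QALYs −2.4% / −2.5%, and the intervention
arm's sugemalimab-specific spend implied by the published tornado
(≈ 50.4k vs our 45.6k, −9%).  The intervention arm's *printed total*
(98,531) is nevertheless 18% above our reconstruction (80,464), and no
combination of the toggles — evaluation point, AE mode, follow-up
state, BSC-for-all-PD, treatment caps — closes more than a third of
that gap without destroying the comparator arm's near-exact match.
Roughly 13–18k of the printed intervention-arm cost (and hence of the
printed incremental cost 73,628 and ICER 148,354) cannot be attributed
to any printed input; the published figures are internally consistent
with each other, so the unexplained component is systematic on their
side (for example an unreported administration or premedication fee
applied mostly to the intervention arm).  The reconstruction therefore
lands at ICER ≈ 114,216 USD/QALY (−23%), with the *qualitative*
conclusions intact: the ICER is ≈ 3× the WTP threshold, the sugemalimab
price dominates the tornado, halving it leaves the strategy
cost-ineffective, and the acceptability curve gives chemotherapy ≈ 100%
at the threshold.  This residual is reported as-is rather than tuned
away; the corresponding reproduction tests are expected to fail and say
so in their docstrings.

## Sensitivity analyses

One-way analysis re-runs the full model at each parameter's printed low
and high value (±25% of base, except the sugemalimab price at −50%,
dosing covariates at ±50% and the discount rate on 0–8%), holding all
else at base, and sorts by ICER width.  The probabilistic analysis
moment-matches each distribution to mean = base and
sd = (max − min)/(2 × 1.96): gamma for costs, beta for utilities,
disutilities, probabilities and the discount rate (rescaled to its
0–0.08 support), and normal for weight/BSA/CrCl truncated below at 10%
of base.  The adverse-event incidences have no printed ranges; they are
sampled as betas with sd = 20% of base (the price table nominally
labels them "Gamma", but they are proportions and the text assigns
probability parameters to the beta family).  Survival parameters are
held fixed — no ranges exist for them, and whether the original PSA
varied them is unstated.  Acceptability curves count, at each WTP on a
0–150,000 grid in steps of 2,500 (61 points), the share of draws in
which each strategy has the strictly higher net monetary benefit; ties
go to the comparator.  All sampling flows through one seeded
`numpy` generator, making every PSA bit-reproducible.

The bundled run uses 2,000 Monte-Carlo draws (the published analysis
reports 10,000); at the threshold the acceptability probabilities are
≈ 0%/100% with a Monte-Carlo standard error well below one percentage
point, so the smaller default loses nothing while keeping routine runs
fast.  `n_draws` is a plain argument for anyone wanting the full count.

## Synthetic trial data

No patient-level data or at-risk tables are published, so the
`simulate` module generates *synthetic* stand-ins with known ground
truth: event times drawn by inverse transform from the published
Weibull curves (arm sizes 320/159 as in the trial), censoring from
uniform accrual over ≈ 24.9 cycles (the trial's enrollment window) with
a single administrative cutoff at ≈ 39.3 cycles, Kaplan–Meier
estimation (product-limit), and emulated digitization (even time grid,
truncated Gaussian jitter on survival readings, isotonic projection
back to a valid curve).  PFS and OS are simulated independently — the
engine only consumes marginal curves.  This emulates the gross shape of
trial follow-up, not its fine structure: no loss to follow-up,
no informative censoring, no correlation between endpoints, and no
reader-specific digitization bias.  Passing round-trip tests therefore
demonstrate that the fitting pipeline recovers known truths under
realistic sample sizes and censoring fractions, not that it would
reproduce any specific published curve.  The bundled fixture CSVs under
`src/psmcea/data/fixtures/` are exactly the generator's output at seed
20181213 (the trial's first-enrollment date) and a test regenerates and
compares them byte for byte.

## Numerical choices

* Horizon cycles by ceiling; the final partial cycle counts as full
  (±1 cycle moves results by < 0.5%).
* Restricted means by adaptive quadrature (or a 4,096-node trapezoid);
  medians by closed-form inversion, with a bracketed Brent fallback at
  1e-8 relative tolerance and an explicit no-median error when S stays
  above 0.5.
* Occupancy conservation is enforced to 1e-12 at every cycle; death is
  monotone by construction.
* Model-selection ties break by BIC, then family name, for a stable
  ordering; fits on different data (or mixing likelihood-based with
  curve-based pseudo-likelihoods) are rejected as incomparable.
* ICERs are computed on unrounded intermediates; a QALY difference
  below 1e-12 raises an explicit undefined-ICER signal rather than
  returning a number.  (The published 0.50 incremental QALYs is itself
  a rounding of the ≈ 0.4963 implied by its printed cost and ICER.)
* PSA draws that violate a domain constraint are excluded and counted;
  under the default ranges the exclusion rate is zero.

## Limitations

Beyond the residual documented above: no background mortality, cure
fraction or tunnel states; only the three printed grade ≥3 adverse
events; no vial wastage or administration fees; prices as printed in
USD (no RMB conversion or inflation adjustment); two strategies only
(no efficiency frontier or value-of-information analysis); survival
uncertainty is absent from the PSA by construction.
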