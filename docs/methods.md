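# Methods

## Decision problem and model structure

The package evaluates the cost-effectiveness, from a Chinese healthcare-payer
perspective, of two first-line chemotherapy regimens for advanced biliary
tract cancer (BTC):

* **XELOX** — capecitabine 1,000 mg/m² orally twice daily on days 1–14 plus
  oxaliplatin 130 mg/m² intravenously on day 1 of each 21-day cycle;
* **GEMOX** — gemcitabine 1,000 mg/m² intravenously on days 1 and 8 plus
  oxaliplatin 100 mg/m² on day 1.

Both arms are treated for at most eight cycles and followed over a lifetime
horizon.  Health is modelled with three states — progression-free survival
(PFS), progressed/post-progression survival (PS), and death — with the
progression-free-to-death shortcut disallowed: patients progress before they
die, and deaths during the first cycle pass through progression within that
cycle.

State occupancy is obtained by **partitioned survival** rather than by
estimating transition intensities: at each cycle boundary *t* (in 21-day
cycles),

```
occ_PFS(t)   = min{ S_PFS(t), S_OS(t) }
occ_Death(t) = 1 − S_OS(t)
occ_PS(t)    = S_OS(t) − occ_PFS(t)
```

where each endpoint follows a Weibull law `S(t) = exp(−λ t^γ)`.  The
per-cycle transition probability implied by a curve is
`P(t) = 1 − exp[λ(t−1)^γ − λ t^γ] = 1 − S(t)/S(t−1)`, time-dependent unless
γ = 1.  The `min` clamp is the standard partitioned-survival repair for
extrapolated curve crossing: with the configured parameters the fitted PFS
curve overtakes the OS curve near cycle 24 (GEMOX) and cycle 57 (XELOX), and
without the clamp PS occupancy would go negative.  A Markov-chain view with
PFS→PS and PS→Death probabilities solved from the trace reproduces the
occupancy exactly up to the crossing (tested); beyond it only the
partitioned view is well defined.

## Survival inputs

Weibull parameters per arm and endpoint (λ is the exponent weight per
cycle^γ, γ the shape):

| arm    | endpoint | λ     | γ     |
|--------|----------|-------|-------|
| XELOX  | PFS      | 0.201 | 0.690 |
| GEMOX  | PFS      | 0.199 | 0.739 |
| XELOX  | OS       | 0.068 | 0.958 |
| GEMOX  | OS       | 0.038 | 1.260 |

The first number is read as λ and the second as γ.  This is the only reading
under which the curves are plausible: it implies a model mean OS of ≈16.9
cycles (≈0.97 years) for XELOX, consistent with the ≈10-month trial median,
whereas the transposed reading collapses survival to less than one cycle.

`survival.fit_weibull` re-estimates (λ, γ) from patient-level data by
censored maximum likelihood (lifelines' `WeibullFitter` behind the module
surface, with its (scale, shape) parametrization converted to λ = scale^−γ).
A least-squares fallback, `fit_weibull_curve`, regresses `log(−log S)` on
`log t` for digitized curve-coordinate input.  MLE is the default route.

## Synthetic data

No patient-level data are deposited; the published fits came from digitized
Kaplan–Meier curves.  `btc_cea.synthetic` replaces that step: event times are
drawn by inverse transform from the assumed Weibull law, and optional
independent censoring uses exponential censoring times whose rate is solved
numerically so the *expected* censored fraction equals the request — the
simplest mechanism satisfying independent censoring.  Kaplan–Meier
estimation is the product-limit estimator (lifelines).  The generator
emulates the distributional assumptions of the analysis, not the artefacts of
real digitized data (step granularity from at-risk tables, digitization
error, administrative censoring patterns); recovery tests therefore show
that the fitting pipeline is correct under the model's own assumptions, not
that the published digitization was accurate.

## Utilities, costs, and accrual conventions

Utilities: PFS 0.69, PS 0.71 (per life-year; ranges 0.455–0.925 and
0.455–0.965).  Costs (2020 USD): capecitabine $3.19/500 mg, oxaliplatin
$304.45/50 mg (one shared parameter for both arms), gemcitabine $229.94/g;
administration $5.80 per treatment cycle; follow-up testing $110.19 per
cycle (hospitalization 14.50 + laboratory 30.45 + CT 65.24); best supportive
care $123.69 per progressed cycle; terminal care $1,567.89 once per death.
Serious adverse events are costed as expected values (incidence × unit
cost, summed over the arm's profile: ≈$747.04 for XELOX, ≈$1,299.28 for
GEMOX) and charged once in the first treatment cycle.  The stomatitis unit
cost is not reported and is set to $0.  Doses scale with a mean body surface
area of 1.72 m².

Both costs and QALYs are discounted at 5% per year, compounded continuously
per cycle fraction: `disc(t) = 1.05^(−t·21/365)`.

Three conventions are genuinely open in this class of model and are exposed
as config switches; their defaults were fixed once by calibrating the
deterministic base case against the published results table and are logged
in every run manifest:

* **Cycle membership** (`settings.membership`): whose occupancy a cycle's
  rewards are weighted by.  Default `start` — beginning-of-cycle occupancy,
  discounted at the cycle start, mirroring stage-0 reward accrual in
  standard cohort-simulation software (every patient then pays for cycle-1
  treatment, which is clinically right: all randomized patients receive at
  least one cycle).  `end` and `half` (half-cycle correction) are available;
  for QALYs they bracket `start` from below.
* **Vial/tablet rounding** (`settings.rounding_policy`): default
  `fractional` (exact milligrams billed, no wastage), which reproduces the
  published per-arm cost levels to within 1.5%/3.4%; `whole_unit` (ceiling
  packs per administration) is available and raises both arms by ≈8%.
* **Follow-up testing scope** (`settings.followup_scope`): default
  `treatment` (follow-up billed during the ≤8 treatment cycles, reading
  "throughout the treatment process" literally); `all_pfs` extends it to
  every progression-free cycle.

Terminal care is charged per incident death at the end of the cycle of
death, under every membership convention.

The horizon default is 174 cycles (≈10 years): under the configured curves
<0.25% of either cohort is then alive, so the lifetime-horizon assumption
holds; the engine warns if >0.1% of the cohort survives the horizon.

## Incremental analysis

Strategy comparison uses unrounded totals: ΔC, ΔE, ICER = ΔC/ΔE (undefined,
not infinite, when ΔE = 0), and a dominance classification (`dominant` when
the first strategy is cheaper and more effective).  Net monetary benefit is
`NMB(WTP) = WTP × QALY − cost`; willingness-to-pay anchors default to 1–3×
China's 2020 per-capita GDP ($10,438.41 / $20,876.83 / $31,315.24 per QALY).

## Sensitivity analysis

**One-way (tornado).**  Every parameter with a configured range is set to
its low and high bound in turn (all else at baseline), the full model is
re-run, and the ICER recorded; bars are ranked by width.  Cost ranges are
the printed ones (±20% of baseline); the GEMOX adverse-event ranges as
printed contain obvious decimal typos ("0.008–0.0012" around a 0.01
baseline) and are normalized to baseline ±20%, the rule the source analysis
states.  BSA is swept (±20%) in the tornado but not sampled in PSA.

**Probabilistic (PSA).**  Each of 1,000 seeded draws samples every uncertain
parameter independently: Beta for utilities and event probabilities, Gamma
for costs, calibrated by method of moments with mean = baseline and
sd = range width / 3.92 (range read as a 95% interval; a width/4 rule is a
config switch).  The Weibull survival parameters are *not* sampled — no
distribution or interval is reported for them — which materially narrows
the spread of incremental QALYs relative to an analysis that propagates
survival uncertainty; see limitations.  CEACs report, per WTP value, the
fraction of draws in which each strategy has the highest NMB; with two
strategies the probabilities sum to 1.

## Verification strategy

* A 100,000-patient individual-level simulation (one uniform draw per
  patient; progression and death times by inverse transform under
  comonotone coupling, which marginalizes exactly to the clamped
  partitioned trace) reproduces occupancy within 0.5 percentage points and
  discounted totals within 1%.
* The transition-probability formula is checked against the conditional
  survival ratio to 1e−12 over 200 cycles for all four curves.
* Simulate-then-fit round trips at n = 5,000 recover both Weibull
  parameters within 5% relative error for every configured curve.
* Distribution calibration is frozen against hand-computed
  method-of-moments values (PFS utility: α ≈ 9.577, β ≈ 4.303; oxaliplatin
  cost: shape ≈ 96.04, scale ≈ 3.170).

## Known limitations

* With the configured Weibull parameters the incremental QALY is ≈0.159
  under every membership convention (conventions shift both arms nearly
  equally).  The published incremental of ≈0.114 (and hence its ICER and
  the GEMOX QALY of 0.54) is therefore not reachable from the printed
  parameter tables alone; the corresponding acceptance checks are left
  failing rather than tuned.  The per-arm XELOX QALY, both per-arm costs,
  the incremental cost, and dominance do reproduce within their stated
  tolerances.
* Because survival parameters are excluded from PSA, the decision is almost
  deterministic under sampled uncertainty: the dominant arm wins in
  essentially all draws at every WTP anchor, compared with the published
  92.1% at the 1×GDP threshold.  Propagating ±20% survival-parameter
  uncertainty was explored and over-disperses in the opposite direction; it
  is not enabled.
* No second-line treatment, no adverse-event disutilities, no indirect
  costs, no currency/inflation adjustment (costs are used as printed in
  2020 USD), and no alternative survival families (the Weibull commitment
  is inherited).
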