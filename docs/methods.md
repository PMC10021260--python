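# Methods

## The decision problem

Two strategies for diagnosing severe pneumonia in children aged 2–59
months presenting at rural health centres are compared from a combined
provider + patient perspective over an 8-month costing horizon with 0%
discounting (standard for horizons under a year): the IMCI clinical
algorithm alone (control) versus IMCI plus fingertip pulse oximetry
(intervention; hypoxemia defined as SpO₂ < 90%). The trial this analysis
is built around could not apply a reference-standard diagnosis, so the
health outcome is the intermediate one the trial measured — diagnosed
severe pneumonia cases — not deaths averted or DALYs; converting to final
outcomes is out of scope.

## Model structure

Each strategy is a chance tree over one presenting child:

```
present ──┬─ diagnosed severe      (p_arm) ──┬─ true positive   (sens_arm)   cost c_sev, effect 1
          │                                  └─ false positive  (1−sens_arm) cost c_sev, effect 0*
          └─ diagnosed non-severe (1−p_arm) ─┬─ true negative   (spec_arm)   cost c_non, effect 0
                                             └─ false negative  (1−spec_arm) cost c_non, effect 0
```

Pathways are mutually exclusive; rollback is the probability-weighted
payoff sum. Costs attach to the *diagnosis* (what the health system and
family actually spend after the classification), so both severe-diagnosis
leaves carry the arm's severe-case average cost.

The published input table gives per-arm sensitivity and specificity whose
only coherent base-case role is this post-diagnosis truth split, and two
effect definitions are then defensible:

- `true_positive` (default): effect 1 only on the true-positive leaf,
  `E[E] = p·sens`. Base-case ICER **38.31** USD per extra detected severe
  case.
- `any_severe_diagnosis`: effect 1 on both severe-diagnosis leaves,
  `E[E] = p`. Base-case ICER **36.27** USD.

The original analysis (built with a commercial decision-tree product whose
model file is not published) prints a base-case ICER of 29 USD. That
figure is not recoverable from the published base values under any
standard rollup we could construct (candidates: 36.27, 38.31, and 39.98
for a variant costing truth status rather than diagnosis). We therefore
document our rollup rather than force agreement, and note that the
published probabilistic results are consistent with the default here: the
acceptability curves are reported to swap rank at a willingness-to-pay of
39 USD, and a two-strategy CEAC crosses ½ at the median per-draw ICER,
which for the default structure is ≈ 38.3. The package's own checks
require the base-case ICER to fall inside the published probabilistic
envelope (7.16–89.29 USD) and inside the 26–40 USD band spanned by the
candidate structures.

Branch probability expressions are restricted to a parameter or its
complement. That is sufficient for this model and makes chance-node
normalization verifiable structurally (exactly, for every valid
assignment) rather than numerically. Rollback accepts scalar or
array-valued assignments; the PSA rolls back all draws in one vectorized
pass.

## Parameters

All ten model inputs (2018 USD; USD 1 = ETB 27.4220) carry a base value,
a min–max range, an SD, and a distribution family:

| parameter | base | min | max | SD | family |
| --- | --- | --- | --- | --- | --- |
| severe-case cost, oximetry+IMCI | 25.74 | 14.87 | 34.51 | 3.62 | gamma |
| non-severe cost, oximetry+IMCI | 3.58 | 2.84 | 4.36 | 0.34 | gamma |
| severe-case cost, IMCI | 17.98 | 14.23 | 24.55 | 2.97 | gamma |
| non-severe cost, IMCI | 2.14 | 1.46 | 2.97 | 0.33 | gamma |
| diagnosed severe, oximetry+IMCI | 0.16 | 0.05 | 0.27 | 0.03 | beta |
| diagnosed severe, IMCI | 0.04 | 0.01 | 0.07 | 0.01 | beta |
| sensitivity, oximetry+IMCI | 0.85 | 0.72 | 0.98 | 0.07 | beta |
| specificity, oximetry+IMCI | 0.87 | 0.73 | 1.00 | 0.07 | beta |
| sensitivity, IMCI | 0.56 | 0.39 | 0.73 | 0.09 | beta |
| specificity, IMCI | 0.87 | 0.73 | 1.00 | 0.07 | beta |

Division of labour between the two uncertainty descriptions: the **SD**
drives the PSA distributions, the **min/max** drive the tornado ranges
only. The distribution families are mapped to parameters by the method of
moments (closed form, standard in health-economic PSA): gamma shape
`(m/s)²`, scale `s²/m`; beta `α = m·ν`, `β = (1−m)·ν` with
`ν = m(1−m)/s² − 1`. Fits round-trip their mean and SD to 1e-9 relative
error; an SD at or above the beta variance bound `√(m(1−m))` is rejected
before any sampling. A `fixed` family (SD 0) is permitted for degenerate
parameters, mainly for testability.

The combined strategy's specificity was assumed equal to IMCI's, so the
two specificity rows share a single Monte Carlo draw by default
(configurable via `PSAConfig.shared_draw_groups`); all other parameters
draw independently — the source analysis states no correlation structure.

## Costing

Capital items (the oximeter, 149.81 USD) are annuitized over a 2-year
product life at 7% interest; the annual equivalent is pro-rated over the
8-month study window and multiplied by the device count. The annuity
factor is computed as `-expm1(-n·log1p(r))/r`, which is exact in the
`r → 0` limit. Per-child costs are quantity × unit cost (km travelled,
hospital days, oxygen m³, drug doses, IV fluids and cannulae,
consultations); consultations accrue both the patient fee and the
arm-specific provider personnel cost. The published per-consultation
personnel unit costs (0.59 / 0.34 USD) are taken as given — the
salary-to-unit-cost allocation behind them is not reproducible from
published information, so a helper taking an explicit time fraction is
exposed instead. Arm-level fixed costs (capital, batteries, training,
residual personnel time) are charged once per arm to the severe ledger,
mirroring the study's itemization.

Internal arithmetic is full precision; display rounds USD to 2 decimals
and shares to integer percent. The published itemized control-arm entries
sum to 612 while their printed total is 611 (hidden decimals); the ledger
reports the recomputed total and conservation is asserted on the exact
entries, not the printed roundings. Effect proportions are carried in the
model at two decimals (0.16, 0.04), so they display as 16.0% and 4.0% and
the arm difference as 12 percentage points, matching the reported figures
(the raw fractions are 15.95% and 3.88%).

## Sensitivity analyses

**Tornado**: each parameter in turn at its min and max, others at base;
entries sort by |ICER(max) − ICER(min)| descending, ties broken by name,
so the ordering is a pure function of the inputs. An end where one
strategy dominates is reported as a status, not a number — ICER spreads
are not comparable across dominance regimes — and such entries sort last.
The published range for the control severe-cost bar (26.24–140.35 USD)
implies a leverage inconsistent with every candidate structure and is not
reproduced as a check.

**PSA**: 10,000 iterations (the source analysis' count) from a single
seeded `numpy` generator; draw order is parameter-table order, one full
iteration vector per parameter, making runs bit-reproducible. Strategies
are ranked by net monetary benefit `NMB = λ·E − C`; ranking by per-draw
ICER is ill-defined under sign changes, but for two strategies the NMB
rule is equivalent to preferring the intervention iff `ΔC/ΔE < λ` on
effect-gaining draws, and this equivalence is verified draw-by-draw in
the tests. Exact NMB ties split probability equally. The default WTP grid
is 0–100 USD in 1-USD steps, covering the published 26 and 39 USD
thresholds; the crossover is reported both as the smallest grid point
where the intervention's probability reaches ½ and as the linear
interpolation of the ½ crossing. Draws with ΔE = 0 (a measure-zero event
under the continuous distributions) are excluded from ratio statistics
and counted. The published 7.16–89.29 USD ICER range does not state
whether it is a min/max over draws or a percentile interval; the summary
reports both, and the seed-sensitive min/max is not treated as a check.

## Synthetic trial generator

The generator emulates the structure the costing pipeline consumes: 24
clusters alternating arms (12 each), cluster sizes negative-binomial
(arm means 928/12 and 876/12, dispersion 8 — mild overdispersion typical
of facility caseloads), diagnosed-severe indicators Bernoulli with the
trial proportions (148/928, 34/876), and per-child item quantities drawn
conditionally on diagnosis class: shifted Poisson for consultations
(every diagnosed child has ≥ 1 visit), Poisson for other counts, and
gamma (CV 0.5) for the continuous quantities (km, oxygen m³). Severe-only
items (oxygen, hospital days, IV supplies) are structurally zero for
non-severe children.

Quantity means are calibrated in code so expected per-case itemized costs
match the published severe-case itemization divided by case counts, and
the non-severe means match the class-average costs (3.58, 2.14 USD). Two
splits are under-determined by the published tables and fixed by
assumption: the pooled drugs-and-supplies line is split as two IV fluids
+ two cannulae per severe case with drug doses absorbing the remainder,
and the provider personnel line exceeds per-consultation personnel cost ×
consultation count, so the residual is carried as an arm-level fixed cost
(supervision and time not tied to a costed visit). The oximetry capital
line is likewise taken as the printed arm total rather than re-derived,
since it is not recoverable from price, fleet size and horizon alone.

By default there is no within-cluster correlation of costs — the
downstream analysis consumes arm aggregates only — but a multiplicative
lognormal cluster effect (`cluster_sigma`) is available for robustness
experiments. Consequences for interpretation: recovery tests demonstrate
that the estimators (proportions, ledger averages) are unbiased for the
generating means at trial scale, not that the model is robust to
real-world features the generator omits (correlated cost components,
cluster-level confounding, measurement error in quantities, seasonal
case-mix drift).

## Problem sizes and numerical choices

The test suite runs the PSA at 10,000 iterations (20 seeds for the
crossover stability check, 8 for interval stability), the sampling-
consistency check at 10⁶ draws, random-tree rollback cross-checks at
depth ≤ 6, and the generator recovery sweep at 100 seeds of full-size
trials — all chosen to keep the whole suite around ten seconds on one
core while leaving Monte Carlo error well inside the asserted tolerances.
Rollback agreement with brute-force path enumeration is asserted at
1e-12; probabilities are validated to [0, 1] within 1e-12 at evaluation
time; averages over zero diagnosed cases raise rather than return 0.

## Limitations

- The effect is an intermediate outcome; no link to mortality or DALYs is
  modelled, so the ICER is not comparable across disease areas.
- The 29 USD base-case figure of the original analysis cannot be
  reproduced from published inputs (see above); this package's rollup is
  documented and self-consistent instead.
- False positives carry severe-case costs but no explicit harm beyond
  cost; caregiver productivity losses and facility capital are excluded,
  as in the source costing.
- Pairwise comparison only: no frontier analysis for > 2 strategies, no
  Markov extension, no value-of-information analysis.
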