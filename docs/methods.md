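# Methods

This note records the modelling conventions, the calibration that fixes the
under-determined accrual rules, the synthetic-data design, and known
limitations. It is the package's own account of choices that the published
model description leaves open; nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model structure

Three states — progression-free (PFS), progressed disease (PD), dead — in
6-week cycles over a 15-year horizon (131 cycles; by cycle 131 more than 99%
of every modelled cohort has died, and doubling the horizon changes totals by
under 1%). Each arm of each cohort is driven by two Weibull survival curves
(overall survival and progression-free survival) on the hazard scale
S(t) = exp(−λ t^γ).

**Fitted time unit.** The Weibull parameters are interpreted on a scale where
one fitted unit equals one 6-week model cycle. Two independent checks support
this reading: (i) medians computed from the parameters, read as months, land
within 4% of the trial's reported medians (16.8/23.4 months OS, 5.1/9.9
months PFS — the closed-form medians come out at 17.3/24.2 and 4.9/10.2);
(ii) life-year totals are recovered only when each fitted unit is weighted by
the 6-week cycle length (e.g. the chemotherapy overall-survival Weibull has
analytic mean 20.25 units ≈ 2.33 years against a published 2.393 LYs).
A month is not exactly 6/4 weeks, so (i) and (ii) are in mild tension;
`fitted_unit_weeks` is exposed as a knob (default 6) for sensitivity to this
convention.

**Occupancy and accrual grid.** The base case is partitioned survival:
at each cycle the occupancy is read off the curves as pfs = S_PFS, dead =
1 − S_OS, pd = S_OS − S_PFS (clamped at zero with a warning if the curves
cross). Accrual uses cycle-start occupancy — an upper Riemann sum — with no
half-cycle correction; a `half_cycle` flag switches to midpoint evaluation.
This choice was made by calibration: against the published per-arm totals,
cycle-start accrual reproduces QALYs within ~1% for five of six
cohort × arm cells, while cycle-end accrual is 4–12% low and midpoint
intermediate. A state-transition mode (occupancy propagated by the per-cycle
conditional-survival transition probabilities, with death claiming
min(tp_OS, tp_PFS) of the PFS exits so no flow goes negative) is provided as
an internal consistency check and agrees with partitioned survival on
life-years within 1% for constant hazards.

**Discounting.** Costs and QALYs are discounted at 3%/year with
continuous-time exponents, (1.03)^(−t years), evaluated at each cycle's
accrual time point. Life-years are reported **undiscounted** by default
(`discount_lys = False`): reproducing the published life-year totals requires
it (undiscounted values match within ±2%; discounted values are uniformly
~5% low), and the published incremental cost over incremental LYs is
consistent with the same undiscounted reading. QALY and cost discounting is
unaffected.

## Cost accrual and the duration-factor calibration

Per cycle: drug + administration cost accrue on PFS occupancy; follow-up on
all alive states (a `followup_in_pfs_only` switch restricts it to PFS);
best-supportive-care cost on PD occupancy weighted by the arm's
post-discontinuation rate (0.081 chemotherapy, 0.162 T-DXd). One-off items:
IHC testing and the aggregate adverse-event cost at model entry; terminal
care (2,844) on each cycle's death increment, discounted at time of death, so
every death pays it exactly once. The adverse-event QALY decrement
(Σ risk_i × disutility_i × one cycle's duration) is likewise applied once at
entry; its economic influence is small.

**Treatment-duration factor.** Published one-way results imply fewer
effective (discounted) drug cycles than mean PFS time: the T-DXd drug-cost
range moves the overall ICER by an amount implying ≈10.8 discounted drug
cycles, whereas discounted PFS occupancy sums to ≈13.9 cycles. The engine
therefore scales drug + administration accrual by a per-arm
`treatment_duration_factor` ∈ (0, 1]. Calibration procedure (implemented in
`cohort.solve_duration_factor`, run once, values frozen in the packaged
config): total discounted cost is affine in the factor, so the factor
matching each arm's published total cost is closed-form; solutions above 1
are clamped to 1. Resulting values:

| cohort  | chemo | T-DXd  |
|---------|-------|--------|
| overall | 1.0 (unclamped 1.048) | 0.759 |
| HR+     | 1.0 (unclamped 1.058) | 0.834 |
| HR−     | 0.881 | 0.6448 |

The overall T-DXd factor gives 10.53 effective discounted drug cycles,
independently consistent with the ≈10.8 implied by the published drug-cost
sensitivity bounds. With these factors the overall incremental cost and ICER
reproduce to within 2%, and the drug-cost-at-minimum one-way ICER to within
2%. Body-surface area is stored and registered but enters no cost line in
the default model (chemotherapy cost is given per cycle, not per mg), so its
tornado span is exactly zero; body weight enters only through linear scaling
of the weight-dosed T-DXd drug cost around the 74 kg baseline.

## Sensitivity analysis

**One-way (tornado).** Every registered scalar (30 per cohort comparison:
unit costs, adverse-event risks and costs, utilities and disutilities,
post-discontinuation rates, weight, body-surface area, discount rate) is set
to its configured minimum and maximum — the published ranges, mostly ±20% —
holding all else at base; entries are ranked by ICER span. A perturbation
that removes the cost/effect trade-off is flagged and excluded from ranking.
T-DXd drug cost and body weight dominate the tornado, in line with the
published figure (here weight is marginally wider than drug cost, because the
59–89 kg range moves the weight-scaled drug cost slightly more than the
drug-cost range itself).

**Probabilistic.** Each draw jointly resamples all registered scalars,
independently, from their stated families: beta for probabilities and
utilities, gamma for costs, normal for weight and body-surface area, uniform
for the discount rate. Families are moment-matched to the base value with
sd = (max − min)/(2 × 1.96), the convention for ranges read as 95% intervals;
the divisor is configurable. Uniform uses the exact endpoints (its mean for
the 0–0.05 discount range is 0.025, not the 0.03 base). Weibull survival
parameters are **not** sampled — no distribution is published for them — and
no correlation structure is imposed. Draws producing invalid inputs (e.g. a
normal tail pushing a utility above 1, or sampled PD utility above sampled
PFS utility) are resampled with a capped retry count. Randomness contract:
draw *i* of root seed *s* uses the dedicated substream
`numpy.random.SeedSequence([s, i])`, making runs bit-reproducible and
order-independent.

**Known limitation.** Because survival-parameter uncertainty is excluded, the
probabilistic incremental-NMB spread is narrower than the published analysis
implies, most visibly for the small (63-patient) HR− cohort: the acceptance
suite measures ≈12% probability of cost-effectiveness at $150k/QALY for HR−
(published ≈28%) and ≈0.2% for the overall cohort (published ≈1.5%), while
the threshold-doubling check (probability at $300k/QALY ≈ 55% vs published
≈50%) reproduces. Matching the published spread would require sampling the
Weibull fits, which cannot be parameterised from the published inputs.

## Subgroup reconstruction

Under proportional hazards on a Weibull, S_new(t) = S_ref(t)^hr is exact:
scale λ multiplies by the hazard ratio, shape γ is unchanged, the median
scales by (1/hr)^(1/γ). `subgroup_ce` rebuilds the T-DXd PFS curve from the
chemotherapy PFS curve and a supplied hazard ratio (and optionally OS, when
an OS hazard ratio is available; otherwise the cohort-level fitted OS curve
is kept — both behaviours are supported because the published analysis does
not state which was used). Costs and utilities are taken unchanged from the
cohort inputs; per-subgroup hazard ratios are caller-supplied, not shipped,
since they are not published in the main text.

## Synthetic-data pipeline

The generator emulates the chain behind any published survival-curve model:
Weibull event times (inverse CDF), independent exponential dropout plus an
administrative follow-up cap, product-limit (Kaplan–Meier) estimation via
lifelines, and sparse digitization — by default 20 points at evenly spaced
survival quantiles with additive Gaussian noise of sd 0.005, clipped,
monotonized, and stripped of exact-zero points (a plausible rendering of
manual graph-digitizer error; both knobs are inputs, not claims about the
trial). It does **not** emulate the trial's true censoring pattern,
numbers-at-risk reconstruction, or image-level digitization artefacts, so
passing recovery tests demonstrates the fitting machinery is unbiased under
the stated noise model, not that any specific published curve was digitized
faithfully.

Refitting supports log(−log S)-on-log t regression (exact on noiseless
Weibull points) and maximum likelihood on a reconstructed pseudo-cohort.
Because a digitized curve only locates events between adjacent points, the
pseudo-cohort likelihood treats events as interval-censored between
consecutive digitized times, with survivors right-censored at the last point;
treating binned events as exact observations at bin endpoints was found to
bias the shape by >10% at 20 points and is not used. AIC/BIC family
comparison (Weibull vs its exponential special case) uses this same
likelihood for both candidates; ties break toward fewer parameters.
End-to-end recovery performance, measured by the test suite: median relative
parameter error ≈4% over 20 replicates at n = 2,000 (threshold 10%).

## Numerical choices

- Weibull MLE on exact times: profile likelihood (closed-form scale given
  shape), scalar optimization over log-shape, tolerance 1e−8, initialized
  from the log–log regression; cross-checked against lifelines'
  `WeibullFitter` to 0.1%.
- Interval-censored MLE: Nelder–Mead over (log λ, log γ), tolerances 1e−8.
- log–log regression excludes points with S ≥ 1 or S ≤ 0 and requires at
  least three survivors.
- Transition probabilities are computed by the closed-form expression and
  verified against the conditional-survival ratio to 1e−12; occupancy
  conservation holds to 1e−9 per cycle.
- Degenerate inputs: zero-sd distributions become point masses; all-censored
  samples yield a flat KM curve with a warning; dominance replaces ICERs
  whenever one strategy is cheaper and more effective (negative ratios are
  never reported).

## Reproduction status

With the calibrated defaults the package reproduces, per the acceptance
suite: all per-arm life-year and QALY totals within 5% except the HR+ T-DXd
cell (the published HR+ T-DXd Weibull OS parameters have analytic mean 27.65
units ≈ 3.18 undiscounted years, strictly below the published 3.484 LYs under
any accrual convention, while their median does match the trial's 23.9
months — the two published values are mutually inconsistent, and this package
follows the parameters); all cost totals within 7%; overall and HR− ICERs
within 5%; the drug-cost one-way bound within 2%; and the acceptability
probabilities as described under the probabilistic-analysis limitation above.
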