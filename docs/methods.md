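# Methods

## Model structure

Each maternal age cohort is modelled independently. At t = 0 (pregnancy and
birth) a decision node selects the arm and a chance node splits the cohort
into three branches: `gdm` (probability *q* under usual care, *q·RR_GDM*
under intervention), `avoided_gdm` (*q·(1 − RR_GDM)*, intervention only) and
`never_gdm`. Perinatal events and costs attach to this node. From t = 1 the
branch cohort runs a deterministic three-state occupancy recursion
(no T2DM / T2DM / dead) in one-year cycles until age 85, entered entirely in
the no-T2DM state.

Within a cycle the no-T2DM state faces background mortality first;
progression to T2DM is then applied to the survivors, so the per-cycle
stay-healthy probability is (1 − p_die)(1 − p_inc). New T2DM cases are not
exposed to the T2DM mortality rate in their cycle of onset. This ordering is
stated explicitly because it changes results at the fourth decimal; it
follows from the mortality inputs being state-wide annual rates. The
recursion is evaluated in closed form with cumulative products (an explicit
per-cycle loop is used only in the degenerate case of a transition
probability at 1), which is what keeps a 10,000-iteration PSA in the
tens of seconds on one CPU.

Maternal death during pregnancy is excluded (extremely rare). GDM itself
carries no utility decrement; its burden enters through perinatal events and
the elevated progression risk.

## Rates

* **Prevalence-corrected RR.** RR_adj = RR/(p·RR + 1 − p). The incidence
  decomposition uses the mixture-consistent form i_noGDM = i_total/(p·RR +
  1 − p) = i_GDM/RR, which satisfies both the mixture identity
  p·i_GDM + (1 − p)·i_noGDM = i_total and the ratio identity exactly, and
  reproduces the printed adjusted RR of 9.01. (A literal subtraction of the
  GDM-group incidence from the total is dimensionally inconsistent and is
  not used.)
* **Background mortality.** For ages ≥ 40, the no-T2DM rate is
  (all-cause deaths − T2DM deaths)/(population − prevalent T2DM); below 40
  the all-cause rate serves both states, since T2DM deaths are negligible
  there. A negative numerator is rejected as inconsistent input.
* **Smoothing.** `smooth_single_year_rates` fits a Poisson GLM with a
  restricted cubic spline in age (4 knots at exposure-weighted quantiles of
  band midpoints, Harrell parameterisation) to band-level event counts with
  a log-exposure offset. A flat input is recovered to ±1e−6 and a Gompertz
  curve binned into 5-year bands is recovered within 5% over ages 45–80
  (both tested).
* **Rate → probability.** p = 1 − exp(−rate·Δt). Whether the source
  analysis converted rates or used them directly as probabilities is not
  stated; the exponential form guarantees probabilities below 1 at the
  oldest ages and is the package's convention.

## Timing, discounting, utilities

Perinatal quantities sit at t = 0 and are undiscounted. Cycle t is
discounted by (1 + r)^−t, r = 0.05/year. Half-cycle correction credits each
state with the mean of its start- and end-of-cycle occupancy (default on).

Healthy utilities are age-banded (18–24 … ≥ 75); maternal ages 15–17 use the
nearest published band (18–24). The T2DM utility (0.785) tracks age via a
configurable `adjustment_mode`. The default is multiplicative scaling of the
age-specific healthy utility by 0.785/0.95, anchored at the 0.95 utility of
the 25–34 band — the band containing most of the cohort at typical onset
ages — so a 30-year-old with T2DM has utility exactly 0.785 and older ages
scale proportionally. An absolute-decrement mode (healthy − 0.165) is also
provided; the anchor utility is a parameter. The published description
("adjusted consistently with age-specific healthy scores") does not pin the
convention down, so it is explicit and configurable here.

## Costs

Base case: an age-banded annual cost attributed to T2DM applies to T2DM
state-years. Micro-costing scenarios (s3 healthcare, s4 societal): new cases
incur the newly-diagnosed annual cost in their onset cycle, continuing
prevalent cases the known-diabetes cost; s4 adds direct non-health costs and
government income subsidies per T2DM case-year. The healthcare-perspective
total always excludes the societal add-ons.

ROI is defined from the incremental cost breakdown as
(pregnancy savings + T2DM management savings [+ NICU/SCN if included]
[+ societal add-ons in s4]) / intervention cost — the definition implied by
the published totals (85,296,057/69,904,575 = 1.22); no formula is printed
in the source. The ICER returns "Dominant"/"Dominated" labels on the
off-diagonal quadrants and a ratio otherwise.

## Sensitivity analysis

* **DSA** varies one parameter at a time across its published 95% CI
  (costs: mean ± 1.96·SE with SE = 10% of the mean) and reports the
  incremental cost/QALY per woman and ICER at each bound, sorted by the
  width of the incremental-cost range.
* **PSA** (default 10,000 iterations, seeded NumPy Generator) samples
  utilities from beta fits (method of moments, SE = CI width/3.92), relative
  risks from log-normal fits (μ = ln mean — the point estimate is the
  median, so the distribution mean sits ~exp(σ²/2) above it, about 1% here —
  σ = CI log-width/3.92) and costs from gamma fits (SE = 10% of mean).
  Draws are independent (no correlation structure is published). A draw
  producing an invalid parameter set is rejected and redrawn, preserving the
  stated families; the count is reported. Collapsing every interval to the
  point estimate makes each iteration exactly equal to the deterministic
  run (tested).
* **Threshold searches** use bisection: the intervention unit cost at which
  Δcost = WTP·ΔQALY (tolerance AU$1; the incremental cost is linear in the
  unit cost, so the result matches the closed form), and the scenario-2
  sweep of the averted-GDM residual risk over RR ∈ [1, 9.5] with roots for
  ROI = 1 and ICER = WTP. At RR equal to the full post-GDM risk the averted
  branch reproduces the GDM branch exactly and no lifetime cases are averted.

## Synthetic data and the reference bundle

The packaged bundle fixes every published point estimate and interval
verbatim (relative risks, utilities, AU$228 unit cost, 0.65% population GDM
prevalence, 5% discounting, AU$50,000/QALY). Schedules available only from
registry sources are synthetic stand-ins chosen once to be realistic for the
2016 Australian setting and are flagged `provenance = synthetic`:

* ~306,600 births distributed over the seven age bands with a mode at
  30–34; pre-existing diabetes (~1%, age-increasing) excluded;
* GDM prevalence rising 6% → 25% across bands (population mean ≈ 12.4%);
* T2DM incidence logistic in age (plateau 0.012/yr, midpoint 58, slope
  0.09) — magnitudes consistent with the published usual-care lifetime
  burden;
* Gompertz female mortality (1.2×10⁻⁴ at age 15, log-slope 0.0946/yr) with
  a 1.8× hazard among prevalent T2DM from age 40; T2DM prevalence logistic
  in age;
* perinatal event probabilities and unit costs whose GDM/no-GDM contrasts
  imply roughly AU$2,000 of perinatal cost per averted GDM pregnancy, and an
  attributed T2DM cost schedule averaging ≈ AU$1,300 per case-year.

`generate_synthetic_bundle` perturbs these (log-normal, relative SD
`noise_sd`, default 0.05) in ways that preserve structure: noise on the
band-to-band GDM-prevalence increments keeps the curve strictly increasing;
noise on the shape parameters (not per age) keeps incidence and mortality
monotone over 40–85. The same seed yields byte-identical bundles.

What the synthetic data does *not* emulate: real registry autocorrelation
and cohort effects, diagnostic-criteria drift, within-band age structure,
parameter correlations, or T2DM complication heterogeneity. Green tests
therefore demonstrate correctness of the machinery and internal consistency
of the model, not numerical fidelity to any national dataset: analyses of
real populations must supply their own bundle.

## Numerical choices and problem sizes

* Tolerances: occupancy conservation and decomposition identities at 1e−12
  (relative); bundle round-trip at 1e−12; bisection at AU$1 (cost) and 1e−3
  (RR sweep).
* Cohort representative age = band midpoint (the within-band convention is
  not published).
* The test suite's microsimulation oracle uses 10⁵ simulated women and
  agreement within 3 Monte-Carlo standard errors; property checks use 1,000
  random transition schedules; the in-suite PSA checks run at 10,000
  iterations (reproducibility) and 400 iterations (consistency with the
  deterministic run).

## Limitations

Cardiovascular sequelae of GDM, offspring outcomes, subsequent-pregnancy
costs, T2DM complication sub-states and price-index inflation are out of
scope (costs are taken as already expressed in one price year). Only one
pregnancy per woman is modelled. The per-woman denominator is the total of
included births across cohorts.
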