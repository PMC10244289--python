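# gdmcea

Lifetime cost-effectiveness and return on investment of a structured
antenatal lifestyle intervention that reduces gestational diabetes mellitus
(GDM) and downstream type 2 diabetes mellitus (T2DM).

The package is aimed at health economists and epidemiological modellers: it
implements a decision-analytic model in which every maternal age cohort
(15–19 … 45–49 years) passes a decision node (usual antenatal care vs a
structured diet and/or physical-activity intervention) and a pregnancy
chance node (GDM / GDM averted / never GDM), then runs a three-state Markov
process — *no T2DM* → *T2DM* → *dead* — in one-year cycles until age 85.

## Model in brief

* **Intervention effect.** The probability of GDM in a cohort with baseline
  prevalence *q* becomes *q·RR* under intervention (base-case RR = 0.67;
  subgroup RRs 0.66 diet-only, 0.62 PA-only, 0.75 diet+PA; all log-normal).
* **Progression risk.** Women with prior GDM progress to T2DM at
  RR = 9.51 relative to women without. Because the national incidence series
  mixes both groups, the RR is first prevalence-corrected,

  RR_adj = RR / (p·RR + (1 − p)),

  with *p* = 0.0065 the GDM prevalence in the total female population,
  giving RR_adj = 9.01; group incidences follow from
  i_GDM = RR_adj · i_total and i_noGDM = i_GDM / RR.
* **Mortality.** Age-specific all-cause female mortality; from age 40 the
  no-T2DM state uses the rate with T2DM deaths and the prevalent T2DM
  population subtracted. Banded rates can be smoothed to single years of age
  with a restricted-cubic-spline Poisson regression. Annual rates convert to
  cycle probabilities by p = 1 − exp(−rate).
* **Economics.** Perinatal costs (GDM antenatal care, Caesarean section,
  induction of labour, optionally NICU/SCN admission) at t = 0; T2DM
  management costs and utility-weighted life-years (healthy utility by age
  band; T2DM utility 0.785) over the Markov cycles, discounted at 5%/year
  with half-cycle correction. Outputs: ICER (AU$/QALY, with dominance
  labels), ROI (savings per intervention dollar, unit cost AU$228), and an
  efficiency frontier with extended dominance.
* **Uncertainty.** One-way DSA over published 95% CIs (costs: SE = 10% of
  the mean), probabilistic SA (10,000 iterations; beta/log-normal/gamma),
  an intervention-cost threshold search against a AU$50,000/QALY
  willingness-to-pay, and a sweep of the residual T2DM risk in women whose
  GDM was averted (RR 1–9.5) with ROI = 1 and ICER = WTP roots.

The packaged reference bundle carries the published point estimates and
intervals verbatim; registry-derived schedules (births by age band,
single-year incidence/mortality, cost schedules) are synthetic stand-ins
with the same statistical shape, flagged `provenance = synthetic`. A
seedable generator (`gdmcea.synthetic_inputs`) produces randomised variants
for testing.

## Worked example

```bash
gdmcea run --out results/base
```

prints

```
ICER (base): Dominant   ROI: 1.22
```

and writes `comparison.csv` whose rounded variant begins

```
outcome,usual_care,base,diet,pa,diet_pa
Cases of GDM,"38,206","-12,608","-12,990","-14,518","-9,552"
Cases of type 2 diabetes,"88,448","-8,025","-8,268","-9,241","-6,079"
...
Incremental cost per woman,,-50.3,-110,-124,17.1
ICER,,Dominant,Dominant,Dominant,660
ROI ratio,,1.22,1.62,1.63,0.925
```

Reading: under usual care the modelled birth cohort accrues 38,206 GDM and
88,448 lifetime T2DM cases; the base-case intervention averts 12,608 GDM and
8,025 T2DM cases, saves AU$50.30 per woman from the healthcare perspective
(hence "Dominant": cheaper and more effective), and returns AU$1.22 in
downstream savings per intervention dollar. The diet+PA subgroup, with the
weakest GDM effect and the full unit cost, is not cost-saving
(ICER ≈ AU$660/QALY — still far below the AU$50,000/QALY threshold).

Other entry points:

```bash
gdmcea synth --seed 1 --out bundle/          # synthetic parameter bundle
gdmcea psa --iterations 10000 --seed 1 --out results/psa
gdmcea dsa --out results/dsa                 # tornado table
gdmcea sweep-rr --out results/sweep          # scenario-2 risk sweep + roots
gdmcea threshold-cost                        # max cost-effective unit cost
```

Scenarios are selected in the config document or with `--scenario`:
`s1_10yr` (elevated post-GDM risk limited to ten years), `s3_microcost_health`
and `s4_microcost_societal` (micro-costing of T2DM from the healthcare and
societal perspectives).

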