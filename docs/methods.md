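# Methods

## Model structure

The model is a two-stage hybrid. A 30-day decision tree allocates the
cohort to MitraClip-plus-OMT or OMT alone, charges the intervention arm's
eight one-time cost components and its one-time procedure (0.043) and
complication (0.005) disutilities, charges both arms one month of OMT drug
cost, and hands each arm a post-30-day NYHA distribution (optionally
depleted by a 30-day mortality, default 0). A Markov cohort model then
propagates the distribution over five states — NYHA I, II, III, IV and an
absorbing dead state — in monthly cycles from age 72 to age 100 (336
cycles), using per-arm, time-homogeneous transition matrices. Death is fed
only by the HF-death column of the transition rows; no background
all-cause mortality is layered on, because the transition structure alone
reproduces the short life expectancies of this severely ill cohort (a
life-table hook would be the natural extension, and is deliberately out of
scope). HF hospitalizations are Bernoulli events per live month,
independent of the concurrent NYHA transition, with per-state monthly
probabilities.

## Accrual conventions

* **Half-cycle correction.** Per-cycle quantities use the mean of start-
  and end-of-cycle occupancy. The same convention is applied to state
  occupancy (utilities, OMT cost, life-years) and to hospitalization
  events, for internal consistency. With the correction disabled, the
  engine uses end-of-cycle occupancy throughout; corrected life-years
  therefore always lie strictly between the end- and start-of-cycle
  Riemann sums for any trace with deaths (a tested property).
* **Discounting.** Costs and QALYs share one annual rate (default 0.05),
  converted to a monthly factor `(1+r)^(1/12) − 1` (compound, not `r/12`);
  cycle `t` is weighted by `(1+r_m)^(−t)`. One-time 30-day-stage
  quantities enter at `t = 0` undiscounted. This makes the lifetime-cost
  difference between two device prices exactly the price difference, which
  is what the published scenario table's arithmetic implies.
* **Disutilities** are stored as positive magnitudes and subtracted once
  where they apply — never negated twice.

## Parameters

All monetary values are 2021 CNY. The monthly OMT cost (428) and the
HF-hospitalization cost (10,926) are derived inside the package from the
source per-patient USD costs: a sub-cohort-weighted mean, conversion at the
source-era exchange rate of 6.75 CNY/USD, and inflation along the
2018–2021 healthcare CPI chain (1.043, 1.024, 1.018, 1.004); results are
reported in USD at the 2021 average rate of 6.45 CNY/USD. The two rates
play distinct roles and are both kept in the configuration. NYHA monthly
utilities are annual utilities divided by 12; NYHA I and II are equal
(0.065) as published, and the validator enforces only non-increasing
severity ordering, so that equality is preserved rather than "corrected".
The WTP threshold defaults to 3 × per-capita GDP (80,976 CNY, 2021), i.e.
242,928 CNY/QALY.

Uncertainty bounds are read as symmetric 95% confidence intervals even
where the printed ranges are asymmetric (mostly half-to-double around the
base): the standard error is `(high − low)/3.92`, gamma distributions are
moment-matched by `shape = base²/σ²`, `rate = base/σ²`, betas by the
standard method-of-moments. The same bounds drive both the one-way
analysis and the PSA; no separate plausibility ranges exist.

## Calibrated inputs

The post-30-day NYHA distributions and the per-state monthly
hospitalization probabilities are not published (they derive from trial
data the study cites but does not tabulate). They are first-class
configuration inputs, and the shipped defaults are produced by
`economics.calibrate`: a bounded least-squares fit (simplex-normalized
initial shares; one hospitalization scale factor per arm applied to a
severity-doubling profile) against nine reported outcomes — life-years
3.72/2.90, hospitalizations 1.16/1.51, QALYs 2.32/1.80, lifetime costs
423,817/28,369 CNY and the ICER 754,410 CNY/QALY. A weak quadratic pull
toward the starting values (weight 1e-3 on the raw optimizer variables)
selects the solution nearest the start when the fit is underdetermined.
The fit residuals are archived in `results/calibration.json`; the largest
is about 1.4% (OMT life-years), and the outcome levels cannot all be
matched exactly: with the published transition matrices and utilities, the
maximum QALY attainable at the reported life expectancy falls ~2% short of
the reported QALY in both arms, so the optimizer balances the two. The
optimizer is local; `analysis/01_calibrate.py` records the informed
starting point from which the shipped defaults were fitted.

## Sensitivity analysis

One-way analysis re-runs the deterministic pipeline at each parameter's
bounds and ranks by ICER swing. The PSA draws all costs (gamma), all
utilities and disutilities (beta) and every nonzero off-diagonal
transition entry (beta) jointly and re-evaluates the pipeline per draw,
10,000 times by default. Transition probabilities carry no published
intervals; their betas use a 95% CI of ±20% of the base value — a
conventional moderate uncertainty — and each perturbed row is renormalized
by its sum so it stays stochastic while structural zeros (e.g. recovery
out of NYHA IV, direct death from NYHA I) are never perturbed. Whether to
perturb rows jointly (Dirichlet) or marginally with renormalization is a
genuinely open choice; the marginal convention was chosen for transparency
of the per-entry intervals. Every parameter draws from its own
`SeedSequence` substream keyed by (master seed, CRC-32 of the parameter
name), so adding or removing a parameter does not shift any other
parameter's draws (tested). The CEAC grid runs from 0 to 1.5 million
CNY/QALY in 10,000-CNY steps.

## Synthetic data

Two generators make every stage testable without external data:

* `microsim.simulate_patients` — an individual-level Monte Carlo
  simulator used as an independent oracle for the cohort engine. Patients
  sample a post-30-day state, step through the monthly chain, and draw
  Bernoulli hospitalization events per live cycle; accrual uses the exact
  cost/utility/discount rules of the deterministic pipeline but omits
  half-cycle correction (events are realized at whole-cycle resolution),
  so agreement is checked against the cohort engine with the correction
  disabled — the correction itself is verified separately against closed
  forms. The cohort model is the exact expectation of this simulation;
  tests require agreement within 3 Monte Carlo standard errors at
  n = 60,000–100,000 patients.
* `microsim.generate_fixture` — emits configuration documents: jitter 0
  reproduces the shipped base case exactly; jitter > 0 perturbs
  parameters within their uncertainty bounds while preserving all
  invariants (simplexes, row sums, utility ordering).

The generators emulate a homogeneous cohort with time-homogeneous
transitions and state-independent event timing within a cycle. They do not
emulate patient-level covariate heterogeneity, age-dependent background
mortality, correlated parameter uncertainty, or repeat-hospitalization
dependence — so passing tests demonstrate internal consistency of the
model machinery, not fidelity of those published inputs to any real-world
population.

## Numerical choices and problem sizes

Transition rows must sum to 1 within 1e-12 and initial distributions
within 1e-9; traces conserve mass within 1e-9 over the full horizon. The
ICER is reported as undefined (not infinite) when ΔQALY = 0, and
"dominant" when the intervention is cheaper and more effective. The
cost-effective device price has the closed form
`price* = device − ΔC + λ·ΔE`; re-running the scenario at `price*`
reproduces `ICER = λ` to 1e-6 relative (tested). The published scenario
table rounds intermediate quantities, so its printed cost-effective price
(54,319 CNY) differs from the unrounded reconstruction (~53,900 CNY) by
about 1%; the package reports the unrounded value. The default test suite
uses 60,000-patient microsimulations and 40–2,000-draw PSAs; the analysis
scripts and acceptance run use 100,000 patients and 10,000 draws, matching
the study's iteration count.

## Limitations

Healthcare-payer perspective only (no societal costs); no EVPI; no tunnel
states or time-varying transitions; calibration recovers a plausible but
non-unique configuration consistent with the reported outcomes — other
post-30-day distributions and hospitalization profiles could reproduce
them equally well.
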