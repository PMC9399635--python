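# Methods

## Natural-history model

The disease process is a discrete-time Markov individual model with a
1-year cycle from age 20 to at most age 100 (the final cycle forces
other-cause death, so every simulated life terminates). The 15 states are
Normal, non-atrophic gastritis (NAG), atrophic gastritis (AG), intestinal
metaplasia (IM), dysplasia, preclinical gastric cancer stages I–IV,
clinical gastric cancer stages I–IV, GC death, and other-cause death; the
two death states are absorbing, and progression is strictly forward
(no spontaneous regression). Preclinical stage *k* either advances to
*k*+1 or surfaces symptomatically to clinical stage *k*; dwell times are
therefore geometric, with surfacing probabilities rising with stage
(0.08, 0.20, 0.45, 0.75 per year) — an occult stage-IV tumour rarely
stays silent for long.

Within a cycle the order is **screening → transition → accrual**:
screening acts on the state held at cycle start, the annual transition is
then sampled, and accrual covers the whole cycle. Competing risks are
composed sequentially: background mortality q_bg first (sex- and
age-specific life table), then stage-specific GC mortality among
survivors (clinical states only), then progression among the remainder,
so each kernel row sums to one exactly. Risk-factor effects multiply
annual probabilities directly, capped at 1 (capping is logged): Hp
infection multiplies NAG→AG, smoking multiplies IM→dysplasia
(light <10 cig/day and heavy ≥10 cig/day separately), and resection
multiplies dysplasia→preclinical progression and — as a residual-lesion
effect — stage-I clinical GC mortality.

Age enters through a fixed multiplier on the Normal→NAG onset edge,
piecewise-constant over 5-year bands from 20–24 (×0.40) saturating at
×1.60 from age 70; the decades-long pipeline then produces the observed
age gradient of incidence downstream. Keeping one age-varying edge keeps
the calibration problem identifiable.

### Accrual conventions

Life-years, QALYs and state costs accrue per cycle with the state held
after the screening phase; a death during the cycle (by transition or by
a screening complication) credits half a life-year and half the utility.
Clinical GC states accrue a stage-specific annual treatment cost for the
full death cycle (terminal care). Discounting is 5%/year anchored at
model entry: factor (1.05)^−(age−20), applied identically to costs and
QALYs. Utilities are 1.0 for all non-cancer states (including occult
preclinical cancer) and stage-specific below 1 for clinical cancer.

## Random numbers and common random numbers

Every stochastic decision draws from a stateless splitmix64-style hash of
(seed, individual id, year, purpose), one purpose code per decision type.
Consequences: identical inputs give bit-identical cohorts; results do not
depend on processing order or vectorization; and the same individual
re-uses the same substream under every screening strategy and parameter
perturbation, so strategy contrasts and one-way sensitivities are
common-random-number paired. The generator passes marginal-uniformity and
cross-stream independence checks in the test suite.

## Screening protocol

From the strategy's starting age, unstratified individuals and level-A
individuals due for retest take the serology panel; observed Hp and
atrophy status are conditionally independent draws through each assay's
sensitivity/specificity, with "true atrophy" defined as any state from AG
through preclinical stage IV. The observed pattern maps to levels A–D;
levels B/C/D are sticky (only level A is retested and can be promoted) —
the protocol specifies retesting only for level A. Newly assigned B/C
receive quadruple-therapy Hp eradication: the therapy cost always
accrues; infection clears with the eradication-success probability and
never recurs (no reinfection is modelled). Adherence is perfect.

Endoscopy detects lesions with grade-specific sensitivity. Detected
dysplasia is resected (80% ESD / 20% surgery by default; the guideline
offers both without stating a split); detected preclinical stage I is
resected (50/50 split) and becomes screen-detected clinical stage I with
the residual-lesion mortality reduction; detected stage II–IV converts
immediately to clinical cancer (stage costs, utilities and mortality)
with no separate resection procedure. Resections carry bleeding and
perforation risks (procedure-specific), each complication a fatality
probability, and surgery an operative-death probability; non-fatal
complications add management cost only. A false-positive endoscopy in
lesion-free mucosa buys a confirmatory-biopsy cost and nothing else.
Already-resected dysplasia is surveilled, not re-resected. Clinical
cancer (symptomatic or screen-detected) leaves the program.

## Synthetic study conditions

The published transition probabilities, test characteristics, costs and
utilities live in an unavailable supplement, so the registry's defaults
are synthetic but pinned to the published epidemiologic setting, which the
package treats as the study conditions:

* cohort composition: 67% Hp prevalence; smoking 64% (men) / 34% (women),
  split 50/50 light/heavy (no published split); equal sexes;
* unscreened burden: 11.6% lifetime GC incidence, ≈9,800 GC deaths per
  100,000 entrants, ≈86% of clinical diagnoses at stage II–IV;
* external validation: lifetime-incidence relative risks ≈4.1 for Hp+
  vs Hp− (band 2.7–7.2) and ≈1.7 for current-vs-never smoking (band
  1.5–1.8). Matching the lifetime Hp RR requires a large annual
  multiplier (12) on the single NAG→AG edge, because pipeline saturation
  damps annual effects over a lifetime;
* the Gompertz–Makeham life table (q = c + A·e^{Ba}, sex-specific, ±2%
  seeded jitter) gives life expectancy at 20 of ≈56.9 years, so the
  unscreened cohort's life-years (≈55.5, GC mortality included) sit near
  the published 56.06.

Costs are 2021 USD, plausible for the setting (serology $9, endoscopy
$45, Hp therapy $55, ESD $2,300, surgery $5,800, stage I–IV annual
treatment $3,200–$9,500); utilities 0.88/0.68/0.50/0.30 for clinical
stages I–IV. Parameter ranges default to base × [0.8, 1.2] unless a
quantity-specific bound is supplied. The `healthy_china_2030` scenario
lowers Hp and both-sex smoking prevalence to 20%.

What the generator does **not** emulate: imperfect adherence, Hp
reinfection, cardia/non-cardia subtypes, stage-specific screen-detection
lead-time bias corrections, post-ESD surveillance schedules beyond level
scheduling, or the published absolute cost level (our unscreened
discounted cost is ≈$200/person vs the published $103.6). Passing tests
therefore demonstrate internal consistency and faithful mechanics, not
forecasts for any real population.

## The matrix oracle

For the no-screening case the engine's exact expectation is computable by
forward matrix multiplication of state occupancy over the 12 risk-profile
strata (sex × Hp × smoking), using the *same* kernel builder as the
microsimulation. The oracle yields expected occupancy by age, diagnoses
by stage, GC deaths, life-years, discounted cost/QALY — used three ways:
as the deterministic model evaluator inside calibration (no stochastic
optimization pathologies), as the independent expectation the
microsimulation must match within Monte-Carlo error, and for
finite-difference monotonicity checks. Screening is history-dependent, so
the oracle deliberately refuses screening strategies.

## Calibration

The loss is a weighted sum of squared relative deviations between oracle
outputs and targets: lesion prevalence (NAG/AG/IM/dysplasia at ages
40/50/60/70 among the alive), annual GC incidence (ages 40–80), and the
clinical stage distribution. Seven quantities are searched: the five
cascade edge probabilities plus global scales on the preclinical advance
and surfacing probabilities (stage-to-stage shape is treated as model
structure; a 12-dimensional free search is not identifiable from these
targets). The search is Latin-hypercube multi-start (default 8 starts
over base × [0.5, 1.5]) refined by Nelder–Mead in log-parameter space
with an out-of-bounds penalty; a candidate is accepted when every target
sits within its stated tolerance (default 15% relative), all accepted
sets are retained for optional use in probabilistic analyses, and an
empty acceptance set raises rather than passing silently. Targets
generated from a known truth registry are recovered with sub-percent
median relative error in the shipped configuration.

## Health economics

Comparative metrics against the paired no-screening cohort: incidence
reduction on cumulative diagnosed cases; net deaths averted = GC deaths
averted − complication-related deaths (fatal complications + surgery
deaths); NNS = n / deaths averted; endoscopy- and life-year-based ratios
use undiscounted life-years (the published life-years row is
undiscounted; cost and QALY rows are discounted). Reported cells round to
the nearest integer for counts, one decimal for life-years per death
averted, three decimals for the benefit-to-harm ratio, whose numerator is
complication *events* by default (a `harm="deaths"` switch substitutes
deaths). The incremental analysis removes strictly dominated strategies,
then prunes extended dominance until incremental ICERs strictly increase
along the frontier; ICERs classify against 1× and 3× per-capita GDP
(2021: $12,552, with the 3× threshold taken as the published $37,655).

## Sensitivity analyses

One-way analysis re-runs the studied strategy and its reference at a
parameter's low and high bound under common random numbers; the tornado
ranks parameters by ICER span. The PSA samples each parameter from a
family chosen by class — beta for probabilities and utilities, gamma for
costs, lognormal for relative risks — fitted by moments from (base, low,
high) with sd = (high − low)/3.92; per draw all strategies run on the
same cohort, and the CEAC records the fraction of draws in which each
strategy has the highest net monetary benefit (ties toward lower cost).
Default PSA cohort size is 10,000 per draw as a variance/compute
trade-off; the acceptance script uses 150 draws × 4,000 individuals and
the examples smaller sizes still, chosen so a full reproduction pass
completes in about a minute on one core. Subgroup runs force the cohort's
risk profile (Hp±, never/light/heavy smoking); scenario runs cover the
lowered-prevalence policy goal and a sweep of the post-surgery
progression RR against the willingness-to-pay threshold.

## Problem sizes and numerical notes

Test and reproduction runs use n = 20,000–200,000 per cohort: oracle
agreement is checked at 200,000 (3 Monte-Carlo SEs), the strategy sweep
at 20,000–50,000 per arm, validation RRs at 50,000 per stratum. Kernel
rows sum to 1 to ≤1e−12 by construction and the sampled cumulative row is
clamped at 1 to guard against last-bin round-off. Probability caps after
RR multiplication are proportional when a row's outgoing mass would
exceed 1. JSON/CSV round-trips are bit-exact (life-table CSVs are written
with `%.17g` and read with round-trip float parsing).

## Known limitations

Stage-I "cure" after resection is approximated by a mortality multiplier
rather than a cure fraction, so treated stage-I patients carry reduced
excess risk for life. Screen-converted individuals begin clinical-state
costs and utilities the cycle after conversion (cycle-start convention),
a one-year offset for a small group. The benefit-to-harm ratio at small
cohort sizes is a ratio of two noisy counts; its monotonicity in starting
age holds in expectation but individual seeds can invert neighbouring
strategies by ~0.03 at n = 20,000, which the tests treat with a
delta-method 3-SE allowance. Simulated absolute economics (ICER level,
cost level) reflect the synthetic registry, not the published calibrated
set; structure-level results (frontier arithmetic, dominance logic,
derived-cell accounting) are validated exactly against the published
strategy table instead.
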