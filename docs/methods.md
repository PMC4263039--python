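# Methods

## Scope and model structure

The package evaluates one year of a capitated diabetes management
programme (intervention) against usual tertiary-level practice
(comparator) for adults with type 2 diabetes, from a government payer
perspective, with life-years gained (LYG) as the effect measure. Four
stages are chained: per-capita costing, cardiovascular risk effects,
cause-decomposed abridged life tables, and incremental
cost-effectiveness analysis with bootstrap uncertainty. Morbidity states
(e.g. microvascular complications), discounting and inflation adjustment
are deliberately out of scope: the horizon is a single programme year,
and the effect side is mortality-only.

## Costing

Each arm is five annual per-capita components — compensation, training,
investigations, medication & consumables (direct) and overheads
(indirect). Amounts are held as exact decimal cents (`decimal.Decimal`):
the reference accounting is exact to the cent and binary floats would
drift. ZAR is canonical; USD is a display conversion at a configurable
average exchange rate (default 8.21 ZAR/USD, the 2012 average).
Percentages are exact rationals internally and rounded half-up to one
decimal only at report time.

The programme's incentive bonus (paid per patient managed without a
diabetes-related emergency, at an amount equal to the training cost per
patient) is treated as already embedded in the packaged intervention
figures; `apply_incentive_bonus` exists for scenario analysis on raw
component costs and carries a flag so it cannot be applied twice.
Consumables follow the fixed-monthly-usage convention
(units × unit price × months). Two consultations per annum is a
documentation-level assumption: fixtures are annual aggregates, with no
per-visit modelling.

## Risk effects

Ten-year absolute risks of CHD, fatal CHD, stroke and fatal stroke per
arm and sex enter as data (percent, with standard errors). The packaged
grid is risk-engine output published for these cohorts; the
`risk_source` seam accepts any engine honouring the same contract, so a
live risk-equation implementation can be plugged in without touching the
pipeline. Risks stay in percent everywhere except inside the life-table
module.

Derived quantities per outcome/sex cell:

* ARR = R_comparator − R_intervention (percentage points);
* RR_m = R_intervention / R_comparator, the ratio that later scales
  diabetic CVD mortality;
* cost consequence = ΔC / ARR, the incremental cost per one
  percentage-point absolute risk reduction.

Demographic weighting of subgroup risks uses the weighted arithmetic
mean; the pooled SE is sqrt(Σ w̃_i · se_i²) with normalised weights. The
source analysis is silent on its pooling rule, so this variance-weighted
choice is isolated in one function and can be swapped.

## Life tables

Abridged life tables run from age 25 in 10-year bands with an open 75+
band (younger ages are excluded because including them over-states years
of life gained). Within each band, all-cause mortality decomposes as
M_T = m_IHD + m_stroke + M_other. Diabetic CVD mortality multiplies each
cause by its sex-specific hazard ratio (fatal CHD → IHD, fatal stroke →
stroke); the intervention scales the diabetic CVD causes by the
corresponding mortality reduction ratios. Both a cause-specific mode
(default: the fatal-CHD ratio on IHD, the fatal-stroke ratio on stroke)
and a pooled-CVD ratio are exposed, because the published analysis does
not state how one ratio per sex was pooled from two outcomes.

Numerical conventions, each isolated behind one function so alternatives
can be swapped:

* closed bands convert rate to probability by
  q = n·M / (1 + n·(1−a)·M) with a = 0.5 (deaths on average half-way
  through the band); person-years L = n·(l − d) + a·n·d;
* the open band contributes L = l/M (stationary-population convention)
  and absorbs all remaining survivors;
* T_x is the reverse cumulative sum of L; e_x = T_x / l_x; LYG between
  scenarios is the difference in T_25, with per-band e_x differences
  reported alongside.

The band radix is the first band's population count when life tables are
population-scaled; e_x is radix-invariant and T_x scales linearly, which
the tests assert. Sex-specific tables are built and reported separately;
no combined-sex table exists.

## Uncertainty analysis

Each of the 14 uncertainty parameters (4 hazard ratios, 8 fatal-event
risks, 2 per-capita costs) is given a normal sampler with mean at the
reported central value and sd = (upper − lower)/(2·1.96), reading the
bounds as 2.5/97.5 percentiles. All three parameter kinds are physically
positive, yet some reported lower bounds are negative — consistent with
untruncated normals in the original bootstrap. Draws at or below 1e-6
are therefore rejected and redrawn, with the rejection count tracked;
this is a deliberate, documented divergence: a hazard ratio ≤ 0 is
meaningless and would crash the life tables.

Joint draws are independent (no correlation structure is reported).
Every draw re-runs the full pipeline: risks → per-sex, per-cause
mortality ratios → diabetic life tables → national LYG → ICER. Draws
producing zero LYG leave the ICER undefined; they are excluded with a
logged count, and more than 10% exclusions aborts. Confidence intervals
are percentile (2.5/97.5) rather than BCa — the simplest interpretation
consistent with a roughly symmetric reported interval. Default 1000
iterations; the RNG seed is mandatory wherever sampling occurs, and a
fixed seed reproduces the sample vector bit-for-bit.

The WTP threshold is a configuration value with no default: the WHO
"highly cost-effective" criterion is national GDP per capita per LYG,
and the relevant 2012 figure is an external World Bank-derived quantity
(≈ZAR 62 000 ≈ USD 7 500 at 8.21 ZAR/USD), which examples and the
acceptance script pass explicitly. The CLI refuses WTP analysis without
a threshold.

National projection ships two strategies because the original
cohort-to-national aggregation is not derivable from the published
numbers: `per_band_delta_e` (default) credits each band's current
population its remaining-lifetime life-expectancy gain,
Σ_band n_band·(e_int − e_comp); `cohort_scaling` multiplies the age-25
cohort's per-capita LYG by the total population. Neither is asserted to
reproduce the originally reported national total. National incremental
cost is the per-capita difference times the covered population in both
strategies. When the population input is not sex-specific it is split
50/50 between the sexes.

## Synthetic data

The original life tables consumed national burden-of-disease mortality
schedules and diabetic population counts that are not public. The
generator emulates their structure:

* all-cause hazard is Gompertz, M_T(x) = a·exp(b·(x−25)), evaluated at
  band midpoints (nominal-width centre for the open band). Defaults
  a = 0.002 per person-year at 25 and b = 0.085 per year give adult life
  expectancies of the same magnitude as the published tables (diabetic
  e_25 ≈ 36 years after hazard-ratio inflation). The baseline is
  sex-neutral; sex differences enter downstream through the sex-specific
  hazard ratios and risk reductions.
* CVD is a constant fraction of all-cause mortality (default 0.25, an
  adult-mortality share plausible for this setting), split evenly
  between IHD and stroke (default 0.5). Both are configurable in (0,1).
* the diabetic population is a fixed unimodal distribution over the six
  bands (weights 0.06/0.17/0.26/0.25/0.17/0.09, peaking in mid-life as
  the reported counts do), apportioned by largest remainder so counts
  sum exactly to the configured total (default 674 075, the reported
  male column total).
* risk grids are generated as comparator risk minus a configurable
  generating ARR per cell, with SEs at 10% of means; a random mode
  jitters comparator means log-normally (10% CV) under the seed.

What the generator does **not** emulate: real age-band-specific CVD
shares (the CVD fraction is constant across age, whereas real shares
rise then fall), HIV/TB-era excess young-adult mortality in South
Africa, cohort effects, and any correlation between costs and risks.
Passing tests therefore demonstrate the machinery is correct and
internally consistent — not that the synthetic levels equal the original
ones. Headline ICER/LYG levels computed on synthetic schedules are
illustrative, and this is why the originally published national totals
are checked only for internal consistency (e_25 = T_25/l_25 on the
printed rows), not reproduced.

Everything is deterministic given the config: identical configs produce
bit-identical outputs.

## Verification strategy

The designated brute-force oracle is a single-year-step life table on
the exact hazard function (one-year intervals, half-interval assumption,
stationary remainder at age 130). Acceptance-level properties:

* constant hazard M: abridged e_25 agrees with the analytic 1/M within
  3% for M ∈ [0.005, 0.05] (with the L = l/M open band the agreement is
  in fact exact);
* Gompertz schedules: abridged T_25 agrees with the single-year oracle
  within 3%;
* parameter recovery: for generating mortality ratios rr_m ∈
  {0.5, 0.7, 0.9}, the pipeline's per-capita LYG matches the oracle
  within 3% (measured ≤ 0.8% at the defaults) and the deterministic ICER
  matches Δcost / oracle-LYG within 3%;
* rr_m = 1 end-to-end yields exactly zero LYG;
* degenerate (zero-width) uncertainty parameters collapse the bootstrap
  onto the deterministic point estimate exactly.

The discretisation error of the abridged table grows as mortality
lightens (the open band's single rate must represent an ever-longer
Gompertz tail); at the default parameters it is well inside the 3%
bound, and the tolerance choices above are tied to those defaults.

## Problem sizes

Default runs use 6 age bands × 2 sexes × 2 arms of life tables per
evaluation and 1000 bootstrap iterations (≈4000 life tables per PSA),
which completes in a few seconds; the oracle integrates 105 single-year
steps. These sizes match the original analysis where stated (1000
iterations) and are configurable.

## Known limitations

* The UKPDS-style risk engine is data, not code: the package cannot
  re-estimate risks from patient-level covariates.
* One-year cost horizon against lifetime effect horizon (as in the
  original design): costs are not accumulated over the life table.
* The national aggregation strategy is a modelling choice; the two
  shipped strategies differ, and neither is canonical.
* Truncated-normal samplers diverge from the original untruncated
  bootstrap for parameters whose reported bounds cross zero; with the
  packaged parameters the effect is a slight upward shift of
  hazard-ratio draws.
* The bootstrap treats all parameters as independent; any real
  correlation (e.g. between arm costs) is ignored, widening or
  narrowing the CI in unknown directions.
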