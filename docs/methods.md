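# Methods

## Study design

`pvfaers` implements an *active-comparator* disproportionality analysis on a
spontaneous-reporting database. Reports are partitioned into mutually
exclusive exposure cohorts — GLP-1RA + metformin combination, GLP-1RA
monotherapy, metformin monotherapy, other — and the combination cohort's
reporting of a target event class is contrasted against the GLP-1RA
monotherapy cohort on a 2×2 table of case/non-case counts:

|                    | target event | other events |
|--------------------|--------------|--------------|
| combination        | a            | b            |
| GLP-1RA monotherapy| c            | d            |

The whole-database background (every non-target report as comparator) is
available via configuration, since disproportionality against a restricted
active comparator and against the full database answer different questions
and can differ by an order of magnitude.

### Exposure rule

A report is *combination* when it has at least one GLP-1RA in the target
role set (default: primary suspect, PS) **and** metformin in the partner
role set (default: any of PS/SS/C/I); *GLP-1RA-only* when a GLP-1RA is in
the target role and no metformin appears in any role; *metformin-only*
symmetrically; everything else is *other*. Both role sets are configurable
because reporting practice for partner drugs varies; PS-only for the target
reflects the convention that the primary suspect is the drug judged most
likely to have caused the event. The four labels are mutually exclusive and
exhaustive by construction.

### Event classification

Events are matched at the MedDRA preferred-term (PT) level against two
shipped narrow SMQ term sets: depression excluding suicide/self-injury
(12 PTs) and suicide/self-injury (9 PTs). Matching is case-insensitive
exact string comparison; broad-scope SMQ terms and SOC-level aggregation are
out of scope. Term sets are replaceable via a two-column CSV.

### Deduplication

FAERS case IDs recur across quarterly files as follow-up versions of the
same case. One report per case ID is kept: the latest receipt date, ties
broken by the numerically largest report ID. The rule is idempotent and
never increases the report count. Output order is by case ID so downstream
results are independent of input file order.

## Disproportionality statistics

**ROR.** `ROR = ad/(bc)`; 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
No continuity correction is applied: a zero cell makes the estimate
non-estimable rather than corrected, because the signal criteria require
a ≥ 3 cases anyway and Haldane–Anscombe corrections bias small-cell RORs.

**IC.** The information component is the log2 observed-to-expected
reporting ratio with `E = (a+b)(a+c)/N`. Two estimators are provided:

- `shrinkage` (default): `IC = log₂((a+½)/(E+½))`; `IC025` is the log2 of
  the 2.5% quantile of the Gamma(a+½, rate E+½) posterior of the
  observed/expected ratio. This is the standard credibility-interval
  construction in modern Bayesian signal detection; it is defined for a = 0
  and shrinks small-count estimates toward zero.
- `plain`: `IC = log₂(aN/((a+c)(a+b)))` with the delta-method spread
  `sd = (1/ln 2)·√(1/a)` and `IC025 = IC − 2·sd`. This is a documented
  approximation: the "IC − 2 SD" formulation leaves the SD estimator open,
  and the delta-method surrogate is the simplest choice consistent with it.
  It requires a > 0.

The shrinkage estimator converges to the plain one as counts grow at fixed
ratios (tested). Which method is active is recorded in every output row.

**Signal criteria.** A signal requires, jointly: a ≥ 3 cases, ROR 95% CI
lower bound > 1, and IC025 > 0. The flag is monotone in a at fixed b, c, d.

**Unmasking.** Re-estimation after removing every report that contains a
drug of an excluded class in any role. Two specs ship: psychoactive
co-medication (antidepressants, benzodiazepines, antipsychotics, opioids,
sedatives, GABAergics) and non-metformin antidiabetics (SGLT-2i, DPP-4i,
TZD, AGI, sulfonylureas, insulins). Exclusion that empties a cohort yields
a non-estimable result carrying the reason, not an error.

**Sex subgroups.** Per-PT 2×2 tables are built within each sex stratum
(Unknown sex excluded so strata are disjoint), and the male/female ROR
ratio is reported per PT, null when either stratum is non-estimable.

## Descriptive comparison and test selection

The characteristics table (sex, weight band, age band, report source,
serious outcomes) uses the full cohort size as the denominator for every
percentage, Unknown rows included, so each block sums to the cohort size.
Serious-outcome rows are compared (outcome present vs absent, combination
vs monotherapy) with:

- uncorrected Pearson χ² when all four expected counts are ≥ 5,
- the two-sided Fisher exact test otherwise, under the probability-mass
  convention (sum of probabilities of all tables no more likely than the
  observed one).

This pair of conventions — no Yates correction, probability-mass Fisher —
is pinned because it exactly reproduces worked-example p-values recomputable
from published cohort counts (0.035 Pearson, 0.562 Fisher); a Yates-always
or Fisher-always rule does not. Age bands are 18–64 / >64 / Unknown and
weight bands <50 / 50–100 / >100 kg / Unknown, matching the conventional
presentation; a <18 band is emitted only when non-empty. A zero margin
makes a comparison not-computable rather than raising.

## Time-to-onset analysis

TTO is the number of days from the earliest *complete* therapy start date
among target-class drugs to the event date. Partial dates (FAERS emits 4-,
6- and 8-digit date strings) and non-positive intervals are excluded, with
the exclusion reason kept as data. No fabrication of missing day/month
components is attempted, and censored-data fitting is out of scope.

Summaries are the sample median and IQR (linear interpolation between order
statistics) and the Weibull shape parameter test. The two-parameter Weibull
MLE is computed by profiling the likelihood over the shape β: given β the
scale has the closed form `α = (mean(xᵝ))^{1/β}`, and the profile score
`1/β + mean(log x) − Σxᵝ log x / Σxᵝ = 0` is solved by doubling-bracket +
Brent root finding (the score is decreasing in β, so the root is unique).
95% CIs are Wald intervals on (log α, log β) from the observed information
matrix (central finite differences at the MLE), exponentiated so bounds stay
positive. Requirements: n ≥ 3 and at least two distinct values; otherwise a
degenerate-sample error. The fit is scale-equivariant (tested) and agrees
with an independent generic MLE to four significant figures on seeded
samples (tested against `scipy.stats.weibull_min.fit`).

Failure-type classification from β and its CI: *early* iff the CI upper
bound < 1 (decreasing hazard), *wear-out* iff the lower bound > 1
(increasing hazard), *random* otherwise — i.e. random is the residual
category for any CI containing 1, which keeps the three regions an
exhaustive partition of valid CIs.

Onset histograms use bins 1–30 / 31–90 / 91–180 / >180 days as 30-day
approximations of "first month / 1–3 / 3–6 / >6 months". A two-sided
Mann–Whitney rank-sum comparison of TTO samples is provided for median
contrasts; its p-values are descriptive, not a signal criterion.

## Synthetic data generator

The generator emulates the *structure* of FAERS quarterly data, not its
content: `'$'`-delimited DEMO/DRUG/REAC/THER/OUTC/RPSR tables, report/case
ID pairs, PS/SS/C/I role codes, verbatim drug names drawn from a catalog of
canonical ingredients plus brand names and development codes (so name
normalization is exercised end to end), MedDRA PT reaction strings in mixed
case, explicit Unknown demographic categories, one serious-outcome code per
report conditional on its event class, and 4/6/8-digit date strings.

Defaults are the study conditions of the motivating analysis:

| parameter | default | rationale |
|---|---|---|
| exposure mix | combination 5%, GLP-1RA-only 78%, metformin-only 7%, other 10% | combination:monotherapy ratio ≈ 0.064, matching the observed cohorts (2,634 vs 40,841) |
| background event rates | depression 1.35%, suicide/self-injury 1.16% | monotherapy reporting rates 550/40,841 and 475/40,841 |
| injected multipliers | 1.3× depression, 3.4× suicide/self-injury in the combination cohort | combination-cohort rates implied by 47/2,634 and 104/2,634 |
| onset distributions | Weibull (scale, shape): combination (70.21, 0.81), GLP-1RA (79.63, 0.69), metformin (92.40, 0.47) | published per-cohort Weibull fits; "other" reuses the GLP-1RA profile |
| duplicate rate | 5% | plausible FAERS follow-up-version contamination |
| partial-date rate | 10% per date | exercises the partial-date exclusions |
| demographics | F 56% / M 38% / Unknown 6%; age 18–64 55%, >64 15%, Unknown 30%; weight Unknown-heavy | rounded from the observed cohort characteristics |

Event dates are therapy start + a Weibull draw rounded to whole days
(minimum 1), receipt = event + a 0–60-day reporting delay, so therapy start
always precedes the event. Duplicates are near-copies with a new (larger)
report ID and a 1–90-day later receipt date, exercising the keep-latest
rule; their case IDs are recorded in the ground-truth sidecar. The
ground truth also stores the per-(exposure, term-set) rates and multipliers,
from which expected 2×2 cells and the theoretical odds ratio
`(r_t/(1−r_t))/(r_c/(1−r_c))` follow.

**What the generator does not emulate** — and hence what passing tests do
not establish about real FAERS data: event flags are independent Bernoulli
draws per term set (no within-report reaction correlation beyond the
injected rates), drug-market shares are uniform within a class, reporting
rates are stationary over the 2014Q1–2024Q3 window, indications are not
modelled (no "diabetic or obese" filter semantics), and duplicates are exact
near-copies rather than the partially conflicting re-submissions real FAERS
contains. Recovery of an injected signal therefore validates the
*arithmetic and plumbing* of the pipeline, not the epidemiology of any real
drug-event pair.

## Calibration and power, as tested

Under the null (all multipliers 1) the full generate → ingest → dedup →
cohort → signal chain flags a non-injected term set in ≤ 10% of 100 seeded
replicates at 4,000 reports each (the joint three-part criterion is
conservative; the observed rate is far below the bound). An injected 10×
reporting-rate multiplier at 50,000 reports is flagged in ≥ 90% of
replicates, and the mean recovered ROR over seeded replicates at injected
multipliers 5/10/20 lies within 25% of the theoretical odds ratio. Weibull
shape recovery at n = 111 over 200 replicates is unbiased within 5% for
shapes 0.5–1.2 with Wald CI coverage within 95% ± 4 points. Problem sizes
(4,000-report null replicates, 50,000-report power replicates, 200-replicate
recovery runs) were chosen as the smallest giving stable Monte-Carlo checks.

## Numerical and degenerate-input choices

- Fisher's exact p agrees with exhaustive hypergeometric enumeration on all
  2×2 tables with n ≤ 30 (tested).
- Probability vectors must sum to 1 within 1e-9; violations raise a
  configuration error naming the field.
- The `'$'` dialect has no quoting or escaping; a field containing the
  delimiter is rejected at write time, a row with the wrong field count is
  rejected at read time with its line number.
- Ages are normalized to years from the FAERS age-unit code; unknown units
  map to missing rather than guessed.
- Unknown report sources and sexes are explicit `Unknown` categories, in
  denominators for percentages but excluded from sex strata.
- All randomness flows from a single integer seed per run
  (`numpy.random.default_rng`); identical config + seed gives byte-identical
  outputs, and the run manifest records the config hash and seed.

## Known limitations

- The shipped term sets are the two narrow SMQ PT lists only; no MedDRA
  hierarchy is included, so spelling variants of a PT outside the lists will
  not match.
- Published headline RORs for the motivating analysis are not reproducible
  from printed cohort totals under the active-comparator design, so the
  package asserts its statistics against arithmetic and simulation ground
  truth, not against those published point estimates.
- No censoring in the Weibull fit: reports lacking a complete start or
  event date are excluded, which in real data may bias onset estimates
  toward well-documented cases.
- PRR, EBGM/MGPS and regression-based signal detection are not implemented.
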