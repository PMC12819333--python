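# Methods

`pvsignal` implements the standard quantitative toolkit of spontaneous-report
pharmacovigilance — disproportionality signal detection plus time-to-onset
(TTO) characterization — for FAERS-style quarterly data, with a synthetic
generator that supplies ground-truth-bearing test data in the exact input
format. This note records the models, the numerical choices, and what the
validation battery does and does not establish.

## Report model and deduplication

The unit of analysis is the *report*: one deduplicated spontaneous
adverse-event report with demographics, drugs (with role codes), reaction
preferred terms (PTs), therapy dates and outcomes. One patient case
(CASEID) may be submitted repeatedly as new report versions (PRIMARYID);
the FDA rule keeps, per case, the version with the latest receipt date
(FDA_DT), breaking FDA_DT ties by the highest PRIMARYID. Records whose
FDA_DT does not parse sort before every dated record, so the rule remains a
deterministic total order; such records can only be kept if the whole case
is undated. Deduplication is idempotent by construction and the store
asserts CASEID and PRIMARYID uniqueness afterwards.

Age is normalized to years from the FAERS unit code (YR x1, MON /12,
WK /52.14, DY /365.25, DEC x10, HR /8766); unknown unit codes and results
outside [0, 120] years become missing rather than guessed. Exposure
classification requires the drug role "primary suspect" (PS): a report is
*monotherapy* for an agent when that agent is its only immune checkpoint
inhibitor (ICI) and is PS; *combination* when two or more ICIs appear with
at least one PS. Combination reports are counted once, under their
combination label, never under each constituent's monotherapy table.

## Disproportionality statistics

Every estimator works on the whole-database 2x2 table for one exposure:
a = reports with exposure and event, b = exposure only, c = event only,
d = neither, N = a+b+c+d. No stratification or multiplicity adjustment is
applied; one unstratified table per exposure.

* **ROR** = ad/bc with the Woolf interval
  exp(ln ROR ± 1.96 sqrt(1/a+1/b+1/c+1/d)). If any cell is zero, 0.5 is
  added to all four cells (Haldane) and the result is flagged degenerate.
* **PRR** = [a/(a+b)] / [c/(c+d)] with the Pearson chi-square of the 2x2,
  uncorrected by default (a Yates flag exists). Same zero-cell rule.
* **BCPNN information component.** IC = log2 P(drug, event) /
  (P(drug) P(event)) with Beta/Dirichlet priors (alpha1 = beta1 =
  gamma11 = 1; alpha = beta = 2), evaluated by the closed-form posterior
  approximation; IC025 = IC − 1.96 sqrt(Var[IC]). The constants and z are
  pinned in `disprop.BCPNN_PRIORS` / `disprop.Z_95`. Validity domain: a
  Monte-Carlo check against the exact Beta posteriors (10^6 draws) shows
  the IC mean accurate to < 0.04 bits across small tables, but the normal
  approximation of IC025 drifts beyond 0.05 bits once a ≲ 12 because the
  posterior of log2 is skewed at small counts; the oracle tests therefore
  run on tables with a ≥ 20. No zero-cell correction: the formulas are
  defined at a = 0.
* **MGPS / EBGM.** Counts on the full drug x event grid (zeros included)
  are modeled as Poisson with rate lambda·E, E the independence
  expectation, and lambda drawn from a two-component gamma mixture. The
  marginal is a negative-binomial mixture; hyperparameters are fitted by
  maximum marginal likelihood from the conventional start
  (0.2, 0.1, 2.0, 4.0, 1/3) in log/logit coordinates. Powell's
  derivative-free search is used, followed by a Nelder–Mead polish: a
  plain simplex from that start reproducibly stalls in a degenerate
  two-point-mass basin on realistic grids (verified ~25 nats below the
  optimum). Transformed parameters are boxed at |log theta| <= 12 — beyond
  e^12 the prior is numerically a point mass and scipy's negative-binomial
  pmf loses meaning — and grid cells are lexicographically sorted before
  summation so the fit is exactly permutation-invariant. EBGM =
  exp(E[ln lambda | a]) via digamma; EBGM05 is the 5% quantile of the
  posterior gamma mixture found by bracketed root-finding on the mixture
  CDF (absolute tolerance 1e-8).

Positivity criteria: ROR signal iff ROR > 1, CI lower bound > 1 and
a >= 3; PRR signal iff PRR >= 2, chi-square >= 4 and a >= 3; BCPNN signal
iff IC025 > 0; MGPS signal iff EBGM05 > 2. Thresholds printed as strict
are strict (an exposure sitting exactly on a threshold is negative), and
any exposure with fewer than three cases is reported all-negative.

## Time to onset

TTO is the calendar-day span from therapy start (earliest day-precision
START_DT among the suspect ICI's therapy rows, linked by drug-sequence key
when present) to event onset (EVENT_DT). Only day-precision pairs count;
partial or missing dates are excluded as *omission*, negative spans as
*discrepancy*, and zero-day spans as *same-day* — observed onsets in this
setting start at one day, and a zero-day span is indistinguishable from
date-entry duplication. Each exclusion is tagged so the validity partition
(valid / omission / discrepancy / same-day) sums to the cohort.

Summaries use the type-7 linearly interpolated median and quartiles. The
Weibull fit maximizes the likelihood through the one-dimensional profile in
the shape: for fixed shape beta the scale MLE is mean(x^beta)^(1/beta),
leaving a strictly decreasing score in beta solved by Brent's method
(tolerance 1e-10). Confidence intervals default to a seeded nonparametric
percentile bootstrap (1000 resamples); the published intervals this package
is validated against are strongly asymmetric, which a symmetric Wald
interval cannot produce (a Wald-on-log option exists). The hazard is typed
from the shape CI: entirely below 1 → "early failure" (onset hazard peaks
just after treatment start and declines), entirely above 1 → "wear-out",
straddling → "random" (constant hazard). The CI-based rule trades a little
sensitivity for misclassification control: simulated constant-hazard data
(beta = 1, n = 250) is typed "random" in ≈ 95% of seeds.

Kaplan–Meier cumulative onset is computed with every record an event —
case-only TTO data carry no censoring, so the curve equals the empirical
CDF exactly; censoring indicators are refused rather than ignored.
Pairwise group contrasts use the two-sided Mann–Whitney U (exact
enumeration when both groups have n <= 8 and the pooled sample is
tie-free; tie-corrected normal approximation otherwise) with Bonferroni
adjustment p_adj = min(1, m·p_raw). The default comparison list includes
the overlapping "All ICIs vs subclass" contrasts used in this study
design; overlapping groups violate the test's independence assumption, and
the pipeline log says so — fidelity over orthodoxy.

## Synthetic generator

`synth.generate` emits the six quarterly tables in the FAERS dialect with
all latent quantities controlled: per-agent exposure marginals, a
multiplicative planted reporting-rate ratio rho (event probability
rho·p0 on signal exposures, p0 elsewhere), per-class Weibull onset times
(dates constructed backward from a uniform event date in the quarter),
demographic marginals, date degradation (truncation to month or year
precision, or blanking, chosen uniformly among start/event modes), and
CASEID duplication with strictly later FDA_DT (an optional tie flag
exercises the PRIMARYID tiebreak). `expected_cells` gives the exact
pre-duplication cell expectations, hence the exact implied odds ratio:
the implied ROR equals rho only in the small-p0 limit, and tests use the
closed form rather than the approximation. Recovery experiments plant one
signal per generated database — with several strong signals sharing one
comparator, the background is itself enriched and each exposure's odds
ratio targets a visibly smaller quantity than its rho.

The shipped "paper-mimic" configuration reproduces the published irBP
reporting profile as generator truth: per-agent rhos near the published
RORs, agent marginals solved so expected case shares across the three ICI
classes are 87.5/7.3/5.2%, ICI share of all reports 1% (a small share
keeps the comparator essentially uncontaminated, as in the real database),
background event probability 0.005, male share 67.8%, valid-TTO share
29.29%, class Weibull onset parameters (295.85, 0.83), (137.83, 0.69),
(76.24, 0.48), and 5% duplication.

What the generator does *not* emulate: reporting biases (stimulated
reporting, the Weber effect), drug-name misspellings, multi-PT reaction
lists per report, within-report demographic/exposure correlations, or
secular trends. Passing recovery tests therefore shows the estimators
invert this generative model correctly at realistic sizes — not that real
FAERS signals are unconfounded.

## Validation battery and problem sizes

The experiment sizes are chosen to give stable pass/fail behavior at
desk scale: ROR CI coverage over rho in {2, 5, 10, 30} uses 100 datasets
of 50,000 reports per rho (exposure marginal 0.05, p0 = 0.001 so the
implied odds ratio sits within a small fraction of a standard error of
rho); Weibull shape recovery uses 200 samples of n = 250 per shape in
{0.5, 0.8, 1.0, 1.5}; hazard typing uses 200 (constant hazard) and 100
(published all-agents profile, n = 249) bootstrap-fitted samples; the
paper-mimic pipeline run uses 200,000 reports. The BCPNN Monte-Carlo
oracle uses 10^6 posterior draws per table on twenty tables.

## Known limitations

* The whole-database comparator is unstratified; age/sex-adjusted or
  regression-based disproportionality is out of scope.
* The packaged pemphigoid PT list is a flat stand-in for the licensed
  MedDRA standardized query; users can substitute their own list.
* The BCPNN closed form should not be trusted for IC025 below roughly a
  dozen cases (see above); the IC point estimate remains accurate.
* Legacy (pre-2012) quarters are supported only through the
  ISR→PRIMARYID / CASE→CASEID header mapping, not a full schema port.
* With both FDA_DT values unparseable within a case, the PRIMARYID
  tiebreak alone decides; this is deterministic but arbitrary.
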