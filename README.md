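# pvsignal

Disproportionality signal detection and time-to-onset analysis for
FAERS-style spontaneous adverse-event reports, built around the
immune-checkpoint-inhibitor (ICI) / bullous-pemphigoid use case: read and
deduplicate quarterly FAERS ASCII tables, select an event cohort by MedDRA
preferred terms, classify ICI therapy regimens, compute four
disproportionality statistics with their conventional positivity criteria,
and characterize onset timing with Weibull hazard typing, Kaplan–Meier
cumulative-onset curves and pairwise rank tests. A synthetic FAERS-format
generator with closed-form ground truth makes the whole pipeline testable
without downloading the database.

Intended users: pharmacovigilance analysts and methods researchers who
want a scriptable, reproducible version of the standard signal-detection
stack, and anyone needing realistic FAERS-shaped test data.

## The statistics

For one exposure, reports are cross-classified against the event over the
whole database: `a` exposed with event, `b` exposed without, `c` event
without exposure, `d` neither (N = a+b+c+d). Four estimators of
over-reporting are computed per exposure, each with its signal criterion:

| Method | Statistic | Signal when |
|---|---|---|
| ROR | ad/bc, Woolf 95% CI | ROR > 1, CI low > 1, a ≥ 3 |
| PRR | [a/(a+b)]/[c/(c+d)], Pearson χ² | PRR ≥ 2, χ² ≥ 4, a ≥ 3 |
| BCPNN | IC = log₂ P(x,y)/(P(x)P(y)), closed-form posterior | IC₀₂₅ > 0 |
| MGPS | EBGM from a two-gamma empirical-Bayes prior | EBGM₀₅ > 2 |

Time to onset (days from therapy start to event onset, day-precision dates
only) is summarized by interpolated median/IQR and fitted with a Weibull
model; the shape parameter β types the hazard (β < 1: early-failure — the
onset hazard peaks right after treatment start and declines). Group
contrasts use two-sided Mann–Whitney U with Bonferroni adjustment.

See `docs/methods.md` for formulas, priors, and numerical choices.

## Worked example

Generate a synthetic quarter whose ground truth mirrors the published ICI
bullous-pemphigoid reporting profile, then run the full pipeline:

```
pvsignal synth --n 200000 --seed 1 --out quarter/
pvsignal run --config run.yaml          # or, from Python:
```

```python
from pvsignal import pipeline, synth

cfg = synth.paper_mimic_config(n_reports=200_000, seed=3)
synth.generate(cfg, "quarter")
bundle = pipeline.run(pipeline.RunConfig(
    quarter_dirs=["quarter"], out_dir="out", seed=4))
print(bundle["signals"][["exposure", "n", "ROR", "ROR_low", "ROR_high",
                         "ror_pos"]].head(4).round(2).to_string(index=False))
```

```
exposure   n   ROR  ROR_low  ROR_high  ror_pos
     all 164 19.49    16.40     23.16     True
   PD-1i 145 23.79    19.81     28.58     True
  PD-L1i  11  6.03     3.30     11.03     True
 CTLA-4i   8  8.10     3.98     16.49     True
```

With 200,000 reports and a planted 1% ICI share, this run finds 164 event
cases among ICI-exposed reports. The estimated class RORs sit on their
planted truths — the generator's exact implied odds ratios for this
configuration are 18.34 (all), 22.83 (PD-1i), 5.71 (PD-L1i) and 7.83
(CTLA-4i) — and every class is positive on the ROR criterion. Exposures
with only a handful of cases (here CTLA-4i, n = 8) fluctuate visibly from
seed to seed; the CI width reflects that. The reporting-rate ratios were
chosen so these values land near the published FAERS estimates (All-ICIs
ROR 18.90, PD-1 22.66). `out/` also receives the cohort summary, the
per-exposure signal table (all four statistics and flags), onset-time test
and Weibull tables, cumulative-onset curves, and a flow-count audit of
each filtering step (here: 209,760 DEMO rows → 200,000 deduplicated
reports → 1,086 event reports → 164 with a primary-suspect ICI → 43 with
valid onset dates).

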