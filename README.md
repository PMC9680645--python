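# finpheno

Financial-behavioral phenotyping of mood episodes from personal bank-statement
ledgers.

Hypomanic episodes in bipolar disorder often surface first in spending:
short bursts of frequent purchases, shifts of expenditure onto credit, and
abrupt collapses of activity as an episode resolves. `finpheno` turns two
modest inputs — delimited bank-statement exports (with the layout artifacts
typical of table extraction from digitized statements) and a retrospective
monthly life chart of mania/depression severity ratings (NIMH Life-Chart
Method) — into a privacy-preserving analysis of those dynamics:

1. **Ingest** — parse statement exports in which a transaction may span
   multiple physical rows, several accounts may share a file, and one account
   spans many monthly files; assemble one date-sorted ledger.
2. **Privacy transform & labeling** — drop income rows, blank all
   descriptions, min-max rescale amounts to [0, 1] per account, and label each
   transaction with its month's mania severity (`none` / `mild` / `moderate`,
   plus a merged `none` / `symptomatic` view).
3. **Features** — daily/weekly/monthly transaction *frequency* (count) and
   *volume* (sum of normalized amounts), with zero-filled periods, and the
   monthly percentage of purchases made on credit.
4. **Burstiness** — B = (r − 1)/(r + 1), where r = σ/τ is the coefficient of
   variation of inter-event intervals. Two day-grain interval schemes:
   B_D (day differences between successive transactions) and B_C (lengths of
   maximal zero-expenditure day runs); overall and per symptomatic phase.
   B = −1 is perfectly regular spending, 0 memoryless, → 1 extreme spikes.
5. **Phase inference** — Welch's heteroscedastic one-way ANOVA plus
   Games-Howell post-hoc contrasts (implemented from formulas) comparing
   per-period frequency and volume across phases.
6. **Anomaly detection** — an isolation forest (own implementation, scored as
   s(x) = 2^(−E[h(x)]/c(ψ))) over the weekly frequency series, flagging
   exactly ⌊contamination · n⌋ top-scoring weeks.

Real ledgers of this kind are private, so the package ships a first-class
**synthetic generator**: a 24-month, two-account ledger at ≈5.2 expenditures
per day whose episode layout (two mild runs totaling 5 months, five moderate
runs totaling 9 months), phase rate multipliers, credit-shift probabilities
and inter-event law (Poisson or heavy-tailed renewal) are all configurable —
along with a statement writer that reproduces the extraction artifacts and
round-trips losslessly through the parser.

Intended users: computational psychiatry / digital-phenotyping researchers
prototyping financial-behavioral markers, and methodologists who need a
tested, reproducible reference pipeline for burstiness and phase-stratified
spending analyses.

## Worked example

```python
from datetime import date
from finpheno import (
    SyntheticConfig, case_study_lifechart, generate_ledger,
    preprocess_ledger, resample, Grain, burstiness_by_phase, Scheme,
    welch_anova, phase_summary,
)
from finpheno.group_inference import phase_groups

chart = case_study_lifechart()                 # 24 months, 2017-2018
ledger, truth = generate_ledger(chart, SyntheticConfig(seed=1))
labeled = preprocess_ledger(ledger, chart)     # filter -> strip -> normalize -> label
span = (date(2017, 1, 1), date(2018, 12, 31))
daily = resample(labeled, Grain.DAILY, chart=chart, span=span)

print(phase_summary(daily))
for r in burstiness_by_phase(labeled, daily, Scheme.D):
    print(f"B_D[{r.phase}] = {r.B:+.3f}  (n = {r.n})")
w = welch_anova(phase_groups(daily, "frequency"))
print(f"Welch F({w.df1:.0f}, {w.df2:.1f}) = {w.F:.3f}, p = {w.p:.3f}")
```

prints

```
           none  mild  moderate
frequency  5.33  5.15      5.34
volume     0.23  0.22      0.27
B_D[none] = +0.806  (n = 1640)
B_D[mild] = +0.898  (n = 761)
B_D[moderate] = +0.846  (n = 1461)
B_D[overall] = +0.349  (n = 3864)
Welch F(2, 389.2) = 0.383, p = 0.682
```

Reading: phase mean daily frequencies sit near their generator targets
(5.23/5.49/5.34); the overall stream is moderately bursty at day grain
(B_D ≈ 0.35 — same-day purchase clusters inflate dispersion), while
per-phase values are higher because between-episode gaps enter each phase's
own interval sequence; the small default phase effects are, as intended,
not significant at this span (p = 0.68).

The same workflow is available from the shell:

```bash
finpheno simulate --out run/ --seed 1
finpheno ingest --in run/statements --out run/ledger.csv
finpheno label --ledger run/ledger.csv --chart run/chart.csv --out run/labeled.csv
finpheno run --config pipeline.yaml --out run/       # everything + manifest
```

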