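# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical choices, and the open design decisions behind `finpheno`.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Setting and data model

The pipeline analyzes an N=1 personal ledger: dated, account-labeled
monetary records from a checking and a credit account, at day resolution
(statement exports list transactions by date only — every temporal statistic
here is therefore day-grain). Mood context comes from a retrospective NIMH
Life-Chart Method (LCM) chart: one mania and one depression severity rating
(`none`/`mild`/`moderate`/`severe`) per calendar month. An *episode* is a
maximal run of consecutive months at the same non-none severity; a change of
severity breaks the run, so adjacent months at different non-none levels are
distinct episodes.

The packaged case-study chart spans 2017-01 through 2018-12 with two mild
episodes totaling 5 months, five moderate episodes totaling 9 months, and no
depressive symptoms. Only these aggregates are meaningful; the placement of
the runs within the span is an arbitrary fixed choice (it tapers the episode
off in late 2018), and no test depends on placement beyond the aggregates.

## Statement ingest

Exports produced by table extraction from digitized statements carry three
layout artifacts the parser absorbs: transactions spanning multiple physical
rows, multiple account sections per file, and one account spanning many
monthly files. Parsing is dialect-driven (column indices, strptime date
format, account-marker regex, sign convention); nothing is inferred from
locale. Detection rules the source material leaves open, fixed here:

- a row with empty date *and* amount cells but a non-empty description is a
  continuation of the preceding transaction (descriptions joined with a
  single space); any other malformed row is collected as a record-level
  error and skipped, so that parsed + skipped = logical records;
- a dedicated marker row (configurable regex) switches the account context;
  a transaction row before any marker with no dialect default is fatal;
- income vs expenditure is a dialect sign convention (default: negative
  amounts are expenditures), since statements encode this differently.

Amounts stay exact `Decimal` through ingest (no cent-level float drift);
expenditures are stored as positive magnitudes with a direction field.
When monthly files overlap, identical records are deduplicated by taking
the per-record maximum multiplicity across files — repeated identical
purchases within one file are genuine and kept.

## Privacy transform

In order, the pipeline (a) drops income rows (the analysis targets
expenditure, over which an individual has more control), (b) blanks all
descriptions, and (c) min-max rescales amounts to [0, 1] independently per
account over the full analysis span: x' = (x − min)/(max − min). The
serialized analysis dataset therefore contains no free text and no raw
monetary value. "Between 0 and 1" is read as min-max (divide-by-max would
leave a positive floor above 0); a `divide_by_max` option exists for
sensitivity analysis. An account with a single distinct amount maps to 0
everywhere, with a warning. Filtering and stripping commute; normalization
is exactly idempotent on already-normalized accounts. Normalizing after
income exclusion is a documented assumption (the two orders coincide only
because income is excluded).

Each transaction then receives its month's mania severity, plus the merged
binary label (`symptomatic` iff severity ≠ `none`). Transactions in months
outside the chart are a hard error by default (`strict`); `lenient` labels
them `none` with a warning.

## Feature series

*Frequency* = transaction count per period; *volume* = sum of normalized
amounts per period. Resampling covers every calendar period in the span,
zero-filled — required because the zero-expenditure interval scheme reads
empty days off the daily series. Weekly bins anchor on Monday (configurable).
Period severity: daily and monthly periods take their month's rating; a
weekly period crossing a month boundary takes the rating of the month
holding the majority of its in-span days (ties to the earlier month — with
7-day weeks and in-span clipping, ties require a custom anchor).

Edge periods clipped by the span (a week with 1 in-span day, a month the
span enters mid-way) are *included* in the series but marked `partial`:
their counts are mechanically depressed by censoring, not behavior.
Downstream, the anomaly stage excludes partial periods by default (see
below); the inference and burstiness stages run at daily grain, where no
period is partial.

The monthly credit ratio is 100 × (credit transactions)/(all transactions),
by count. Count, not volume: per-account normalization makes cross-account
volume sums incommensurable, so a volume-based ratio would be meaningless;
a volume variant exists but is off by default. Months with zero
transactions are omitted with a warning.

## Burstiness

For an interval sample x₁…xₙ, B = (r − 1)/(r + 1) with r = σ/τ, τ the mean
and σ the standard deviation. σ is the **population** (n-denominator) form
by default — the definition does not specify, and the population form makes
the σ = 0 ⇒ B = −1 identity exact; `ddof=1` is available for sensitivity.
B ∈ [−1, 1): −1 for perfectly regular timing, 0 for a memoryless process,
and 1 only in the r → ∞ limit. B is scale-invariant and, at fixed τ,
strictly increasing in σ. τ = 0 (all-zero intervals) is undefined and
raises; fewer than 2 intervals is insufficient data.

Two day-grain interval schemes:

- **Scheme D** — day differences between successive transactions (n − 1
  intervals for n transactions; same-day pairs give zeros). At several
  transactions per day, these zeros dominate and push B_D positive even for
  a memoryless generator — a discretization effect worth keeping in mind:
  B_D at day grain measures clustering relative to the daily grid, not
  sub-daily timing.
- **Scheme C** — lengths of maximal runs of zero-expenditure days in the
  zero-filled daily series. Runs touching the span edges are censored;
  they are included by default (`include_edges=False` drops them). At high
  spending rates zero days are rare and scheme C is frequently undefined
  (< 2 runs) — reported as an undefined result, not an error.

Per-phase values group the transaction stream (scheme D) or the daily
series (scheme C) by phase label and compute intervals within each phase's
own subsequence; gaps that cross a phase boundary are not assigned to
either phase. Consequence: months between two episodes of the same phase
appear as long intervals inside that phase's subsequence, so per-phase B
can exceed the overall B substantially. The alternative (per-episode
computation with pooling) is defensible but was not chosen; the grouped
subsequence matches the phase-grouping description and avoids
double-counting boundary gaps. Phases with insufficient intervals yield
results flagged `defined=False`.

## Phase inference

Welch's one-way ANOVA and Games-Howell post-hoc contrasts are implemented
from their defining formulas (see `group_inference` module docstring for
the algebra); only the F and studentized-range distribution tails come from
`scipy` (`scipy.stats.studentized_range`, a vetted implementation; its
documented accuracy is well below the 1e-6 oracle tolerance used in tests).
`pingouin` — an independent code path — is the test oracle, with exact
small-sample identities as additional anchors: for k = 2, Welch F = t² and
the Games-Howell p equals the Welch t-test p (the studentized range with
2 groups reduces to √2·|t|). The balanced equal-variance identity with the
classic ANOVA F is exact only at k = 2; for k ≥ 3 the Welch denominator
carries an O(1/n) correction, so the test suite checks convergence there.
df1 is always k − 1.

Daily grain is the default inference grain; frequency and volume are tested
separately with no multiplicity correction across the two endpoints — a
deliberate mirroring of common practice in this setting, noted as a
limitation.

## Isolation forest

Own implementation (so the internals are assertable; `scikit-learn` is only
a cross-check in tests). ψ = min(256, n) uniform subsample per tree, 100
trees, uniform random split between per-node min and max, height limit
⌈log₂ ψ⌉. Scores s(x) = 2^(−E[h(x)]/c(ψ)) with the standard average-path-
length normalizer c(n) = 2H(n−1) − 2(n−1)/n; unexpanded leaves contribute
c(size). Constant input admits no isolating split: the model is flagged
degenerate and scores are uniformly 0.5.

Input is the weekly frequency series as a single feature (a
frequency+volume mode exists, off by default). Scoring is transductive
(fit and score the same series). Flagging: exactly k = ⌊contamination · n⌋
top-scoring points, ties to the earlier period; the reported threshold is
the (1 − contamination) score quantile. The default contamination 0.05 is a
user-supplied judgment, not estimated. Partial edge weeks are excluded from
fitting and flagging by default — their censored counts otherwise absorb
flags as guaranteed low-frequency "anomalies" that reflect the observation
window, not behavior; their report entries carry NaN scores.

## Synthetic data model

The generator emulates the study conditions, not retail reality. Defaults:

| parameter | default | rationale |
|---|---|---|
| span | 24 months from 2017-01 | case-study duration |
| episode layout | mild runs (2, 3) months; moderate (2, 2, 2, 2, 1) | case-study aggregates: 2 episodes/5 months, 5 episodes/9 months |
| base daily rate λ₀ | 5.23 /day | none-phase mean daily frequency |
| phase multipliers | mild 5.49/5.23 ≈ 1.050, moderate 5.34/5.23 ≈ 1.021 | ratios of the case study's phase means — deliberately near-null effects; tests needing detectable signal inflate them explicitly (e.g. moderate ×1.3) |
| amount law | log-normal, meanlog 3.1/3.2/3.3, sdlog 1.0–1.1 by phase | right-skewed positive spending; levels are free choices, not sourced (normalized volume depends on the private normalization span) |
| credit probability | none 0.25, mild 0.35, moderate 0.40 | rises with severity to emulate the credit-shift dynamic |
| interval law | `poisson` (daily Poisson counts) or `heavy_tailed` (Lomax renewal, shape α = 2.2) | spans the memoryless and bursty regimes; at λ₀ ≈ 5/day, day-grain B_D is ≈ 0.35 even in Poisson mode (same-day zeros), and the heavy-tailed default moves the 50-seed mean into the 0.3–0.5 band |
| income | 2 deposits/month, log-normal(7.3, 0.25), checking | excluded by the pipeline; exercises the filter |

Daily counts are Poisson(λ₀ · multiplier(day)) in `poisson` mode; in
`heavy_tailed` mode a renewal process accumulates Lomax inter-event times
with mean matched to the local rate and floors event times to days
(α must exceed 2 so the variance is finite). Everything is drawn from one
`numpy` PCG64 generator, so identical config + seed reproduce byte-identical
statement files. A `GroundTruth` record (per-transaction phase, per-day
rate, episode windows, income count) enables bookkeeping and recovery tests.

Randomized episode placement (off by default) places the runs uniformly
subject to same-severity runs staying separated, preserving the aggregate
counts across seeds.

What the generator does **not** model: merchant categories, recurring
bills, paydays, depressive-phase spending changes, sub-daily timestamps,
or any dependence of amounts on frequency. Passing tests therefore show
that the pipeline recovers the effects the generator encodes at the study's
scale — not that real ledgers behave this way.

## Numerical and procedural choices

- Currency is exact `Decimal` until normalization; analysis stages use
  binary floats. Normalization idempotence is asserted at 1e-12.
- Burstiness scale invariance is asserted at 1e-9 (catastrophic
  cancellation is possible for near-constant large intervals).
- Statistical calibration checks in the test suite use committed seed
  blocks and replicate counts sized so the binomial noise of the estimated
  rate is small against the acceptance band (1000 replicate ledgers for the
  null rejection rate, 5000 draws for the type-I check at n = (15, 20, 25)).
- Problem sizes in tests (24-month ledgers at ≈5/day, 200-seed power loops)
  are the study's own scale; the power analysis inflates the moderate
  multiplier to 1.3, where Welch power at daily grain exceeds 0.8.
- Degenerate inputs are first-class: empty ledgers, all-income ledgers,
  single-distinct-amount accounts, spend-every-day series (no scheme-C
  intervals), constant anomaly input, zero-flag contamination — each has a
  defined behavior (warning, undefined-flag, or typed error) and a test.

## Known limitations

- Day grain throughout; sub-daily burstiness is out of reach by design.
- Scheme C is frequently undefined at realistic spending rates; both the
  overall and per-phase variants are reported without asserting any
  particular relationship between them.
- Per-phase scheme-D burstiness conflates within-episode dynamics with
  between-episode gaps (see above); interpret against the overall value.
- No multiplicity correction across the frequency/volume endpoints.
- The N=1 design means phase contrasts are within-person only; nothing
  here generalizes across individuals.
- No PDF extraction: ingest starts at delimited text that reproduces the
  extraction artifacts.
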