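# Methods

## The statistical model

Spontaneous-report databases have no denominator: reports arrive only
when someone suspects a drug–event link, so incidence cannot be
estimated.  Disproportionality analysis instead compares, within the
database, the reporting frequency of an event for a target drug with
its frequency among all other reports.  Every statistic here is a
function of the fourfold table (a, b, c, d) with N = a + b + c + d,
where a counts deduplicated reports naming both the target drug
(primary-suspect role) and the event term, and the counting unit is
the report (a report never contributes more than 1 to a cell, and a
report with two PTs inside one SOC adds 1 to that SOC).

Four algorithms are computed jointly, as is conventional — the
frequentist pair is sensitive, the Bayesian pair shrinks small counts,
and requiring agreement of all four suppresses false positives:

* **ROR** (a·d)/(b·c), with Woolf's lognormal CI
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).
* **PRR** (a/(a+b))/(c/(c+d)), CI via
  SE(ln PRR) = √(1/a − 1/(a+b) + 1/c − 1/(c+d)).
* **Pearson χ²** of the 2×2 table, Yates-corrected by default.
* **BCPNN**: the information component IC = log₂(a·N/((a+b)(a+c)))
  and the closed-form posterior moments of Bate et al. (1998) with the
  standard priors α₁ = β₁ = γ₁₁ = 1, α = β = 2, and
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)), which centres E[IC] at 0 under
  independence.  The credibility bound is IC025 = E[IC] − 2·√V[IC]
  (the two-standard-deviation form, not a posterior quantile).
* **EBGM**: reported as the relative reporting ratio
  a·N/((a+b)(a+c)) with a lognormal interval using the same SE as the
  ROR; EBGM05 is the lower bound.  No DuMouchel gamma-mixture (MGPS)
  shrinkage fit is performed, so EBGM = 2^IC identically — a property
  the test suite asserts at machine precision and that also holds in
  published FAERS tables computed this way (e.g. EBGM 3.62 with
  IC 1.86 = log₂ 3.62).

Screening keeps terms with a ≥ 3 and flags, per algorithm:
ROR ≥ 3 with CI lower bound > 1 (the point threshold is configurable
and may be disabled — ROR ≥ 2 or CI-only conventions exist); PRR ≥ 2
with CI lower bound > 1; IC025 > 0 (strict); EBGM05 > 2 (strict).
"All four positive" is the conjunction.

Assumptions worth stating: the comparator is *all other reports* in
the ingested quarters (full-background design); analyses are crude
(no age/sex/period stratification); the Wald intervals are asymptotic
and the a ≥ 3 floor exists precisely because they are unreliable below
it.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `roles` | `("PS",)` | drug roles counted as exposure; add `"SS"` to include secondary suspects |
| `min_a` | 3 | screening floor on target-drug report count |
| `ror_point_threshold` | 3.0 | ROR point criterion; `None` disables |
| `prr_point_threshold` | 2.0 | PRR point criterion |
| `ic025_threshold` / `ebgm05_threshold` | 0 / 2 | Bayesian bounds (strict `>`) |
| `yates` | `True` | continuity correction for χ² |
| `zero_cell_policy` | `"none"` | `"haldane"` adds 0.5 to all cells of a table containing a zero |
| `counting` | `"reports"` | `"event_rows"` counts reaction rows instead (see below) |
| `z` | 1.96 | normal quantile of all 95% intervals |

## Deduplication and linking

FAERS re-publishes corrected case versions under new `primaryid`s.  We
keep, per `caseid`, the row with the newest FDA receipt date; date
ties break toward the numerically larger `primaryid` (later-assigned
versions), making the choice deterministic.  Dates are accepted at
YYYYMMDD, YYYYMM or YYYY precision, truncated to the period start for
ordering and flagged imprecise for onset arithmetic; unparseable dates
sort as oldest.  Rows of the remaining tables join on `primaryid`;
rows pointing at no retained DEMO row are counted as orphans (this
includes rows of superseded case versions), and reports with no
reaction rows are dropped and counted.  Drug names are standardized by
case-insensitive, whitespace-trimmed dictionary lookup; unmatched
names pass through upper-cased and are counted.  No NLP normalization
is attempted.

Time to onset is event date minus earliest therapy start date
(preferring therapy rows linked to the primary-suspect drug), in days,
requiring both dates complete to the day.  Negative onsets are counted
as invalid rather than banded; zero is a valid onset (same-day event).

## Descriptive summaries

Each characteristic's percentages use the sum of its own category
counts as denominator: the report total for sex, age, reporter,
country, route and report year; the outcome-*entry* total for serious
outcomes (a report may carry several outcomes); and the number of
reports with therapy-date information for onset bands.  This is the
convention under which the published descriptive table of the
99,651-report sacubitril/valsartan corpus is internally consistent,
and the package reproduces all of its printed percentages to two
decimals from the printed counts.  Percentages round half-up to two
decimals.  Age bands are half-open on the right ([60, 70), etc. — the
published table does not say which band holds exactly 70, so the
convention is documented and configurable in code); onset bands <7,
7–14, 14–28, 28–60, ≥60 days likewise.  Quantiles use linear
interpolation (`numpy.percentile(method="linear")`).

## The synthetic generator

`synthetic_data` emulates the features of FAERS that the pipeline must
survive: multiple quarterly files; duplicate case versions (default
rate 0.1; each duplicate clones all linked DRUG/REAC/OUTC/THER rows
under an older receipt date, or the same date for a quarter of them so
the `primaryid` tie-break is exercised); the target drug spelled as
free-text variants ("Entresto", "SACUBITRIL AND VALSARTAN", ...);
per-report PT lists (mean 2.6 distinct PTs, matching the events-per-
report ratio of large published FAERS corpora); 71% missing age and
6.7% missing sex (the missingness of the published corpus); therapy
dates on one third of reports with two thirds of those lacking a
usable event date; and onset days drawn as a 15%-at-zero/lognormal
mixture whose median sits near two weeks.

Signal injection: each report carries PT *j* independently with
probability π_j = background_pt_probs[j] × mean PTs per report
(defaults: 100 PTs, uniform 0.01); for target-drug reports (prevalence
0.05) the odds of each injected PT are multiplied by its rate ratio.
Because presence is per-PT Bernoulli, the injected rate ratio *is* the
report-level reporting odds ratio — the exact estimand of the ROR — so
CI-coverage studies have a well-defined truth.  (Multiplying odds
within a renormalized categorical draw would instead bias the realized
report-level ROR below the nominal ratio, by roughly 4% at the default
configuration — enough to distort coverage at n = 50,000.)  Reports
drawing zero PTs are redrawn; conditioning on ≥1 PT perturbs the odds
ratio only in the fourth significant digit at the defaults.

The returned `GroundTruth` records per-PT target/background counts of
the post-dedup corpus, so `realized_table` reproduces every fourfold
table bit-exactly — equality with `build_contingency` on the emitted
and re-ingested files is asserted in the tests.

What the generator does **not** emulate: real FAERS marginal term
frequencies and term correlations (real PTs co-occur in syndromes),
reporting trends over time, country/reporter effects on event mix,
true duplicates with *differing* content, and indication channeling
(confounding by indication).  Passing tests therefore demonstrate the
pipeline's correctness and calibration under a clean generative model,
not robustness to every artefact of real spontaneous data.

## Validation studies and problem sizes

Replicate studies run on the in-memory post-dedup store (the ASCII
round trip being validated separately), at the sizes the package's
checks use: null calibration pools eligible PTs over 200 replicates of
20,000 reports (the one-sided false-positive rate of the ROR CI
criterion lands near 3%, against the nominal 2.5%, bounded at 7.5% to
allow small-count discreteness); signal recovery uses 200 replicates
of 50,000 reports with one rate-ratio-5 PT (flagged by all four
algorithms in ≈100% of replicates; ROR CI coverage of 5 within
95% ± 4 points).

## Numerical choices

* All ratio statistics and bounds are computed in log space, so large
  d never overflows and tiny expected counts never underflow to zero.
* With `zero_cell_policy="none"`, a statistic whose formula divides by
  an empty cell is NaN — an undefined-result marker that never
  signals — rather than an exception; χ² with an empty margin is 0
  with a warning.
* Yates correction clamps |ad − bc| − N/2 at zero.
* BCPNN moments are always finite for non-negative cells (the priors
  regularize), so the raw counts are used even under Haldane
  correction of the frequentist statistics.
* Ranking ties break on the secondary key and then the term name, so
  output order is platform-independent.
* IC/EBGM monotonicity in a is *not* universal: because a enters both
  margins, a·N/((a+b)(a+c)) can decrease with a when b and c are of
  a's order (e.g. (1,1,1,6) → (2,1,1,6)).  ROR and PRR are strictly
  increasing in a; the IC/EBGM property is asserted only against large
  backgrounds, the regime screening operates in.

## Open design decisions

* **SOC counting.** Published SOC tables for this corpus sum to more
  than the report total, implying event-row aggregation at SOC level;
  report-level counting is statistically cleaner and is the default,
  with `counting="event_rows"` available for comparison.  Neither is
  asserted to be the published convention.
* **ROR ≥ 3 point threshold.** Unusually strict (ROR ≥ 2 or CI-only is
  common); kept as the default because it is the printed convention of
  the reference analysis, and configurable because the reading is
  uncertain.
* **Background definition.** Non-target reports form the comparator
  regardless of their drugs' roles; excluding, say, secondary-suspect
  reports of the target from the background is possible via the store
  but not the default.
* **Onset denominator.** Reports with a therapy start record define
  the onset characteristic's denominator; reports with no therapy
  information at all are not "unknown onset", they are outside the
  characteristic.

## Known limitations

No MGPS gamma-mixture EBGM (the printed-formula variant is
implemented; the shrinkage fit would be an extension); no stratified
or regression-adjusted analyses; no designated-medical-event lists or
duplicate-content clustering; FAERS `INDI` (indication) tables are not
read.  All signals are statistical associations in a self-selected
reporting stream — they carry no incidence or causality
interpretation.
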