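# pvsignal

Disproportionality signal detection for spontaneous adverse-event
report databases, built around the FAERS quarterly ASCII format.

Post-marketing drug-safety surveillance asks: among the reports that
name a given drug, is a given adverse event reported *disproportionately*
often compared with all other reports?  `pvsignal` implements the
standard pipeline used to answer this for FAERS-scale corpora — for
example, for screening the adverse-event profile of the heart-failure
drug sacubitril/valsartan — and pairs it with a synthetic-data
generator with known ground truth so every stage is testable without
access to (or download of) the real database.

## What it does

1. **Ingest** `'$'`-delimited quarterly tables (DEMO, DRUG, REAC, OUTC,
   THER, RPSR), collecting malformed lines into a rejects report.
2. **Deduplicate** case versions: one row per `caseid`, keeping the
   most recent FDA receipt date (ties broken by the larger `primaryid`).
3. **Link** the tables on `primaryid` into a normalized report store,
   standardizing free-text drug names through a user-supplied
   dictionary and MedDRA PTs to SOCs through a user-supplied two-column
   mapping (both are licensed vocabularies, so they are inputs).
4. **Count** each drug–event pair into the fourfold table

   |            | event | no event |
   |------------|-------|----------|
   | drug       | a     | b        |
   | all others | c     | d        |

   at PT or SOC level, with the *report* as counting unit.
5. **Score** each table with the four standard algorithms:
   - ROR = (a/c)/(b/d), 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`
   - PRR = (a/(a+b))/(c/(c+d)) with its lognormal CI
   - Pearson χ² (Yates-corrected by default)
   - BCPNN information component IC = log₂(aN/((a+b)(a+c))) with the
     Bayesian credibility bound IC025 = E[IC] − 2·√V[IC]
   - EBGM = aN/((a+b)(a+c)) with lognormal bounds (EBGM05 lower)
6. **Screen** terms with a ≥ 3, flag signals per algorithm
   (ROR: a ≥ 3, ROR ≥ 3, CI low > 1; PRR: a ≥ 3, PRR ≥ 2, CI low > 1;
   BCPNN: IC025 > 0; EBGM: EBGM05 > 2), mark terms positive on all
   four, and rank by report count or ROR.
7. **Describe** the target-drug reports: sex, age bands, reporter,
   country, route, serious outcomes, time-to-onset bands and report
   year, with median (Q1, Q3) for age and onset.

The synthetic module (`pvsignal.synthetic_data`) emits the same file
dialect with configurable duplicate rate, demographic missingness,
drug-name misspelling variants and *injected* drug–PT rate ratios, and
returns the realized fourfold counts as ground truth.

## Worked example

```
$ cat run.toml
target_drug = "SACUBITRIL/VALSARTAN"
out_dir = "out"
seed = 11

[synthetic]
n_reports = 20000
injected_signals = [["PT_001", 5.0], ["PT_002", 3.0]]
duplicate_rate = 0.2
seed = 11

$ pvsignal run --config run.toml
20000 cases, 975 on target drug, 100 screened PTs -> out
```

24,000 raw DEMO rows (20% duplicate case versions) collapse back to
exactly 20,000 cases; 975 name the target drug as primary suspect.
The top of `out/pt_signals.tsv` by report count:

```
  term   a  ror  ror_lo95  ror_hi95  prr   chi2   ic  ic025  ebgm  ebgm05  all_four_positive
PT_001 144 5.94      4.88      7.23 5.21 397.00 2.11   1.80  4.32    3.55               True
PT_002  81 3.16      2.48      4.03 2.98  93.63 1.44   1.06  2.72    2.13               True
PT_089  38 1.47      1.05      2.05 1.45   4.61 0.50  -0.00  1.42    1.01              False
PT_042  37 1.35      0.96      1.89 1.33   2.63 0.39  -0.12  1.31    0.93              False
PT_097  37 1.39      0.99      1.95 1.37   3.23 0.43  -0.08  1.35    0.96              False
```

The two injected PTs — and only those — come out positive on all four
algorithms: PT_001 (injected odds ratio 5) is estimated at ROR 5.94
with CI (4.88, 7.23) covering 5, and both its IC025 > 0 and
EBGM05 > 2; the strongest null PT (PT_089, ROR 1.47) clears none of
the point thresholds.  `out/` also holds `soc_signals.tsv`,
`pt_top.tsv`, `descriptives.tsv`, the normalized store and a
`manifest.json` with the counts at every stage.

The same stages are available individually (`pvsignal simulate`,
`ingest`, `signals`, `describe`) and as library functions.

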