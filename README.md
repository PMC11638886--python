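# pvsignal

Pharmacovigilance signal detection for FAERS-style spontaneous adverse-event
reports: a tested, reproducible pipeline from raw quarterly ASCII files to
disproportionality signal tables and time-to-onset models, plus a seeded
synthetic-data generator with known ground truth so every stage can be
validated without downloading the multi-gigabyte FAERS archive.

## Who this is for

Drug-safety researchers mining the FDA Adverse Event Reporting System (or
any spontaneous-reporting database with the same shape): multi-table case
reports keyed by `PRIMARYID`/`CASEID`, drug mentions with role codes
(PS/SS/C/I), MedDRA preferred-term (PT) reactions, and the usual real-world
artifacts — duplicate case versions, partial dates (`YYYY[MM[DD]]`), mixed
age/weight units, and heavy missingness.

## What it computes

For each drug–event pair the package builds the 2×2 table

|              | target PT | other PTs |
|--------------|-----------|-----------|
| target drug  | a         | b         |
| other drugs  | c         | d         |

with N = a+b+c+d and expected count E = (a+b)(a+c)/N, and evaluates four
disproportionality algorithms:

- **ROR** = ad/bc, with 95% Wald CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
- **PRR** = [a/(a+b)] / [c/(c+d)], Wald CI, plus the uncorrected Pearson χ²;
- **BCPNN information component** IC = log₂((a+½)/(E+½)) with IC025 the
  2.5th percentile of the Gamma(a+½, E+½) posterior on the log₂ scale;
- **MGPS/EBGM**: a two-component gamma mixture prior on the relative
  reporting rate λ, fitted by maximizing the negative-binomial marginal
  likelihood over all database (a, E) pairs; EBGM = 2^{E[log₂λ | a]} and
  EBGM05 the 5th posterior percentile.

A pair is a *signal* when n = a ≥ 3 and the ROR lower 95% bound exceeds 1;
the other three algorithms form a concordance set (PRR ≥ 2 ∧ χ² ≥ 4 ∧ n ≥ 3;
IC025 > 0; EBGM05 ≥ 2). Screening within one MedDRA system organ class adds
χ²/Fisher p-values with Benjamini–Hochberg FDR (volcano-plot output),
important-medical-event flagging, and exclusion lists. Subgroup analyses
stratify by sex and age band (<45, 45–59, >59).

Time-to-onset (EVENT_DT − START_DT, day precision only, events preceding
therapy start excluded) is summarized as median/IQR/min–max, fitted with a
two-parameter Weibull by maximum likelihood, and hazard-typed from the shape
β: CI below 1 → early failure (decreasing risk), CI containing 1 → random,
CI above 1 → wear-out. Kaplan–Meier cumulative incidence and the log-rank
test compare drugs.

## Worked example

```python
from pvsignal.synthetic import default_config, default_synonym_map, generate_dataset
from pvsignal.io import deduplicate_dataset
from pvsignal.cohort import build_analytic_dataset, build_contingency, all_pairs_2x2
from pvsignal.disproportionality import fit_mgps_prior, compute_signal_stats, evaluate_signal
from pvsignal.tto import compute_tto, tto_summary, fit_weibull

# a 50,000-case FAERS-like database with two SNRI-like target drugs and
# injected reproductive-system signals (ground truth returned alongside)
dataset, truth = generate_dataset(default_config(seed=1, n_cases=50_000))
clean = deduplicate_dataset(dataset)                       # FDA dedup rule
analytic = build_analytic_dataset(clean, default_synonym_map())

pairs = all_pairs_2x2(analytic)                            # all (a, E) pairs
prior = fit_mgps_prior(pairs["a"].to_numpy(float),
                       pairs["expected"].to_numpy(float), seed=1)

table = build_contingency(analytic, "duloxetine", "Erectile dysfunction")
stats = compute_signal_stats(table, prior)
is_signal, met = evaluate_signal(stats)
print(f"n={stats.n}  ROR={stats.ror:.2f} ({stats.ror_lo95:.2f}-{stats.ror_hi95:.2f})")
print(f"EBGM={stats.ebgm:.2f} (EBGM05={stats.ebgm05:.2f})  algorithms={sorted(met)}")

sample = compute_tto(analytic, "duloxetine", "Erectile dysfunction")
fit = fit_weibull(sample)
print(f"TTO n={sample.n}  Weibull shape={fit.shape:.2f} "
      f"({fit.shape_lo95:.2f}-{fit.shape_hi95:.2f})  type={fit.failure_type}")
```

Output:

```
n=176  ROR=4.12 (3.50-4.85)
EBGM=3.63 (EBGM05=3.23)  algorithms=['BCPNN', 'MGPS', 'PRR', 'ROR']
TTO n=73  Weibull shape=0.65 (0.54-0.78)  type=early
```

The injected pair (configured relative risk 5, Weibull onset scale 110 days
/ shape 0.65) is recovered by all four algorithms, and the fitted shape's CI
sits below 1 — an early-failure (front-loaded) onset profile.

The same analysis runs from the shell:

```bash
pvsignal generate --seed 1 --n-cases 20000 --outdir quarter/   # ASCII files
pvsignal run --mode faers --input-dir quarter/ --outdir results/
pvsignal run --mode synthetic --seed 1 --outdir results/       # in-memory
```

`results/` then contains per-drug descriptive summaries, annual counts,
volcano and signal tables (overall and per stratum), TTO summaries, KM step
tables, and a `manifest.json` with stage-by-stage record counts.

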