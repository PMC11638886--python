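# Methods

This note records the statistical models, conventions, and design choices
behind `pvsignal`, at the level of detail a maintainer or reviewer needs to
judge what the package's tests do and do not establish.

## Data model and cleaning

A spontaneous-reporting database is a set of case reports, each carrying one
or more drug mentions with role codes (PS = primary suspect, SS = second
suspect, C = concomitant, I = interacting) and one or more MedDRA preferred
terms (PTs). Cases arrive in versions: the same `CASEID` may appear under
several `PRIMARYID`s as follow-up information accrues.

**Deduplication** keeps, per `CASEID`, the record maximal in the
lexicographic order (FDA_DT, PRIMARYID) — the latest regulatory receipt
date, ties broken by the larger report identifier. The rule is idempotent
and order-independent, and child-table rows (DRUG/REAC/THER) of superseded
versions are dropped with the DEMO row. A record with a missing or
unparseable FDA_DT sorts as the oldest possible date, so a dated version of
the same case always supersedes it; this keeps the more informative record
without inventing a date.

**Dates** are strings `YYYY`, `YYYYMM`, or `YYYYMMDD`; parsing is total
(invalid input yields an explicit invalid value, never an exception) and
carries the precision, because downstream rules differ: annual report counts
need only year precision, while time-to-onset requires day precision on both
endpoints.

**Units.** Age codes convert to years (YR×1, DEC×10, MON÷12, WK÷52.1775,
DY÷365.25, HR÷8766); a value with a missing or unknown code is taken as
years. Results ≤0 or ≥150 years are implausible and treated as unknown.
Weight converts to kg (LBS×0.453592, GMS÷1000) with a 700 kg plausibility
cap.

**Drug-name matching** is deterministic: case-fold, strip punctuation, drop
dosage/formulation tokens (`30mg`, `tablets`, `XR`, …), then exact match
against a user-supplied synonym→generic map. No fuzzy matching — an
auditable map is preferable to an unreproducible similarity threshold.
Only PS mentions of mapped drugs enter the target cohort; the comparator
population is every PS mention in the cleaned database.

## Contingency tables and counting units

For drug D and term P in stratum S, a = records with (D, P), b = D-records
with other PTs, c = P-records of other drugs, d = the remainder; both
margins are restricted to the stratum. The counting unit is explicit:

- `records` (default): each distinct (case, PT) pair counts once. AE totals
  in reporting databases are conventionally reaction-level, and with this
  unit the per-drug a-cells sum exactly to the drug's reaction-record total.
- `cases`: distinct reports. Useful when the denominator convention of a
  published analysis is case-level; both modes are tested.

Age bands follow the literal boundaries `<45`, `45–59` (inclusive), `>59`;
records with unknown sex or age are excluded from the corresponding
stratified analysis but retained overall, so sex-stratified a-cells sum to
at most the overall a-cell. Printed percentages use decimal half-up rounding
to one decimal.

## Disproportionality statistics

With E = (a+b)(a+c)/N the null-expected count:

- **ROR** ad/bc; CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). Any zero cell
  makes the result an explicit undefined marker; a Haldane +0.5 correction
  exists behind a flag but is off by default — pairs at the n ≥ 3 reporting
  threshold always have a > 0, and inflating c = 0 pairs would manufacture
  signals.
- **PRR** [a/(a+b)]/[c/(c+d)]; CI exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c −
  1/(c+d))); Pearson χ² without Yates correction (the common
  PRR ≥ 2 / χ² ≥ 4 / n ≥ 3 rule is defined on the uncorrected statistic;
  Yates is available by flag).
- **BCPNN IC** via the gamma-posterior formulation: λ | a ~ Gamma(a+½, E+½),
  IC = log₂((a+½)/(E+½)), IC025 = log₂ of the posterior 2.5th percentile.
  The credible bound is count-dependent by construction; tests verify it
  against 10⁶-draw Monte-Carlo quantiles to 0.02 log₂ units.
- **MGPS/EBGM**: prior λ ~ p·Gamma(α₁,β₁) + (1−p)·Gamma(α₂,β₂) (shape/rate),
  fitted by maximizing the marginal negative-binomial mixture likelihood
  over all database (a, E) pairs. Optimization is multi-start L-BFGS-B on
  (log α, log β, logit p) from the canonical published values (0.2, 0.1,
  2.0, 4.0, ⅓) plus seeded perturbations; parameters are clipped to
  |log| ≤ 30 inside the objective so line-search excursions cannot overflow.
  Components are reported in descending prior-mean order. The posterior is
  again a two-gamma mixture; EBGM uses the digamma closed form per
  component, EBGM05 is root-found on the mixture CDF. The prior is fitted on
  the full database, not one organ class — empirical Bayes needs the global
  count distribution.

Two algebraic facts worth recording: ROR/PRR = (1 + a/b)/(1 + c/d), so the
PRR always lies between 1 and the ROR (on either side of 1); and EBGM is a
posterior *geometric* mean, which sits slightly below the posterior mean —
near a ≈ E this can place |log EBGM| marginally above |log(a/E)|, so the
shrinkage property is checked on tables drawn from the population the prior
was fitted to, with slack 1/(2a) + 0.02 for this offset and for the fitted
prior's components sitting slightly off λ = 1.

**Screening** within one system organ class computes a raw p per PT
(Pearson χ² when all four expected cells are ≥ 5, else two-sided Fisher) and
Benjamini–Hochberg FDR across the SOC's PTs for that drug — that family
matches a per-drug volcano plot of one organ class. Exclusion lists (e.g.
breast-related terms when the question is sexual dysfunction) are removed
from signal tables but stay visible in volcano output.

## Time-to-onset

Onset = EVENT_DT − START_DT of the PS mention's first therapy episode, kept
only when both dates have day precision and the event does not precede
therapy start; every exclusion is tallied by reason so retained + excluded =
input. Same-day onsets map to day 1 by default (dates are day-resolution;
a same-day onset is a first-day onset) with an `exclude` switch.

Quartiles use the averaging convention: position (n+1)·p, fractional
positions averaging the two adjacent order statistics — the convention that
yields half-integer quartiles on integer-day data.

The Weibull fit maximizes the two-parameter likelihood; the shape solves the
standard profile equation by bracketing + Brent root-finding (deterministic,
no random starts) and the scale follows in closed form. 95% CIs are Wald on
(log α, log β) from the finite-difference observed information, then
exponentiated — respecting positivity. Coverage of the shape CI is verified
by simulation (90–98% over 500 replicates at n = 100). Failure typing:
shape CI entirely below 1 → early, containing 1 → random, above 1 →
wear-out; exhaustive and mutually exclusive.

Every retained report has an observed onset, so Kaplan–Meier cumulative
incidence reduces to the empirical CDF; the KM machinery is kept so that a
censoring-aware design drops in without interface changes. The log-rank test
(lifelines) is cross-checked in tests against an independently implemented
statistic and a 10⁴-replicate permutation null.

## Synthetic data generator

The generator emulates the quarterly multi-table structure with exactly one
PS drug per case (categorical over configured marginals), SS/C/I noise
mentions to exercise role filtering, brand-name spellings to exercise
synonym matching, and 1 + Poisson(1) reaction PTs per case sampled without
replacement via Gumbel top-k from weights baseline(PT) × RR(drug, PT). Under
the null all RR = 1 and drug and event are independent by construction; an
injected pair's realized cross-product ratio approaches its configured RR in
the rare-event limit (at the default baselines and ~2 PTs per case the
realized odds ratio is mildly attenuated, e.g. ≈ 4.1–4.6 for RR = 5 — the
generator injects sampling weight, not a guaranteed marginal odds ratio).

Onset days for configured (drug, PT) pairs are ⌈Weibull(α, β)⌉ with a 1-day
floor — day-resolution data with a 1-day minimum; other cases draw from a
background Weibull (scale 90, shape 1). Therapy start dates are uniform over
the window; FDA receipt follows the event by 1–180 days. Duplicates are
always *older* versions (same CASEID, strictly smaller FDA_DT, or equal
FDA_DT with smaller PRIMARYID for ~20% of duplicates to exercise the
tie-break), so the surviving record is unambiguous and dedup ground truth is
exact. Missingness blanks fields at configured per-field rates; a configured
fraction of EVENT_DT/START_DT values is truncated to month or year
precision. FDA_DT stays day-precision: the dedup rule orders on it, and
regulatory receipt dates in practice are complete.

The default study scenario is two SNRI-like target drugs (duloxetine ~4%,
venlafaxine ~3% of 50,000 cases) among 28 background drugs and 50 PTs across
9 organ classes, with reproductive-system signals (RR 4–8) injected for the
targets and erectile-dysfunction onset laws Weibull(110, 0.65) and
Weibull(500.55, 0.49) — scale/shape values of the magnitude reported for
these drugs in published pharmacovigilance work, so the failure-typing and
between-drug comparison stages run in a realistic regime.

What the generator does **not** emulate: stimulated reporting, masking and
competition bias, duplicate reports with conflicting content, verbatim
reaction text needing MedDRA coding, or real FAERS name chaos beyond
brand/dosage tokens. Passing tests therefore establish correctness of the
computations and calibration under independent tilted sampling — not
robustness to those reporting-behavior phenomena.

## Determinism and problem sizes

All randomness flows from explicit integer seeds into `numpy` Generators;
identical (config, seed) reproduces byte-identical tables on disk. Test and
validation problem sizes are chosen to make each check statistically
decisive at desk scale: 10⁴ random tables for closed-form equivalence, 10⁶
Monte-Carlo draws per grid point for posterior quantiles, 50,000 simulated
pairs for prior recovery, 50,000-case databases (10 seeds) for null
calibration of the signal rule, 20 seeded end-to-end runs for
injected-signal recovery, and 500 replicates for CI coverage. At n = 2000
the Weibull scale estimate's sampling error at shape ≈ 0.5 is itself close
to 5%, so the recovery check is on the median of 10 replicates — a
consistency statement at that tolerance rather than a coin flip on one
draw.

## Known limitations

- The ROR/PRR intervals are Wald approximations; for very small cells the
  coverage is approximate (the n ≥ 3 rule bounds the worst of it).
- The MGPS mixture likelihood is multimodal in principle; multi-start
  optimization from the canonical prior has recovered truth in all tested
  regimes but carries no global-optimality guarantee.
- Undefined statistics (zero cells) propagate as explicit markers and fail
  signal rules rather than being corrected; this is conservative.
- The pipeline treats each quarter directory as one database; multi-quarter
  concatenation is the caller's concern (tables share one schema, so
  `pandas.concat` suffices).
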