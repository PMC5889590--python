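# Methods

## The gap measure

Continuous Medication Gap (CMG) estimates secondary non-adherence — failure
to refill an already-initiated medication — as the proportion of days
without available supply between a patient's first and last fill inside the
lookback window.  The engine works per ingredient on the ordered fill
series.  For each refill interval between consecutive fills:

- `supply_available = carryover_in + days_supply(opening fill)`
- `gap_days = max(0, length − supply_available)`
- `carryover_out = max(0, supply_available − length)`

Gap and observed days are summed over intervals; CMG is the exact rational
`gap_days / observed_days`.  This is the *time-forward* treatment of
stockpiling: surplus pills from early or large fills are banked for future
intervals, but a later fill never retroactively offsets a gap already
incurred.  A day-by-day pill-inventory simulation (`daily_inventory_oracle`)
is provably equivalent and is kept in the package as an independent check;
the property suite asserts equality on randomized fill series.

Key structural choices, each open in the measure's general tradition and
fixed here:

- **Observation denominator.** The observation runs from the first to the
  last fill within the window; supply remaining at the last fill is
  discarded.  A refill interval needs a closing fill, so no terminal
  interval is scored.  Consequently a patient who stops refilling entirely
  after an early fill contributes no observed days past that point — the
  measure is conditional on continued engagement, which is why fewer-fill
  patients are flagged non-calculable rather than scored.
- **Run-in.** Fills dated before the window are ignored entirely, even if
  their supply would extend into it.  This is the simplest auditable rule;
  it can overstate the gap in the first scored interval for patients who
  stockpiled just before the window.
- **Within-class aggregation.** An indication-level CMG pools day counts
  over all ingredients with ≥ 2 windowed fills (Σ gaps / Σ observed), so
  drugs are weighted by observed time and the result remains a day
  proportion.  An unweighted per-ingredient mean is available as
  `aggregation_mode: mean_per_ingredient`.
- **Drug switching.** Each ingredient forms its own fill series; supply is
  never transferred across different drugs of the same class.
- **Exact arithmetic.** Gap accounting is integer and CMG a
  `fractions.Fraction`, so the classification at the 20% bound
  (`optimal iff CMG ≤ 1/5`) has no floating-point ambiguity: a CMG of
  exactly 0.20 is optimal.

## Calculability

A patient × indication CMG is computed only when the claims can support
it.  Gates apply in fixed precedence so exclusion tallies are reproducible:
insulin (no meaningful fixed days-supply) → dual coverage (claims capture
incomplete) → no continuous benefits → fewer than two fills of any single
ingredient in the window.  Non-calculable respondents are excluded from the
exact test but reported per response category next to the tested table,
because non-calculability is itself adherence-informative (patients with
few fills tend to be less adherent, making the test conservative).

## Self-report handling

One response is analyzed per patient × indication × assessment mode: the
first completed by default, the last as a sensitivity alternative.
Same-date duplicates tie-break to the lower missed-day count (conservative
toward adherence) with a logged warning.  Responses are grouped as
0 / 1 / 2–7 missed days.  The claims lookback is anchored at the selected
response's own date, separately per mode, so each measure covers the 12
months preceding the assessment it is compared with.

For cross-mode concordance, ATSM and interview selections for the same
patient and indication are paired when their dates differ by at most 30
days (symmetric in either direction — the window exists to limit true
behavior change between measurements, which is direction-free).  Agreement
compares the raw 0–7 counts, not the 3 categories, since the summary's
direction labels ("higher disclosure on …") order reported days.

## Exact test

Validity tables are 3×2 (category × optimal/suboptimal).  The test is the
Fisher–Freeman–Halton two-sided exact test: conditioning on both margins,
the table probability is `(Π rᵢ! Π cⱼ!)/(n! Π aᵢⱼ!)`, and the p-value sums
the probabilities of all margin-preserving tables no more probable than the
observed one.  Tables are enumerated recursively by row compositions.  The
"no more probable" comparison is done on integers (`Π aᵢⱼ!` products), and
the p-value is accumulated as an exact rational before a single conversion
to float — there is no tolerance in the ordering and no accumulation error.
Zero rows/columns are dropped first; a table left with a single row or
column is uninformative and returns p = 1.  Tests verify agreement with an
independent degrees-of-freedom brute-force enumerator and, on 2×2 tables,
with the classical two-sided hypergeometric test (scipy).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with parameters in `BehaviorParams`:

- `adherence_alpha, adherence_beta` (default 8, 2): per-patient taking
  propensity `p ~ Beta(8, 2)`, mean 0.8 — a mostly-adherent managed-care
  cohort with a tail of poor adherence.
- `days_supply` (default 30 days): standard retail fill.
- Refill timing: the next fill comes `days_supply + delay` days after the
  previous one, `delay ~ Geometric` on {0, 1, …} with mean
  `days_supply·(1−p)/p`, so the expected uncovered fraction of each refill
  cycle is approximately `1 − p`.  Each interval then has exactly
  `days_supply` of supply against `days_supply + delay` days, so the
  realized uncovered fraction between first and last fill — recorded in
  the truth table — is reproduced *exactly* by the pipeline's CMG.  This
  makes parameter recovery a construction-level identity rather than a
  statistical estimate, which is the point: it isolates bookkeeping errors
  from sampling noise.
- Recall responses: per mode, `missed ~ Binomial(7, 1−p)`, thinned by
  `disclosure_prob` (default 1 = honest; lower values emulate the
  under-disclosure bias of self-report).  The two modes draw independently
  given `p`, so even honest reporting yields imperfect cross-mode
  concordance, as two real assessments days apart would.
- Contamination: `frac_single_fill` (default 0.10) truncates patients to
  one fill; `frac_dual_coverage` (default 0.05) flags dual coverage.  Flags
  derive from a dedicated random stream with per-patient uniforms, so
  raising a fraction only adds flagged patients and perturbs nobody else
  (the contamination-monotonicity property).  Each patient's behavior draws
  from its own spawned substream for the same reason.
- Dates: the ATSM response anchors the patient's window; the interview
  follows within `response_offset_days` (default 7).  The first fill is
  placed after the latest possible interview-anchored window start so that
  both anchors observe the identical fill series.

What the generator does **not** emulate: drug switching and multi-drug
regimens within a class (one ingredient per indication), dose changes,
seasonal refill behavior, benefit interruptions, correlated indication
behavior beyond the shared patient propensity, and recall error beyond
thinning.  Passing tests therefore validate the measurement and analysis
machinery, not the realism of any particular cohort; with real claims the
structural choices above (run-in, aggregation, denominator) matter and are
surfaced as configuration and documented limitations.

### Estimator bias

Per patient, CMG is the ratio `ΣD/Σ(S+D)` over k realized intervals, which
is a consistent but finitely-biased estimator of `1 − p` (Jensen: the mean
of a ratio is below the ratio of means here).  Over a 365-day window at the
default parameters (k ≈ 7–12 refills) the cohort-level downward bias is
about 0.005–0.01 against a mean uncovered fraction of 0.2, within the
Monte-Carlo error of the cohort mean at n = 500 and shrinking with longer
windows.  The recovery report exposes both comparisons: against the
realized gap fraction (error exactly 0) and against `1 − p` (small finite-k
bias).

## Problem sizes

Default validation sizes: 200–250 randomized fill series for the oracle and
causality suites, 500+ random margin configurations (n ≤ 25) for the exact
test, a 500-patient cohort for parameter recovery, and a 50-patient cohort
plus a 6-patient hand fixture for pipeline determinism and accounting.
These sizes give the properties enough variety to fail loudly while keeping
the whole suite in seconds.

## Degenerate inputs and tie-breaks

- Same-day, same-ingredient fills merge by summing supply before gap
  accounting; same-day different-ingredient fills stay separate.
- Fewer than two fills raises a typed signal, surfaced as a non-calculable
  result, never a crash.
- An empty validity table (all respondents non-calculable) carries no test;
  its p-value is reported as missing rather than 1.
- Zero concordance pairs yield undefined (missing) percentages, flagged by
  `n_pairs = 0`.
- CSV parsing collects row-numbered errors and continues; `strict_parse`
  aborts on the first report instead.
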