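# Methods

## Problem and model

Epidemiologic studies of diseases with long latency need subjects'
*residential histories* — the sequence of addresses with occupancy
intervals — rather than the enrollment-time address alone.  When a
cohort has collected addresses during follow-up, a commercial
public-records extract can be evaluated against that gold standard.
`reshist` implements this evaluation as a reusable pipeline with three
parts: approximate component-wise address matching, eleven agreement
metrics, and a synthetic generator that emulates the data-collection
process so the whole pipeline is testable end to end.

### Address matching

Components (house number, street name, city, state) are compared
separately.  City and street use the generalized Levenshtein edit
distance (minimal insertions, deletions, substitutions) after
normalization: uppercasing, whitespace collapsing, punctuation removal,
and a USPS-style abbreviation table (`STREET→ST`, `NORTH→N`, …) shipped
as an editable two-column resource.  State codes and house numbers are
compared exactly; full state names are mapped to 2-letter codes and
unit/apartment designators are stripped from house numbers first.
Rationale for exact states: state typos are rare while fuzzy state
matching creates systematic false positives (VA↔VT at distance 1).

Three nested match levels are defined for a study address against the
set of same-subject records addresses: *city/state*, *street*
(city/state + street name), and *detailed* (+ house number).  A study
address matches at a level when **any** records address satisfies all
that level's comparisons.

The edit-distance tolerance `d` is tuned, not assumed.  Given a sample
of subjects whose true number of distinct city names is known, each
candidate `d` (default {0, 1, 2, 3, 4}) is scored by the fraction of
subjects whose estimated unique-city count is wrong; the minimizer
wins, ties to the smallest `d`.  Because approximate equality is not
transitive, the unique count is defined by deterministic greedy
clustering in input order (first representative within `d` wins).
The tuned `d` is always reported with results.

### Time axis

All interval arithmetic uses fractional years.  Study first-seen years
are placed at mid-year (July 1); the final study spell ends at mid-year
of the last follow-up year, each earlier spell at the next spell's
start.  Records month-years are treated as whole-month intervals
(first-of-first-month through end-of-last-month), so a records spell
can reproduce a study boundary exactly (July 1 of `y` = `y + 0.5`) and
the natural minimum records duration is one month, which is also the
floor applied after window clipping.  Records intervals are clipped to
the window (Jan 1 of the start year through Dec 31 of the end year)
for all time metrics; component matching uses all records rows.

### Metrics

Each of Metrics 1–3 is reported as an *overall* rate (pooled over all
unique addresses) and a *mean* rate (per-subject proportions averaged);
the two coincide exactly when every subject holds the same number of
addresses.  Unique addresses are obtained by collapsing consecutive
duplicate study rows; a subject absent from the records extract keeps
all addresses with m = 0 (nonappearance is a retrieval failure the
metric should reflect).  Study rows missing a street name are excluded
from the street/detailed denominators and tallied as incomplete, so
data incompleteness is not conflated with matching failure.

"Time covered" (Metrics 5 and 7) is calendar intersection between the
study spell and the union of its matching records intervals — union, so
overlapping records spells are not double counted.  The Metric 6
duration difference pairs each matched study address with the single
best-overlapping records spell (ties to the earlier one), keeping one
pair per address.  Metric 5 restricts to matched addresses; Metric 7
spreads covered time over **all** of a subject's study time.

Metric 10 counts an address in every calendar year its spell overlaps,
so a mover contributes both the outgoing and incoming address in the
move year; the alternative denominator that assigns a move year to the
incoming address only (occupancy at mid-year) is exposed as
`count_single` since the convention is not uniquely forced.  Metric 11
declares a spatial match when any same-subject records point lies
within the threshold (default 100 ft) of the study point — planar
Euclidean for `planar-feet` coordinates, great-circle distance
converted to feet for `lon-lat`; mixed frames are an error.

Stratification assigns each study address to a stratum by a study-side
attribute (its state, or a binary partition such as CA vs non-CA) and
recomputes the rates within strata.  Strata with zero addresses are
reported as absent rather than 0%, with counts included so sparse
strata are visible.

## Synthetic generator

The generator emulates the data-collection process, not any real
geography:

* **Mobility.** Per-year Bernoulli moves at 0.117 (the U.S. one-year
  mover rate), giving geometric residence durations with median
  ≈ ln 2 / 0.117 ≈ 5.9 years, bracketing the cited 4.7-year median.
  This is a deliberate stand-in for duration-table mobility models.
  Moves take effect at mid-year, so the year-resolution study view and
  the month-resolution records view align exactly when degradation is
  off — a property the perfect-copy identity tests rely on.  Spells
  tile the window exactly (durations sum to 19 years).
* **Geography.** Synthetic states (real 2-letter codes), city names
  constructed ≥ 8 edits apart and street base names ≥ 6 edits apart
  within a city, so tuning ground truth is unambiguous even after
  corruption and a corrupted string cannot drift into a different
  true name at realistic tolerances.  Addresses carry planar-feet
  points.
* **Study view.** Components verbatim (the study is the gold
  standard); each post-baseline address gets a first-seen year equal to
  the move year plus an update lag (P(0,1,2 yr) = 0.6/0.3/0.1),
  reflecting that recorded years are address *update* years.  Subjects
  enroll in the window's first or second year.
* **Records view.** Recall truncation (basic = 3 most recent
  addresses; enhanced = unlimited), dropout (5%), 1–2-character typos
  in city/street (5% per component), abbreviation expansions
  (ST→STREET, 15%), digit errors in house numbers (typo rate / 2,
  never in state codes), exponential first/last-seen drift (mean 1.4
  years per end, lengthening recorded spells by ≈ 2.8 years on
  average), and ≤ 25 ft point jitter.  The error-model parameters have
  no published counterpart; they are calibration knobs chosen to be
  modest but consequential, not estimates of any provider's quality.

All draws flow from one seed through four named substreams, and every
per-spell degradation quantity is drawn whether or not it is applied.
This yields three useful exactness properties: byte-identical output
under a fixed seed; the basic view is literally the enhanced view
truncated per subject (so recall-truncation monotonicity holds
deterministically, not just in expectation); and raising the typo rate
only enlarges the set of applied corruptions without changing their
content.

What the generator does **not** emulate: real place names and street
networks, household co-movement, in/out-migration from the cohort,
sub-year true residence durations (drift supplies sub-annual variation
on the records side), geocoding failure, and any correlation of record
quality with geography.  Passing tests therefore demonstrate the
pipeline's correctness and the qualitative structure of
recall/degradation effects, not the match rates any real records
product would achieve.

## Numerical and design choices

* Zero-length study spells (two updates reported for the same year)
  are kept as unique addresses for match rates but contribute no
  occupied time; a matched zero-length spell is excluded from the
  Metric 5 per-address ratios.
* Degenerate subjects with zero total study time are excluded from
  Metric 7 with a logged count.
* The Metric 6 histogram uses year-wide bins centred on integers over
  ±19 years.
* Perfect-copy reference: `records_from_study` emits records rows whose
  parsed intervals equal the study spells exactly (July/June month
  boundaries encode mid-year), which is what makes the all-metrics-1.0
  identity an exact assertion rather than a tolerance check.
* Problem sizes in the test suite (60–500 subjects; 20 replicates for
  stochastic directionality checks) were chosen as the smallest runs
  that make the checked orderings stable across seeds.

## Known limitations

* The tuned tolerance is a single global `d` for both city and street
  names; component-specific tolerances are plausible but unsupported.
* Matching is string-based only — no phonetic (Soundex) or
  probabilistic (Fellegi–Sunter) linkage, and no ZIP-code comparison.
* Geocoding is consumed, never produced; coordinates must arrive on
  the rows.
* The per-year denominator question (movers counted at one or both
  addresses) is resolved in favor of both, with the alternative count
  reported, but real tabulations may follow either convention.
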