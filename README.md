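# reshist

Concordance assessment of residential address histories against
public-records databases.

## What this is for

Spatial and environmental epidemiology often needs *where a subject
lived over decades*, not just the enrollment-time address: population
mobility (≈ 12% of U.S. residents move each year) and long disease
latencies make the enrollment address a poor exposure surrogate.  When
a study has collected addresses during follow-up, a purchased
public-records extract (e.g. a commercial address-history service) can
be evaluated against that gold standard before being trusted in
studies that collected nothing.  `reshist` implements that evaluation
for anyone with two address-history tables: epidemiologists,
record-linkage methodologists, and data managers assessing a vendor.

## The method

**Matching.**  Address components are compared separately: city and
street by generalized Levenshtein edit distance ≤ *d* after
normalization (case, whitespace, punctuation, USPS abbreviations);
state and house number exactly.  The tolerance *d* is tuned by
minimizing, over a sample of subjects with known numbers of distinct
city names, the fraction of subjects whose estimated unique-city count
is wrong; *d* = 0 is exact matching.

**Metrics.**  Eleven agreement metrics: component match rates at three
nesting levels, per-address duration distributions, time coverage of
matched addresses and of all subject time, the records-minus-study
duration difference, most-recent/baseline address matches, per-year
match rates, and a 100-ft spatial point match.  Match rates are
reported both pooled over the *N* = Σᵢ nᵢ unique study addresses,

    overall = Σ mⱼ / N,

and averaged over the *n* subjects,

    mean = (1/n) Σᵢ ( Σ_{j∈i} mⱼ / nᵢ ),

where mⱼ ∈ {0,1} flags whether study address *j* has any matching
records address.

**Simulation.**  A synthetic generator produces a ground-truth mobility
process (annual move probability 0.117 over a 1995–2013 window), a
study view with address-update lag, and a degraded records view with
limited recall depth (a "basic" three-address service vs an "enhanced"
unlimited one), typos, abbreviation flips, dropout and spell-lengthening
first/last-seen drift — so the whole pipeline is validated end to end
with no external data.  See `docs/methods.md` for the model details.

## Worked example

```sh
reshist simulate --seed 7 --n-subjects 200 --out sim/
reshist assess \
    --study sim/study_addresses.csv --records sim/records_basic.csv \
    --tuning sim/tuning_sample.csv --tuning-truth sim/tuning_truth.csv \
    --out out_basic/
```

prints (abridged):

```
Residential-history concordance assessment
  window: 1995-2013; subjects: 200; edit-distance tolerance d=2
  tuned over candidates [0, 1, 2, 3, 4], tuning error rate 0.0%

Match rates (overall over addresses / mean over subjects)
  Metric 1 City and state match           86.7% / 91.1%
  Metric 2 Street match                   78.5% / 85.6%
  Metric 3 Detailed match                 76.5% / 84.0%
  Metric 5 Years at matched address       98.5% / 98.2%

Years at each address (min / Q1 / median / Q3 / max / mean)
  study   0.0 / 2.0 / 4.0 / 8.0 / 18.0 / 5.7
  records 0.7 / 4.5 / 7.5 / 11.8 / 19.0 / 8.5

Metric 7 time covered (mean over subjects): 80.9%
Metric 9 baseline address match:            64.0%
```

Reading this: tuning picked edit distance 2 (it reproduced every
sampled subject's true unique-city count); the three-address "basic"
records view finds a detailed match — city, state, street and house
number — for 76.5% of study addresses (84.0% averaging within subjects
first); recorded spells run ≈ 2.4 years longer than study spells
because first/last-seen dates drift outward; and limited recall hurts
most at the window start (baseline-address match 64.0% vs a 96.0%
most-recent match).  Re-running `assess` against
`records_enhanced.csv` shows every rate improve, with the largest gains
in the early years — the signature of recall depth.  Full per-year and
per-state tables land in `out_basic/*.csv`, alongside a
`provenance.json` with the tuned *d*, config hash and row counts.

The library surface mirrors the CLI: `reshist.SimConfig` /
`generate_truth` / `derive_study_view` / `degrade_to_records` for data,
`select_edit_param` for tuning, and `run_metrics` for the full
`AssessmentResult`.

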