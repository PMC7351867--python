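# Methods

## Free-sugar estimation ladder

Free sugar (FS) cannot be assayed; it is inferred per food from total sugar
(TS), lactose, ingredient knowledge and classification flags.  The ladder is
a fixed-order decision list; the first applicable rung wins and is recorded
on the assignment:

| rung | predicate | estimate | basis |
|---|---|---|---|
| 1 | unprocessed whole food (intact fruit/veg, plain milk) | 0 | objective |
| 2 | fruit juice or smoothie | TS | objective |
| 3 | pure-sugar product, not a diet beverage | TS | objective |
| 4 | no unsweetened equivalent, analytical lactose present | TS − lactose | objective |
| 5 | unsweetened equivalent in the table | TS − TS(equivalent) | objective |
| 6 | recipe/ingredient fraction known | fraction × TS | objective |
| 7 | objectively-assigned same-group food with description similarity ≥ 0.6 | borrowed value | subjective |
| 8 | same-group objective assignments exist | group-median FS/TS × TS | subjective |
| 9 | always | 0.5 × TS | subjective |
| 10 | always (only reachable if 9 is removed from the order) | TS | subjective |

Conventions:

- Every estimate is clipped to `[0, TS]`.  Negative intermediates
  (`TS − lactose < 0`, noisy equivalent subtraction) floor at 0 rather than
  propagate: composition-table noise must never produce negative FS.
- Rung 4 requires lactose to be *analysed*; a missing value is not 0.  This
  is why the food table representation distinguishes `None` from `0.0`.
- A rung-5 reference to an absent food code logs a warning and falls
  through; it is a data gap, not a fatal error, because later rungs still
  produce a defensible estimate.
- Diet beverages are excluded from rung 3; with TS ≈ 0 they resolve to
  FS = 0 wherever they land.
- The rung order is configuration (`LadderConfig.step_order`), so variant
  protocols (e.g. an added-sugar ladder that assigns juice 0) can be swapped
  in without code changes.
- Determinism: rungs contain no randomness; identical table + config give
  identical assignments.  `apply_ladder` computes objective assignments for
  all foods first, so rungs 7–8 see the same pool regardless of table order.

Dual estimation is supported by `reconcile`, which lists foods whose two
independent estimates differ by strictly more than a tolerance
(default 0.1 g/100 g); resolution is an input (a third adjudicator), never
computed.  `compare_distributions` wraps the two-sample Kolmogorov–Smirnov
test (scipy) for comparing an estimate set against an external one.

## Aggregation conventions

- A *consumption* is any diary entry; an *eating occasion* is the
  (subject, day, sequence) triple.  Frequencies count occasions whose summed
  sugar mass is positive — entry multiplicity inside an occasion never
  inflates frequency, and FS-positive implies TS-positive, so
  `freq_fs ≤ freq_ts ≤ n_occasions` always.
- %TEI uses 0.017 MJ per gram of sugar.  Per subject it is computed as the
  **ratio of multi-day means** (mean g/day × 0.017 / mean MJ/day); the
  mean-of-daily-ratios alternative sits behind
  `pct_tei_method="mean_of_ratios"`.  Ratio-of-means is the default because
  single low-energy days otherwise produce unstable daily ratios.
- WHO categories from FS %TEI: `below_5` strictly below 5, `above_10`
  strictly above 10, boundaries belong to the middle band.
- Quartiles interpolate linearly between order statistics (numpy's default
  rule); SD is the sample SD (n − 1).
- Group contributions average over **all** subjects (non-consumers
  contribute zeros), so per-group means partition the cohort means exactly
  (float tolerance); "consumer" means ≥ 1 consumption of the group in the
  survey window, any amount.  Snack/meal probabilities divide a group's
  snack-occasion consumptions by its total consumptions; a group never
  consumed yields no row rather than 0/0.
- Coverage metrics are exact partitions: counts, gram weights, TS and FS
  each satisfy covered + non-covered = total by construction.

## Under-reporting screen

BMR is predicted from the Schofield weight-and-height equations
(`bmr = a·kg + b·m + c`, MJ/day), shipped as JSON with six sex × age bands
(0–3, 3–10, 10–18 years); any same-shaped file can be substituted.  A child
whose mean reported energy intake is strictly below `1.28 × BMR` is flagged
as an under-reporter — 1.28 is the customary Goldberg-type floor for 4-day
records.  Flagged children remain in every statistic; the flag and cohort
prevalence are descriptive.  The full Goldberg machinery (PAL distributions,
within-subject CVs) is deliberately out of scope: the method being modelled
applies a fixed cutoff.

## Synthetic cohort: the stated world

The generator emulates a 126-child, 4-day preschool diary survey whose
cohort-level parameters match the published ones:

- **FS %TEI ~ lognormal**, moment-matched to arithmetic mean 14.1 /
  SD 5.81.  A normal law is impossible here: it would put ~6% of children
  below 5 %TEI where the publication reports under 4%, and it admits
  negative intakes.  The lognormal alone reproduces both headline
  compliance figures (analytically: P(>10) = 74.8%, P(<5) = 0.78%).
- **Energy intake ~ Normal(4.8, 0.9) MJ/day**, floored at 2.0.  The mean is
  backed out of the published 40.0 g/day at 14.1 %TEI; the SD is a
  realistic ~19% CV for 3-year-olds.  %TEI and energy are drawn
  independently — the true correlation is unknowable from the published
  tables; this is the main acknowledged simplification.
- **Group profiles** (consumer probability, mean FS g/day over all
  subjects, entry rate, snack probability) restate the published group
  table, e.g. fruit juice (73%, 8.4 g, snack 27%), chocolate confectionery
  (59.5%, 3.1 g, snack 73%), RTEBC (92.1%, 3.1 g, snack 5%).
- **Back-solved amounts**: each child's daily FS target
  (`%TEI/100 × TEI / 0.017`) is split across their consumed groups in
  proportion to the group FS weights; gram amounts are then solved from
  each food's ladder-assigned FS per 100 g and jittered ±10%.  Foods whose
  FS density is tiny for their group (plain bread, low-sugar cereal) are
  excluded from this stream — back-solving through them implies absurd
  portions — but stay in the table for the ladder.
- **Energy closure at the subject level**: zero-FS staples (milk, fruit,
  vegetables, porridge) plus a savoury filler top total energy up to the
  child's drawn 4-day budget.  Budgeting per subject rather than per day
  avoids one-sided clipping on heavy-sugar days; since %TEI is a ratio of
  4-day means this is exact for the recovered quantities.
- **Occasions**: three meal and three snack slots per day; every entry
  draws snack-vs-meal from its group's probability *before* choosing a
  food, so merging duplicate (slot, food) rows cannot bias snack
  probabilities.
- Reproducibility: (config, seed) → byte-identical output; stage sub-seeds
  derive from one `SeedSequence`.

What a green parameter-recovery test establishes: the pipeline, run over a
10,000-child generated cohort, returns the configured FS %TEI mean and SD,
the implied mean FS g/day, the consumer percentages and the snack
probabilities within 3 standard errors.  What it does not establish: the
generator is *not* a reconstruction of the real survey — the food list is
synthetic, the between-subject correlation structure is independence plus
the back-solve, day-of-week effects are absent, occasion-frequency
dispersion is narrower than the published SDs (Poisson within-subject only,
no between-subject rate heterogeneity), and the SFQ definitions are toy
exemplars whose non-covered set (RTEBC, juices, sugars/syrups) was chosen
to mirror the published "about one-third of FS non-covered" finding at the
calibration level only.

## Record linkage

Fuzzy similarity is difflib's normalized longest-common-subsequence ratio
on lowercased, punctuation-stripped strings — a Levenshtein-like ratio with
no extra dependency.  The threshold default of 0.85 is a design choice (the
manual protocol being modelled published none); ties at equal score resolve
to the first group in declared order with a logged warning, standing in for
the human arbiter.  Manual overrides are first-class, win over the cascade,
and are marked `manual_override` in the audit map.

## Known limitations

- The 77-group and 19-group source categorisations of the original food
  database are unpublished; the shipped regrouping scheme is an
  illustrative default, not a reconstruction.
- The real survey's per-rung assignment counts are unknowable; the ladder's
  step histogram is validated only on constructed tables.
- Published %TEI quartile columns in the source tables are typographically
  unreliable; no quartile expectations are taken from them, only means/SDs.
- The published TS %TEI (26.9) and FS %TEI (14.1) imply cohort energies
  differing by ~0.7% (printed rounding); table-consistency checks use the
  respective implied energy per quantity.
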