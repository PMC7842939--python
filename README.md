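# bedrestdt

Decision-tree identification of **bedrest** — nighttime sleep plus daytime
naps, as distinct from physiologically staged sleep — from waist-worn
triaxial accelerometer counts in preschool children (3–6 years), recorded
as minute epochs in ActiGraph-style exports.

Field studies of young children's sleep need an automated, reproducible
way to separate time in bed from wake over many free-living days. Visual
scoring of count traces is the accepted reference but does not scale;
generic sleep algorithms were derived for older children and misread quiet
daytime sedentary behavior as sleep. `bedrestdt` implements, end to end,
the pipeline such a study runs: parsing epoch exports, non-wear detection,
recording quality control, the four-parameter bedrest decision tree, an
automated transcription of the visual-scoring heuristic, the Sadeh
comparator, nap/awakening classification with daily summaries, epoch-level
agreement statistics, and Nelder–Mead calibration of the tree's
parameters — plus a seeded synthetic-data generator so everything is
testable without any recordings.

## The algorithm

Each epoch carries the vector magnitude of its three axis counts,
`VM = sqrt(axis1² + axis2² + axis3²)`. With parameters
*block length* `L`, *threshold* `T`, *bedrest-start trigger* `T_s` and
*bedrest-end trigger* `T_e` (defaults for preschool children:
`L = 36` epochs, `T = 230`, `T_s = 305`, `T_e = 1129` counts/min):

1. Partition the recording into blocks of `L` epochs and set the initial
   status from the first block's mean (≤ `T` → bedrest, > `T` → wake).
2. While wake, find the first block with mean < `T`; in that block and the
   preceding one, the epoch after the *last* two consecutive epochs
   > `T_s` marks **bedrest-start**.
3. While bedrest, find the first block with mean > `T`; in the same
   two-block window the epoch before the *first* two consecutive epochs
   > `T_e` marks **bedrest-end**.
4. Alternate steps 2–3 until the recording is exhausted, then relabel
   bedrest episodes shorter than a minimum duration (default 30 min) as
   wake.

Bedrest episodes of 30–90 min are naps, longer ones bedrest periods, and
5–15 min wake interruptions inside bedrest are awakenings. Agreement
between two scorings is summarized by sensitivity `TP/(TP+FN)`,
specificity `TN/(TN+FP)`, accuracy `(TP+TN)/N`, Cohen's κ, and the overlap
coefficient `|A ∩ B| / min(|A|, |B|)` on bedrest time. See
`docs/methods.md` for the complete rules, tie handling and design notes.

## Worked example

Simulate a week of preschool wear, detect bedrest, and score against the
planted truth:

```sh
bedrestdt simulate --days 7 --seed 7 -o trace.csv --truth truth.csv
bedrestdt detect trace.csv -o labels.csv --episodes episodes.csv
bedrestdt score --test labels.csv --reference truth.csv
```

```json
{
  "tp": 3376,
  "tn": 6286,
  "fp": 39,
  "fn": 259,
  "sensitivity": 0.928748280605227,
  "specificity": 0.9938339920948617,
  "accuracy": 0.9700803212851405,
  "kappa": 0.9346107539057896,
  "overlap": 0.9885797950219619
}
```

Of 9,961 worn epochs compared, the detector agrees with the planted truth
on 97.0%: it finds 92.9% of true bedrest minutes (misses are mostly short
naps and boundary minutes) and almost never calls active time bedrest
(specificity 99.4%). `bedrestdt classify labels.csv` then summarizes
periods per day:

```json
{
  "bedrest_min_per_day": 487.85714285714283,
  "wake_min_per_day": 935.0,
  "naps_per_day": 0.42857142857142855,
  "nap_min_per_day": 28.571428571428573,
  "awakenings_per_day": 0.0,
  "awakening_min_per_day": 0.0
}
```

about 8.1 hours of bedrest per day including a nap every other day or so,
in the range reported for this age group. `bedrestdt qc trace.csv` confirms
the recording is analyzable (7 valid nights, 5 weeknights + 2 weekend
nights). Other subcommands: `nonwear`, `sadeh`, `reference` (the automated
visual heuristic), and `optimize`, which re-calibrates the four parameters
on a directory of reference-labeled recordings with Nelder–Mead
(ρ, χ, γ, α = 1, 2, 0.5, 0.5; 100 iterations) and writes the iteration
trace. Every subcommand also accepts a YAML `--config` mirroring its
flags, and the same functionality is available as a library
(`import bedrestdt`).

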