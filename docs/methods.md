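# Methods

`bedrestdt` identifies *bedrest* — sustained periods of minimal movement
comprising nighttime sleep and daytime naps, as opposed to physiologically
staged sleep — from waist-worn triaxial accelerometer counts aggregated
into 60-second epochs. This note records the models implemented, the
numerical choices made where the design was genuinely open, and what the
synthetic data do and do not establish.

## Data model

An `EpochSeries` is a gap-free grid: the timestamp of epoch *i* is
`start_time + i * epoch_length`, strictly increasing with no missing rows
(gaps must be represented explicitly, e.g. as zero-filled or non-wear
epochs). The vector magnitude of an epoch is the Euclidean norm of its
three axis counts, `vm = sqrt(axis1² + axis2² + axis3²)`, stored as a real
number and never rounded; every threshold comparison downstream operates
on the real value, which avoids artifacts at integer thresholds.
Re-integration to a coarser epoch sums the axes within each window and
recomputes vm from the summed axes — the norm of sums, not the sum of
norms. A trailing window shorter than the target is dropped with a
warning, because a partial window would bias block averages.

Episodes use 0-based, half-open `[start, end)` epoch indices; an epoch is
identified by its start instant. Labels take exactly one of four states:
`BEDREST`, `WAKE`, `NONWEAR`, `EXCLUDED`.

## Non-wear detection

Non-wear is a maximal run of at least 90 consecutive zero-count minutes on
the tested signal (vm by default; vm is zero exactly when all three axes
are), tolerating interruptions of at most 2 non-zero minutes when at least
30 zero minutes flank the interruption on both sides. Tolerated spike
minutes are flagged together with the surrounding zeros. These defaults
(90/2/30) are the cited algorithm's published standard settings; when
several spikes occur in sequence, the upstream flank is measured on the
already-merged zero stretch. "Zero" means exactly 0. Detection requires
60-second epochs; finer data must be re-integrated first.

## Quality control

A night is the window 22:00–06:59 indexed by the calendar date of its
22:00 start; it is valid when worn (non-non-wear, in-coverage) epochs in
the window total at least 360 minutes (inclusive; contiguity is not
required). Epochs outside the recording count as not worn, so a recording
that begins mid-window can still contribute a valid night if enough of the
window is covered and worn — the rule is applied literally to worn minutes
in the window. Weekend nights start on Friday or Saturday. A recording is
analyzable with ≥ 3 valid nights, of which ≥ 2 weeknights and ≥ 1 weekend
night, evaluated after everything following the first non-wear run of ≥ 48
hours (inclusive) has been excluded.

## Visual-identification heuristic (reference scorer)

The automated reference scorer transcribes the raters' guidelines.
Scanning forward within each worn segment:

* bedrest-start: the first minute of 10 consecutive minutes ≤ 100
  counts/min whose following 20-minute window contains at most 2 minutes
  above 100;
* bedrest-end: the minute preceding the first minute ≥ 500 counts/min that
  is followed by ≥ 5 of the next 9 minutes ≥ 500.

Comparisons are inclusive exactly as written (≤ 100, ≥ 500). When a run or
confirm window extends past the end of the segment, the rule is applied to
the minutes that exist, so trailing bedrest is not discarded. After the
scan, episode minima are enforced in a fixed order: wake runs shorter than
10 minutes lying strictly between bedrest runs are absorbed into bedrest
first, then bedrest runs shorter than 30 minutes are demoted to wake. The
order matters (the two passes do not commute) and was chosen to mirror how
raters perceive consolidated blocks before discarding slivers.

Two raters' sequences are merged by keeping agreements and resolving
disagreements to wake (*True1*) or to bedrest (*True2*); the *True2*
bedrest set therefore always contains the *True1* set.

## The bedrest decision tree

The detector has four parameters: `block_length` (epochs), `threshold`
(counts/min), `bedrest_start_trigger` and `bedrest_end_trigger`
(counts/min), plus a user-specified minimum bedrest duration
(`min_bedrest_min`, default 30 minutes). The shipped defaults —
block length 36, threshold 230, start trigger 305, end trigger 1129 — are
the values calibrated for preschool children (3–6 years); they suit
waist-worn vm counts and should be re-optimized for other populations.

Within each worn segment (blocks never span a non-wear gap):

1. Partition into consecutive blocks of `block_length` epochs; the final
   partial block is averaged over its own epochs. The first block's mean
   sets the initial status: mean ≤ threshold is bedrest (a tie goes to the
   bedrest side, consistent with the start rule's wording), above is wake.
2. While wake: find the first block with mean **strictly below** the
   threshold; within that block and the preceding block (clamped to the
   current position; the first block has no predecessor), the epoch after
   the **last** two consecutive epochs strictly above the start trigger is
   bedrest-start.
3. While bedrest: find the first block with mean **strictly above** the
   threshold; within the same two-block window, the epoch before the
   **first** two consecutive epochs strictly above the end trigger is
   bedrest-end.
4. When no further qualifying block exists, the remaining epochs keep the
   current status. After the cycle completes, every bedrest episode
   shorter than `min_bedrest_min` is relabeled wake — a single final pass,
   not interleaved with the search.

Block-mean comparisons at exact equality satisfy neither search, so such a
block is skipped by both; trigger comparisons are strict. When no trigger
pair exists in the two-block window, the boundary falls back to the
identified block's first epoch (clamped so boundaries never move
backwards) — a conservative, deterministic locator for a case where a
boundary is guaranteed to exist but its position is not otherwise pinned
down. Scanning resumes at the boundary epoch itself.

Degenerate parameter combinations (for instance an end trigger far below
the start trigger, which the optimizer is free to explore) can produce a
start/end cycle with zero net progress. A deterministic guard detects a
repeated (status, position) pair, labels that single epoch with the
current status, and advances one epoch. The guard is part of the
documented procedure and is exercised by the equivalence tests.

A naive pure-Python transcription of these rules (plain loops, no array
shortcuts) lives in the test suite and must agree with the production
detector epoch-for-epoch on a thousand randomized traces.

## Sadeh comparator

The comparator scores each epoch with the published linear discriminant
`PS = 7.601 − 0.065·AVG − 1.08·NAT − 0.056·SD − 0.703·LG`, computed on
counts capped at 300: AVG is the mean of the centered 11-epoch window, NAT
the number of window epochs with counts in [50, 100), SD the population
standard deviation of the trailing 6 epochs, LG the natural log of the
current count plus one; PS ≥ 0 is sleep. The constants are stored in
`SadehParams` so published variants can be configured. Edge windows are
truncated to the available epochs by default (zero-padding is available).
The vertical axis (axis1) is the default input, matching the discriminant's
single-axis derivation; a vm mode exists only for exploratory parity.
Bit-exact parity with any particular commercial implementation is not a
goal (their edge handling is unpublished).

## Period classification and daily summaries

Bedrest episodes shorter than 30 minutes are wake; 30–90 minutes
(inclusive) is a nap; longer than 90 minutes is a bedrest period. Wake
interruptions of 5–15 minutes (inclusive) inside bedrest are awakenings:
their epochs stay wake for epoch-level metrics, while at the period level
the flanking bedrest spans are reported as a single bedrest period.
Whether a span is "long" is evaluated on the merged span (bedrest plus
candidate awakenings) — an open reading; the alternative (each fragment
judged alone) would split a night with an early awakening into fragments.
A period's `bedrest_min` counts only its bedrest epochs, so period totals
reconcile exactly with epoch totals.

Days split at local midnight; a period crossing midnight contributes
minutes to each day it covers, while nap/awakening *counts* belong to the
day the episode starts. Daily minutes are computed over worn epochs only;
non-wear and excluded epochs contribute to nothing.

## Agreement statistics

Epochs non-wear or excluded in either sequence are dropped from every
statistic. With bedrest as the positive state: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/total. An undefined ratio is
reported as NaN, never 0. Cohen's kappa (via scikit-learn; unweighted,
linear and quadratic weightings coincide for binary labels) of two
identical constant sequences is 0/0 and is reported as 1.0 with a
degenerate-marginals warning — total agreement is the honest summary. The
overlap coefficient is the agreed bedrest time divided by the smaller of
the two totals, hence exactly 1.0 whenever one bedrest set is a subset of
the other, and NaN when either set is empty.

## Parameter optimization

The Nelder–Mead engine is implemented in full (reflection ρ = 1, expansion
χ = 2, contraction γ = 0.5, shrinkage α = 0.5, all configurable; 100
iterations by default) rather than delegated, because the search needs
configurable move coefficients, a per-iteration trace, and best-ever
bookkeeping; it is cross-checked against SciPy's simplex on standard test
functions. Vertex ordering breaks ties toward the lexicographically
smaller vertex, so runs are fully deterministic.

The DT objective is epoch accuracy against reference labels, pooled over
the development set by default (every epoch weighs equally, matching how
the calibration counted epochs); a per-recording mean is selectable.
Parameters are rounded to integers at evaluation time (block length
clamped to ≥ 2, triggers to ≥ 0), keeping the simplex continuous while
honoring epoch-granular parameters; evaluations are cached on the rounded
grid. The shipped initial simplex is a documented spread over plausible
preschool-to-youth activity regimes — (60, 400, 500, 1500),
(24, 150, 200, 800), (48, 300, 600, 2000), (12, 100, 400, 600) and their
centroid — and is overridable. The returned optimum is the best point ever
evaluated, so the best-so-far trace is non-decreasing by construction.

## Synthetic data: what it emulates and what it does not

The generator plants a known truth: one night per day with bedtime drawn
around 20:45 (SD 30 min) and 570 ± 40 minutes in bed (clipped to 7–12 h);
a daytime nap on 30% of days, 30–90 minutes long, placed between 09:00 and
18:00 clear of nights and non-wear; awakenings at 0.18 per bedrest-hour
(about 1.7 per night), 5–15 minutes each, at least 20 minutes from the
night edges; and one 120-minute non-wear run on day 1 at 13:00 by default.
These rates sit in the range reported for preschool wear: roughly 8–9.5
hours of daily bedrest, one to two brief awakenings per day, naps on a
minority of days.

Counts are drawn per state: wake vm is lognormal with median 1500
counts/min (σ = 0.6), bedrest epochs are 80% exact zeros with residual
counts uniform on [1, 100] plus Poisson-timed bursts of 200–600 counts/min
at 0.01/min, and non-wear is exactly zero. These regimes deliberately
straddle every decision boundary the scorers use (100, 500 counts/min for
the heuristic; 230, 305, 1129 for the DT). Target vm values are decomposed
onto the three axes along a random positive-octant direction, axes are
rounded to integers, and vm is recomputed from the rounded axes, so the
axis/vm invariant holds exactly.

What passing tests on this data show: the detector recovers planted
transitions, the period classifier honors its duration boundaries, the
whole pipeline composes, and the optimizer improves on fixed parameters
for data of this structure. What they do not show: performance on real
preschool recordings, whose count distributions, postural artifacts,
device filtering and behavioral variety the generator does not model. The
synthetic world has sharp state transitions and stationary within-state
distributions; real transitions are gradual and children are not
stationary processes. Accuracy numbers on synthetic data are therefore
internal-consistency checks, not validity claims.

## Problem sizes and tolerances

The test suite uses traces of up to 2,000 epochs for equivalence testing
(1,000 random trace/parameter draws), 7-day recordings (10,080 epochs, 10
seeds) for recovery checks, and five 3-day recordings for optimization
runs of 100 iterations — sizes at which the full suite completes in a few
seconds on one core. vm consistency is enforced to 1e−9; the quadratic
optimizer sanity check requires the minimum to 1e−3 within 200 iterations;
metric identities are exact. All randomness flows through seeded
`numpy.random.default_rng` instances; identical seeds reproduce identical
traces, labels and optimizer paths.

## Known limitations

* The decision tree labels bedrest, not sleep; it cannot distinguish quiet
  wakefulness in bed from sleep.
* The 48-hour truncation and night-validity rules assume 60-second epochs
  and local clock time; daylight-saving transitions are not modeled.
* The fallback boundary (block start) can move a transition by up to one
  block when counts hover near a trigger without ever forming a pair.
* Raising the end trigger normally delays bedrest end, but when a higher
  trigger eliminates the only trigger pair the fallback can place the
  boundary earlier; the monotonicity property holds on trigger ranges
  where pairs exist.
* The Sadeh implementation follows the published discriminant; agreement
  with proprietary implementations is approximate at segment edges.
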