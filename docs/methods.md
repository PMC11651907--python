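# Methods

This note records the models implemented in `tempnet`, the defaults and
their rationale, what the synthetic generators do and do not emulate,
and the numerical conventions that make results reproducible.

## From records to snapshots

A tij record `t i j` states that pair (i, j) was in proximity during
the interval [t, t + res), where `res` is the deployment's fixed
recording resolution.  Node identifiers are opaque strings; timestamps
are normalised to seconds since the first observation (the original
epoch is kept as metadata).  Duplicate lines — common in sensor
dumps — are collapsed silently but counted in a parse report, so no
data loss is invisible.  Directed (face-to-face badge) data keeps
ordered pairs; simultaneous i→j and j→i records count as two directed
contacts, and an explicit undirected conversion collapses them.

A contact *episode* is a maximal run of consecutive records of one pair
(a single missing interval splits the run).  Two per-deployment medians
set the analysis scales: the median episode duration (validity
threshold) and the median gap between same-pair episodes (time-step
length).  Shipped presets carry the published values for the classic
deployments (cruise 900 s/900 s at 15 s resolution; community
300 s/600 s at 5 min; high school and hospital 20 s/140 s and
workplaces 20 s/220 s at 20 s), and fixed 15 min/1 h/1 day steps
support sensitivity analyses.

Windows are half-open `[start, start + L)` intervals anchored at the
first record's time floored to the step length, tiling the study span;
an episode straddling a boundary contributes its overlap to each
window.  A pair is a valid contact in a window when its recorded
contact time there reaches the threshold *cumulatively* over episodes
— the more inclusive reading of "lasts for at least" the threshold; a
`require_continuous` switch demands one unbroken episode instead.
Windows with no valid contact remain in the series as empty snapshots,
and every individual observed anywhere in the study belongs to the
population N, entering all averages with degree 0 when inactive.

## Retention index

A retained contact is a pair in contact in two consecutive steps.  With
k_t an individual's contact count in step t, the observed mean retained
contacts per individual r̄_temp is compared against:

* the **static null** — contacts never change, so the retained-count
  distribution is the step-t degree distribution and
  r̄_stat = E[k_t];
* the **fully dynamic null** — contacts are redrawn every step with the
  degree distribution preserved.  The retained count of an individual
  with degrees (k_t, k_{t+1}) is modelled as
  Binomial(min(k_t, k_{t+1}), p) with per-contact retention probability
  p = k_{t+1}/(N−1), mixed over the empirical degree distributions;
  the mean is r̄_dyna = E[min(k_t, k_{t+1}) · k_{t+1}]/(N−1).

The retention index r̄ = (r̄_temp − r̄_dyna)/(r̄_stat − r̄_dyna) is
reported *unclamped*: sampling noise legitimately pushes single step
pairs below 0 or above 1, and clamping would bias the median.  A step
pair is flagged undefined when r̄_stat = r̄_dyna (empty or complete
snapshots) and excluded from summaries; summaries require at least two
defined pairs and report the median and IQR using linear-interpolation
quantiles.

Two readings of the dynamic null are provided.  The default mixes the
*marginal* degree distributions of the two steps, treating degrees as
independent across steps; `joint=True` instead uses each individual's
own (k_t, k_{t+1}) pair, matching a rewiring that preserves per-node
degrees.  The marginal reading is the default because it is the one the
binomial mixture itself assumes, and it corresponds operationally to
rewiring in which the step-t+1 degree sequence is shuffled across
individuals before the graph is resampled.  Two caveats of the binomial
closed form are worth recording: (i) capping the trial count at
min(k_t, k_{t+1}) while keeping p = k_{t+1}/(N−1) understates the
exchangeability-exact mean E[k_t]·E[k_{t+1}]/(N−1) whenever an
individual's degree drops between steps (k_t > k_{t+1} ≥ 1); the form
is exact for degree sequences valued in {0, k} — matchings and regular
graphs — which is where the Monte-Carlo validation tests operate;
(ii) for directed networks the same formulas are applied to incident
ordered contacts without further adjustment.

Retained contacts are typed from the endpoints' group attribute as
`same-X`/`different-X` (label `unknown` when either endpoint lacks the
attribute); finer cross-category taxonomies would need study-specific
semantics and are not modelled.

## Repeated contacts across days

Days are multiples of a configurable day length (default 86 400 s) from
the study start — sensor studies start mid-day, so calendar days are not
assumed.  A pair counts once per day in which it has at least one valid
contact.  The ledger tracks, per day d, the cumulative unique pairs
since day 1 and the sum of the daily unique-pair counts; their
difference is reported both relative to N (comparable across studies)
and relative to the cumulative unique count (the overestimation factor
of a planning model that assumes independent days).  Both
normalisations are emitted because each answers a different question;
neither is silently preferred.

## Top-contributor persistence

Per step, nodes are ordered by weight — contact count, or in-step
contact seconds — and the top group is the smallest prefix covering 80%
(configurable) of the step's total weight.  Tie-breaking is
deterministic (weight descending, then node id ascending) so that
repeated runs are identical; an optional seeded random tie-break exists
because in homogeneous networks large equal-weight blocks would
otherwise pin the cut to the same individuals every step.  Empty steps
contribute no memberships but count toward S unless skipped.

ρ_s is the population fraction in the top group for at most s of S
steps; it is non-decreasing with ρ_S = 1 by construction.
Classification uses unrounded thresholds matching their definitions:
superspreaders have counts ≥ S/2 ("at least half"), superspreading-event
drivers counts < S/4 ("less than a quarter"); both fractions are
configurable, and with S < 4 a warning notes that the cut-offs barely
differ.  The fully dynamic reference curve is the geometric p80^s — the
probability of independent per-step identification — with p80 = 0.8 for
a homogeneous network and 0.5 for the overdispersed reference used
throughout.

## Synthetic generators

The generators define the conditions every metric is tested under; they
emulate the *structural* features the metrics respond to and nothing
else.  One degree law (constant, Poisson, or negative binomial with
dispersion α) feeds three regimes:

* **static** — one graph repeated for T steps;
* **fully dynamic** — the degree sequence is drawn once and each step is
  an independent simple-graph realisation; per-node degrees stay fixed
  by default, and a `shuffle_degrees` option additionally permutes the
  sequence across individuals each step, so *who* is central also
  re-randomises (the regime behind the geometric reference curve);
* **partial retention** — each edge survives to the next step with
  probability q; the stubs freed by dropped edges are rewired at random
  avoiding the kept edges, preserving every node's degree exactly.  q is
  the recoverable ground truth: q = 1 is static, q = 0 an edge-resampled
  dynamic network.

Graphs are simple (no self-loops or multi-edges).  Degree sequences are
capped at N−1, parity-repaired by decrementing one random positive
degree, and projected to graphicality (Erdős–Gallai test, shaving the
largest degrees) when heavy overdispersion demands it.  Sampling is
stub matching with re-shuffles of colliding stubs and an exhaustive
degree-preserving edge-swap repair; if that dead-ends (rare, hub-heavy
sequences), a Havel–Hakimi construction randomised by ~5 swaps per edge
guarantees success.  For small oracle graphs an *exact* mode resamples
the whole configuration-model matching until simple, which is uniform
over simple graphs with the given sequence.  The partial-retention
rewiring retries with a fresh survival draw on the rare dead end.  All
generators are bit-reproducible from their seed.

Overdispersion is calibrated rather than assumed: `calibrate_dispersion`
bisects the negative-binomial dispersion (common random numbers,
tolerance 0.02) until single-snapshot simulations realise a target p80.
At mean degree 5, Poisson-like sequences realise p80 ≈ 0.64 — degree
randomness alone concentrates contacts below the 0.8 of an exactly
constant-degree network — and p80 = 0.5 needs dispersion ≈ 2.2.

The multi-day generator emits raw records: a base set of pairs on day 1,
each base pair recurring independently on later days with probability
ρ, topped up with never-before-seen pairs to keep the daily unique count
constant; each selected pair is written as one three-interval episode.
Expected day-D overcount is then (D−1)ρ / (1 + (D−1)(1−ρ)), the closed
form the Monte-Carlo tests check.

What the generators do **not** emulate: diurnal activity rhythms and
overnight recording gaps, household/venue community structure, open
populations and sensor dropout, degree–retention correlations, and
contact-duration heterogeneity within a step (generated contacts span
their whole window).  Tests passing on these networks therefore verify
the metrics' correctness and calibration, not robustness to every
artefact of field data; the pipeline's handling of gaps and thresholds
is exercised separately on constructed record sets.

## Problem sizes and tolerances

Simulation checks run at N = 500, T = 50 for retention (the
recovery error of q is then well under ±0.1, and the fully dynamic
median index falls within ±0.05 of 0), N = 1000, T = 25 for the
homogeneous static top-group split (exactly 80%/20% by tie-breaking),
and N ≤ 12 with ≥10⁴ rewiring draws for the dynamic-null oracle (3
standard errors).  The reference-results script
(`scripts/acceptance.py`) re-runs these from scratch, deriving all
seeds from a single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

* The binomial dynamic null is a mean-field approximation for
  heterogeneous degree sequences (see above); the package reports it as
  defined rather than the exchangeability-exact alternative, keeping the
  two extremes interpretable as the printed closed forms.
* Retention is a pairwise, first-order metric: higher-order structure
  (triangles, communities) retained across steps is not measured.
* The day ledger counts pairs, not tracing effort per individual; no
  cost model is attached.
* Directed analyses treat in- and out-contacts symmetrically through
  incident degree; asymmetric exposure models are out of scope.
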