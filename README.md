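# tempnet

Temporal contact-network metrics for epidemic planning: **contact
retention**, **repeated-contact accounting** and **top-contributor
persistence**, with synthetic network generators for ground-truthed
testing and a small command-line pipeline.

## The problem

Proximity sensors (RFID badges, phone apps) record who was near whom in
fixed intervals — 15 s, 20 s or 5 min in the classic cruise, community,
school, hospital and workplace deployments.  Outbreak models usually
flatten these records into either a *static* network (contacts never
change) or a *fully dynamic* one (contacts redrawn at random every time
step).  Where a real network sits between those extremes decides whether
contact tracing budgets, targeted closures and "superspreader"
interventions are planned correctly.  `tempnet` measures exactly that,
for epidemiologists and network scientists working with timestamped
contact data or simulation studies.

## The metrics

Records are first merged into contact *episodes* and binned into
half-open time-step windows; a pair is a valid contact in a step if its
in-window contact time reaches a duration threshold (each deployment's
median contact duration; the step length defaults to its median delay
between contacts).

**Retention index.**  For consecutive steps t, t+1 the mean number of
retained contacts per individual, r̄_temp, is rescaled between two
analytic nulls computed from the empirical degree distributions P(k_t),
P(k_{t+1}) over all N individuals:

- static null: r̄_stat = E[k_t] — every contact is retained;
- fully dynamic null: each individual's retained count is
  Binomial(min(k_t, k_{t+1}), k_{t+1}/(N−1)) mixed over the degree
  distributions, giving r̄_dyna;

and the retention index is

    r̄ = (r̄_temp − r̄_dyna) / (r̄_stat − r̄_dyna),

≈1 for frozen contacts, ≈0 for chance-level retention.  Per-step
breakdowns by contact type (same/different department, class, cabin …)
identify who drives the retained contacts.

**Repeated-contact accounting.**  Summing daily unique contacts over a
tracing window double-counts pairs that meet again; the ledger compares
cumulative unique pairs with the summed daily counts, reporting the gap
relative to population size and to the true unique count.

**Top-contributor persistence.**  Per step, the *top group* is the
smallest node set carrying 80% of contacts (or contact seconds).  With
s = number of steps a node is in that group out of S, the curve
ρ_s — the population fraction in the top group for *at most* s
steps — separates persistent **superspreaders** (s ≥ S/2) from
unpredictable drivers of **superspreading events** (s < S/4).  A fully
dynamic network with per-step top-group fraction p80 follows the
geometric reference p80^s.

## Worked example

`examples/retention_continuum.py` generates networks whose edges survive
each step with probability q (N = 500, T = 50, Poisson mean degree 5)
and scores them blind:

```
 q (truth)  median index               IQR
      0.00         0.006    [0.004, 0.008]
      0.25         0.251    [0.244, 0.260]
      0.50         0.497    [0.487, 0.506]
      0.75         0.752    [0.743, 0.761]
      1.00         1.000    [1.000, 1.000]
```

The recovered median retention index lands on the generating q: the
metric reads off where a network sits on the static↔dynamic continuum.
The other scripts in `examples/` walk through the contact-tracing
overcount ledger, superspreader persistence under overdispersion, and a
full raw-records-to-metrics pipeline.

## Command line

```sh
tempnet simulate --model partial --n 200 --steps 20 --q 0.6 --seed 1 -o sim
tempnet run sim.tij --resolution 300 --step-length 300 \
    --duration-threshold 300 --no-directed -d results/
```

`run` writes snapshot edge/degree tables, the per-step retention table,
the repeat ledger, top-group counts, the ρ_s curve and a reproducibility
manifest.  Individual subcommands (`snapshots`, `retention`, `repeats`,
`topgroups`) expose the stages separately; `--preset
cruise|community|highschool|hospital|workplace` applies the time scales
of the corresponding sensor deployments, e.g. `--preset hospital` sets a
20 s validity threshold and 140 s steps.

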