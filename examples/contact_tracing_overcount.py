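"""How badly does assuming independent days overestimate unique contacts?

Simulates a five-day deployment in which half of the day-1 contact pairs
recur on each later day, then compares the cumulative number of unique
pairs with the sum of daily unique-pair counts — the figure a
contact-tracing resource plan would use if it treated days as
independent.
"""

from tempnet import (
    DayStructure,
    DegreeLaw,
    GeneratorConfig,
    build_snapshots,
    encounter_days,
    generate_multiday,
    overcount_metrics,
    unique_contact_ledger,
)

cfg = GeneratorConfig(
    n=100, t=1, degree_law=DegreeLaw.poisson(3), seed=7, resolution=300,
    days=DayStructure(n_days=5, pairs_per_day=60, repeat_prob=0.5),
)
records = generate_multiday(cfg)
series = build_snapshots(records, step_length=900, duration_threshold=300)

ledger = unique_contact_ledger(series, day_length=86_400)
table = overcount_metrics(ledger)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

last = table.iloc[-1]
print()
print(
    f"After {int(last['day'])} days a planner assuming independent days would "
    f"budget for {int(last['summed_daily'])} contacts, but only "
    f"{int(last['cumulative_unique'])} distinct pairs occurred: an overestimate "
    f"of {last['relative_to_unique']:.0%} of the true unique contacts "
    f"({last['relative_to_population']:.0%} of the population)."
)

summary = encounter_days(series, day_length=86_400)
print()
print("Encounter-day distribution over contact pairs:")
for days, prop in summary.distribution.items():
    print(f"  met on {days} day(s): {prop:.1%} of pairs")
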