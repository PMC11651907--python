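"""Repeated contacts across days and the independence-assumption bias.

Contact-tracing resource models often take the measured number of daily
contacts and treat the days as independent.  Because real pairs meet
again on later days, summing per-day unique contacts over a tracing
window overstates the number of distinct individuals that would actually
need follow-up.  This module measures that gap: the distribution of how
many distinct days each pair was in contact, and a per-day ledger
comparing the cumulative number of unique pairs since the study start
with the sum of daily unique-pair counts.

Worked two-day example: day 1 has pairs A-B, C-D, E-F and day 2 has
A-B, G-H, I-J.  Cumulative unique pairs by day 2: five; summed daily
unique pairs: six — the difference (one) is the double-counted repeat.
The difference is reported both relative to the population size (the
scale-free comparison across studies) and relative to the cumulative
unique count (the overestimation factor of a planning model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .snapshots import Pair, SnapshotSeries

__all__ = [
    "EncounterSummary",
    "UniqueContactLedger",
    "daily_pair_sets",
    "encounter_days",
    "unique_contact_ledger",
    "ledger_from_daily_pairs",
    "overcount_metrics",
]

DAY = 86_400


@dataclass
class EncounterSummary:
    """Distribution of per-pair encounter days over the whole study."""

    pair_days: dict[Pair, int]
    days_observed: int
    distribution: dict[int, float]  # encounter-day count -> proportion of pairs
    cdf: np.ndarray  # P(pair met on <= d days), d = 1 .. days_observed


@dataclass
class UniqueContactLedger:
    """Per-day cumulative-unique vs summed-daily-unique contact pairs."""

    days: list[int]  # 1-based day indices
    cumulative_unique: list[int]
    summed_daily: list[int]
    n_population: int


def daily_pair_sets(
    series: SnapshotSeries, day_length: int = DAY
) -> dict[int, set[Pair]]:
    """Valid contact pairs per day (1-based).

    Day boundaries are multiples of ``day_length`` from the series start,
    not calendar days; a snapshot belongs to the day containing its
    window start.  Days with no contacts still appear (empty sets) so day
    indices run contiguously over the observed span.
    """
    if day_length <= 0:
        raise ValueError("day_length must be positive")
    if series.n_steps == 0:
        return {}
    n_days = (series.snapshots[-1].window[0] - series.start) // day_length + 1
    daily: dict[int, set[Pair]] = {d: set() for d in range(1, n_days + 1)}
    for snap in series:
        d = (snap.window[0] - series.start) // day_length + 1
        daily[d].update(snap.contacts)
    return daily


def encounter_days(
    series: SnapshotSeries, day_length: int = DAY
) -> EncounterSummary:
    """How many distinct days each contact pair was seen on.

    A pair is counted once per day in which it has at least one valid
    contact in any time step of that day.
    """
    daily = daily_pair_sets(series, day_length)
    if not daily:
        raise ValueError("empty series: no days observed")
    days_observed = len(daily)
    pair_days: dict[Pair, int] = {}
    for pairs in daily.values():
        for p in pairs:
            pair_days[p] = pair_days.get(p, 0) + 1
    n_pairs = len(pair_days)
    dist: dict[int, float] = {}
    for d in pair_days.values():
        dist[d] = dist.get(d, 0.0) + 1.0
    dist = {d: c / n_pairs for d, c in sorted(dist.items())} if n_pairs else {}
    cdf = np.cumsum([dist.get(d, 0.0) for d in range(1, days_observed + 1)])
    return EncounterSummary(pair_days, days_observed, dist, cdf)


def ledger_from_daily_pairs(
    daily: Mapping[int, Iterable[Pair]], n_population: int
) -> UniqueContactLedger:
    """Build the ledger from explicit day -> pair-set data (1-based days)."""
    if n_population < 1:
        raise ValueError("population size must be at least 1")
    days = sorted(daily)
    seen: set[Pair] = set()
    cumulative, summed = [], []
    running = 0
    for d in days:
        pairs = set(daily[d])
        running += len(pairs)
        seen |= pairs
        cumulative.append(len(seen))
        summed.append(running)
    return UniqueContactLedger(days, cumulative, summed, n_population)


def unique_contact_ledger(
    series: SnapshotSeries, day_length: int = DAY
) -> UniqueContactLedger:
    """Cumulative-unique vs summed-daily-unique contact pairs per day."""
    daily = daily_pair_sets(series, day_length)
    if not daily:
        raise ValueError("empty series: no days observed")
    return ledger_from_daily_pairs(daily, series.n)


def overcount_metrics(ledger: UniqueContactLedger) -> pd.DataFrame:
    """Per-day overcounting of unique contacts under daily independence.

    Columns: ``difference`` (summed daily unique minus cumulative unique),
    ``relative_to_population`` (difference / N, comparable across studies)
    and ``relative_to_unique`` (difference / cumulative unique, the
    factor by which an independence-assuming planning model overestimates
    — NaN where no contact has been seen yet).
    """
    cum = np.array(ledger.cumulative_unique, dtype=float)
    summed = np.array(ledger.summed_daily, dtype=float)
    diff = summed - cum
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_unique = np.where(cum > 0, diff / cum, np.nan)
    return pd.DataFrame(
        {
            "day": ledger.days,
            "cumulative_unique": ledger.cumulative_unique,
            "summed_daily": ledger.summed_daily,
            "difference": diff,
            "relative_to_population": diff / ledger.n_population,
            "relative_to_unique": rel_unique,
        }
    )
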