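"""Contact episodes and the per-network duration/delay medians.

A contact *episode* is a maximal run of consecutive recording intervals in
which the same pair is in proximity: records at t, t+res, t+2*res ... with
no missing interval.  Its duration is (number of records) * resolution.
The *delay* between two episodes of the same pair is the gap from the end
of one to the start of the next.

The medians of these two quantities over a whole deployment are the
study-specific scales used downstream: the median duration is the default
validity threshold for a contact inside a time-step window, and the median
delay is the default time-step length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import ContactRecordSet

__all__ = [
    "ContactEpisode",
    "build_episodes",
    "median_contact_duration",
    "median_delay",
]


@dataclass(frozen=True, order=True)
class ContactEpisode:
    """A maximal run of consecutive recorded intervals for one pair."""

    start: int
    pair: tuple[str, str]
    duration: int

    @property
    def end(self) -> int:
        return self.start + self.duration


def build_episodes(record_set: ContactRecordSet) -> list[ContactEpisode]:
    """Merge each pair's records into maximal consecutive runs.

    Two records of the same pair belong to one episode iff they are
    exactly one resolution apart (zero missing intervals).  A single
    record yields an episode of one resolution.
    """
    res = record_set.resolution
    by_pair: dict[tuple[str, str], list[int]] = {}
    for rec in record_set.records:
        by_pair.setdefault(rec.pair(record_set.directed), []).append(rec.time)
    episodes: list[ContactEpisode] = []
    for pair, times in by_pair.items():
        times.sort()
        run_start = times[0]
        prev = times[0]
        for t in times[1:]:
            if t - prev > res:
                episodes.append(ContactEpisode(run_start, pair, prev + res - run_start))
                run_start = t
            prev = t
        episodes.append(ContactEpisode(run_start, pair, prev + res - run_start))
    episodes.sort()
    return episodes


def median_contact_duration(episodes: Sequence[ContactEpisode]) -> float:
    """Median episode duration in seconds (requires at least one episode)."""
    if not episodes:
        raise ValueError("median_contact_duration requires at least one episode")
    return float(np.median([e.duration for e in episodes]))


def median_delay(episodes: Iterable[ContactEpisode]) -> float:
    """Median gap between consecutive episodes of the same pair, in seconds.

    Raises ``ValueError`` when no pair has a repeat episode, in which case
    the delay is undefined for the network.
    """
    by_pair: dict[tuple[str, str], list[ContactEpisode]] = {}
    for ep in episodes:
        by_pair.setdefault(ep.pair, []).append(ep)
    gaps: list[int] = []
    for eps in by_pair.values():
        eps.sort()
        gaps.extend(nxt.start - cur.end for cur, nxt in zip(eps, eps[1:]))
    if not gaps:
        raise ValueError("median_delay undefined: no pair has more than one episode")
    return float(np.median(gaps))
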