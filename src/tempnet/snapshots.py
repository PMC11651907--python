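"""Time-step snapshots: the graph sequence all network metrics run on.

The study span is partitioned into contiguous half-open windows of fixed
length (the *time step*).  Within each window, a pair counts as a valid
contact if its recorded contact time in the window reaches a duration
threshold — by default cumulatively over all its episodes, optionally
requiring a single unbroken episode.  Each window then defines a graph
snapshot; the ordered collection, together with the full study population
(individuals with no contact in a window appear with degree zero), is the
:class:`SnapshotSeries`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .episodes import build_episodes
from .records import ContactRecordSet

__all__ = ["Snapshot", "SnapshotSeries", "build_snapshots"]

Pair = tuple[str, str]


@dataclass(frozen=True)
class Snapshot:
    """The contact graph of one time-step window.

    ``contacts`` holds node pairs (ordered pairs when the series is
    directed, canonically sorted otherwise); ``pair_seconds`` the recorded
    in-window contact time per pair; ``degree`` the per-node count of
    incident contacts (only nonzero entries stored — use
    :meth:`degree_of`).
    """

    index: int
    window: tuple[int, int]
    contacts: frozenset[Pair]
    pair_seconds: Mapping[Pair, float] = field(default_factory=dict)
    degree: Mapping[str, int] = field(default_factory=dict)

    @staticmethod
    def from_contacts(
        index: int,
        window: tuple[int, int],
        contacts: Iterable[Pair],
        pair_seconds: Mapping[Pair, float] | None = None,
    ) -> "Snapshot":
        contacts = frozenset(contacts)
        deg: dict[str, int] = {}
        for u, v in contacts:
            if u == v:
                raise ValueError(f"self-contact {u!r} in snapshot {index}")
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        if pair_seconds is None:
            length = float(window[1] - window[0])
            pair_seconds = {p: length for p in contacts}
        return Snapshot(index, window, contacts, dict(pair_seconds), deg)

    def degree_of(self, node: str) -> int:
        return self.degree.get(node, 0)

    def node_seconds(self, node: str) -> float:
        """Total recorded contact time of ``node`` in this window."""
        return sum(s for (u, v), s in self.pair_seconds.items() if node in (u, v))

    def nodes(self) -> set[str]:
        return set(self.degree)

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)


@dataclass
class SnapshotSeries:
    """Ordered snapshots over a fixed population.

    ``population`` is every individual observed in the study; it is a
    superset of each snapshot's active nodes, and its size N is the
    normalising constant of all per-individual averages.
    """

    snapshots: list[Snapshot]
    population: frozenset[str]
    step_length: int
    duration_threshold: int
    directed: bool = False
    start: int = 0

    def __post_init__(self) -> None:
        for k, snap in enumerate(self.snapshots):
            if snap.index != k:
                raise ValueError(f"snapshot indices must be consecutive from 0, got {snap.index} at {k}")
            if not snap.nodes() <= self.population:
                extra = sorted(snap.nodes() - self.population)[:3]
                raise ValueError(f"snapshot {k} contains nodes outside the population, e.g. {extra}")

    @property
    def n(self) -> int:
        return len(self.population)

    @property
    def n_steps(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __len__(self) -> int:
        return len(self.snapshots)

    def step_pairs(self) -> Iterable[tuple[Snapshot, Snapshot]]:
        return zip(self.snapshots, self.snapshots[1:])


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def build_snapshots(
    record_set: ContactRecordSet,
    step_length: int,
    duration_threshold: int,
    require_continuous: bool = False,
    population: Iterable[str] | None = None,
) -> SnapshotSeries:
    """Bin records into fixed windows and apply the contact-validity rule.

    Windows are half-open ``[start, start + L)`` intervals anchored at the
    first record's time floored to the step length, tiling the study span.
    A pair is a contact in a window iff its recorded contact time there
    reaches ``duration_threshold`` — summed over episodes by default, or
    within a single unbroken episode when ``require_continuous`` is set
    (the stricter reading of "lasts for at least" the threshold).

    Every individual appearing anywhere in the records (or in the given
    ``population`` override) belongs to the series population; windows
    with no valid contact are kept as empty snapshots.
    """
    if step_length < record_set.resolution:
        raise ValueError("step_length must be at least the recording resolution")
    if duration_threshold < record_set.resolution:
        raise ValueError("duration_threshold must be at least the recording resolution")
    if duration_threshold > step_length:
        raise ValueError(
            f"duration_threshold {duration_threshold} exceeds step_length {step_length}: "
            "no contact could ever be valid"
        )

    pop = set(population) if population is not None else set()
    pop |= record_set.nodes()

    episodes = build_episodes(record_set)
    if episodes:
        first = min(e.start for e in episodes)
        last = max(e.end for e in episodes)
        anchor = (first // step_length) * step_length
        n_windows = max(1, math.ceil((last - anchor) / step_length))
    else:
        anchor, n_windows = 0, 0

    cum: dict[tuple[int, Pair], float] = {}
    longest: dict[tuple[int, Pair], float] = {}
    for ep in episodes:
        w_first = (ep.start - anchor) // step_length
        w_last = (ep.end - 1 - anchor) // step_length
        for w in range(w_first, w_last + 1):
            w0 = anchor + w * step_length
            ov = _overlap(ep.start, ep.end, w0, w0 + step_length)
            if ov <= 0:
                continue
            key = (w, ep.pair)
            cum[key] = cum.get(key, 0.0) + ov
            longest[key] = max(longest.get(key, 0.0), ov)

    measure = longest if require_continuous else cum
    per_window: dict[int, dict[Pair, float]] = {}
    for (w, pair), secs in cum.items():
        if measure[(w, pair)] >= duration_threshold:
            per_window.setdefault(w, {})[pair] = secs

    snaps = []
    for w in range(n_windows):
        w0 = anchor + w * step_length
        valid = per_window.get(w, {})
        snaps.append(
            Snapshot.from_contacts(w, (w0, w0 + step_length), valid.keys(), valid)
        )
    return SnapshotSeries(
        snapshots=snaps,
        population=frozenset(pop),
        step_length=step_length,
        duration_threshold=duration_threshold,
        directed=record_set.directed,
        start=anchor,
    )
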