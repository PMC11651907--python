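"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

from tempnet import ContactRecord, ContactRecordSet, Snapshot, SnapshotSeries
from tempnet.generate import sample_simple_graph


def snap(index: int, contacts, step: int = 100) -> Snapshot:
    """Snapshot with unit windows from a bare contact collection."""
    window = (index * step, (index + 1) * step)
    return Snapshot.from_contacts(index, window, contacts)


def series_of(contact_sets, population=None, step: int = 100) -> SnapshotSeries:
    snaps = [snap(i, c, step) for i, c in enumerate(contact_sets)]
    pop = set(population) if population is not None else set()
    for s in snaps:
        pop |= s.nodes()
    return SnapshotSeries(
        snapshots=snaps,
        population=frozenset(pop),
        step_length=step,
        duration_threshold=step,
        directed=False,
    )


def record_set(triples, directed=False, resolution=20) -> ContactRecordSet:
    records = []
    for t, i, j in triples:
        if not directed and i > j:
            i, j = j, i
        records.append(ContactRecord(t, i, j))
    return ContactRecordSet(records=records, directed=directed, resolution=resolution)


def mc_rewired_retention(
    edges_t: set, degrees_t1: np.ndarray, n: int, rng: np.random.Generator,
    draws: int = 10_000,
) -> tuple[float, float]:
    """Monte-Carlo mean retained contacts per individual, with its standard error.

    Each draw permutes the step-t+1 degree sequence across individuals
    (degree independence between steps) and samples a uniform simple
    graph realising it; retained contacts are the edges shared with the
    step-t graph.
    """
    samples = np.empty(draws)
    for d in range(draws):
        perm_degrees = rng.permutation(degrees_t1)
        g = sample_simple_graph(perm_degrees, rng, exact=True)
        samples[d] = 2 * len(edges_t & g) / n
    return float(samples.mean()), float(samples.std(ddof=1) / np.sqrt(draws))


def int_edges_to_snapshot(index: int, edges, n: int) -> Snapshot:
    names = [f"n{i:03d}" for i in range(n)]
    return snap(index, {(names[a], names[b]) for a, b in edges})
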