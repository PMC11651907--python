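"""The retention index: contact persistence relative to two null models.

A *retained contact* is a pair in contact in two consecutive time steps.
The mean number of retained contacts per individual in the observed
network, r̄_temp, is located between two analytic extremes computed from
the same degree distributions:

* **static null** — contacts never change, so every contact of step t is
  retained and the expected retained count per individual is the mean
  degree at step t (the retained-contact distribution *is* the degree
  distribution);
* **fully dynamic null** — each individual's contacts are redrawn at
  random every step while preserving the degree distribution.  The
  retained count of an individual with degrees (k_t, k_{t+1}) is modelled
  as Binomial(min(k_t, k_{t+1}), k_{t+1}/(N-1)), mixed over the empirical
  degree distributions of the two steps.

The **retention index**

    r̄ = (r̄_temp − r̄_dyna) / (r̄_stat − r̄_dyna)

standardises where a network sits on the static↔dynamic continuum: values
near 1 mean contacts are almost fully predictable from one step to the
next, values near 0 mean the network re-randomises every step.  The index
is reported unclamped; sampling noise can push individual step pairs
slightly outside [0, 1].

Degree distributions are taken over the *whole* population N, so
individuals with no contact in a step contribute zeros to every average.
By default the dynamic null mixes the two steps' marginal degree
distributions (degree independence across steps); ``joint=True`` instead
uses each individual's own (k_t, k_{t+1}) pair, matching a rewiring that
preserves per-node degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .snapshots import Pair, Snapshot, SnapshotSeries

__all__ = [
    "RetentionResult",
    "RetentionSummary",
    "retained_contacts",
    "static_null_mean",
    "dynamic_null_mean",
    "dynamic_null_distribution",
    "retention_index",
    "retained_type_breakdown",
    "summarize_retention",
]


@dataclass
class RetentionResult:
    """Retention metrics for one consecutive step pair (t, t+1)."""

    step_pair: tuple[int, int]
    r_bar_temp: float
    r_bar_stat: float
    r_bar_dyna: float
    index: float  # NaN when undefined
    defined: bool
    retained_pairs: frozenset[Pair]
    per_node_retained: dict[str, int] = field(repr=False, default_factory=dict)


@dataclass
class RetentionSummary:
    """Per-step results plus the median/IQR headline numbers."""

    per_step: list[RetentionResult]
    median_index: float
    iqr_index: tuple[float, float]
    type_breakdown: list[dict[str, float]] | None = None

    @property
    def indices(self) -> np.ndarray:
        return np.array([r.index for r in self.per_step if r.defined])


def _check_consecutive(snap_t: Snapshot, snap_t1: Snapshot) -> None:
    if snap_t1.index != snap_t.index + 1:
        raise ValueError(
            f"snapshots {snap_t.index} and {snap_t1.index} are not consecutive"
        )


def retained_contacts(
    snap_t: Snapshot, snap_t1: Snapshot
) -> tuple[dict[str, int], frozenset[Pair]]:
    """Per-node retained-contact counts and the retained pair set.

    A pair is retained iff it is a valid contact in both snapshots.  Each
    node's count is bounded by min(k_t, k_{t+1}).
    """
    _check_consecutive(snap_t, snap_t1)
    retained = snap_t.contacts & snap_t1.contacts
    counts: dict[str, int] = {}
    for u, v in retained:
        counts[u] = counts.get(u, 0) + 1
        counts[v] = counts.get(v, 0) + 1
    return counts, frozenset(retained)


def _degree_probs(snap: Snapshot, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Empirical degree distribution over all N individuals (support, probs)."""
    degs = np.zeros(n, dtype=int)
    active = list(snap.degree.values())
    degs[: len(active)] = active
    support, counts = np.unique(degs, return_counts=True)
    return support, counts / n


def static_null_mean(snap_t: Snapshot, n: int) -> float:
    """Mean retained contacts under the static null: the mean degree at t.

    Zero-degree individuals are included in the average over N.
    """
    if n < 2:
        raise ValueError("need a population of at least 2")
    return sum(snap_t.degree.values()) / n


def _joint_degree_pairs(
    snap_t: Snapshot, snap_t1: Snapshot, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node (k_t, k_t1) pairs over all N individuals, with weights 1/N."""
    nodes = snap_t.nodes() | snap_t1.nodes()
    kt = [snap_t.degree_of(v) for v in nodes]
    kt1 = [snap_t1.degree_of(v) for v in nodes]
    n_zero = n - len(nodes)
    if n_zero < 0:
        raise ValueError("population size n smaller than the number of active nodes")
    kt.append(0)
    kt1.append(0)
    w = np.full(len(kt), 1.0 / n)
    w[-1] = n_zero / n
    return np.array(kt), np.array(kt1), w


def _mixture_terms(
    snap_t: Snapshot, snap_t1: Snapshot, n: int, joint: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(k_t, k_t1, weight) triples of the null-model degree mixture."""
    if joint:
        return _joint_degree_pairs(snap_t, snap_t1, n)
    kt_sup, kt_p = _degree_probs(snap_t, n)
    kt1_sup, kt1_p = _degree_probs(snap_t1, n)
    kt = np.repeat(kt_sup, len(kt1_sup))
    kt1 = np.tile(kt1_sup, len(kt_sup))
    w = np.repeat(kt_p, len(kt1_sup)) * np.tile(kt1_p, len(kt_sup))
    return kt, kt1, w


def dynamic_null_mean(
    snap_t: Snapshot, snap_t1: Snapshot, n: int, joint: bool = False
) -> float:
    """Expected retained contacts per individual under the dynamic null.

    Sum over the degree mixture of min(k_t, k_{t+1}) * k_{t+1}/(N-1): the
    binomial mean with the trial count capped at the smaller degree and
    per-contact retention probability k_{t+1}/(N-1).
    """
    if n < 2:
        raise ValueError("need a population of at least 2")
    kt, kt1, w = _mixture_terms(snap_t, snap_t1, n, joint)
    return float(np.sum(w * np.minimum(kt, kt1) * kt1 / (n - 1)))


def dynamic_null_distribution(
    snap_t: Snapshot,
    snap_t1: Snapshot,
    n: int,
    p: float | None = None,
    joint: bool = False,
) -> np.ndarray:
    """Full PMF of the per-individual retained-contact count under the null.

    Entry r of the returned array is P(r retained contacts),
    r = 0 .. max min(k_t, k_{t+1}).  By default the per-contact retention
    probability is the dynamic-null value k_{t+1}/(N-1); passing ``p``
    forces a fixed probability instead (``p=1`` with ``joint=True`` on a
    static pair degenerates to the step-t degree distribution, the static
    null).  The mean of the PMF equals :func:`dynamic_null_mean` exactly
    when ``p`` is not forced.
    """
    if n < 2:
        raise ValueError("need a population of at least 2")
    kt, kt1, w = _mixture_terms(snap_t, snap_t1, n, joint)
    kmin = np.minimum(kt, kt1)
    probs = np.full(len(kt), p, dtype=float) if p is not None else kt1 / (n - 1)
    rmax = int(kmin.max(initial=0))
    pmf = np.zeros(rmax + 1)
    r = np.arange(rmax + 1)
    for k_i, p_i, w_i in zip(kmin, probs, w):
        if w_i == 0:
            continue
        pmf += w_i * stats.binom.pmf(r, k_i, p_i)
    return pmf


def retention_index(
    snap_t: Snapshot, snap_t1: Snapshot, n: int, joint: bool = False
) -> RetentionResult:
    """Locate one step pair on the static↔dynamic continuum.

    The result is flagged undefined (index NaN) when the static and
    dynamic null means coincide — empty steps, or a complete graph where
    random rewiring cannot lose any contact — and such pairs are excluded
    from summaries.
    """
    _check_consecutive(snap_t, snap_t1)
    counts, retained = retained_contacts(snap_t, snap_t1)
    r_temp = sum(counts.values()) / n
    r_stat = static_null_mean(snap_t, n)
    r_dyna = dynamic_null_mean(snap_t, snap_t1, n, joint=joint)
    denom = r_stat - r_dyna
    defined = denom > 1e-12
    index = (r_temp - r_dyna) / denom if defined else float("nan")
    return RetentionResult(
        step_pair=(snap_t.index, snap_t1.index),
        r_bar_temp=r_temp,
        r_bar_stat=r_stat,
        r_bar_dyna=r_dyna,
        index=index,
        defined=defined,
        retained_pairs=retained,
        per_node_retained=counts,
    )


def pair_type(
    pair: Pair, attributes: Mapping[str, Mapping[str, str]], attribute: str
) -> str:
    """Label a contact pair from its endpoints' group attribute.

    Same label -> ``same-<attribute>``, different labels ->
    ``different-<attribute>``; any missing or "unknown" label ->
    ``unknown``.
    """
    u, v = pair
    a = attributes.get(u, {}).get(attribute)
    b = attributes.get(v, {}).get(attribute)
    if a is None or b is None or "unknown" in (a, b):
        return "unknown"
    return f"same-{attribute}" if a == b else f"different-{attribute}"


def retained_type_breakdown(
    result: RetentionResult,
    attributes: Mapping[str, Mapping[str, str]],
    attribute: str,
) -> dict[str, float]:
    """Proportion of retained contacts by contact type for one step pair.

    Returns an empty map when nothing was retained; otherwise proportions
    sum to 1.
    """
    if not result.retained_pairs:
        return {}
    counts: dict[str, int] = {}
    for pair in result.retained_pairs:
        label = pair_type(pair, attributes, attribute)
        counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    return {label: c / total for label, c in counts.items()}


def summarize_retention(
    series: SnapshotSeries,
    attributes: Mapping[str, Mapping[str, str]] | None = None,
    attribute: str | None = None,
    joint: bool = False,
) -> RetentionSummary:
    """Retention index for every consecutive step pair, with median and IQR.

    Quantiles use linear interpolation.  Raises ``ValueError`` when fewer
    than two step pairs have a defined index (nothing meaningful to
    summarise).
    """
    if series.n_steps < 2:
        raise ValueError("need at least two snapshots to assess retention")
    results = [
        retention_index(a, b, series.n, joint=joint) for a, b in series.step_pairs()
    ]
    indices = [r.index for r in results if r.defined]
    if len(indices) < 2:
        raise ValueError(
            f"only {len(indices)} step pair(s) have a defined retention index; "
            "need at least 2 to summarise"
        )
    q1, med, q3 = np.quantile(indices, [0.25, 0.5, 0.75])
    breakdown = None
    if attributes is not None:
        if attribute is None:
            raise ValueError("an attribute name is required for the type breakdown")
        breakdown = [
            retained_type_breakdown(r, attributes, attribute) for r in results
        ]
    return RetentionSummary(
        per_step=results,
        median_index=float(med),
        iqr_index=(float(q1), float(q3)),
        type_breakdown=breakdown,
    )
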