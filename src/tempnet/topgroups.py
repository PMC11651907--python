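"""Top-80% contributors: superspreaders versus superspreading events.

In each time step the *top group* is the smallest set of individuals
accounting for at least 80% of that step's contacts (or contact
duration).  Tracking how often each individual lands in the top group
over S steps separates two very different epidemiological profiles:

* **superspreaders** — individuals in the top group for at least half of
  the steps: persistently highly connected, so targetable in advance;
* **superspreading-event drivers** — individuals in the top group for
  less than a quarter of the steps: usually weakly connected, but
  occasionally central, so essentially unpredictable.

The persistence curve rho_s is the cumulative proportion of the
population that was in the top group for *at most* s of S steps; it is
non-decreasing and reaches 1 at s = S.  For a fully dynamic network
whose per-step top group holds a fraction p80 of the population, the
proportion still identified after s independent steps is approximately
p80**s, which serves as the dynamic reference curve (p80 = 0.8 for a
homogeneous network, 0.5 for the overdispersed reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .snapshots import Snapshot, SnapshotSeries

__all__ = [
    "TopGroupTrajectory",
    "PersistenceCurve",
    "top_group",
    "trajectory",
    "persistence_curve",
    "classify",
    "dynamic_reference_curve",
]


@dataclass
class TopGroupTrajectory:
    """Per-node counts of time steps spent in the top-80% group."""

    counts: dict[str, int]  # every population member, zeros included
    n_steps: int  # S
    weight_mode: str
    threshold: float
    p80_per_step: list[float]

    @property
    def n(self) -> int:
        return len(self.counts)


@dataclass
class PersistenceCurve:
    """rho_s for s = 0..S plus the classification cut-offs."""

    rho: np.ndarray  # length S + 1
    n_steps: int
    superspreader_min: float  # count threshold (>=), default S/2
    sse_max: float  # count threshold (<), default S/4


def top_group(
    snapshot: Snapshot,
    weight_mode: str = "contacts",
    threshold: float = 0.8,
    rng: np.random.Generator | None = None,
) -> set[str]:
    """Smallest node set covering ``threshold`` of the step's total weight.

    Weight is the per-node contact count (``"contacts"``) or total
    in-step contact seconds (``"duration"``).  Nodes are taken in order
    of decreasing weight until the running sum first reaches the
    threshold share.  Ties are broken by node identifier ascending
    (deterministic, the default) or uniformly at random when an ``rng``
    is supplied — relevant for homogeneous networks, where large blocks
    of equal weights make the cut otherwise fall on the same individuals
    every step.  An empty snapshot yields an empty set.
    """
    if weight_mode not in ("contacts", "duration"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if weight_mode == "contacts":
        weights: dict[str, float] = dict(snapshot.degree)
    else:
        weights = {}
        for (u, v), secs in snapshot.pair_seconds.items():
            weights[u] = weights.get(u, 0.0) + secs
            weights[v] = weights.get(v, 0.0) + secs
    total = sum(weights.values())
    if total <= 0:
        return set()
    if rng is None:
        order = sorted(weights, key=lambda v: (-weights[v], v))
    else:
        jitter = {v: rng.random() for v in weights}
        order = sorted(weights, key=lambda v: (-weights[v], jitter[v]))
    target = threshold * total
    group: set[str] = set()
    running = 0.0
    for node in order:
        group.add(node)
        running += weights[node]
        if running >= target:
            break
    return group


def trajectory(
    series: SnapshotSeries,
    weight_mode: str = "contacts",
    threshold: float = 0.8,
    skip_empty_steps: bool = False,
    rng: np.random.Generator | None = None,
) -> TopGroupTrajectory:
    """Count, per individual, the steps spent in the top group.

    Steps with no contacts contribute no memberships but still count
    toward S unless ``skip_empty_steps`` is set.  ``rng`` switches the
    per-step top-group tie-breaking from deterministic to random.
    """
    if series.n_steps == 0:
        raise ValueError("empty series: no time steps to analyse")
    counts = {v: 0 for v in series.population}
    p80s: list[float] = []
    n_steps = 0
    for snap in series:
        if skip_empty_steps and not snap.contacts:
            continue
        n_steps += 1
        group = top_group(snap, weight_mode, threshold, rng=rng)
        for v in group:
            counts[v] += 1
        p80s.append(len(group) / series.n)
    if n_steps == 0:
        raise ValueError("all steps empty and skip_empty_steps set")
    return TopGroupTrajectory(counts, n_steps, weight_mode, threshold, p80s)


def persistence_curve(
    traj: TopGroupTrajectory,
    superspreader_min: float | None = None,
    sse_max: float | None = None,
) -> PersistenceCurve:
    """rho_s: proportion of the population in the top group <= s times.

    rho is non-decreasing with rho_S = 1 by construction; rho_0 is the
    fraction never identified.
    """
    s_total = traj.n_steps
    n = traj.n
    if n == 0:
        raise ValueError("empty population")
    hist = np.bincount(list(traj.counts.values()), minlength=s_total + 1)
    rho = np.cumsum(hist) / n
    return PersistenceCurve(
        rho=rho,
        n_steps=s_total,
        superspreader_min=(s_total / 2 if superspreader_min is None else superspreader_min),
        sse_max=(s_total / 4 if sse_max is None else sse_max),
    )


def classify(
    traj: TopGroupTrajectory, ss_frac: float = 0.5, sse_frac: float = 0.25
) -> dict[str, set[str]]:
    """Split the population by top-group persistence.

    ``superspreaders``: in the top group for at least ``ss_frac`` of the
    S steps; ``sse_drivers``: for less than ``sse_frac`` of them;
    ``neither``: in between.  Thresholds are applied unrounded.  With
    fewer than 4 steps the two cut-offs are not meaningfully distinct; a
    warning is emitted but the classification is still returned.
    """
    if not 0 < sse_frac <= ss_frac <= 1:
        raise ValueError("need 0 < sse_frac <= ss_frac <= 1")
    s_total = traj.n_steps
    if s_total < 4:
        warnings.warn(
            f"only {s_total} time steps: the {ss_frac:g}/{sse_frac:g} cut-offs "
            "barely differ and the classification is weakly informative",
            stacklevel=2,
        )
    ss_min = ss_frac * s_total
    sse_lim = sse_frac * s_total
    out: dict[str, set[str]] = {"superspreaders": set(), "sse_drivers": set(), "neither": set()}
    for node, c in traj.counts.items():
        if c >= ss_min:
            out["superspreaders"].add(node)
        elif c < sse_lim:
            out["sse_drivers"].add(node)
        else:
            out["neither"].add(node)
    return out


def dynamic_reference_curve(p80: float, n_steps: int) -> np.ndarray:
    """Reference persistence of a fully dynamic network: p80**s, s = 0..S.

    Under per-step independence, the chance an individual is in the top
    group in s particular steps decays geometrically with ratio p80.
    """
    if not 0 < p80 <= 1:
        raise ValueError("p80 must be in (0, 1]")
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    return p80 ** np.arange(n_steps + 1, dtype=float)
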