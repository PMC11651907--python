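"""Synthetic temporal contact networks spanning the static↔dynamic continuum.

Every metric in this package is exercised against generated networks with
known ground truth rather than against (non-redistributable) sensor
datasets.  Three temporal regimes are produced from one degree law:

* **static** — one configuration-model graph repeated every step (edges
  perfectly retained);
* **fully dynamic** — per-node target degrees fixed once, an independent
  simple-graph realisation of that degree sequence each step (retention
  at chance level);
* **partial retention** — each edge survives to the next step with
  probability q, freed stubs are rewired at random; q interpolates the
  two extremes and is the ground truth a retention analysis should
  recover.

Degree laws cover constant (homogeneous), Poisson and negative-binomial
(overdispersed) sequences; overdispersion is parameterised by the
negative-binomial dispersion and can be calibrated so a target fraction
of the population (p80) carries 80% of contacts in a step.  A separate
multi-day generator emits raw timestamped records in which a base set of
pairs recurs across days with probability rho, the ground truth for the
repeated-contact ledger.

All graphs are simple (no self-loops or multi-edges).  Sampling is
stub-matching with re-shuffles and a bounded edge-swap repair; an exact
rejection mode (uniform over simple graphs with the given degrees) is
available for small oracle computations.  Every generator is fully
reproducible from its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

from .records import ContactRecord, ContactRecordSet
from .snapshots import Pair, Snapshot, SnapshotSeries
from .topgroups import top_group

__all__ = [
    "DegreeLaw",
    "DayStructure",
    "GeneratorConfig",
    "GenerationError",
    "sample_degree_sequence",
    "sample_simple_graph",
    "generate_static",
    "generate_fully_dynamic",
    "generate_partial_retention",
    "generate_multiday",
    "calibrate_p80",
    "calibrate_dispersion",
    "assign_groups",
    "series_to_records",
]


class GenerationError(RuntimeError):
    """Raised when a feasible simple graph could not be assembled."""


@dataclass(frozen=True)
class DegreeLaw:
    """Per-step target degree distribution.

    ``constant`` gives every node the same degree (homogeneous network);
    ``poisson`` mild, ``negative_binomial`` tunable overdispersion
    (smaller dispersion = heavier tail = smaller p80).
    """

    kind: str
    mean: float
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "poisson", "negative_binomial"):
            raise ValueError(f"unknown degree law {self.kind!r}")
        if self.mean < 0:
            raise ValueError("mean degree must be non-negative")
        if self.kind == "negative_binomial":
            if self.dispersion is None or self.dispersion <= 0:
                raise ValueError("negative_binomial needs a positive dispersion")

    @staticmethod
    def constant(k: int) -> "DegreeLaw":
        return DegreeLaw("constant", float(k))

    @staticmethod
    def poisson(mu: float) -> "DegreeLaw":
        return DegreeLaw("poisson", mu)

    @staticmethod
    def negative_binomial(mu: float, dispersion: float) -> "DegreeLaw":
        return DegreeLaw("negative_binomial", mu, dispersion)


@dataclass(frozen=True)
class DayStructure:
    """Multi-day record layout: pairs per day and the daily repeat probability."""

    n_days: int
    pairs_per_day: int
    repeat_prob: float
    day_length: int = 86_400

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.pairs_per_day < 1:
            raise ValueError("need at least one day and one pair per day")
        if not 0 <= self.repeat_prob <= 1:
            raise ValueError("repeat_prob must be a probability")


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic temporal network.

    ``retention_q`` is the per-edge survival probability used by the
    partial-retention generator (1 = static, 0 = fully re-randomised).
    ``n_groups`` optionally partitions the population into equally sized
    groups used as contact-type labels.  ``days`` switches on the
    multi-day raw-record generator.
    """

    n: int
    t: int
    degree_law: DegreeLaw
    retention_q: float = 1.0
    seed: int | None = None
    step_length: int = 300
    resolution: int = 300
    n_groups: int | None = None
    days: DayStructure | None = None
    shuffle_degrees: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population size must be at least 2")
        if self.t < 1:
            raise ValueError("need at least one time step")
        if not 0 <= self.retention_q <= 1:
            raise ValueError("retention_q must be a probability")

    def node_names(self) -> list[str]:
        width = len(str(self.n - 1))
        return [f"n{i:0{width}d}" for i in range(self.n)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# degree sequences and simple-graph sampling


def _graphical(degrees: np.ndarray) -> bool:
    """Erdős–Gallai test (assumes an even stub sum)."""
    d = np.sort(degrees)[::-1].astype(np.int64)
    n = len(d)
    if n == 0 or d[0] == 0:
        return True
    cum = np.cumsum(d)
    asc = d[::-1]
    asc_cum = np.concatenate([[0], np.cumsum(asc)])
    for k in range(1, n + 1):
        if d[k - 1] < k and k > 1:
            break  # beyond the Durfee square the inequalities hold
        tail = d[k:]
        if tail.size:
            # sum of min(d_i, k) over the tail, via the ascending order
            pos = np.searchsorted(asc[: n - k], k, side="right")
            tail_sum = asc_cum[pos] + k * (n - k - pos)
        else:
            tail_sum = 0
        if cum[k - 1] > k * (k - 1) + tail_sum:
            return False
    return True


def sample_degree_sequence(
    law: DegreeLaw, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a graphical degree sequence from the law.

    Degrees are capped at n-1; an odd stub total is repaired by
    decrementing one randomly chosen positive degree; a non-graphical
    sequence (possible under heavy overdispersion) is projected to a
    graphical one by repeatedly shaving the largest degrees, with the
    number of removed stubs logged.
    """
    if law.kind == "constant":
        k = int(round(law.mean))
        degrees = np.full(n, k, dtype=np.int64)
    elif law.kind == "poisson":
        degrees = rng.poisson(law.mean, size=n)
    else:
        d = law.dispersion
        degrees = rng.negative_binomial(d, d / (d + law.mean), size=n)
    degrees = np.minimum(degrees, n - 1).astype(np.int64)
    if degrees.sum() % 2 == 1:
        positive = np.flatnonzero(degrees > 0)
        if positive.size == 0:
            degrees[rng.integers(n)] = 1
        else:
            degrees[rng.choice(positive)] -= 1
    shaved = 0
    while not _graphical(degrees):
        degrees[int(np.argmax(degrees))] -= 1
        degrees[int(np.argmax(degrees))] -= 1
        shaved += 2
    if shaved:
        logger.debug(
            "degree sequence projected to graphical: removed %d stubs", shaved
        )
    return degrees


def _canon(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def _force_edge(
    a: int, b: int, edges: set[tuple[int, int]], rng: np.random.Generator
) -> None:
    """Place the stub pair (a, b) by a degree-preserving double-edge swap.

    Scans the existing edges in random order, both orientations, for a
    partner (x, y) such that replacing it with (a, x) and (b, y) keeps
    the graph simple.
    """
    if a != b and _canon(a, b) not in edges:
        edges.add(_canon(a, b))
        return
    edge_list = list(edges)
    rng.shuffle(edge_list)
    for ex, ey in edge_list:
        for x, y in ((ex, ey), (ey, ex)):
            if x in (a, b) or y in (a, b):
                continue
            e1, e2 = _canon(a, x), _canon(b, y)
            if e1 == e2 or e1 in edges or e2 in edges:
                continue
            edges.remove(_canon(ex, ey))
            edges.add(e1)
            edges.add(e2)
            return
    raise GenerationError(f"no degree-preserving swap can place stub pair ({a}, {b})")


def _match_stubs(
    existing: set[tuple[int, int]],
    stubs: Sequence[int],
    rng: np.random.Generator,
    max_shuffles: int = 50,
) -> set[tuple[int, int]]:
    """Pair stubs into simple edges avoiding ``existing``; repair leftovers."""
    edges = set(existing)
    pool = list(stubs)
    if len(pool) % 2:
        raise GenerationError("odd number of stubs")
    for _ in range(max_shuffles):
        if not pool:
            return edges
        rng.shuffle(pool)
        leftover: list[int] = []
        for a, b in zip(pool[::2], pool[1::2]):
            if a == b or _canon(a, b) in edges:
                leftover.append(a)
                leftover.append(b)
            else:
                edges.add(_canon(a, b))
        pool = leftover
    order = rng.permutation(len(pool) // 2)
    for i in order:
        _force_edge(pool[2 * i], pool[2 * i + 1], edges, rng)
    return edges


def _havel_hakimi_randomised(
    degrees: np.ndarray, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Havel–Hakimi construction followed by random double-edge swaps.

    Succeeds for every graphical sequence; the swap pass (about five per
    edge) decorrelates the deterministic construction.
    """
    remaining = [(int(d), i) for i, d in enumerate(degrees) if d > 0]
    edges: set[tuple[int, int]] = set()
    while remaining:
        remaining.sort(reverse=True)
        d, v = remaining.pop(0)
        if d > len(remaining):
            raise GenerationError("degree sequence is not graphical")
        targets = remaining[:d]
        for k, (dt, u) in enumerate(targets):
            edges.add(_canon(v, u))
            targets[k] = (dt - 1, u)
        remaining[:d] = [t for t in targets if t[0] > 0]
    edge_list = list(edges)
    for _ in range(5 * len(edge_list)):
        i, j = rng.integers(len(edge_list), size=2)
        (a, b), (c, d2) = edge_list[i], edge_list[j]
        if rng.random() < 0.5:
            c, d2 = d2, c
        if len({a, b, c, d2}) < 4:
            continue
        e1, e2 = _canon(a, c), _canon(b, d2)
        if e1 in edges or e2 in edges:
            continue
        edges.discard(_canon(a, b))
        edges.discard(_canon(c, d2))
        edges.add(e1)
        edges.add(e2)
        edge_list[i], edge_list[j] = e1, e2
    return edges


def sample_simple_graph(
    degrees: Sequence[int],
    rng: np.random.Generator,
    exact: bool = False,
    max_tries: int = 20_000,
) -> set[tuple[int, int]]:
    """Simple graph on nodes 0..n-1 realising ``degrees``.

    Default mode: stub matching with re-shuffles of colliding stubs and a
    bounded edge-swap repair (fast, slightly non-uniform).  ``exact``
    mode resamples the whole configuration-model matching until it is
    simple, which yields the uniform distribution over simple graphs with
    the given degree sequence — use for small oracle graphs only.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    n = len(degrees)
    if (degrees < 0).any() or (degrees > n - 1).any():
        raise GenerationError("degrees must lie in [0, n-1]")
    stubs = np.repeat(np.arange(n), degrees)
    if stubs.size % 2:
        raise GenerationError("degree sequence has an odd stub sum")
    if not exact:
        for attempt in range(5):
            try:
                return _match_stubs(set(), stubs, rng)
            except GenerationError as exc:
                logger.debug("stub matching failed (attempt %d): %s", attempt + 1, exc)
        # guaranteed construction for graphical sequences, randomised by swaps
        return _havel_hakimi_randomised(degrees, rng)
    for _ in range(max_tries):
        perm = rng.permutation(stubs)
        a, b = perm[::2], perm[1::2]
        if (a == b).any():
            continue
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keys = lo * n + hi
        if len(np.unique(keys)) != len(keys):
            continue
        return {(int(x), int(y)) for x, y in zip(lo, hi)}
    raise GenerationError(
        f"no simple realisation found in {max_tries} rejection draws"
    )


# ---------------------------------------------------------------------------
# temporal series generators


def _series_from_edge_sets(
    cfg: GeneratorConfig, edge_sets: list[set[tuple[int, int]]]
) -> SnapshotSeries:
    names = cfg.node_names()
    length = cfg.step_length
    snaps = []
    for i, edges in enumerate(edge_sets):
        contacts = {(names[a], names[b]) for a, b in edges}
        snaps.append(
            Snapshot.from_contacts(i, (i * length, (i + 1) * length), contacts)
        )
    return SnapshotSeries(
        snapshots=snaps,
        population=frozenset(names),
        step_length=length,
        duration_threshold=length,
        directed=False,
    )


def generate_static(cfg: GeneratorConfig) -> SnapshotSeries:
    """Fully static network: one realised graph repeated for all T steps."""
    rng = cfg.rng()
    degrees = sample_degree_sequence(cfg.degree_law, cfg.n, rng)
    graph = sample_simple_graph(degrees, rng)
    return _series_from_edge_sets(cfg, [graph] * cfg.t)


def generate_fully_dynamic(cfg: GeneratorConfig) -> SnapshotSeries:
    """Fully dynamic network: per-node degrees fixed, contacts rewired each step.

    The degree sequence is drawn once and every step is an independent
    simple-graph realisation of it, so the step-level degree distribution
    is preserved while all structure decorrelates between steps.  By
    default each individual keeps its own degree across steps; with
    ``cfg.shuffle_degrees`` the sequence is additionally permuted across
    individuals every step, so *who* is highly connected also
    re-randomises (the regime behind the geometric persistence
    reference).
    """
    rng = cfg.rng()
    degrees = sample_degree_sequence(cfg.degree_law, cfg.n, rng)
    edge_sets = []
    for _ in range(cfg.t):
        step_degrees = rng.permutation(degrees) if cfg.shuffle_degrees else degrees
        edge_sets.append(sample_simple_graph(step_degrees, rng))
    return _series_from_edge_sets(cfg, edge_sets)


def generate_partial_retention(cfg: GeneratorConfig) -> SnapshotSeries:
    """Interpolate the continuum: edges survive with probability q per step.

    Step 1 is a static draw; at each subsequent step every edge is kept
    independently with probability ``cfg.retention_q`` and the stubs of
    dropped edges are rewired at random (avoiding the kept edges), so
    per-node degrees are preserved exactly.  q = 1 reproduces the static
    generator's behaviour, q = 0 an edge-resampled dynamic network.
    """
    rng = cfg.rng()
    q = cfg.retention_q
    degrees = sample_degree_sequence(cfg.degree_law, cfg.n, rng)
    current = sample_simple_graph(degrees, rng)
    edge_sets = [current]
    for _ in range(cfg.t - 1):
        if q >= 1.0:
            edge_sets.append(current)
            continue
        for attempt in range(20):
            kept: set[tuple[int, int]] = set()
            stubs: list[int] = []
            for e in current:
                if rng.random() < q:
                    kept.add(e)
                else:
                    stubs.extend(e)
            try:
                current = _match_stubs(kept, stubs, rng)
                break
            except GenerationError as exc:
                # rare dead end (e.g. a freed hub already adjacent to every
                # active node); redraw the survival mask and try again
                logger.debug("rewiring retry %d: %s", attempt + 1, exc)
        else:
            raise GenerationError(
                "could not rewire freed stubs after 20 survival redraws"
            )
        edge_sets.append(current)
    return _series_from_edge_sets(cfg, edge_sets)


# ---------------------------------------------------------------------------
# overdispersion calibration


def calibrate_p80(
    degree_law: DegreeLaw,
    n: int,
    seed: int | None = None,
    replicates: int = 20,
    threshold: float = 0.8,
) -> float:
    """Realised top-group fraction (p80) of single snapshots from a law.

    Averages, over ``replicates`` independently generated snapshots, the
    fraction of the population in the smallest set carrying ``threshold``
    of the contacts.
    """
    rng = np.random.default_rng(seed)
    names = [f"n{i}" for i in range(n)]
    fracs = []
    for _ in range(replicates):
        degrees = sample_degree_sequence(degree_law, n, rng)
        edges = sample_simple_graph(degrees, rng)
        snap = Snapshot.from_contacts(
            0, (0, 1), {(names[a], names[b]) for a, b in edges}
        )
        fracs.append(len(top_group(snap, "contacts", threshold)) / n)
    return float(np.mean(fracs))


def calibrate_dispersion(
    mean: float,
    p80_target: float,
    n: int,
    seed: int | None = None,
    tol: float = 0.02,
    replicates: int = 20,
    max_iter: int = 40,
) -> float:
    """Negative-binomial dispersion whose snapshots realise a target p80.

    p80 increases monotonically with dispersion (more homogeneous
    degrees); the value is found by bisection on log-dispersion using
    common random numbers.  Raises ``GenerationError`` when the target is
    outside the achievable range for the given mean and population.
    """

    def achieved(log_d: float) -> float:
        law = DegreeLaw.negative_binomial(mean, 10.0 ** log_d)
        return calibrate_p80(law, n, seed=seed, replicates=replicates)

    lo, hi = -2.0, 3.0
    p_lo, p_hi = achieved(lo), achieved(hi)
    if not p_lo - tol <= p80_target <= p_hi + tol:
        raise GenerationError(
            f"p80 target {p80_target:.3f} outside achievable range "
            f"[{p_lo:.3f}, {p_hi:.3f}] for mean degree {mean}"
        )
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        p_mid = achieved(mid)
        if abs(p_mid - p80_target) <= tol:
            return 10.0 ** mid
        if p_mid < p80_target:
            lo = mid
        else:
            hi = mid
    return 10.0 ** ((lo + hi) / 2)


# ---------------------------------------------------------------------------
# contact types, multi-day records, record emission


def assign_groups(
    nodes: Sequence[str], n_groups: int, rng: np.random.Generator,
    attribute: str = "group",
) -> dict[str, dict[str, str]]:
    """Randomly partition nodes into ``n_groups`` equally likely labels."""
    if n_groups < 1:
        raise ValueError("need at least one group")
    labels = rng.integers(n_groups, size=len(nodes))
    return {v: {attribute: f"g{g}"} for v, g in zip(nodes, labels)}


def _sample_new_pairs(
    n: int, count: int, used: set[tuple[int, int]], rng: np.random.Generator
) -> list[tuple[int, int]]:
    max_pairs = n * (n - 1) // 2
    if len(used) + count > max_pairs:
        raise GenerationError("not enough unused pairs in the population")
    out: list[tuple[int, int]] = []
    taken = set(used)
    while len(out) < count:
        a, b = rng.integers(n), rng.integers(n)
        if a == b:
            continue
        e = _canon(int(a), int(b))
        if e in taken:
            continue
        taken.add(e)
        out.append(e)
    return out


def generate_multiday(cfg: GeneratorConfig) -> ContactRecordSet:
    """Raw multi-day records with controllable daily pair repetition.

    Day 1 carries a base set of ``pairs_per_day`` random pairs.  On each
    later day every base pair recurs independently with probability
    ``repeat_prob`` and previously unseen pairs are drawn to keep the
    daily unique-pair count constant.  Each selected pair is written as a
    run of consecutive records long enough to pass any validity threshold
    up to three recording intervals.
    """
    if cfg.days is None:
        raise ValueError("GeneratorConfig.days must be set for multiday generation")
    day = cfg.days
    rng = cfg.rng()
    names = cfg.node_names()
    res = cfg.resolution
    ticks = 3  # records per episode -> episode duration 3 * resolution
    if ticks * res > day.day_length:
        raise GenerationError("day_length too short for one contact episode")

    base = _sample_new_pairs(cfg.n, day.pairs_per_day, set(), rng)
    used: set[tuple[int, int]] = set(base)
    records: list[ContactRecord] = []

    def emit(pairs: Iterable[tuple[int, int]], d: int) -> None:
        start = (d - 1) * day.day_length
        for a, b in pairs:
            u, v = sorted((names[a], names[b]))
            for k in range(ticks):
                records.append(ContactRecord(start + k * res, u, v))

    emit(base, 1)
    for d in range(2, day.n_days + 1):
        repeats = [e for e in base if rng.random() < day.repeat_prob]
        fresh = _sample_new_pairs(
            cfg.n, day.pairs_per_day - len(repeats), used, rng
        )
        used.update(fresh)
        emit(repeats + fresh, d)
    return ContactRecordSet(records=records, directed=False, resolution=res)


def series_to_records(
    series: SnapshotSeries, resolution: int | None = None
) -> ContactRecordSet:
    """Serialise a snapshot series back to raw timestamped records.

    Each valid contact is written as a run of records covering its whole
    window, so re-binning with the same step length and any threshold up
    to the step length reproduces the series exactly.
    """
    res = resolution if resolution is not None else series.step_length
    if series.step_length % res != 0:
        raise ValueError("resolution must divide the step length")
    ticks = series.step_length // res
    records = []
    for snap in series:
        w0 = snap.window[0]
        for u, v in snap.contacts:
            if not series.directed and u > v:
                u, v = v, u
            for k in range(ticks):
                records.append(ContactRecord(w0 + k * res, u, v))
    return ContactRecordSet(
        records=records, directed=series.directed, resolution=res
    )
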