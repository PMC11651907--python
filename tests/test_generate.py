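"""Generator contracts: reproducibility, degree preservation, limits."""

import numpy as np
import pytest

from tempnet import (
    DegreeLaw,
    GenerationError,
    GeneratorConfig,
    calibrate_dispersion,
    calibrate_p80,
    generate_fully_dynamic,
    generate_multiday,
    generate_partial_retention,
    generate_static,
    retention_index,
    sample_degree_sequence,
    sample_simple_graph,
    series_to_records,
    build_snapshots,
    write_tij,
    read_tij,
)
from tempnet.generate import _graphical


def degrees_of(edges, n):
    d = np.zeros(n, dtype=int)
    for a, b in edges:
        d[a] += 1
        d[b] += 1
    return d


class TestSimpleGraphSampler:
    @pytest.mark.parametrize("law", [DegreeLaw.constant(4), DegreeLaw.poisson(5),
                                     DegreeLaw.negative_binomial(5, 0.3)])
    def test_realises_degree_sequence_exactly(self, law):
        rng = np.random.default_rng(0)
        for _ in range(5):
            degs = sample_degree_sequence(law, 80, rng)
            edges = sample_simple_graph(degs, rng)
            assert (degrees_of(edges, 80) == degs).all()
            assert all(a != b for a, b in edges)  # simple: no self-loops

    def test_heavily_overdispersed_sequences_made_graphical(self):
        rng = np.random.default_rng(1)
        degs = sample_degree_sequence(DegreeLaw.negative_binomial(5, 0.02), 120, rng)
        assert _graphical(degs)
        edges = sample_simple_graph(degs, rng)
        assert (degrees_of(edges, 120) == degs).all()

    def test_exact_mode_matches_sequence(self):
        rng = np.random.default_rng(2)
        degs = np.array([2, 2, 1, 1, 1, 1])
        edges = sample_simple_graph(degs, rng, exact=True)
        assert (degrees_of(edges, 6) == degs).all()

    def test_infeasible_degrees_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(GenerationError):
            sample_simple_graph([5, 1], rng)


class TestReproducibility:
    @pytest.mark.parametrize("gen", [generate_static, generate_fully_dynamic,
                                     generate_partial_retention])
    def test_same_seed_gives_identical_series(self, gen):
        cfg = dict(n=40, t=5, degree_law=DegreeLaw.poisson(3), retention_q=0.5, seed=9)
        a = gen(GeneratorConfig(**cfg))
        b = gen(GeneratorConfig(**cfg))
        assert [s.contacts for s in a] == [s.contacts for s in b]

    def test_different_seeds_differ(self):
        base = dict(n=40, t=5, degree_law=DegreeLaw.poisson(3))
        a = generate_fully_dynamic(GeneratorConfig(**base, seed=1))
        b = generate_fully_dynamic(GeneratorConfig(**base, seed=2))
        assert [s.contacts for s in a] != [s.contacts for s in b]

    def test_multiday_round_trips_through_tij(self, tmp_path):
        from tempnet import DayStructure

        cfg = GeneratorConfig(
            n=30, t=1, degree_law=DegreeLaw.poisson(3), seed=4, resolution=300,
            days=DayStructure(3, 10, 0.5),
        )
        records = generate_multiday(cfg)
        path = tmp_path / "m.tij"
        write_tij(records, path)
        back = read_tij(path, directed=False, resolution=300)
        assert back.records == records.records


class TestTemporalRegimes:
    def test_static_snapshots_identical(self):
        series = generate_static(GeneratorConfig(n=30, t=6, degree_law=DegreeLaw.poisson(3), seed=5))
        first = series.snapshots[0].contacts
        assert all(s.contacts == first for s in series)

    def test_dynamic_keeps_per_node_degrees_fixed(self):
        series = generate_fully_dynamic(
            GeneratorConfig(n=50, t=5, degree_law=DegreeLaw.poisson(4), seed=6)
        )
        ref = {v: series.snapshots[0].degree_of(v) for v in series.population}
        for s in series:
            assert {v: s.degree_of(v) for v in series.population} == ref

    def test_dynamic_shuffled_degrees_preserve_distribution_not_assignment(self):
        series = generate_fully_dynamic(
            GeneratorConfig(n=60, t=4, degree_law=DegreeLaw.poisson(4), seed=7,
                            shuffle_degrees=True)
        )
        dists = [sorted(s.degree_of(v) for v in series.population) for s in series]
        assert all(d == dists[0] for d in dists)  # same multiset each step
        assignments = [
            tuple(s.degree_of(v) for v in sorted(series.population)) for s in series
        ]
        assert len(set(assignments)) > 1  # but different individuals

    def test_partial_retention_q1_is_static(self):
        series = generate_partial_retention(
            GeneratorConfig(n=40, t=5, degree_law=DegreeLaw.poisson(3), retention_q=1.0, seed=8)
        )
        first = series.snapshots[0].contacts
        assert all(s.contacts == first for s in series)

    def test_partial_retention_preserves_degrees_every_step(self):
        series = generate_partial_retention(
            GeneratorConfig(n=60, t=8, degree_law=DegreeLaw.poisson(4), retention_q=0.4, seed=9)
        )
        ref = {v: series.snapshots[0].degree_of(v) for v in series.population}
        for s in series:
            assert {v: s.degree_of(v) for v in series.population} == ref

    def test_partial_retention_expected_retained_fraction(self):
        """Retained edges per step pair: a fraction q survives by design,
        plus (1 - q) times the chance-level rewiring overlap."""
        n, q, t = 200, 0.5, 40
        series = generate_partial_retention(
            GeneratorConfig(n=n, t=t, degree_law=DegreeLaw.poisson(5), retention_q=q, seed=10)
        )
        fracs, chances = [], []
        for a, b in series.step_pairs():
            res = retention_index(a, b, n)
            m = a.n_contacts
            fracs.append(len(res.retained_pairs) / m)
            # per-edge chance of a rewired edge landing back, from the null
            chances.append(res.r_bar_dyna * n / (2 * m))
        observed = np.mean(fracs)
        expected = q + (1 - q) * np.mean(chances)
        assert observed == pytest.approx(expected, abs=0.03)


class TestCalibration:
    def test_constant_degrees_hit_ceiling_fraction(self):
        assert calibrate_p80(DegreeLaw.constant(4), 100, seed=0) == pytest.approx(0.8)

    def test_overdispersion_lowers_p80(self):
        """Heavier degree tails concentrate contacts: p80 drops from the
        Poisson-like value (~0.64 at mean 5) toward well below 0.5."""
        poisson_like = calibrate_p80(DegreeLaw.negative_binomial(5, 1e3), 200, seed=1)
        assert poisson_like == pytest.approx(
            calibrate_p80(DegreeLaw.poisson(5), 200, seed=1), abs=0.03
        )
        heavy = calibrate_p80(DegreeLaw.negative_binomial(5, 0.3), 200, seed=1)
        assert heavy < 0.4 < poisson_like

    def test_p80_approaches_homogeneous_limit_as_mean_grows(self):
        vals = [calibrate_p80(DegreeLaw.poisson(mu), 200, seed=1) for mu in (5, 15, 40)]
        assert vals == sorted(vals)
        assert 0.6 < vals[0] < vals[-1] < 0.8

    def test_dispersion_calibrated_to_overdispersed_target(self):
        disp = calibrate_dispersion(5, 0.5, 200, seed=2, replicates=10)
        achieved = calibrate_p80(DegreeLaw.negative_binomial(5, disp), 200, seed=3,
                                 replicates=10)
        assert achieved == pytest.approx(0.5, abs=0.04)

    def test_unreachable_target_raises(self):
        # no dispersion makes 90% of a mean-5 population carry 80% of contacts
        with pytest.raises(GenerationError, match="outside achievable"):
            calibrate_dispersion(5, 0.9, 100, seed=4, replicates=5)


class TestSeriesToRecords:
    def test_round_trip_reproduces_snapshots(self):
        series = generate_partial_retention(
            GeneratorConfig(n=30, t=4, degree_law=DegreeLaw.poisson(3), retention_q=0.5,
                            seed=11, step_length=300)
        )
        records = series_to_records(series)
        rebuilt = build_snapshots(records, 300, 300)
        # rebuilt series may be shorter if trailing steps are empty
        assert rebuilt.n_steps <= series.n_steps
        for orig, back in zip(series, rebuilt):
            assert orig.contacts == back.contacts
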