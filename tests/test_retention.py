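"""Retained contacts, the two null models and the retention index."""

import numpy as np
import pytest

from tempnet import (
    DegreeLaw,
    dynamic_null_distribution,
    dynamic_null_mean,
    generate_static,
    GeneratorConfig,
    retained_contacts,
    retained_type_breakdown,
    retention_index,
    static_null_mean,
    summarize_retention,
)
from tempnet.generate import sample_degree_sequence, sample_simple_graph

from util import int_edges_to_snapshot, mc_rewired_retention, series_of, snap


def random_edges(rng, n, mu=2.0):
    return sample_simple_graph(
        sample_degree_sequence(DegreeLaw.poisson(mu), n, rng), rng
    )


class TestRetainedContacts:
    def test_identical_snapshots_retain_everything(self):
        a = snap(0, {("A", "B"), ("C", "D")})
        b = snap(1, {("A", "B"), ("C", "D")})
        counts, pairs = retained_contacts(a, b)
        assert counts == {"A": 1, "B": 1, "C": 1, "D": 1}
        assert pairs == {("A", "B"), ("C", "D")}

    def test_partial_overlap_counts_per_node(self):
        counts, pairs = retained_contacts(
            snap(0, {("A", "B"), ("A", "C")}), snap(1, {("A", "B"), ("C", "D")})
        )
        assert counts == {"A": 1, "B": 1}
        assert pairs == {("A", "B")}

    def test_disjoint_snapshots_retain_nothing(self):
        counts, pairs = retained_contacts(
            snap(0, {("A", "B")}), snap(1, {("C", "D")})
        )
        assert counts == {} and pairs == frozenset()

    def test_non_consecutive_snapshots_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            retained_contacts(snap(0, {("A", "B")}), snap(2, {("A", "B")}))

    def test_retained_bounded_by_both_degrees(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            e1 = random_edges(rng, 10)
            e2 = random_edges(rng, 10)
            a, b = int_edges_to_snapshot(0, e1, 10), int_edges_to_snapshot(1, e2, 10)
            counts, _ = retained_contacts(a, b)
            for v, r in counts.items():
                assert r <= min(a.degree_of(v), b.degree_of(v))


class TestStaticNull:
    def test_mean_degree_over_whole_population(self):
        assert static_null_mean(snap(0, {("A", "B"), ("A", "C")}), 4) == 1.0

    def test_empty_snapshot_gives_zero(self):
        assert static_null_mean(snap(0, set()), 5) == 0.0

    def test_complete_graph_gives_n_minus_one(self):
        nodes = [f"v{i}" for i in range(6)]
        edges = {(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]}
        assert static_null_mean(snap(0, edges), 6) == 5.0


class TestDynamicNull:
    def test_single_edge_closed_form(self):
        # one edge among N=4: only the (1,1) degree pair contributes,
        # min(1,1) * (1/3) * (1/2) * (1/2) = 1/12
        a, b = snap(0, {("A", "B")}), snap(1, {("A", "B")})
        assert dynamic_null_mean(a, b, 4) == pytest.approx(1 / 12)

    def test_empty_future_snapshot_gives_zero(self):
        assert dynamic_null_mean(snap(0, {("A", "B")}), snap(1, set()), 4) == 0.0

    def test_distribution_sums_to_one_with_consistent_mean(self):
        rng = np.random.default_rng(7)
        for joint in (False, True):
            for _ in range(10):
                e1 = random_edges(rng, 9)
                e2 = random_edges(rng, 9)
                a, b = int_edges_to_snapshot(0, e1, 9), int_edges_to_snapshot(1, e2, 9)
                pmf = dynamic_null_distribution(a, b, 9, joint=joint)
                assert pmf.sum() == pytest.approx(1.0)
                mean = float(np.arange(len(pmf)) @ pmf)
                assert mean == pytest.approx(dynamic_null_mean(a, b, 9, joint=joint))

    def test_forced_certain_retention_degenerates_to_degree_distribution(self):
        """With per-contact retention probability forced to 1 on a static
        step pair, the null PMF collapses onto the degree distribution."""
        rng = np.random.default_rng(19)
        for _ in range(10):
            edges = random_edges(rng, 8)
            a = int_edges_to_snapshot(0, edges, 8)
            b = int_edges_to_snapshot(1, edges, 8)
            pmf = dynamic_null_distribution(a, b, 8, p=1.0, joint=True)
            deg_counts = np.bincount(
                [a.degree_of(f"n{i:03d}") for i in range(8)], minlength=len(pmf)
            )
            assert np.allclose(pmf, deg_counts[: len(pmf)] / 8)

    @pytest.mark.parametrize(
        "kind,n",
        [("matching", 8), ("matching", 12), ("regular", 10), ("regular", 12)],
    )
    def test_analytic_mean_matches_rewiring_oracle(self, kind, n):
        """The binomial-mixture mean agrees with brute-force rewiring
        (degree sequence shuffled across individuals, uniform simple
        graph) within 3 standard errors, in the regimes where the
        per-contact retention probability is degree-exact."""
        rng = np.random.default_rng(n + (0 if kind == "matching" else 1))
        if kind == "matching":
            degrees = np.zeros(n, dtype=int)
            degrees[: 2 * (n // 3)] = 1  # a few degree-1 nodes, rest isolated
        else:
            degrees = np.full(n, 3)
        e1 = sample_simple_graph(rng.permutation(degrees), rng, exact=True)
        snap_t = int_edges_to_snapshot(0, e1, n)
        snap_t1 = int_edges_to_snapshot(1, sample_simple_graph(degrees, rng, exact=True), n)
        analytic = dynamic_null_mean(snap_t, snap_t1, n)
        mc, se = mc_rewired_retention(e1, degrees, n, rng, draws=10_000)
        assert abs(analytic - mc) <= 3 * se + 1e-12


class TestRetentionIndex:
    def test_identical_snapshots_score_exactly_one(self):
        r = retention_index(snap(0, {("A", "B"), ("C", "D")}), snap(1, {("A", "B"), ("C", "D")}), 4)
        assert r.index == 1.0 and r.defined

    def test_hand_computed_intermediate_case(self):
        r = retention_index(
            snap(0, {("A", "B"), ("A", "C")}), snap(1, {("A", "B"), ("C", "D")}), 4
        )
        assert r.r_bar_temp == 0.5
        assert r.r_bar_stat == 1.0
        assert r.r_bar_dyna == pytest.approx(0.25)
        assert r.index == pytest.approx(1 / 3)

    def test_degenerate_denominator_flagged_undefined(self):
        r = retention_index(snap(0, set()), snap(1, set()), 4)
        assert not r.defined and np.isnan(r.index)

    def test_index_not_clamped(self):
        # fewer retained contacts than chance pushes the index below 0
        a = snap(0, {("A", "B"), ("C", "D")})
        b = snap(1, {("A", "C"), ("B", "D")})
        r = retention_index(a, b, 4)
        assert r.defined and r.index < 0


class TestSummaries:
    def test_static_series_has_median_one_and_zero_iqr_width(self):
        cfg = GeneratorConfig(n=60, t=8, degree_law=DegreeLaw.poisson(3), seed=5)
        summary = summarize_retention(generate_static(cfg))
        assert summary.median_index == 1.0
        assert summary.iqr_index == (1.0, 1.0)

    def test_median_uses_linear_interpolation(self):
        contact_sets = [
            {("A", "B"), ("C", "D")},
            {("A", "B"), ("C", "D")},
            {("A", "B"), ("C", "E")},
        ]
        series = series_of(contact_sets, population=list("ABCDE"))
        summary = summarize_retention(series)
        # indices are exactly [1.0, 0.375]; median of two interpolates
        assert summary.indices == pytest.approx([1.0, 0.375])
        assert summary.median_index == pytest.approx(0.6875)

    def test_all_degenerate_pairs_raise(self):
        series = series_of([set(), set(), set()], population=list("ABCD"))
        with pytest.raises(ValueError, match="defined"):
            summarize_retention(series)


class TestTypeBreakdown:
    ATTRS = {
        "A": {"dept": "ICU"}, "B": {"dept": "ICU"},
        "C": {"dept": "ER"}, "D": {"dept": "ICU"},
        "E": {"dept": "ER"}, "F": {"dept": "ICU"},
        "G": {"dept": "ICU"}, "H": {"dept": "ER"},
    }

    def _result(self, pairs):
        a = snap(0, pairs)
        return retention_index(a, snap(1, pairs), len(self.ATTRS))

    def test_all_same_department(self):
        res = self._result({("A", "B"), ("D", "F")})
        assert retained_type_breakdown(res, self.ATTRS, "dept") == {"same-dept": 1.0}

    def test_mixed_proportions(self):
        res = self._result({("A", "B"), ("D", "F"), ("A", "G"), ("A", "C")})
        bd = retained_type_breakdown(res, self.ATTRS, "dept")
        assert bd == {"same-dept": 0.75, "different-dept": 0.25}
        assert sum(bd.values()) == pytest.approx(1.0)

    def test_unlabelled_node_typed_unknown(self):
        res = self._result({("A", "Z")})
        assert retained_type_breakdown(res, self.ATTRS, "dept") == {"unknown": 1.0}

    def test_nothing_retained_gives_empty_map(self):
        res = retention_index(snap(0, {("A", "B")}), snap(1, {("C", "D")}), 8)
        assert retained_type_breakdown(res, self.ATTRS, "dept") == {}
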