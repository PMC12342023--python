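"""Dynamic network analysis: edge rule, complexity, connectivity."""

import networkx as nx
import numpy as np
import pytest

from conftest import make_dataset, random_dataset
from dynanet.dyna import (
    ComplexityProfile,
    DynamicNetworkAnalysis,
    DynamicNetworkSet,
    build_networks,
    complexity,
    interval_correlations,
    mediator_connectivity,
)
from dynanet.exceptions import ConfigError, PanelLookupError
from dynanet.simulate import PlantedEdge, SyntheticSpec, generate
from oracles import brute_dyna_edges, brute_pearson


def dataset_from_columns(cols, times=(0.0, 1.0)):
    """One subject per row index, columns = mediator series over the
    pooled window (values alternate across the two boundary times)."""
    rows = []
    n = len(next(iter(cols.values())))
    for i in range(n):
        s = f"s{i // 2:02d}"
        t = times[i % 2]
        for m, values in cols.items():
            rows.append((s, "G", t, m, values[i]))
    return make_dataset(rows, mediators=list(cols))


class TestIntervalCorrelations:
    def test_perfect_linear_dependence(self):
        a = [1.0, 2.0, 3.0, 5.0]
        ds = dataset_from_columns({"A": a, "B": [2 * v for v in a]})
        r, n = interval_correlations(ds, "G", (0.0, 1.0))
        assert r.at["A", "B"] == pytest.approx(1.0)
        assert n.at["A", "B"] == 4

    def test_hand_computed_pearson(self):
        ds = dataset_from_columns({"A": [1, 2, 3, 5], "B": [2, 1, 4, 6]})
        r, _ = interval_correlations(ds, "G", (0.0, 1.0))
        expected, _ = brute_pearson([1, 2, 3, 5], [2, 1, 4, 6])
        assert r.at["A", "B"] == pytest.approx(expected)
        # direct evaluation of the Pearson formula gives 0.9022
        assert r.at["A", "B"] == pytest.approx(0.9022, abs=5e-4)

    def test_constant_mediator_undefined(self):
        ds = dataset_from_columns({"A": [1, 2, 3, 5], "C": [4, 4, 4, 4]})
        r, _ = interval_correlations(ds, "G", (0.0, 1.0))
        assert np.isnan(r.at["A", "C"])
        nets = build_networks([(r, _)], [(0.0, 1.0)], ds.mediators)
        assert "C" in nets.excluded[0]

    def test_min_pairs_guard(self):
        ds = dataset_from_columns({"A": [1, 2, 3], "B": [1, 2, 3]})
        r, n = interval_correlations(ds, "G", (0.0, 1.0), min_pairs=4)
        assert np.isnan(r.at["A", "B"])
        r2, _ = interval_correlations(ds, "G", (0.0, 1.0), min_pairs=3)
        assert r2.at["A", "B"] == pytest.approx(1.0)

    def test_differences_mode_requires_both_samples(self):
        rows = [
            ("a", "G", 0.0, "A", 1.0), ("a", "G", 1.0, "A", 3.0),
            ("a", "G", 0.0, "B", 2.0), ("a", "G", 1.0, "B", 5.0),
            ("b", "G", 0.0, "A", 2.0), ("b", "G", 1.0, "A", 3.0),
            ("b", "G", 0.0, "B", 1.0), ("b", "G", 1.0, "B", 1.5),
            ("c", "G", 0.0, "A", 9.0),  # no t=1 sample: excluded
            ("c", "G", 0.0, "B", 9.0),
        ]
        ds = make_dataset(rows)
        r, n = interval_correlations(ds, "G", (0.0, 1.0), mode="differences", min_pairs=2)
        assert n.at["A", "B"] == 2

    def test_unknown_interval(self):
        ds = dataset_from_columns({"A": [1, 2, 3, 4]})
        with pytest.raises(PanelLookupError):
            interval_correlations(ds, "G", (0.0, 5.0))


class TestEdgeRule:
    def _nets_for(self, r_value):
        import pandas as pd

        meds = ["A", "B"]
        r = pd.DataFrame([[np.nan, r_value], [r_value, np.nan]], index=meds, columns=meds)
        n = pd.DataFrame(10, index=meds, columns=meds)
        return build_networks([(r, n)], [(0.0, 1.0)], meds)

    def test_threshold_inclusive_at_085(self):
        nets = self._nets_for(0.85)
        assert nets.graphs[0].has_edge("A", "B")

    def test_just_below_threshold(self):
        nets = self._nets_for(0.849)
        assert not nets.graphs[0].has_edge("A", "B")

    def test_negative_edge_sign(self):
        nets = self._nets_for(-0.90)
        (edge,) = nets.edges(0)
        assert edge.sign == "negative"

    def test_threshold_validation(self):
        with pytest.raises(ConfigError):
            build_networks([], [], ["A", "B"], threshold=1.5)


class TestComplexity:
    def _nets(self, edges, n_meds):
        meds = [f"M{i}" for i in range(n_meds)]
        g = nx.Graph()
        g.add_nodes_from(meds)
        for a, b in edges:
            g.add_edge(meds[a], meds[b], r=0.9, n_pairs=10)
        return DynamicNetworkSet([(0.0, 1.0)], [g], meds, 0.85, "levels", [{}])

    def test_empty_network(self):
        prof = complexity(self._nets([], 10))
        assert prof.complexity == [0.0]
        assert prof.total_connections == 0

    def test_single_edge_23_panel(self):
        prof = complexity(self._nets([(0, 1)], 23))
        assert prof.complexity[0] == pytest.approx(2.0 / 22.0)

    def test_complete_graph_identity(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        prof = complexity(self._nets(edges, 5))
        assert prof.complexity[0] == pytest.approx(5.0)

    def test_complexity_equals_degree_sum_over_nm1(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 12))
            g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.9), seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {i: f"M{i}" for i in range(n)})
            for a, b in g.edges:
                g.edges[a, b].update(r=0.9, n_pairs=9)
            nets = DynamicNetworkSet([(0.0, 1.0)], [g], list(g.nodes), 0.85, "levels", [{}])
            prof = complexity(nets, n)
            degsum = sum(dict(g.degree).values())
            assert prof.complexity[0] == pytest.approx(degsum / (n - 1))
            assert prof.complexity[0] == pytest.approx(2 * g.number_of_edges() / (n - 1))

    def test_small_panel_rejected(self):
        with pytest.raises(ConfigError):
            complexity(self._nets([], 5), n_mediators=1)


class TestConnectivity:
    def test_degree_totals(self):
        meds = ["A", "B", "C"]
        g1, g2, g3 = nx.Graph(), nx.Graph(), nx.Graph()
        for g in (g1, g2, g3):
            g.add_nodes_from(meds)
        g1.add_edge("A", "B", r=0.9, n_pairs=8)
        g1.add_edge("A", "C", r=-0.9, n_pairs=8)
        g3.add_edge("A", "B", r=0.88, n_pairs=8)
        nets = DynamicNetworkSet(
            [(0, 1), (1, 2), (2, 3)], [g1, g2, g3], meds, 0.85, "levels", [{}, {}, {}]
        )
        c = mediator_connectivity(nets, "A")
        assert c["degree"] == [2, 0, 1]
        assert c["total"] == 3
        assert c["partners"][0] == {"B": "positive", "C": "negative"}
        iso = mediator_connectivity(nets, "C")
        assert iso["degree"] == [1, 0, 0]
        with pytest.raises(PanelLookupError):
            mediator_connectivity(nets, "ZZZ")

    def test_planted_hub_has_top_connectivity(self):
        hits = 0
        for seed in range(10):
            # hub M0 planted in non-adjacent windows (adjacent reuse would
            # split the shared boundary time between two patterns)
            spec = SyntheticSpec(
                mediators=[f"M{i}" for i in range(8)],
                subgroup_sizes={"G": 20},
                time_grid=[0.0, 1.0, 2.0, 3.0, 4.0],
                planted_edges=[
                    PlantedEdge("M0", "M1", 0, 0.95),
                    PlantedEdge("M0", "M2", 2, 0.95),
                    PlantedEdge("M4", "M5", 1, 0.95),
                    PlantedEdge("M6", "M7", 3, 0.95),
                ],
                seed=seed,
            )
            ds, _ = generate(spec)
            est = DynamicNetworkAnalysis().fit(ds, subgroup="G")
            totals = {m: est.connectivity(m)["total"] for m in ds.mediators}
            if max(totals, key=totals.get) == "M0":
                hits += 1
        assert hits >= 9


class TestOracleEquivalence:
    def test_edges_match_brute_force(self, rng):
        for _ in range(20):
            ds = random_dataset(
                rng,
                n_mediators=int(rng.integers(3, 7)),
                n_subjects=int(rng.integers(5, 16)),
                n_times=int(rng.integers(2, 5)),
                missing_rate=float(rng.uniform(0, 0.3)),
            )
            est = DynamicNetworkAnalysis().fit(ds, subgroup="G")
            expected = brute_dyna_edges(ds, "G")
            for k in range(len(ds.intervals)):
                got = {
                    frozenset((e.mediator_a, e.mediator_b))
                    for e in est.networks_.edges(k)
                }
                assert got == expected[k]


class TestProperties:
    def test_symmetry_and_no_self_edges(self, rng):
        ds = random_dataset(rng, n_mediators=6, n_subjects=10, n_times=3)
        est = DynamicNetworkAnalysis(threshold=0.3).fit(ds, subgroup="G")
        for g in est.networks_.graphs:
            for a, b in g.edges:
                assert a != b
                assert g.has_edge(b, a)

    def test_monotone_in_threshold(self, rng):
        ds = random_dataset(rng, n_mediators=6, n_subjects=10, n_times=3)
        prev_edges = None
        prev_complexity = None
        for thr in (0.2, 0.4, 0.6, 0.8, 0.95):
            est = DynamicNetworkAnalysis(threshold=thr).fit(ds, subgroup="G")
            edges = {
                (k, frozenset((e.mediator_a, e.mediator_b)))
                for k in range(len(ds.intervals))
                for e in est.networks_.edges(k)
            }
            total_cx = sum(est.complexity_.complexity)
            if prev_edges is not None:
                assert edges <= prev_edges
                assert total_cx <= prev_complexity + 1e-12
            prev_edges, prev_complexity = edges, total_cx

    def test_estimator_params_roundtrip(self):
        est = DynamicNetworkAnalysis(threshold=0.9, mode="differences", min_pairs=5)
        params = est.get_params()
        est2 = DynamicNetworkAnalysis(**params)
        assert est2.get_params() == params
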