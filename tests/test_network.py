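"""Geodesic sets, alteration fractions and the brute-force path oracle."""

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gtpase_circuit.network import (InteractionGraph, MalformedRowError,
                                    delete_node_diff, load_interactions,
                                    rank_end_proteins, seeded_paths)
from gtpase_circuit.synthetic import generate_ppi_fixture


def edges_df(rows):
    return pd.DataFrame(rows, columns=["protein1", "protein2",
                                       "combined_score"])


class TestLoadInteractions:
    def test_cutoff_filters_edges(self):
        df = edges_df([("A", "B", 700), ("B", "C", 500), ("C", "D", 900)])
        ig = load_interactions(df, cutoff=667)
        assert ig.graph.number_of_edges() == 2
        assert not ig.graph.has_edge("B", "C")

    def test_cutoff_zero_keeps_all(self):
        df = edges_df([("A", "B", 700), ("B", "C", 500)])
        assert load_interactions(df, cutoff=0).graph.number_of_edges() == 2

    def test_duplicates_keep_max_score(self):
        df = edges_df([("A", "B", 700), ("B", "A", 900)])
        ig = load_interactions(df, cutoff=0)
        assert ig.graph["A"]["B"]["combined_score"] == 900

    def test_malformed_row_reports_line(self):
        df = edges_df([("A", "B", 700), ("B", "C", None)])
        with pytest.raises(MalformedRowError, match="line 3"):
            load_interactions(df, cutoff=0)

    def test_empty_graph_rejected(self):
        df = edges_df([("A", "B", 100)])
        with pytest.raises(ValueError, match="no edges"):
            load_interactions(df, cutoff=667)

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\n"
                        "ARF1\tGIV\t910\nGIV\tGNAI1\t880\n")
        ig = load_interactions(path, cutoff=667, seeds=["ARF1", "GNAI1"])
        assert set(ig.seeds) == {"ARF1", "GNAI1"}


def graph_of(edges, seeds):
    g = nx.Graph()
    g.add_edges_from(edges)
    return InteractionGraph(g, frozenset(seeds), cutoff=0)


class TestSeededPaths:
    def test_path_graph_single_geodesic(self):
        ig = graph_of([("A", "B"), ("B", "C")], ["A", "C"])
        assert seeded_paths(ig) == {("A", "C"): frozenset({("A", "B", "C")})}

    def test_square_has_two_geodesics(self):
        ig = graph_of([("A", "B"), ("B", "C"), ("A", "D"), ("D", "C")],
                      ["A", "C"])
        assert seeded_paths(ig)[("A", "C")] == frozenset(
            {("A", "B", "C"), ("A", "D", "C")})

    def test_disconnected_pair_recorded_empty(self):
        ig = graph_of([("A", "B"), ("C", "D")], ["A", "C"])
        assert seeded_paths(ig)[("A", "C")] == frozenset()


class TestDeleteNodeDiff:
    def test_full_turnover_with_longer_detour(self):
        # unique geodesic A-B-C; detour A-D-E-C appears after deleting B
        ig = graph_of([("A", "B"), ("B", "C"), ("A", "D"), ("D", "E"),
                       ("E", "C")], ["A", "C"])
        delta, = delete_node_diff(ig, "B", anchor="A")
        assert delta.alteration_fraction == 1.0
        assert delta.geodesics_after == frozenset({("A", "D", "E", "C")})

    def test_partial_turnover_on_equal_length_alternative(self):
        ig = graph_of([("A", "B"), ("B", "C"), ("A", "D"), ("D", "C")],
                      ["A", "C"])
        delta, = delete_node_diff(ig, "B", anchor="A")
        assert delta.alteration_fraction == pytest.approx(0.5)

    def test_off_geodesic_node_changes_nothing(self):
        ig = graph_of([("A", "B"), ("B", "C"), ("C", "Z")], ["A", "C"])
        delta, = delete_node_diff(ig, "Z", anchor="A")
        assert delta.alteration_fraction == 0.0

    def test_anchor_deletion_refused(self):
        ig = graph_of([("A", "B")], ["A", "B"])
        with pytest.raises(ValueError):
            delete_node_diff(ig, "A", anchor="A")
        with pytest.raises(KeyError):
            delete_node_diff(ig, "QQ", anchor="A")

    def test_relabeling_invariance(self):
        edges = [("A", "B"), ("B", "C"), ("A", "D"), ("D", "E"), ("E", "C")]
        ig = graph_of(edges, ["A", "C"])
        frac = delete_node_diff(ig, "B", "A")[0].alteration_fraction
        mapping = {"A": "n1", "B": "n2", "C": "n3", "D": "n4", "E": "n5"}
        ig2 = graph_of([(mapping[u], mapping[v]) for u, v in edges],
                       ["n1", "n3"])
        frac2 = delete_node_diff(ig2, "n2", "n1")[0].alteration_fraction
        assert frac == frac2


class TestRankEndProteins:
    def test_single_impacted_pair(self):
        ig = graph_of([("A", "B"), ("B", "C"), ("A", "D"), ("D", "E"),
                       ("E", "C")], ["A", "C"])
        deltas = delete_node_diff(ig, "B", "A")
        ranking = rank_end_proteins(deltas)
        assert ranking == [("C", 2)]     # one deleted + one added geodesic

    def test_no_full_turnover_means_empty_ranking(self):
        ig = graph_of([("A", "B"), ("B", "C"), ("A", "D"), ("D", "C")],
                      ["A", "C"])
        assert rank_end_proteins(delete_node_diff(ig, "B", "A")) == []

    def test_empty_deltas_rejected(self):
        with pytest.raises(ValueError):
            rank_end_proteins([])

    def test_planted_fixture_recovered(self):
        ig, linker, partners = generate_ppi_fixture(n_nodes=12, n_seeds=4,
                                                    seed=3)
        deltas = delete_node_diff(ig, linker, "ANCHOR")
        ranking = rank_end_proteins(deltas)
        assert {name for name, _ in ranking} == set(partners)
        fracs = {d.partner: d.alteration_fraction for d in deltas}
        assert all(fracs[prot] == 1.0 for prot in partners)


def brute_force_geodesics(g, a, b):
    """All shortest paths by exhaustive simple-path enumeration."""
    nodes = list(g)
    best, paths = None, set()
    for k in range(2, len(nodes) + 1):
        for mid in permutations([n for n in nodes if n not in (a, b)],
                                k - 2):
            path = (a, *mid, b)
            if all(g.has_edge(u, v) for u, v in zip(path, path[1:])):
                if best is None or len(path) < best:
                    best, paths = len(path), {path}
                elif len(path) == best:
                    paths.add(path)
        if best is not None:
            break          # all longer candidates cannot be shortest
    return frozenset(paths)


class TestBruteForceOracle:
    @pytest.mark.parametrize("n,p,seed", [(4, 0.5, 0), (5, 0.4, 1),
                                          (6, 0.35, 2), (7, 0.3, 3),
                                          (8, 0.3, 4), (8, 0.5, 5)])
    def test_bfs_matches_enumeration(self, n, p, seed):
        g = nx.gnp_random_graph(n, p, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g})
        for a, b in combinations(sorted(g), 2):
            if not nx.has_path(g, a, b):
                continue
            bfs = frozenset(tuple(path)
                            for path in nx.all_shortest_paths(g, a, b))
            assert bfs == brute_force_geodesics(g, a, b), (a, b)
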