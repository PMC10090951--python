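"""Differential shortest-path analysis of a seeded PPI network.

A confidence-filtered STRING-style interaction graph is probed by in
silico deletion of a node (e.g. GIV): for every (anchor, partner) seed
pair the sets of unweighted geodesics before and after deletion are
compared, and the shortest-path alteration fraction measures how
completely the geodesic set turns over.  A fraction of 1 means only
deleted or newly created paths -- the pairs the downstream ranking uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["InteractionGraph", "PathDelta", "MalformedRowError",
           "load_interactions", "seeded_paths", "delete_node_diff",
           "rank_end_proteins", "DEFAULT_SCORE_CUTOFF"]

#: interaction confidence cutoff used for the Golgi Arf1-GIV network
DEFAULT_SCORE_CUTOFF = 667


class MalformedRowError(ValueError):
    """An edge-table row that cannot be parsed (carries the line number)."""


@dataclass
class InteractionGraph:
    """Scored undirected PPI graph with a designated seed set."""

    graph: nx.Graph
    seeds: frozenset[str]
    cutoff: int = DEFAULT_SCORE_CUTOFF

    def __post_init__(self):
        self.seeds = frozenset(self.seeds)
        missing = self.seeds - set(self.graph)
        if missing:
            raise ValueError(f"seed proteins not in graph: {sorted(missing)}")
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("graph must not contain self-loops")

    @property
    def nodes(self):
        return self.graph.nodes

    def without(self, node: str) -> "InteractionGraph":
        if node not in self.graph:
            raise KeyError(f"node {node!r} not in graph")
        g = self.graph.copy()
        g.remove_node(node)
        return InteractionGraph(g, self.seeds - {node}, self.cutoff)


def load_interactions(edge_table, cutoff: int = DEFAULT_SCORE_CUTOFF,
                      seeds=()) -> InteractionGraph:
    """Build the graph from a STRING-export TSV or DataFrame.

    Expected columns ``protein1, protein2, combined_score`` (``proteinA/
    proteinB`` accepted).  Edges below the cutoff are dropped, duplicates
    collapsed keeping the maximal score, self-loops discarded.
    """
    if isinstance(edge_table, (str, Path)):
        df = pd.read_csv(edge_table, sep="\t", dtype=str)
    else:
        df = pd.DataFrame(edge_table).astype(str)
    rename = {"proteinA": "protein1", "proteinB": "protein2"}
    df = df.rename(columns=rename)
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise MalformedRowError(
            f"edge table must have columns {sorted(required)}, "
            f"got {list(df.columns)}")

    g = nx.Graph()
    for idx, row in df.iterrows():
        line_no = idx + 2          # header is line 1
        a, b, score = (row["protein1"], row["protein2"],
                       row["combined_score"])
        if pd.isna(a) or pd.isna(b) or str(a) == "nan" or str(b) == "nan":
            raise MalformedRowError(f"missing protein name at line {line_no}")
        try:
            score = int(float(score))
        except (TypeError, ValueError):
            raise MalformedRowError(
                f"missing/invalid combined_score at line {line_no}: "
                f"{score!r}") from None
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], score)
        else:
            g.add_edge(a, b, combined_score=score)

    drop = [(u, v) for u, v, s in g.edges(data="combined_score")
            if s < cutoff]
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        raise ValueError(f"no edges retained at cutoff {cutoff}")
    return InteractionGraph(g, frozenset(s for s in seeds if s in g), cutoff)


GeodesicSet = frozenset[tuple[str, ...]]


def _geodesics(g: nx.Graph, a: str, b: str) -> GeodesicSet:
    if a not in g or b not in g:
        return frozenset()
    try:
        return frozenset(tuple(path)
                         for path in nx.all_shortest_paths(g, a, b))
    except nx.NetworkXNoPath:
        return frozenset()


def seeded_paths(ig: InteractionGraph) -> dict[tuple[str, str], GeodesicSet]:
    """All equal-length shortest paths between every pair of seed proteins.

    Pairs in different components map to the empty set (recorded, not an
    error).  Pair keys are sorted tuples.
    """
    out = {}
    for a, b in combinations(sorted(ig.seeds), 2):
        out[(a, b)] = _geodesics(ig.graph, a, b)
    return out


@dataclass(frozen=True)
class PathDelta:
    """Geodesic turnover of one (anchor, partner) pair upon node deletion."""

    anchor: str
    partner: str
    geodesics_before: GeodesicSet
    geodesics_after: GeodesicSet

    @property
    def alteration_fraction(self) -> float:
        """|symmetric difference| / |union| of the two geodesic sets.

        1 means every surviving path is newly created and every original
        path was deleted; 0 means the geodesic set is unchanged (or the
        pair had no geodesics at all).
        """
        union = self.geodesics_before | self.geodesics_after
        if not union:
            return 0.0
        changed = self.geodesics_before ^ self.geodesics_after
        return len(changed) / len(union)

    @property
    def impacted_geodesics(self) -> GeodesicSet:
        return self.geodesics_before ^ self.geodesics_after


def delete_node_diff(ig: InteractionGraph, node: str,
                     anchor: str) -> list[PathDelta]:
    """Recompute anchor-to-seed geodesics with ``node`` deleted.

    Returns one :class:`PathDelta` per (anchor, partner) pair, partner
    ranging over the other seeds (the deleted node excluded).
    """
    if node not in ig.graph:
        raise KeyError(f"node {node!r} not in graph")
    if anchor not in ig.graph:
        raise KeyError(f"anchor {anchor!r} not in graph")
    if node == anchor:
        raise ValueError("cannot delete the anchor node itself")
    after = ig.without(node)
    deltas = []
    for partner in sorted(ig.seeds - {anchor, node}):
        deltas.append(PathDelta(
            anchor, partner,
            _geodesics(ig.graph, anchor, partner),
            _geodesics(after.graph, anchor, partner)))
    return deltas


def rank_end_proteins(deltas: list[PathDelta]) -> list[tuple[str, int]]:
    """Partners of fully altered pairs, ranked by impacted-geodesic count.

    Only deltas with alteration fraction 1 (geodesic sets fully turned
    over) contribute; ties are broken alphabetically.
    """
    if not deltas:
        raise ValueError("deltas must be nonempty")
    counts = {}
    for d in deltas:
        if d.alteration_fraction == 1.0:
            counts[d.partner] = counts.get(d.partner, 0) \
                + len(d.impacted_geodesics)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def deltas_to_frame(deltas: list[PathDelta]) -> pd.DataFrame:
    return pd.DataFrame({
        "anchor": [d.anchor for d in deltas],
        "partner": [d.partner for d in deltas],
        "n_before": [len(d.geodesics_before) for d in deltas],
        "n_after": [len(d.geodesics_after) for d in deltas],
        "alteration_fraction": [d.alteration_fraction for d in deltas],
    })
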