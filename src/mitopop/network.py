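"""Haplotype networks: minimum spanning networks and median joining.

The minimum spanning network (MSN) is the union of all minimum spanning
trees over the observed haplotypes under Hamming (mutational-step)
distance: an edge of weight w is kept when its endpoints are still in
different components of the strictly-lighter subgraph. Median joining
additionally proposes consensus (Steiner) haplotypes — majority vectors
of node triplets — and keeps those that lower the total spanning cost,
which resolves the reticulations a star-burst genealogy leaves behind.
Node weights are pooled relative frequencies; for a star-like network the
highest-frequency node is the natural ancestral candidate (the printed
"outgroup weights" of network software equal these frequencies).
"""

from __future__ import annotations

import json
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .distances import pairwise_difference_count
from .errors import MitopopError
from .haplotypes import HaplotypeTable


def _require_sequences(tab: HaplotypeTable) -> dict[str, str]:
    if tab.sequences is None:
        raise MitopopError("haplotype sequences required to build a network")
    return tab.sequences


def _annotate(g: nx.Graph, tab: HaplotypeTable) -> nx.Graph:
    pooled = tab.pooled_counts()
    total = tab.total_n
    for node in g.nodes:
        observed = node in pooled.index and pooled[node] > 0
        g.nodes[node]["median"] = not observed
        g.nodes[node]["count"] = int(pooled.get(node, 0))
        g.nodes[node]["weight"] = float(pooled.get(node, 0)) / total
        g.nodes[node]["pop_counts"] = json.dumps(
            {p: int(tab.counts.at[p, node]) for p in tab.populations
             if observed and tab.counts.at[p, node] > 0}
        )
    return g


def _msn_edges(seqs: dict[str, str]) -> list[tuple[str, str, int]]:
    """Edges of the minimum spanning network (union of all MSTs)."""
    nodes = sorted(seqs)
    edges = sorted(
        (pairwise_difference_count(seqs[a], seqs[b]), a, b)
        for a, b in combinations(nodes, 2)
    )
    uf = nx.utils.UnionFind(nodes)
    kept: list[tuple[str, str, int]] = []
    i = 0
    while i < len(edges):
        w = edges[i][0]
        block = []
        while i < len(edges) and edges[i][0] == w:
            block.append(edges[i])
            i += 1
        # same-weight edges judged against components of lighter edges only
        for _, a, b in block:
            if uf[a] != uf[b]:
                kept.append((a, b, w))
        for _, a, b in block:
            uf.union(a, b)
    return kept


def minimum_spanning_network(
    tab: HaplotypeTable, d=None
) -> nx.Graph:
    """MSN over the table's haplotypes (``d`` accepted for interface
    symmetry; step counts are recomputed from sequences)."""
    seqs = _require_sequences(tab)
    g = nx.Graph()
    g.add_nodes_from(sorted(seqs))
    for a, b, w in _msn_edges(seqs):
        g.add_edge(a, b, steps=int(w))
    return _annotate(g, tab)


def _spanning_cost(seqs: dict[str, str]) -> int:
    """Total weight of a minimum spanning tree over the given sequences."""
    g = nx.Graph()
    nodes = sorted(seqs)
    for a, b in combinations(nodes, 2):
        g.add_edge(a, b, weight=pairwise_difference_count(seqs[a], seqs[b]))
    if len(nodes) == 1:
        return 0
    return int(sum(
        d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True)
    ))


def _majority_median(sa: str, sb: str, sc: str) -> str:
    out = []
    for x, y, z in zip(sa, sb, sc):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)  # three states: no true median, keep first
    return "".join(out)


def median_joining(tab: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Median-joining network (ε = 0).

    Iteratively proposes the majority-consensus vector of every triplet of
    current nodes whose mutual connection cost is within the network
    diameter (a runtime bound), accepts a proposal when it strictly lowers
    the minimum-spanning cost, and stops at a fixed point. Median nodes are
    named M1, M2, …, carry zero counts and are flagged ``median=True``.
    """
    observed = dict(_require_sequences(tab))
    working = dict(observed)
    if len(working) == 1:
        g = nx.Graph()
        g.add_nodes_from(working)
        return _annotate(g, tab)
    n_median = 0
    improved = True
    while improved:
        improved = False
        cost = _spanning_cost(working)
        names = sorted(working)
        diam = max(
            pairwise_difference_count(working[a], working[b])
            for a, b in combinations(names, 2)
        )
        candidates: list[str] = []
        seen = set(working.values())
        for a, b, c in combinations(names, 3):
            if epsilon == 0:
                span = max(
                    pairwise_difference_count(working[a], working[b]),
                    pairwise_difference_count(working[a], working[c]),
                    pairwise_difference_count(working[b], working[c]),
                )
                if span > diam:
                    continue
            med = _majority_median(working[a], working[b], working[c])
            if med not in seen:
                seen.add(med)
                candidates.append(med)
        best_gain, best_seq = 0, None
        for med in candidates:
            trial = dict(working)
            trial["_cand"] = med
            gain = cost - _spanning_cost(trial)
            if gain > best_gain + epsilon:
                best_gain, best_seq = gain, med
        if best_seq is not None:
            n_median += 1
            working[f"M{n_median}"] = best_seq
            improved = True
    # prune medians that no minimum spanning network edge uses
    g = nx.Graph()
    g.add_nodes_from(sorted(working))
    for a, b, w in _msn_edges(working):
        g.add_edge(a, b, steps=int(w))
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            if node.startswith("M") and node not in observed and g.degree(node) <= 1:
                g.remove_node(node)
                changed = True
    return _annotate(g, tab)


def ancestral_weights(tab: HaplotypeTable) -> pd.Series:
    """Pooled relative frequency of each haplotype (the quantity printed
    as an "outgroup weight" by network software on star-like data)."""
    pooled = tab.pooled_counts()
    return pooled / pooled.sum()


def edge_list(g: nx.Graph, path: str | Path | None = None) -> str:
    rows = [
        f"{a}\t{b}\t{g.edges[a, b]['steps']}"
        for a, b in sorted(g.edges)
    ]
    text = "from\tto\tsteps\n" + "\n".join(rows) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_gml(g: nx.Graph, path: str | Path) -> None:
    nx.write_gml(g, str(path))
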