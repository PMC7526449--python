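"""Regulator->regulator interaction networks from motif target sets.

Motif sets naming the same gene symbol are amalgamated (union of targets);
a directed edge A->B exists when B's symbol appears in A's amalgamated
target list, including self-loops (self-regulating feedback). Nodes carry a
correlation-sign category (how the regulator's activity relates to MRSS in
the fibroproliferative/inflammatory subsets) and a degree where a self-loop
counts once.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .io_formats import RegulatorSet, extract_symbol


class NetworkError(ValueError):
    pass


def amalgamate_sets(
    sets: Iterable[RegulatorSet],
    aliases: Mapping[str, str] | None = None,
    exclude_pattern: str | None = None,
) -> dict[str, frozenset[str]]:
    """Union targets across motif sets sharing a gene symbol.

    Sets whose name yields no symbol, or whose symbol matches the exclusion
    pattern, are unclassified motifs and are dropped.
    """
    merged: dict[str, set[str]] = {}
    for s in sets:
        symbol = extract_symbol(s.name, aliases)
        if symbol is None:
            continue
        if exclude_pattern and re.search(exclude_pattern, symbol):
            continue
        merged.setdefault(symbol, set()).update(s.targets)
    return {sym: frozenset(t) for sym, t in merged.items()}


def node_degree(graph: nx.DiGraph, node: str) -> int:
    """In-degree + out-degree, counting a self-loop once."""
    deg = graph.in_degree(node) + graph.out_degree(node)
    if graph.has_edge(node, node):
        deg -= 1
    return deg


def build_network(
    sets: Iterable[RegulatorSet],
    selected: Iterable[str],
    annotations: Mapping[str, str] | None = None,
    aliases: Mapping[str, str] | None = None,
    exclude_pattern: str | None = None,
) -> nx.DiGraph:
    """Directed regulator interaction graph over the selected symbols.

    Both edge endpoints are restricted to the selected set. Node attributes:
    ``category`` (correlation-sign annotation, ``"unannotated"`` when
    missing) and ``degree``.
    """
    selected = [s.upper() for s in selected]
    if not selected:
        raise NetworkError("empty regulator selection")
    merged = amalgamate_sets(sets, aliases, exclude_pattern)
    annotations = annotations or {}
    graph = nx.DiGraph()
    for sym in selected:
        if sym not in merged:
            continue
        graph.add_node(
            sym, category=str(annotations.get(sym, "unannotated"))
        )
    for src in graph.nodes:
        for dst in graph.nodes:
            if dst in merged[src]:
                graph.add_edge(src, dst, relation="targets")
    for node in graph.nodes:
        graph.nodes[node]["degree"] = node_degree(graph, node)
    return graph


#: Fig-style sign categories for the combined two-subset network
def sign_category(pcc_fibro: float | None, pcc_inflam: float | None) -> str:
    """Correlation-sign category from the two per-subset aggregates."""
    def sgn(v):
        if v is None:
            return None
        return "pos" if v > 0 else "neg"

    f, i = sgn(pcc_fibro), sgn(pcc_inflam)
    if f and i:
        if f == i:
            return f"{'positive' if f == 'pos' else 'negative'}-both"
        return (
            "positive-fibro-negative-inflam"
            if f == "pos"
            else "negative-fibro-positive-inflam"
        )
    if f:
        return f"{'positive' if f == 'pos' else 'negative'}-fibro-only"
    if i:
        return f"{'positive' if i == 'pos' else 'negative'}-inflam-only"
    return "unannotated"


def export_network(
    net: nx.DiGraph, fmt: str, path: str | Path
) -> None:
    """Write the network as GraphML (lossless), SIF, or a TSV edge list."""
    if net.number_of_nodes() == 0:
        raise NetworkError("cannot export an empty network")
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for a, b in sorted(net.edges):
                fh.write(f"{a} targets {b}\n")
            for node in sorted(net.nodes):
                if net.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif fmt == "edge_tsv":
        with path.open("w", encoding="utf-8") as fh:
            fh.write(
                "source\ttarget\tsource_category\ttarget_category"
                "\tsource_degree\ttarget_degree\n"
            )
            for a, b in sorted(net.edges):
                fh.write(
                    f"{a}\t{b}\t{net.nodes[a]['category']}"
                    f"\t{net.nodes[b]['category']}"
                    f"\t{net.nodes[a]['degree']}\t{net.nodes[b]['degree']}\n"
                )
    else:
        raise NetworkError(f"unknown export format {fmt!r}")


def import_graphml(path: str | Path) -> nx.DiGraph:
    graph = nx.read_graphml(path)
    return nx.DiGraph(graph)
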