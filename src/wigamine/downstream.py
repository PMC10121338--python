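"""Summaries computed from a mined result set.

* a *global view*: the union graph of all result patterns, each edge weighted
  by the number of patterns containing it, with connected components labeled
  and small components (size <= 4) flagged as below the usual analysis
  threshold;
* co-occurrence frequencies of gene singles/pairs/triples/quadruples across
  patterns;
* hub flagging of genes of interest against a protein-protein interaction
  edge list (hub = degree >= 10 by default).
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "GlobalView",
    "build_global_view",
    "cooccurrence_frequencies",
    "flag_hubs",
    "read_ppi_edges",
]

SMALL_COMPONENT_SIZE = 4
HUB_DEGREE = 10


@dataclasses.dataclass(frozen=True)
class GlobalView:
    """Union graph of result patterns with pattern-count edge weights."""

    graph: nx.Graph
    components: tuple[tuple[str, ...], ...]  # node tuples, largest first

    @property
    def component_sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.components)

    def small_components(self, threshold: int = SMALL_COMPONENT_SIZE) -> tuple[tuple[str, ...], ...]:
        """Components at or below the size threshold (flagged, not dropped)."""
        return tuple(c for c in self.components if len(c) <= threshold)

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "n_patterns": d["weight"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_patterns"])

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.graph, path)

    def write_tsv(self, path: str) -> None:
        self.to_edge_table().to_csv(path, sep="\t", index=False)


def _patterns_of(results) -> list:
    return [sp.pattern if hasattr(sp, "pattern") else sp for sp in results]


def build_global_view(results: Sequence) -> GlobalView:
    """Union graph of the result patterns; edge weight = number of containing patterns."""
    g = nx.Graph()
    for pat in _patterns_of(results):
        for a, b in pat.edges:
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    comps = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c),
    )
    return GlobalView(graph=g, components=tuple(comps))


def cooccurrence_frequencies(results: Sequence, arity: int) -> pd.DataFrame:
    """Counts of gene tuples of the given arity across result patterns.

    Each pattern contributes 1 for every size-``arity`` subset of its node
    set; patterns with fewer nodes contribute nothing.  Ranked by descending
    count, ties by tuple key.
    """
    if not 1 <= arity <= 4:
        raise ValueError(f"arity must be in 1..4: {arity}")
    counts: Counter = Counter()
    for pat in _patterns_of(results):
        nodes = pat.nodes
        for combo in itertools.combinations(nodes, arity):
            counts[combo] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [{"genes": ";".join(t), "count": c} for t, c in rows],
        columns=["genes", "count"],
    )


def read_ppi_edges(path: str) -> list[tuple[str, str]]:
    """Two-column (gene/protein, gene/protein) TSV; other columns ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two identifier columns")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def flag_hubs(
    ppi_edges: Iterable[tuple[str, str]],
    genes_of_interest: Sequence[str],
    degree_threshold: int = HUB_DEGREE,
    id_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Degree and hub flag of each gene of interest in the PPI graph.

    Self-loops and duplicate undirected edges are dropped before counting.
    Genes absent from the PPI graph get degree 0.  ``id_map`` optionally maps
    expression gene identifiers to PPI identifiers (exact string match
    otherwise).
    """
    if degree_threshold < 1:
        raise ValueError("degree threshold must be >= 1")
    g = nx.Graph()
    for a, b in ppi_edges:
        if a != b:
            g.add_edge(a, b)
    rows = []
    for gene in genes_of_interest:
        node = id_map.get(gene, gene) if id_map else gene
        deg = g.degree(node) if node in g else 0
        rows.append({"gene": gene, "degree": int(deg), "hub": bool(deg >= degree_threshold)})
    return pd.DataFrame(rows, columns=["gene", "degree", "hub"])
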