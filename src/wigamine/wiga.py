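"""Per-individual weighted gene association networks and pattern primitives.

Each individual gets one weighted graph over the shared gene universe: the
weight of edge (a_i, a_j) is the (normalized) strength of their association in
that individual, and the edge is kept only if the relevance of the association
exceeds a threshold tau_r (0.9 in the reference experiments).

A *pattern* is a connected edge set over the shared node universe.  Because
every network is defined on the same nodes, a pattern has at most one match
per network: it occurs iff all its edges are present.  The value of a match is
the mean edge weight, the incidence of a pattern over a network collection is
the sum of its match values, and the incidence at x% is the sum of the top
ceil(x% * |collection|) match values — null (0, flagged) when the support is
below that count.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .association import GeneStats, TailTable, strength_tail_given_margin, strength_vec

__all__ = [
    "Edge",
    "WigaNetwork",
    "NetworkSet",
    "Pattern",
    "IncidenceProfile",
    "normalize_strength",
    "build_wiga_network",
    "build_network_set",
    "pattern_occurs",
    "match_value",
    "incidence",
    "incidence_at_x",
    "incidence_profile",
    "is_subpattern",
    "n_x_of",
]

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    if a == b:
        raise ValueError(f"self-loop on {a!r}")
    return (a, b) if a < b else (b, a)


def _connected(edges: Iterable[Edge]) -> bool:
    edges = list(edges)
    if not edges:
        return False
    adj: dict[str, list[str]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    start = edges[0][0]
    seen = {start}
    stack = [start]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(adj)


@dataclasses.dataclass(frozen=True)
class Pattern:
    """A connected edge set; the canonical key is the sorted edge tuple."""

    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("a pattern has at least one edge")
        if list(self.edges) != sorted(set(self.edges)):
            raise ValueError("edges must be sorted, unique and canonical (use Pattern.make)")
        for a, b in self.edges:
            if not a < b:
                raise ValueError(f"edge not canonical: {(a, b)}")
        if not _connected(self.edges):
            raise ValueError(f"pattern not connected: {self.edges}")

    @classmethod
    def make(cls, edges: Iterable[tuple[str, str]]) -> "Pattern":
        return cls(edges=tuple(sorted({canonical_edge(a, b) for a, b in edges})))

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted({v for e in self.edges for v in e}))

    @property
    def key(self) -> tuple[Edge, ...]:
        return self.edges

    def extend(self, edge: Edge) -> "Pattern":
        """Pattern plus one edge touching the current node set."""
        nodes = set(self.nodes)
        if edge[0] not in nodes and edge[1] not in nodes:
            raise ValueError(f"extension edge {edge} disconnected from pattern")
        return Pattern(edges=tuple(sorted(set(self.edges) | {edge})))


def is_subpattern(sub: Pattern, sup: Pattern, strict: bool = False) -> bool:
    """Edge/node inclusion test; ``strict`` excludes equality."""
    ok = set(sub.edges) <= set(sup.edges)
    if strict:
        ok = ok and sub.edges != sup.edges
    return ok


@dataclasses.dataclass(frozen=True)
class WigaNetwork:
    """One individual's filtered association network on the shared node universe."""

    sample_id: str
    label: str
    nodes: tuple[str, ...]
    weights: dict[Edge, float]
    relevance: dict[Edge, float] | None = None

    def __post_init__(self) -> None:
        universe = set(self.nodes)
        for (a, b), w in self.weights.items():
            if a >= b:
                raise ValueError(f"edge not canonical: {(a, b)}")
            if a not in universe or b not in universe:
                raise ValueError(f"edge endpoint outside node universe: {(a, b)}")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"edge weight outside [0, 1]: {(a, b)} -> {w}")

    @property
    def edge_set(self) -> frozenset[Edge]:
        return frozenset(self.weights)


@dataclasses.dataclass(frozen=True)
class NetworkSet:
    """Two labeled sub-collections of networks on a shared node universe.

    ``n1`` is the first (by convention guiding) population.
    """

    n1: tuple[WigaNetwork, ...]
    n2: tuple[WigaNetwork, ...]

    def __post_init__(self) -> None:
        if not self.n1 or not self.n2:
            raise ValueError("both populations must be non-empty")
        universe = self.n1[0].nodes
        for net in self.all_networks:
            if net.nodes != universe:
                raise ValueError(f"network {net.sample_id} has a different node universe")
        ids = [net.sample_id for net in self.all_networks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample identifiers across networks")

    @property
    def all_networks(self) -> tuple[WigaNetwork, ...]:
        return self.n1 + self.n2

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.n1[0].nodes

    def swapped(self) -> "NetworkSet":
        return NetworkSet(n1=self.n2, n2=self.n1)

    def union_edges(self) -> tuple[Edge, ...]:
        out: set[Edge] = set()
        for net in self.all_networks:
            out |= net.edge_set
        return tuple(sorted(out))


# ---------------------------------------------------------------------------
# network construction


_STRENGTH_MAPS = ("clamp", "abs", "affine")


def normalize_strength(rho_hat: float | np.ndarray, mapping: str = "clamp"):
    """Map a strength in [-1, 1] to an edge weight in [0, 1].

    ``clamp`` (default): max(rho, 0) — negative associations carry no weight;
    ``abs``: |rho|; ``affine``: (rho + 1) / 2.
    """
    rho = np.asarray(rho_hat, float)
    if np.any(rho < -1.0) or np.any(rho > 1.0):
        raise ValueError("strength outside [-1, 1]")
    if mapping == "clamp":
        out = np.maximum(rho, 0.0)
    elif mapping == "abs":
        out = np.abs(rho)
    elif mapping == "affine":
        out = (rho + 1.0) / 2.0
    else:
        raise ValueError(f"unknown strength mapping {mapping!r}; choose from {_STRENGTH_MAPS}")
    return float(out) if np.isscalar(rho_hat) else out


def build_wiga_network(
    sample_values: Mapping[str, float],
    stats: GeneStats,
    tau_r: float = 0.9,
    genes: Sequence[str] | None = None,
    *,
    sample_id: str = "",
    label: str = "",
    strength_map: str = "clamp",
    relevance_method: str = "quadrature",
    quadrature_cells: int = 20001,
    tail_table: TailTable | None = None,
) -> WigaNetwork:
    """Build one individual's filtered network from its expression tuple.

    Every unordered pair of candidate genes gets a strength and a relevance;
    edges with relevance strictly greater than ``tau_r`` survive, weighted by
    ``normalize_strength(strength)``.  ``relevance_method`` is ``quadrature``
    (vectorized, default) or ``bisection`` (per-pair root inversion).
    """
    if not 0.0 <= tau_r < 1.0:
        raise ValueError(f"tau_r must be in [0, 1): {tau_r}")
    genes = tuple(genes) if genes is not None else stats.retained
    if not genes:
        raise ValueError("empty candidate gene list")
    unknown = [g for g in genes if g not in stats.genes]
    if unknown:
        raise ValueError(f"candidate genes missing from stats: {unknown}")
    in_zero = [g for g in genes if g in stats.zero_variance]
    if in_zero:
        raise ValueError(f"zero-variance genes cannot enter a network: {in_zero}")

    z = stats.standardize(sample_values, genes)
    g = len(genes)
    ii, jj = np.triu_indices(g, k=1)
    rho = strength_vec(z[ii], z[jj])

    if relevance_method == "quadrature":
        table = tail_table if tail_table is not None else TailTable(z, cells=quadrature_cells)
        rel = np.empty_like(rho)
        for gi in range(g):
            mask_i = ii == gi
            mask_j = jj == gi
            if np.any(mask_i):
                rel[mask_i] = table.tail(gi, rho[mask_i])
            if np.any(mask_j):
                rel[mask_j] = np.minimum(rel[mask_j], table.tail(gi, rho[mask_j]))
    elif relevance_method == "bisection":
        rel = np.array(
            [
                min(
                    strength_tail_given_margin(z[a], r),
                    strength_tail_given_margin(z[b], r),
                )
                for a, b, r in zip(ii, jj, rho)
            ]
        )
    else:
        raise ValueError(f"unknown relevance method {relevance_method!r}")

    keep = rel > tau_r
    eta = normalize_strength(rho, strength_map)
    weights: dict[Edge, float] = {}
    rel_map: dict[Edge, float] = {}
    for a, b, w, r, k in zip(ii, jj, np.atleast_1d(eta), rel, keep):
        if k:
            e = canonical_edge(genes[a], genes[b])
            weights[e] = float(w)
            rel_map[e] = float(r)
    return WigaNetwork(
        sample_id=sample_id, label=label, nodes=tuple(sorted(genes)),
        weights=weights, relevance=rel_map,
    )


def build_network_set(
    dataset,
    stats: GeneStats | None = None,
    tau_r: float = 0.9,
    genes: Sequence[str] | None = None,
    *,
    guiding_class: str | None = None,
    strength_map: str = "clamp",
    relevance_method: str = "quadrature",
    quadrature_cells: int = 20001,
    moments: str = "pooled",
) -> NetworkSet:
    """One filtered network per sample, split into (guiding, other) populations.

    ``guiding_class`` defaults to the lexicographically first class label.
    ``moments`` selects the standardization reference: ``pooled`` (default,
    both classes together — keeps the two network sets comparable) or
    ``per-class`` (each sample standardized against its own class's moments).
    A quadrature table is built per sample (tails depend on the sample's own
    standardized values).
    """
    from .association import estimate_gene_stats

    if moments not in ("pooled", "per-class"):
        raise ValueError(f"moments must be 'pooled' or 'per-class': {moments!r}")
    per_class_stats: dict[str, GeneStats] = {}
    if moments == "per-class":
        if stats is not None:
            raise ValueError("per-class moments are estimated internally; pass stats=None")
        for cls in dataset.classes:
            cols = dataset.samples_of(cls)
            vals = dataset.values[cols].to_numpy(float)
            mean = vals.mean(axis=1)
            sd = vals.std(axis=1, ddof=1)
            zero = tuple(g for g, s in zip(dataset.genes, sd) if not s > 0)
            per_class_stats[cls] = GeneStats(
                genes=tuple(dataset.genes), mean=mean,
                sd=np.where(sd > 0, sd, 1.0), zero_variance=zero,
            )
    if stats is None and not per_class_stats:
        stats = estimate_gene_stats(dataset)
    if genes is not None:
        genes = tuple(genes)
    elif per_class_stats:
        # a gene must have positive variance in every class
        zero_union = {g for s in per_class_stats.values() for g in s.zero_variance}
        genes = tuple(g for g in dataset.genes if g not in zero_union)
    else:
        genes = stats.retained
    cls1, cls2 = dataset.classes
    if guiding_class is not None:
        if guiding_class not in (cls1, cls2):
            raise ValueError(f"guiding class {guiding_class!r} not among {dataset.classes}")
        if guiding_class == cls2:
            cls1, cls2 = cls2, cls1
    nets: dict[str, list[WigaNetwork]] = {cls1: [], cls2: []}
    for sample in dataset.samples:
        sample_stats = per_class_stats.get(str(dataset.labels[sample]), stats)
        net = build_wiga_network(
            dataset.values[sample], sample_stats, tau_r, genes,
            sample_id=sample, label=str(dataset.labels[sample]),
            strength_map=strength_map, relevance_method=relevance_method,
            quadrature_cells=quadrature_cells,
        )
        nets[net.label].append(net)
    return NetworkSet(n1=tuple(nets[cls1]), n2=tuple(nets[cls2]))


# ---------------------------------------------------------------------------
# occurrence / incidence


def pattern_occurs(pattern: Pattern, network: WigaNetwork) -> bool:
    """True iff every pattern edge is present in the network (unique match)."""
    return all(e in network.weights for e in pattern.edges)


def match_value(pattern: Pattern, network: WigaNetwork) -> float:
    """Mean edge weight of the (unique) match; error if the pattern does not occur."""
    if not pattern_occurs(pattern, network):
        raise ValueError(f"pattern {pattern.edges} does not occur in {network.sample_id}")
    return float(np.mean([network.weights[e] for e in pattern.edges]))


def incidence(pattern: Pattern, networks: Sequence[WigaNetwork]) -> float:
    """Sum of match values over the networks where the pattern occurs."""
    return float(sum(match_value(pattern, n) for n in networks if pattern_occurs(pattern, n)))


def n_x_of(n_networks: int, x: float) -> int:
    """Support threshold: ceil(x% of the collection size)."""
    if not 0.0 < x <= 100.0:
        raise ValueError(f"x must be in (0, 100]: {x}")
    return math.ceil(x / 100.0 * n_networks)


def incidence_at_x(
    pattern: Pattern, networks: Sequence[WigaNetwork], x: float
) -> tuple[float, bool]:
    """Sum of the n_x largest match values, or (0, null=True) if support < n_x.

    Ties in match value are broken by sample-identifier order (deterministic).
    """
    n_x = n_x_of(len(networks), x)
    matches = sorted(
        ((match_value(pattern, n), n.sample_id) for n in networks if pattern_occurs(pattern, n)),
        key=lambda t: (-t[0], t[1]),
    )
    if len(matches) < n_x:
        return 0.0, True
    return float(sum(v for v, _ in matches[:n_x])), False


@dataclasses.dataclass(frozen=True)
class IncidenceProfile:
    """Per-population support, incidence and incidence-at-x% of one pattern."""

    support1: int
    support2: int
    incidence1: float
    incidence2: float
    s_hat1: float
    s_hat2: float
    null1: bool
    null2: bool
    n_x1: int
    n_x2: int

    @property
    def s_hat_total(self) -> float:
        return self.s_hat1 + self.s_hat2


def incidence_profile(pattern: Pattern, networkset: NetworkSet, x: float) -> IncidenceProfile:
    """Full per-population incidence bookkeeping; x% is taken of each population size."""
    vals = {}
    for name, pop in (("1", networkset.n1), ("2", networkset.n2)):
        occ = [(match_value(pattern, n), n.sample_id) for n in pop if pattern_occurs(pattern, n)]
        occ.sort(key=lambda t: (-t[0], t[1]))
        n_x = n_x_of(len(pop), x)
        null = len(occ) < n_x
        vals[name] = {
            "support": len(occ),
            "incidence": float(sum(v for v, _ in occ)),
            "s_hat": 0.0 if null else float(sum(v for v, _ in occ[:n_x])),
            "null": null,
            "n_x": n_x,
        }
    return IncidenceProfile(
        support1=vals["1"]["support"], support2=vals["2"]["support"],
        incidence1=vals["1"]["incidence"], incidence2=vals["2"]["incidence"],
        s_hat1=vals["1"]["s_hat"], s_hat2=vals["2"]["s_hat"],
        null1=vals["1"]["null"], null2=vals["2"]["null"],
        n_x1=vals["1"]["n_x"], n_x2=vals["2"]["n_x"],
    )


def connected_subpatterns(pattern: Pattern, proper: bool = True) -> list[Pattern]:
    """All connected (proper) subpatterns, enumerated exhaustively."""
    edges = pattern.edges
    out = []
    max_r = len(edges) - 1 if proper else len(edges)
    for r in range(1, max_r + 1):
        for combo in itertools.combinations(edges, r):
            if _connected(combo):
                out.append(Pattern(edges=tuple(sorted(combo))))
    return out
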