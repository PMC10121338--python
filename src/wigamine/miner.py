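"""Top-k discriminative pattern search.

Depth-first mining seeded from every edge present in at least one
guiding-population network.  Each pattern is extended one edge at a time
(either closing an edge between two pattern nodes or reaching one new node),
extensions are ranked by decreasing incidence, discriminative extensions are
recorded, and a branch is abandoned when the admissible upper bound of an
extension falls below the power of the pattern it extends — every deeper
pattern would then fail the discriminative test against that ancestor.  After
the search, non-maximal patterns are removed and the k highest-power patterns
are returned (ties: larger total incidence-at-x%, then canonical key).

`brute_force_mine` is the independent reference: it enumerates the entire
search space without pruning and applies the definitions directly.
"""

from __future__ import annotations

import dataclasses
import logging

from .scoring import (
    ScoredPattern,
    is_discriminative,
    score_pattern,
)
from .wiga import Edge, NetworkSet, Pattern, is_subpattern

__all__ = [
    "MiningConfig",
    "MiningState",
    "get_seed_edges",
    "rank_extensions",
    "pattern_mine",
    "prune_maximal",
    "top_k_patterns",
    "brute_force_mine",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class MiningConfig:
    """Knobs of the mining run.

    tau_r
        Relevance threshold for network edges (used upstream; recorded here
        for provenance).
    x_percent
        Incidence-at-x% percentage; the support threshold per population is
        ceil(x% of that population's size).
    k
        Number of patterns returned.
    max_nodes
        Maximum pattern size in genes.
    direction
        ``forward``: population 1 guides; ``reverse``: population 2 guides.
    extension_metric
        Incidence used to rank extensions: ``all`` (raw incidence over both
        populations, default), ``guiding`` (guiding population only) or
        ``x_percent`` (total incidence at x%).
    cascade_prune
        When an extension fails the bound gate, skip all later (lower-ranked)
        extensions as well.  Off by default: it assumes the bound is monotone
        in the ranking metric, which holds on all test instances but is not
        proven for this bound; treat as a heuristic accelerator.
    require_guiding_enrichment
        Record a pattern only if its incidence rate at x% in the guiding
        population is at least the other population's
        (s_hat1 / |N1| >= s_hat2 / |N2|).  The conditional-entropy gain is
        invariant under swapping the two populations, so this condition is
        what makes the two mining directions characterize different
        populations; the search itself is not restricted by it.
    """

    tau_r: float = 0.9
    x_percent: float = 20.0
    k: int = 20
    max_nodes: int = 10
    direction: str = "forward"
    log_base: float = 2.0
    exhaustive_limit: int = 12
    cascade_prune: bool = False
    bound_grid_step: float = 0.01
    use_bound_pruning: bool = True
    extension_metric: str = "all"
    strength_map: str = "clamp"
    require_guiding_enrichment: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.x_percent <= 100.0:
            raise ValueError(f"x_percent must be in (0, 100]: {self.x_percent}")
        if not 0.0 <= self.tau_r < 1.0:
            raise ValueError(f"tau_r must be in [0, 1): {self.tau_r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_nodes < 2:
            raise ValueError("max_nodes must be >= 2")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward|reverse: {self.direction!r}")
        if self.extension_metric not in ("all", "guiding", "x_percent"):
            raise ValueError(f"unknown extension metric: {self.extension_metric!r}")


class _EdgeIndex:
    """Posting lists and weights for fast incidence profiles.

    Per population: edge -> sorted tuple of network positions containing it,
    plus each network's weight map and sample id.  A pattern's occurrence set
    is the intersection of its edges' posting lists, so profiles cost
    O(edges * occurrences) instead of a scan over every network.
    """

    def __init__(self, networkset: NetworkSet, x: float):
        from .wiga import n_x_of

        self.x = x
        self.pops = []
        for pop in (networkset.n1, networkset.n2):
            posting: dict[Edge, set[int]] = {}
            for i, net in enumerate(pop):
                for e in net.weights:
                    posting.setdefault(e, set()).add(i)
            self.pops.append(
                {
                    "nets": pop,
                    "posting": {e: frozenset(s) for e, s in posting.items()},
                    "n_x": n_x_of(len(pop), x),
                }
            )
        # union adjacency for extension candidates
        self.adjacency: dict[str, set[Edge]] = {}
        for net in networkset.all_networks:
            for e in net.weights:
                self.adjacency.setdefault(e[0], set()).add(e)
                self.adjacency.setdefault(e[1], set()).add(e)

    def _occurrences(self, edges, pop) -> list[int]:
        posting = pop["posting"]
        sets = []
        for e in edges:
            s = posting.get(e)
            if not s:
                return []
            sets.append(s)
        sets.sort(key=len)
        occ = set(sets[0])
        for s in sets[1:]:
            occ &= s
            if not occ:
                return []
        return sorted(occ)

    def profile(self, pattern: Pattern):
        from .wiga import IncidenceProfile

        vals = []
        for pop in self.pops:
            nets = pop["nets"]
            occ = self._occurrences(pattern.edges, pop)
            matches = []
            inv = 1.0 / len(pattern.edges)
            for i in occ:
                w = nets[i].weights
                matches.append((sum(w[e] for e in pattern.edges) * inv, nets[i].sample_id))
            matches.sort(key=lambda t: (-t[0], t[1]))
            n_x = pop["n_x"]
            null = len(matches) < n_x
            vals.append(
                {
                    "support": len(matches),
                    "incidence": float(sum(v for v, _ in matches)),
                    "s_hat": 0.0 if null else float(sum(v for v, _ in matches[:n_x])),
                    "null": null,
                    "n_x": n_x,
                }
            )
        a, b = vals
        return IncidenceProfile(
            support1=a["support"], support2=b["support"],
            incidence1=a["incidence"], incidence2=b["incidence"],
            s_hat1=a["s_hat"], s_hat2=b["s_hat"],
            null1=a["null"], null2=b["null"],
            n_x1=a["n_x"], n_x2=b["n_x"],
        )


@dataclasses.dataclass
class MiningState:
    """Search bookkeeping: visited keys, accumulated results, counters."""

    visited: set = dataclasses.field(default_factory=set)
    results: dict = dataclasses.field(default_factory=dict)
    expanded: int = 0
    pruned_by_bound: int = 0
    pruned_by_duplicate: int = 0
    pruned_by_cascade: int = 0
    pruned_by_null: int = 0
    profile_cache: dict = dataclasses.field(default_factory=dict)
    index: _EdgeIndex | None = None

    def profiler(self, networkset: NetworkSet, x: float):
        if self.index is None:
            self.index = _EdgeIndex(networkset, x)
        return self.index.profile


def _oriented_networks(networkset: NetworkSet, config: MiningConfig) -> NetworkSet:
    """The networks with population 1 always the guiding one."""
    return networkset if config.direction == "forward" else networkset.swapped()


def get_seed_edges(guiding_networks) -> list[Pattern]:
    """One single-edge pattern per distinct edge in the guiding population."""
    edges: set[Edge] = set()
    for net in guiding_networks:
        edges |= net.edge_set
    return [Pattern(edges=(e,)) for e in sorted(edges)]


def _incidence_metric(profile, config: MiningConfig) -> float:
    if config.extension_metric == "all":
        return profile.incidence1 + profile.incidence2
    if config.extension_metric == "guiding":
        return profile.incidence1
    return profile.s_hat_total


def rank_extensions(
    pattern: Pattern,
    networkset: NetworkSet,
    config: MiningConfig,
    state: MiningState | None = None,
) -> list[Pattern]:
    """All one-edge extensions of ``pattern`` occurring in >= 1 network,
    sorted by decreasing incidence (ties by canonical key).

    ``networkset`` must already be oriented (population 1 = guiding).
    """
    from .wiga import incidence_profile

    if state is not None:
        profiler = state.profiler(networkset, config.x_percent)
        adjacency = state.index.adjacency
    else:
        profiler = None
        adjacency = {}
        for net in networkset.all_networks:
            for e in net.edge_set:
                adjacency.setdefault(e[0], set()).add(e)
                adjacency.setdefault(e[1], set()).add(e)

    nodes = set(pattern.nodes)
    current = set(pattern.edges)
    candidates: set[Edge] = set()
    for v in nodes:
        for e in adjacency.get(v, ()):
            if e in current:
                continue
            internal = e[0] in nodes and e[1] in nodes
            if not internal and len(nodes) >= config.max_nodes:
                continue  # would exceed the size cap with a new external node
            candidates.add(e)
    scored = []
    cache = state.profile_cache if state is not None else None
    for e in sorted(candidates):
        ext = pattern.extend(e)
        if cache is not None and (ext.key, "forward") in cache:
            prof = cache[(ext.key, "forward")][1]
        elif profiler is not None:
            prof = profiler(ext)
        else:
            prof = incidence_profile(ext, networkset, config.x_percent)
        if prof.support1 + prof.support2 == 0:
            continue
        scored.append((-_incidence_metric(prof, config), ext.key, ext))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [t[2] for t in scored]


def pattern_mine(
    pattern: Pattern,
    state: MiningState,
    config: MiningConfig,
    networkset: NetworkSet,
) -> MiningState:
    """Depth-first extension of ``pattern`` (already oriented network set).

    Records every discriminative extension; recurses into an extension only if
    its upper bound is at least the power of ``pattern``; with
    ``cascade_prune`` the first bound failure also discards all later
    extensions in the ranked list.  A branch whose support has fallen below
    the x% threshold in *both* populations is abandoned: every deeper pattern
    then has zero incidence at x% in both populations, hence power 0 and a
    total incidence tie it cannot win against its own subpatterns, so none is
    discriminative.
    """
    pow_p, _ = _pow_of(pattern, state, config, networkset)
    state.expanded += 1
    for ext in rank_extensions(pattern, networkset, config, state):
        key = ext.key
        seen = key in state.visited
        if not seen:
            state.visited.add(key)
            if _guiding_enriched(ext, state, config, networkset) and is_discriminative(
                ext, networkset, config.x_percent, "forward", config.log_base,
                config.exhaustive_limit, state.profile_cache,
                state.profiler(networkset, config.x_percent),
            ):
                state.results[key] = _score(ext, state, config, networkset)
        else:
            state.pruned_by_duplicate += 1
        _, prof = _pow_of(ext, state, config, networkset)
        if prof.null1 and prof.null2:
            state.pruned_by_null += 1
            continue
        if config.use_bound_pruning:
            sp = _score(ext, state, config, networkset)
            if sp.upper_bound < pow_p:
                state.pruned_by_bound += 1
                if config.cascade_prune:
                    state.pruned_by_cascade += 1
                    break
                continue
        if seen:
            continue
        pattern_mine(ext, state, config, networkset)
    return state


def _pow_of(pattern, state, config, networkset):
    from .scoring import _cached_pow

    return _cached_pow(
        pattern, networkset, config.x_percent, "forward", config.log_base,
        state.profile_cache, state.profiler(networkset, config.x_percent),
    )


def _guiding_enriched(pattern, state, config, networkset) -> bool:
    if not config.require_guiding_enrichment:
        return True
    _, prof = _pow_of(pattern, state, config, networkset)
    return prof.s_hat1 * len(networkset.n2) >= prof.s_hat2 * len(networkset.n1)


_SCORE_KEY = "__scored__"


def _score(pattern, state, config, networkset) -> ScoredPattern:
    cache = state.profile_cache.setdefault(_SCORE_KEY, {})
    if pattern.key in cache:
        return cache[pattern.key]
    powv, prof = _pow_of(pattern, state, config, networkset)
    from .scoring import power_upper_bound

    upper = power_upper_bound(
        pattern, networkset, config.x_percent, "forward", config.log_base,
        profile=prof, grid_step=config.bound_grid_step,
    )
    sp = ScoredPattern(
        pattern=pattern, profile=prof, pow=powv,
        upper_bound=max(upper, powv), direction=config.direction,
    )
    cache[pattern.key] = sp
    return sp


def prune_maximal(results: list[ScoredPattern]) -> list[ScoredPattern]:
    """Keep exactly the patterns with no strict superpattern in the set."""
    out = []
    for sp in results:
        if not any(
            other is not sp and is_subpattern(sp.pattern, other.pattern, strict=True)
            for other in results
        ):
            out.append(sp)
    return out


def _ranked(results: list[ScoredPattern]) -> list[ScoredPattern]:
    return sorted(results, key=lambda sp: (-sp.pow, -sp.profile.s_hat_total, sp.pattern.key))


def top_k_patterns(
    networkset: NetworkSet, k: int | None = None, config: MiningConfig | None = None
) -> list[ScoredPattern]:
    """Seeds -> depth-first mining -> maximality pruning -> top-k by power.

    Deterministic for a fixed input and configuration.  The returned
    ScoredPatterns are oriented so population 1 is the guiding one of
    ``config.direction``.
    """
    config = config or MiningConfig()
    if k is not None:
        config = dataclasses.replace(config, k=k)
    oriented = _oriented_networks(networkset, config)
    state = MiningState()
    seeds = get_seed_edges(oriented.n1)
    logger.info("mining: %d seed edges, direction=%s", len(seeds), config.direction)
    for seed in seeds:
        if seed.key not in state.visited:
            state.visited.add(seed.key)
            # single-edge seeds are vacuously discriminative
            if _guiding_enriched(seed, state, config, oriented):
                state.results[seed.key] = _score(seed, state, config, oriented)
        pattern_mine(seed, state, config, oriented)
    maximal = prune_maximal(list(state.results.values()))
    ranked = _ranked(maximal)
    logger.info(
        "mining done: expanded=%d pruned_bound=%d pruned_dup=%d results=%d maximal=%d",
        state.expanded, state.pruned_by_bound, state.pruned_by_duplicate,
        len(state.results), len(maximal),
    )
    return ranked[: config.k]


# ---------------------------------------------------------------------------
# reference miner


def brute_force_mine(
    networkset: NetworkSet, config: MiningConfig | None = None
) -> list[ScoredPattern]:
    """Exhaustive reference: every connected edge subset that occurs in >= 1
    network and contains >= 1 guiding-population edge, judged directly by the
    discriminative and maximality definitions, no pruning.

    Exponential; intended for small test instances only.
    """
    config = config or MiningConfig()
    oriented = _oriented_networks(networkset, config)
    guiding_edges = {e for net in oriented.n1 for e in net.edge_set}

    # grow all connected occurring subsets breadth-first with dedup
    from .wiga import incidence_profile

    all_edges = oriented.union_edges()
    frontier = {(e,) for e in all_edges}
    seen: set = set(frontier)
    all_sets: list[tuple[Edge, ...]] = sorted(frontier)
    while frontier:
        nxt = set()
        for key in frontier:
            pat = Pattern(edges=key)
            nodes = set(pat.nodes)
            for e in all_edges:
                if e in key:
                    continue
                a_in, b_in = e[0] in nodes, e[1] in nodes
                if not (a_in or b_in):
                    continue
                if not (a_in and b_in) and len(nodes) >= config.max_nodes:
                    continue
                new_key = tuple(sorted(set(key) | {e}))
                if new_key in seen:
                    continue
                prof = incidence_profile(Pattern(edges=new_key), oriented, config.x_percent)
                if prof.support1 + prof.support2 == 0:
                    continue
                seen.add(new_key)
                nxt.add(new_key)
        all_sets.extend(sorted(nxt))
        frontier = nxt

    cache: dict = {}
    results = []
    for key in all_sets:
        pat = Pattern(edges=key)
        if not guiding_edges & set(key):
            continue
        prof = incidence_profile(pat, oriented, config.x_percent)
        if prof.support1 + prof.support2 == 0:
            continue
        if config.require_guiding_enrichment and (
            prof.s_hat1 * len(oriented.n2) < prof.s_hat2 * len(oriented.n1)
        ):
            continue
        if is_discriminative(
            pat, oriented, config.x_percent, "forward", config.log_base,
            exhaustive_limit=64, profile_cache=cache,
        ):
            results.append(
                score_pattern(
                    pat, oriented, config.x_percent, "forward", config.log_base,
                    grid_step=config.bound_grid_step, profile=prof,
                )
            )
    results = [
        dataclasses.replace(sp, direction=config.direction) for sp in prune_maximal(results)
    ]
    return _ranked(results)
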