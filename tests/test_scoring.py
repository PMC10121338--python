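"""Entropy scoring, the discriminative predicate and the pruning bound."""

import numpy as np
import pytest

from tests.conftest import random_networkset
from wigamine.scoring import (
    conditional_entropy,
    discriminative_power,
    is_discriminative,
    is_maximal,
    population_entropy,
    power_upper_bound,
    score_pattern,
)
from wigamine.wiga import (
    Pattern,
    WigaNetwork,
    NetworkSet,
    connected_subpatterns,
    incidence_profile,
)


class TestEntropy:
    @pytest.mark.parametrize(
        "n1, n2, expected",
        [(5, 5, 1.0), (10, 0, 0.0), (3, 1, 0.8112781244591328)],
    )
    def test_population_entropy(self, n1, n2, expected):
        assert population_entropy(n1, n2) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_fatal(self):
        with pytest.raises(ValueError):
            population_entropy(-1, 3)

    def test_conditional_entropy_worked_case(self):
        # s1=2, s2=0, n1=n2=5: q=0.2, pure inside part, q2=3/8 outside
        h = conditional_entropy(2.0, 0.0, 5, 5)
        q2 = 3 / 8
        expected = 0.8 * (-(q2 * np.log2(q2) + (1 - q2) * np.log2(1 - q2)))
        assert h == pytest.approx(expected, abs=1e-12)
        assert h == pytest.approx(0.7635472023399721, abs=1e-10)

    def test_proportional_incidence_gives_zero_gain(self):
        # s1/n1 == s2/n2 reproduces the class split exactly
        for n1, n2, f in [(5, 5, 0.4), (6, 3, 0.5), (8, 2, 0.25)]:
            h = conditional_entropy(f * n1, f * n2, n1, n2)
            assert h == pytest.approx(population_entropy(n1, n2), abs=1e-12)

    def test_zero_incidence_reduces_to_population_entropy(self):
        assert conditional_entropy(0.0, 0.0, 5, 5) == pytest.approx(1.0)

    def test_swap_invariance(self, rng):
        """H(N|P) is invariant under swapping the two populations."""
        for _ in range(50):
            n1, n2 = rng.integers(1, 20, size=2)
            s1 = rng.uniform(0, n1)
            s2 = rng.uniform(0, n2)
            assert conditional_entropy(s1, s2, int(n1), int(n2)) == pytest.approx(
                conditional_entropy(s2, s1, int(n2), int(n1)), abs=1e-12
            )

    def test_entropy_range(self, rng):
        for _ in range(100):
            n1, n2 = (int(v) for v in rng.integers(1, 15, size=2))
            h = conditional_entropy(rng.uniform(0, n1), rng.uniform(0, n2), n1, n2)
            assert -1e-12 <= h <= 1.0 + 1e-12


class TestDiscriminativePower:
    def test_case_specific_pattern_has_positive_power(self, toy_networkset):
        p = Pattern.make([("a", "b")])  # occurs in cases only
        assert discriminative_power(p, toy_networkset, x=20.0) > 0

    def test_power_bounded_by_population_entropy(self, rng):
        for _ in range(20):
            ns = random_networkset(rng, n_nodes=5, n_networks=6)
            edges = sorted({e for n in ns.all_networks for e in n.weights})
            if not edges:
                continue
            p = Pattern.make([edges[0]])
            h = population_entropy(len(ns.n1), len(ns.n2))
            assert discriminative_power(p, ns, 20.0) <= h + 1e-12

    def test_log_base_preserves_ranking(self, rng):
        ns = random_networkset(rng, n_nodes=6, n_networks=8, p=0.4)
        edges = sorted({e for n in ns.all_networks for e in n.weights})
        pats = [Pattern.make([e]) for e in edges[:10]]
        pow2 = [discriminative_power(p, ns, 20.0, base=2.0) for p in pats]
        powe = [discriminative_power(p, ns, 20.0, base=np.e) for p in pats]
        assert np.argsort(pow2).tolist() == np.argsort(powe).tolist()

    def test_direction_swap_equals_population_swap(self, toy_networkset):
        p = Pattern.make([("b", "c")])
        fwd_on_swapped = discriminative_power(p, toy_networkset.swapped(), 20.0, "forward")
        rev = discriminative_power(p, toy_networkset, 20.0, "reverse")
        assert rev == pytest.approx(fwd_on_swapped, abs=1e-15)


class TestUpperBound:
    def test_bound_covers_pattern_itself(self, toy_networkset):
        for edges in [[("a", "b")], [("a", "b"), ("b", "c")]]:
            p = Pattern.make(edges)
            sp = score_pattern(p, toy_networkset, 20.0)
            assert sp.upper_bound >= sp.pow - 1e-12

    def test_bound_admissible_over_all_superpatterns(self, rng):
        """U(P) dominates the power of every enumerated connected superpattern."""
        checked = 0
        for _ in range(15):
            ns = random_networkset(rng, n_nodes=6, n_networks=8, p=0.35)
            edges = sorted({e for n in ns.all_networks for e in n.weights})
            if not edges:
                continue
            # enumerate every occurring connected pattern up to 4 edges
            univ = []
            frontier = [Pattern.make([e]) for e in edges]
            seen = {p.key for p in frontier}
            while frontier:
                univ.extend(frontier)
                nxt = []
                for p in frontier:
                    if len(p.edges) >= 4:
                        continue
                    nodes = set(p.nodes)
                    for e in edges:
                        if e in p.edges or (e[0] not in nodes and e[1] not in nodes):
                            continue
                        q = p.extend(e)
                        prof = incidence_profile(q, ns, 20.0)
                        if q.key not in seen and prof.support1 + prof.support2 > 0:
                            seen.add(q.key)
                            nxt.append(q)
                frontier = nxt
            occurring = [
                p for p in univ
                if incidence_profile(p, ns, 20.0).support1 + incidence_profile(p, ns, 20.0).support2 > 0
            ]
            for p in occurring[:40]:
                u = power_upper_bound(p, ns, 20.0)
                for q in occurring:
                    if set(p.edges) < set(q.edges):
                        assert u >= discriminative_power(q, ns, 20.0) - 1e-9
                        checked += 1
        assert checked > 100

    def test_degenerate_box_segment(self):
        """Support 0 in one population collapses the feasible box to a segment."""
        nodes = ("a", "b")
        n1 = tuple(
            WigaNetwork(sample_id=f"c{i}", label="", nodes=nodes, weights={("a", "b"): 0.8})
            for i in range(4)
        )
        n2 = tuple(
            WigaNetwork(sample_id=f"k{i}", label="", nodes=nodes, weights={})
            for i in range(4)
        )
        ns = NetworkSet(n1=n1, n2=n2)
        p = Pattern.make([("a", "b")])
        u = power_upper_bound(p, ns, 20.0)
        # the minimum over the [0, n_x] x {0} segment is at s1 = n_x = 1
        expected = population_entropy(4, 4) - conditional_entropy(1.0, 0.0, 4, 4)
        assert u == pytest.approx(expected, abs=1e-6)


class TestDiscriminativePredicate:
    def test_single_edge_vacuously_discriminative(self, toy_networkset):
        assert is_discriminative(Pattern.make([("c", "d")]), toy_networkset, 20.0)

    def test_two_edge_pattern_below_best_edge_rejected(self, toy_networkset):
        # a-b alone is case-pure; chaining b-c (common everywhere) dilutes the
        # top match values, so the chain cannot strictly beat its subpattern
        chain = Pattern.make([("a", "b"), ("b", "c")])
        pow_chain = discriminative_power(chain, toy_networkset, 20.0)
        subs = connected_subpatterns(chain, proper=True)
        best_sub = max(discriminative_power(s, toy_networkset, 20.0) for s in subs)
        if pow_chain <= best_sub:
            assert not is_discriminative(chain, toy_networkset, 20.0)

    def test_equal_power_larger_incidence_wins(self):
        """pow tie resolved by strictly larger total incidence at x%."""
        nodes = ("a", "b", "c")
        n1 = tuple(
            WigaNetwork(sample_id=f"c{i}", label="", nodes=nodes,
                        weights={("a", "b"): 1.0, ("b", "c"): 1.0})
            for i in range(2)
        )
        n2 = (WigaNetwork(sample_id="k0", label="", nodes=nodes, weights={}),
              WigaNetwork(sample_id="k1", label="", nodes=nodes, weights={}))
        ns = NetworkSet(n1=n1, n2=n2)
        chain = Pattern.make([("a", "b"), ("b", "c")])
        # all weights 1: chain and each edge have s_hat1 = n_x = 1, equal pow,
        # but the chain's total s_hat across populations is not larger -> tie fails
        assert not is_discriminative(chain, ns, 50.0)


class TestMaximality:
    def test_pairwise_inclusion(self):
        tri = Pattern.make([("a", "b"), ("b", "c"), ("a", "c")])
        edge = Pattern.make([("a", "b")])
        other = Pattern.make([("d", "e")])
        assert not is_maximal(edge, [edge, tri])
        assert is_maximal(tri, [edge, tri])
        assert is_maximal(other, [edge, tri, other])
        assert is_maximal(edge, [edge])

    def test_agrees_with_brute_force_inclusion(self, rng):
        import itertools as it

        nodes = list("abcde")
        pool = [tuple(sorted(p)) for p in it.combinations(nodes, 2)]
        pats = []
        for _ in range(25):
            k = int(rng.integers(1, 5))
            try:
                pats.append(Pattern.make([pool[i] for i in rng.choice(len(pool), k, replace=False)]))
            except ValueError:
                continue
        for p in pats:
            expected = not any(
                q.edges != p.edges and set(p.edges) < set(q.edges) for q in pats
            )
            assert is_maximal(p, pats) == expected
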