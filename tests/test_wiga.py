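"""Network construction and pattern/occurrence/incidence primitives."""

import itertools

import pytest

from wigamine.association import estimate_gene_stats, relevance
from wigamine.wiga import (
    NetworkSet,
    Pattern,
    WigaNetwork,
    build_wiga_network,
    incidence,
    incidence_at_x,
    incidence_profile,
    is_subpattern,
    match_value,
    n_x_of,
    normalize_strength,
    pattern_occurs,
)


class TestPattern:
    def test_canonicalization_and_connectivity(self):
        p = Pattern.make([("b", "a"), ("c", "b")])
        assert p.edges == (("a", "b"), ("b", "c"))
        assert p.nodes == ("a", "b", "c")
        with pytest.raises(ValueError, match="connected"):
            Pattern.make([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="self-loop"):
            Pattern.make([("a", "a")])

    def test_subpattern_relation(self):
        tri = Pattern.make([("a", "b"), ("b", "c"), ("a", "c")])
        edge = Pattern.make([("a", "b")])
        assert is_subpattern(edge, tri, strict=True)
        assert is_subpattern(tri, tri) and not is_subpattern(tri, tri, strict=True)
        assert not is_subpattern(tri, edge)

    def test_subpattern_agrees_with_set_inclusion(self, rng):
        nodes = list("abcde")
        pool = [tuple(sorted(p)) for p in itertools.combinations(nodes, 2)]
        for _ in range(50):
            k1, k2 = rng.integers(1, 6, size=2)
            try:
                p1 = Pattern.make([pool[i] for i in rng.choice(len(pool), k1, replace=False)])
                p2 = Pattern.make([pool[i] for i in rng.choice(len(pool), k2, replace=False)])
            except ValueError:
                continue
            assert is_subpattern(p1, p2) == (
                set(p1.edges) <= set(p2.edges) and set(p1.nodes) <= set(p2.nodes)
            )


class TestNormalizeStrength:
    @pytest.mark.parametrize(
        "rho, mapping, expected",
        [
            (0.7, "clamp", 0.7),
            (-0.3, "clamp", 0.0),
            (-0.3, "abs", 0.3),
            (-0.3, "affine", 0.35),
            (1.0, "affine", 1.0),
        ],
    )
    def test_mappings(self, rho, mapping, expected):
        assert normalize_strength(rho, mapping) == pytest.approx(expected)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            normalize_strength(1.5)


class TestBuildNetwork:
    def test_matches_pairwise_brute_force(self, small_dataset):
        """Edge set equals an exhaustive per-pair recomputation at tau_r."""
        stats = estimate_gene_stats(small_dataset)
        tau_r = 0.5
        sample = "s1"
        net = build_wiga_network(
            small_dataset.values[sample], stats, tau_r, sample_id=sample,
            relevance_method="bisection",
        )
        z = stats.standardize(small_dataset.values[sample], stats.retained)
        expected = {}
        for (i, gi), (j, gj) in itertools.combinations(enumerate(stats.retained), 2):
            score = relevance(z[i], z[j])
            if score.relevance > tau_r:
                expected[tuple(sorted((gi, gj)))] = max(score.strength, 0.0)
        assert set(net.weights) == set(expected)
        for e, w in expected.items():
            assert net.weights[e] == pytest.approx(w)

    def test_quadrature_and_bisection_agree(self, small_dataset):
        stats = estimate_gene_stats(small_dataset)
        a = build_wiga_network(small_dataset.values["s2"], stats, 0.5,
                               relevance_method="bisection", sample_id="s2")
        b = build_wiga_network(small_dataset.values["s2"], stats, 0.5,
                               relevance_method="quadrature", sample_id="s2")
        assert set(a.weights) == set(b.weights)

    def test_threshold_is_strict(self, small_dataset):
        """An edge whose relevance equals tau_r exactly is filtered out."""
        stats = estimate_gene_stats(small_dataset)
        sample = "s1"
        z = stats.standardize(small_dataset.values[sample], stats.retained)
        rels = {
            tuple(sorted((gi, gj))): relevance(z[i], z[j]).relevance
            for (i, gi), (j, gj) in itertools.combinations(enumerate(stats.retained), 2)
        }
        interior = {e: r for e, r in rels.items() if 0.0 < r < 1.0}
        edge, r = max(interior.items(), key=lambda kv: kv[1])
        net = build_wiga_network(
            small_dataset.values[sample], stats, tau_r=r, sample_id=sample,
            relevance_method="bisection",
        )
        assert edge not in net.weights

    def test_per_class_moments_switch(self, small_dataset):
        """Per-class standardization yields valid (generally different) networks."""
        from wigamine.wiga import build_network_set

        pooled = build_network_set(small_dataset, tau_r=0.5)
        per_class = build_network_set(small_dataset, tau_r=0.5, moments="per-class")
        assert len(per_class.all_networks) == len(pooled.all_networks)
        for net in per_class.all_networks:
            for (a, b), w in net.weights.items():
                assert a < b and 0.0 <= w <= 1.0
        with pytest.raises(ValueError, match="moments"):
            build_network_set(small_dataset, moments="robust")

    def test_empty_candidates_fatal(self, small_dataset):
        stats = estimate_gene_stats(small_dataset)
        with pytest.raises(ValueError, match="empty"):
            build_wiga_network(small_dataset.values["s1"], stats, 0.9, genes=())

    def test_weight_invariants(self, small_dataset):
        stats = estimate_gene_stats(small_dataset)
        net = build_wiga_network(small_dataset.values["s3"], stats, 0.1, sample_id="s3")
        for (a, b), w in net.weights.items():
            assert a < b and 0.0 <= w <= 1.0


class TestOccurrenceAndIncidence:
    def test_occurrence_is_edge_subset(self, toy_networkset):
        n1 = toy_networkset.n1
        p_ab = Pattern.make([("a", "b")])
        p_chain = Pattern.make([("a", "b"), ("b", "c")])
        assert pattern_occurs(p_ab, n1[0])
        assert pattern_occurs(p_chain, n1[0])
        assert not pattern_occurs(p_chain, toy_networkset.n2[0])

    def test_occurrence_brute_force_on_random_instances(self, rng):
        from tests.conftest import random_networkset

        for _ in range(20):
            ns = random_networkset(rng, n_nodes=6, n_networks=4)
            net = ns.all_networks[int(rng.integers(len(ns.all_networks)))]
            edges = sorted({e for n in ns.all_networks for e in n.weights})
            if not edges:
                continue
            k = int(rng.integers(1, min(4, len(edges)) + 1))
            chosen = [edges[i] for i in rng.choice(len(edges), k, replace=False)]
            try:
                p = Pattern.make(chosen)
            except ValueError:
                continue
            assert pattern_occurs(p, net) == set(p.edges).issubset(net.weights)

    def test_match_value_is_mean_weight(self, toy_networkset):
        net = toy_networkset.n1[0]
        p = Pattern.make([("a", "b"), ("a", "c")])
        assert match_value(p, net) == pytest.approx((0.9 + 0.8) / 2)
        single = Pattern.make([("b", "c")])
        assert match_value(single, net) == pytest.approx(0.7)
        with pytest.raises(ValueError, match="does not occur"):
            match_value(Pattern.make([("c", "d")]), net)

    def test_incidence_sums_match_values(self, toy_networkset):
        p = Pattern.make([("a", "b")])
        # occurs in all three case networks with weights 0.9, 0.8, 0.4
        assert incidence(p, toy_networkset.n1) == pytest.approx(2.1)
        assert incidence(Pattern.make([("a", "d")]), toy_networkset.n1) == 0.0

    def test_incidence_at_x_top_values(self):
        nodes = ("a", "b")
        nets = [
            WigaNetwork(sample_id=f"s{i}", label="", nodes=nodes,
                        weights=({("a", "b"): w} if w else {}))
            for i, w in enumerate([0.9, 0.8, 0.4, None, None, None, None, None, None, None])
        ]
        p = Pattern.make([("a", "b")])
        value, null = incidence_at_x(p, nets, 20.0)
        assert (value, null) == (pytest.approx(1.7), False)  # n_x = 2, top two of {0.9, 0.8, 0.4}
        value, null = incidence_at_x(p, nets[2:], 20.0)  # support 1 < n_x 2
        assert (value, null) == (0.0, True)

    def test_incidence_at_100_equals_incidence_when_everywhere(self):
        nodes = ("a", "b")
        nets = [
            WigaNetwork(sample_id=f"s{i}", label="", nodes=nodes, weights={("a", "b"): w})
            for i, w in enumerate([0.5, 0.25])
        ]
        p = Pattern.make([("a", "b")])
        value, null = incidence_at_x(p, nets, 100.0)
        assert not null and value == pytest.approx(incidence(p, nets))

    def test_n_x_rounding_is_ceiling(self):
        assert n_x_of(10, 20.0) == 2
        assert n_x_of(3, 20.0) == 1
        assert n_x_of(40, 20.0) == 8

    def test_property_incidence_bounds_on_random_patterns(self, rng):
        """s_hat <= min(s, n_x) and incidence <= support, every random pattern."""
        from tests.conftest import random_networkset

        for _ in range(30):
            ns = random_networkset(rng, n_nodes=6, n_networks=8)
            edges = sorted({e for n in ns.all_networks for e in n.weights})
            if not edges:
                continue
            e = edges[int(rng.integers(len(edges)))]
            p = Pattern.make([e])
            prof = incidence_profile(p, ns, 20.0)
            assert prof.incidence1 <= prof.support1 + 1e-12
            assert prof.incidence2 <= prof.support2 + 1e-12
            assert prof.s_hat1 <= min(prof.incidence1, prof.n_x1) + 1e-12
            assert prof.s_hat2 <= min(prof.incidence2, prof.n_x2) + 1e-12


class TestNetworkSet:
    def test_shared_universe_enforced(self, toy_networkset):
        odd = WigaNetwork(sample_id="x", label="", nodes=("a", "b"), weights={})
        with pytest.raises(ValueError, match="node universe"):
            NetworkSet(n1=(odd,), n2=toy_networkset.n2)

    def test_both_populations_required(self, toy_networkset):
        with pytest.raises(ValueError, match="non-empty"):
            NetworkSet(n1=toy_networkset.n1, n2=())
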