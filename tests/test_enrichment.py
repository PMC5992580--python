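"""Network clustering, term over-representation/assignment, and the
GO-term burden test."""

import itertools

import networkx as nx
import pytest

from famburden.enrichment import (
    GeneCluster,
    GoTerm,
    assign_term,
    build_network,
    find_clusters,
    over_representation_test,
    term_burden_test,
)
from famburden.stats import ContingencyTable2x2, fisher_one_tailed_greater
from famburden.variants import CohortDesign, Sample

from .conftest import make_variant


def brute_force_components(edges, nodes):
    """Reachability by repeated expansion; independent of networkx."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    seen, comps = set(), []
    for n in nodes:
        if n in seen:
            continue
        comp, frontier = {n}, {n}
        while frontier:
            frontier = {m for f in frontier for m in adj[f]} - comp
            comp |= frontier
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestFindClusters:
    def test_planted_clique_recovered(self):
        clique = [f"C{i}" for i in range(8)]
        edges = list(itertools.combinations(clique, 2)) + [("X1", "X2")]
        net = build_network(edges)
        clusters = find_clusters(net, clique + ["X1", "X2", "LONER"])
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(clique)

    def test_pairs_below_min_size(self):
        net = build_network([("A", "B"), ("C", "D")])
        assert find_clusters(net, ["A", "B", "C", "D"]) == []

    def test_ordering_by_size(self):
        big = [f"B{i}" for i in range(10)]
        small = [f"S{i}" for i in range(5)]
        edges = [(big[i], big[i + 1]) for i in range(9)]
        edges += [(small[i], small[i + 1]) for i in range(4)]
        clusters = find_clusters(build_network(edges), big + small)
        assert [c.size for c in clusters] == [10, 5]

    def test_components_match_reachability_oracle(self):
        # deterministic 50-node sparse graph
        nodes = [f"N{i}" for i in range(50)]
        edges = [(nodes[i], nodes[(i * 7 + 3) % 50]) for i in range(50)
                 if i != (i * 7 + 3) % 50]
        net = build_network(edges)
        ours = find_clusters(net, nodes, min_size=1)
        oracle = brute_force_components(edges, nodes)
        got = {c.members for c in ours}
        isolated = {frozenset({n}) for n in nodes if n not in net}
        assert got | isolated == oracle
        # disjointness
        seen = set()
        for c in ours:
            assert not (c.members & seen)
            seen |= c.members

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            find_clusters(build_network([("A", "B")]), [])


class TestOverRepresentation:
    def test_enumerated_tail(self):
        cluster = GeneCluster(frozenset(f"g{i}" for i in range(5)))
        background = frozenset(f"g{i}" for i in range(20))
        term = GoTerm("T", "t", frozenset(["g0", "g1", "g10", "g11"]))
        # overlap k=2, N=20, K=4, n=5 -> P(X>=2) = 3856/15504
        assert over_representation_test(cluster, term, background) == \
            pytest.approx(3856 / 15504, rel=1e-12)

    def test_zero_overlap_is_one(self):
        cluster = GeneCluster(frozenset(["a", "b"]))
        background = frozenset(["a", "b", "c", "d", "e", "f"])
        term = GoTerm("T", "t", frozenset(["c", "d"]))
        assert over_representation_test(cluster, term, background) == 1.0

    def test_perfect_overlap_most_extreme(self):
        background = frozenset(f"g{i}" for i in range(100))
        cluster = GeneCluster(frozenset(["g0", "g1", "g2"]))
        full = over_representation_test(
            cluster, GoTerm("T", "t", frozenset(["g0", "g1", "g2"])), background
        )
        partial = over_representation_test(
            cluster, GoTerm("U", "u", frozenset(["g0", "g1", "g50"])), background
        )
        assert full < partial

    def test_equals_fisher_on_2x2(self):
        background = frozenset(f"g{i}" for i in range(30))
        cluster = GeneCluster(frozenset(f"g{i}" for i in range(6)))
        term = GoTerm("T", "t", frozenset(f"g{i}" for i in range(3, 12)))
        k = len(cluster.members & term.genes)
        K = len(term.genes & background)
        table = ContingencyTable2x2(
            a=k, b=cluster.size - k, c=K - k,
            d=len(background) - cluster.size - (K - k),
        )
        assert over_representation_test(cluster, term, background) == \
            pytest.approx(fisher_one_tailed_greater(table), rel=1e-12)

    def test_cluster_outside_background_rejected(self):
        with pytest.raises(ValueError):
            over_representation_test(
                GeneCluster(frozenset(["zzz"])),
                GoTerm("T", "t", frozenset(["a"])),
                frozenset(["a", "b"]),
            )


class TestAssignTerm:
    def _setup(self):
        background = frozenset(f"g{i}" for i in range(500))
        cluster = GeneCluster(frozenset(f"g{i}" for i in range(8)))
        planted = GoTerm("GO:PLANT", "planted",
                         frozenset(f"g{i}" for i in range(20)))
        return background, cluster, planted

    def test_planted_term_wins_over_decoys(self):
        background, cluster, planted = self._setup()
        decoys = [
            GoTerm(f"GO:D{j}", "decoy",
                   frozenset(f"g{i}" for i in range(100 + 20 * j, 140 + 20 * j)))
            for j in range(5)
        ]
        res = assign_term(cluster, [planted] + decoys, background)
        assert res is not None and res.term.id == "GO:PLANT"
        assert res.adjusted_p == pytest.approx(min(res.raw_p * 6, 1.0))

    def test_size_window_skips_oversized_term(self):
        background, cluster, planted = self._setup()
        oversized = GoTerm("GO:BIG", "big",
                           frozenset(f"g{i}" for i in range(300)))
        res = assign_term(cluster, [oversized, planted], background)
        assert res is not None and res.term.id == "GO:PLANT"
        res2 = assign_term(cluster, [oversized], background)
        assert res2 is None

    def test_undersized_term_skipped(self):
        background, cluster, _ = self._setup()
        tiny = GoTerm("GO:TINY", "tiny", frozenset(f"g{i}" for i in range(8)))
        assert assign_term(cluster, [tiny], background) is None

    def test_nothing_significant_returns_none(self):
        background, cluster, _ = self._setup()
        weak = GoTerm("GO:WEAK", "weak",
                      frozenset(f"g{i}" for i in range(490, 500)) | {"g0"})
        assert assign_term(cluster, [weak], background) is None


def _two_family_design():
    return CohortDesign(
        samples=[
            Sample("A1", "FA", True), Sample("A2", "FA", True),
            Sample("B1", "FB", True), Sample("U1", "FA", False),
        ]
    )


def _lof(gene, pos, carriers):
    return make_variant(gene=gene, pos=pos, consequence="stop_gained",
                        genotypes={c: 1 for c in carriers})


class TestTermBurden:
    def test_delegation_identity(self):
        design = _two_family_design()
        term = GoTerm("T", "t", frozenset(["IN1", "IN2"]))
        case = (
            [_lof("IN1", p, ["A1"]) for p in range(1, 7)]
            + [_lof("OUT" + str(p), 100 + p, ["A1"]) for p in range(94)]
        )
        control = {"IN1": 6, "OUT1": 94}
        res = term_burden_test(term, case, design, control, control_size=100)
        assert res.table == ContingencyTable2x2(6, 94, 6, 94)
        assert res.p == pytest.approx(
            fisher_one_tailed_greater(ContingencyTable2x2(6, 94, 6, 94))
        )
        assert res.p >= 0.5  # identical proportions cannot look enriched

    def test_family_dedup_in_case_count(self):
        design = _two_family_design()
        term = GoTerm("T", "t", frozenset(["G1"]))
        shared = _lof("G1", 1, ["A1", "A2"])  # one family, counts once
        other = _lof("G2", 2, ["B1"])
        res = term_burden_test(term, [shared, other], design, {"G1": 1, "G2": 1},
                               control_size=100)
        assert res.case_count == 1
        assert res.table.a == 1 and res.table.b == 1

    def test_carrier_mode_denominators(self):
        design = _two_family_design()
        term = GoTerm("T", "t", frozenset(["G1"]))
        res = term_burden_test(term, [_lof("G1", 1, ["A1"])], design,
                               {"G1": 2}, control_size=100, mode="carrier")
        assert res.table == ContingencyTable2x2(1, 7, 2, 198)

    def test_zero_totals_raise(self):
        design = _two_family_design()
        term = GoTerm("T", "t", frozenset(["G1"]))
        with pytest.raises(ValueError, match="nonzero"):
            term_burden_test(term, [], design, {"G1": 0}, control_size=100)

    def test_gene_universe_restriction(self):
        design = _two_family_design()
        term = GoTerm("T", "t", frozenset(["G1", "HYPER"]))
        case = [_lof("G1", 1, ["A1"]), _lof("HYPER", 2, ["A1"]),
                _lof("G2", 3, ["B1"])]
        control = {"G1": 1, "HYPER": 50, "G2": 1}
        res = term_burden_test(
            term, case, design, control, control_size=100,
            gene_universe=frozenset(["G1", "G2"]),
        )
        assert res.case_count == 1 and res.control_count == 1
        assert res.table == ContingencyTable2x2(1, 1, 1, 1)
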