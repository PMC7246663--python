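"""Modularity, Louvain optimization, and the exhaustive-partition oracle."""

import random

import networkx as nx
import pytest

from comorbnet import (
    Partition,
    brute_force_best_partition,
    louvain,
    modularity,
    module_report,
)
from comorbnet.community import ModularityUndefinedError


def test_all_in_one_community_q_zero(two_cliques_bridge):
    g = two_cliques_bridge
    assert modularity(g, {u: 0 for u in g}) == pytest.approx(0.0, abs=1e-12)


def test_two_cliques_bridge_clique_partition(two_cliques_bridge):
    q = modularity(two_cliques_bridge, {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})
    assert q == pytest.approx(5 / 14, abs=1e-12)


def test_triangle_singletons():
    g = nx.complete_graph(3)
    assert modularity(g, {0: 0, 1: 1, 2: 2}) == pytest.approx(-1 / 3, abs=1e-12)


def test_modularity_invariant_under_relabelling(two_cliques_bridge):
    a = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
    b = {u: {0: 7, 1: -3}[c] for u, c in a.items()}
    assert modularity(two_cliques_bridge, a) == pytest.approx(
        modularity(two_cliques_bridge, b)
    )


def test_modularity_agrees_with_networkx_on_random_graphs():
    rng = random.Random(7)
    for _ in range(20):
        g = nx.gnp_random_graph(rng.randint(4, 12), 0.4, seed=rng.randint(0, 9999))
        if g.number_of_edges() == 0:
            continue
        for u, v in g.edges:
            g[u][v]["weight"] = rng.randint(1, 5)
        labels = {u: rng.randint(0, 2) for u in g}
        comms = [
            {u for u in g if labels[u] == c}
            for c in set(labels.values())
        ]
        assert modularity(g, labels) == pytest.approx(
            nx.community.modularity(g, comms, weight="weight"), abs=1e-10
        )


def test_modularity_undefined_without_edges():
    g = nx.empty_graph(3)
    with pytest.raises(ModularityUndefinedError):
        modularity(g, {u: 0 for u in g})
    with pytest.raises(ModularityUndefinedError):
        louvain(g, seed=0)


def test_louvain_recovers_two_cliques_any_seed(two_cliques_bridge):
    for seed in range(10):
        part = louvain(two_cliques_bridge, seed=seed)
        assert part.modularity == pytest.approx(5 / 14, abs=1e-12)
        assert part.assignment[0] == part.assignment[1] == part.assignment[2]
        assert part.assignment[3] == part.assignment[4] == part.assignment[5]
        assert part.assignment[0] != part.assignment[3]


def test_louvain_disjoint_cliques_each_their_own():
    g = nx.disjoint_union_all([nx.complete_graph(k) for k in (3, 4, 2)])
    part = louvain(g, seed=1)
    expected = {frozenset(c) for c in nx.connected_components(g)}
    found = {frozenset(c) for c in part.communities()}
    assert found == expected
    assert part.modularity == pytest.approx(
        brute_force_best_partition(g).modularity, abs=1e-12
    )


def test_louvain_deterministic_given_seed(two_cliques_bridge):
    g = nx.gnp_random_graph(20, 0.2, seed=5)
    a = louvain(g, seed=13)
    b = louvain(g, seed=13)
    assert a.assignment == b.assignment and a.modularity == b.modularity


def test_louvain_reported_q_consistent_with_modularity():
    g = nx.les_miserables_graph()
    part = louvain(g, seed=3)
    assert part.modularity == pytest.approx(
        modularity(g, part.assignment), abs=1e-12
    )
    # canonical labels: contiguous ints from 0 in first-appearance order
    seen = []
    for u in g.nodes:
        c = part.assignment[u]
        if c not in seen:
            seen.append(c)
    assert seen == list(range(len(seen)))


def test_louvain_isolated_nodes_get_singletons():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2)])
    g.add_node(99)
    part = louvain(g, seed=0)
    assert sum(1 for u, c in part.assignment.items()
               if c == part.assignment[99]) == 1


def test_oracle_dominates_louvain_on_small_graphs():
    rng = random.Random(99)
    worst = 0.0
    for trial in range(25):
        g = nx.gnp_random_graph(rng.randint(4, 8), 0.3, seed=rng.randint(0, 10**6))
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        bf = brute_force_best_partition(g)
        lv = louvain(g, seed=trial)
        assert lv.modularity <= bf.modularity + 1e-9
        worst = max(worst, bf.modularity - lv.modularity)
    assert worst <= 0.05


def test_oracle_single_edge_and_unique_optimum(two_cliques_bridge):
    g = nx.Graph([(0, 1)])
    part = brute_force_best_partition(g)
    assert part.n_communities == 1 and part.modularity == pytest.approx(0.0)
    part2 = brute_force_best_partition(two_cliques_bridge)
    assert part2.modularity == pytest.approx(5 / 14, abs=1e-12)
    assert part2.assignment == {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}


def test_oracle_path_graph_matches_networkx_exhaustive_check():
    # independent check: networkx modularity over the oracle's partition and
    # every 2-block contiguous split of the path
    g = nx.path_graph(5)  # 4 unit edges
    part = brute_force_best_partition(g)
    for cut in range(1, 5):
        split = {u: (0 if u < cut else 1) for u in g}
        assert part.modularity >= modularity(g, split) - 1e-12
    assert part.modularity == pytest.approx(
        modularity(g, part.assignment), abs=1e-12
    )


def test_oracle_refuses_large_graphs():
    with pytest.raises(ValueError, match="12 nodes"):
        brute_force_best_partition(nx.path_graph(13))


def test_module_report_orders_by_size_then_prevalence(two_cliques_bridge):
    g = two_cliques_bridge
    g.add_edge(5, 6)  # make one side bigger
    for u in g.nodes:
        g.nodes[u]["prevalence"] = 0.1 * (u + 1)
    part = Partition(
        {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1, 6: 1},
        modularity=modularity(g, {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1, 6: 1}),
    )
    rep = module_report(g, part)
    assert rep["size"].tolist() == [4, 4, 4, 4, 3, 3, 3]
    first = rep[rep["module"] == 1]
    assert first["disease"].tolist() == [6, 5, 4, 3]  # prevalence descending


def test_module_report_invariant_to_node_insertion_order():
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    g1 = nx.Graph()
    g1.add_edges_from(edges)
    g2 = nx.Graph()
    g2.add_nodes_from(reversed(range(6)))
    g2.add_edges_from(edges)
    p1, p2 = louvain(g1, seed=0), louvain(g2, seed=0)
    sets1 = {frozenset(c) for c in p1.communities()}
    sets2 = {frozenset(c) for c in p2.communities()}
    assert sets1 == sets2
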