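import itertools
import random

import numpy as np
import pytest

import oracles
from conftest import graph_from_edges, to_igraph
from volnet import (
    best_partition,
    composition_summary,
    generate_planted_sbm,
    modularity,
    walktrap_dendrogram,
)
from volnet.community import CommunityPartition


def _ari(a, b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(a, b)


class TestModularity:
    def test_single_community_is_zero(self, two_cliques_bridge):
        membership = {lab: 0 for lab in two_cliques_bridge.labels}
        assert modularity(two_cliques_bridge, membership) == pytest.approx(0.0)

    def test_two_triangles_with_bridge(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (0, 3)])
        membership = {g.labels[i]: (0 if i < 3 else 1) for i in range(6)}
        assert modularity(g, membership) == pytest.approx(5 / 14)

    def test_two_disjoint_triangles(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        membership = {g.labels[i]: (0 if i < 3 else 1) for i in range(6)}
        assert modularity(g, membership) == pytest.approx(0.5)

    def test_missing_label_rejected(self, triangle):
        with pytest.raises(ValueError, match="missing"):
            modularity(triangle, {triangle.labels[0]: 0})

    def test_matches_oracle_on_random_graphs(self):
        rng = random.Random(5)
        for _ in range(30):
            n = rng.randrange(4, 8)
            edges = oracles.random_connected_graph(n, rng)
            g = graph_from_edges(n, edges)
            membership_idx = [rng.randrange(3) for _ in range(n)]
            membership = {g.labels[i]: membership_idx[i] for i in range(n)}
            assert modularity(g, membership) == pytest.approx(
                oracles.modularity(n, edges, membership_idx)
            )


class TestWalktrap:
    def test_two_cliques_split_exactly(self, two_cliques_bridge):
        d = walktrap_dendrogram(two_cliques_bridge, t_steps=6)
        p = best_partition(d, two_cliques_bridge)
        assert p.n_communities == 2
        groups = {}
        for lab, c in p.membership.items():
            groups.setdefault(c, set()).add(lab)
        assert set(map(frozenset, groups.values())) == {
            frozenset(two_cliques_bridge.labels[:4]),
            frozenset(two_cliques_bridge.labels[4:]),
        }

    def test_single_clique_is_one_community(self):
        g = graph_from_edges(6, [(i, j) for i in range(6) for j in range(i + 1, 6)])
        p = best_partition(walktrap_dendrogram(g), g)
        assert p.n_communities == 1
        assert p.Q == pytest.approx(0.0)

    def test_invalid_steps_rejected(self, triangle):
        with pytest.raises(ValueError):
            walktrap_dendrogram(triangle, t_steps=0)

    def test_disconnected_components_never_merge(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        d = walktrap_dendrogram(g)
        assert len(d.merges) == g.n_nodes - 2  # n - c merges for c components
        p = best_partition(d, g)
        comp_a = {p.membership[g.labels[i]] for i in range(3)}
        comp_b = {p.membership[g.labels[i]] for i in range(3, 6)}
        assert comp_a.isdisjoint(comp_b)

    def test_merge_count_equals_n_minus_components(self, two_cliques_bridge):
        d = walktrap_dendrogram(two_cliques_bridge)
        assert len(d.merges) == two_cliques_bridge.n_nodes - 1

    def test_partition_q_equals_recomputed_modularity(self, two_cliques_bridge):
        p = best_partition(walktrap_dendrogram(two_cliques_bridge), two_cliques_bridge)
        assert p.Q == pytest.approx(modularity(two_cliques_bridge, p.membership))

    def test_increasing_steps_never_splits_a_clique(self, two_cliques_bridge):
        for t in (2, 4, 8, 12):
            p = best_partition(
                walktrap_dendrogram(two_cliques_bridge, t_steps=t), two_cliques_bridge
            )
            for clique in (two_cliques_bridge.labels[:4], two_cliques_bridge.labels[4:]):
                assert len({p.membership[lab] for lab in clique}) == 1

    def test_tracks_exhaustive_optimum_on_small_graphs(self):
        """On small unique-optimum graphs the best cut matches igraph's
        walktrap exactly and reaches the exhaustive modularity optimum in
        the large majority of cases (the agglomerative heuristic cannot
        guarantee the global optimum on every landscape)."""
        pytest.importorskip("igraph")
        rng = random.Random(11)
        unique = reached = 0
        for _ in range(50):
            n = rng.randrange(5, 8)
            edges = oracles.random_connected_graph(n, rng)
            g = graph_from_edges(n, edges)
            best_q, optima = oracles.best_modularity_partition(n, edges)
            if len(optima) > 1:
                continue
            unique += 1
            p = best_partition(walktrap_dendrogram(g), g)
            igg = to_igraph(g)
            ig_membership = igg.community_walktrap(steps=6).as_clustering().membership
            assert p.Q == pytest.approx(igg.modularity(ig_membership))
            if p.Q == pytest.approx(best_q):
                pred = [p.membership[lab] for lab in g.labels]
                assert _ari(list(optima[0]), pred) == pytest.approx(1.0)
                reached += 1
        assert unique >= 20
        assert reached / unique >= 0.6

    def test_matches_igraph_walktrap_on_planted_graphs(self):
        ig = pytest.importorskip("igraph")
        for seed in range(3):
            truth = generate_planted_sbm([12, 12, 12], 0.6, 0.05, seed)
            g = truth.graph
            ours = best_partition(walktrap_dendrogram(g, t_steps=6), g)
            theirs = to_igraph(g).community_walktrap(steps=6).as_clustering()
            ours_m = [ours.membership[lab] for lab in g.labels]
            assert _ari(ours_m, theirs.membership) == pytest.approx(1.0)

    def test_planted_sbm_recovery(self):
        truth = generate_planted_sbm([20] * 4, 0.5, 0.02, seed=0)
        p = best_partition(walktrap_dendrogram(truth.graph), truth.graph)
        pred = [p.membership[lab] for lab in truth.graph.labels]
        target = [truth.planted_membership[lab] for lab in truth.graph.labels]
        assert _ari(target, pred) >= 0.9


class TestComposition:
    def test_simple_counts(self, roster82):
        membership = {lab: (0 if lab.endswith("_l") else 1) for lab in roster82.labels}
        part = CommunityPartition(
            membership=membership, n_communities=2, Q=0.1, method_params={}
        )
        comp = composition_summary(part, roster82)
        assert comp["hemisphere_communities"]["LEFT"] == 1
        assert comp["hemisphere_communities"]["RIGHT"] == 1
        assert comp["by_hemisphere"].loc[0, "LEFT"] == 41
        assert comp["by_hemisphere"].loc[0, "RIGHT"] == 0  # zero rows present

    def test_unknown_label_rejected(self, roster82):
        part = CommunityPartition(
            membership={"nope_l": 0}, n_communities=1, Q=0.0, method_params={}
        )
        with pytest.raises(ValueError, match="not in roster"):
            composition_summary(part, roster82)

    def test_process_counts_cover_multi_membership(self, roster82):
        membership = {lab: 0 for lab in roster82.labels}
        part = CommunityPartition(
            membership=membership, n_communities=1, Q=0.0, method_params={}
        )
        comp = composition_summary(part, roster82)
        # A6m et al. belong to both Planning and Timing, counted in each
        assert comp["by_process"].loc[0, "PLANNING"] == 30
        assert comp["by_process"].loc[0, "TIMING"] == 14
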