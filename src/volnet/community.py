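"""Walktrap community detection, modularity, and composition summaries.

Walktrap is an agglomerative method built on short random walks: after t
steps a walk started inside a densely connected group tends to stay inside
it, so the t-step transition profiles of two nodes in the same community
are similar. Starting from singleton communities, the algorithm repeatedly
merges the pair of *adjacent* communities whose merge least increases the
mean squared walk-profile distance, recording the merge dendrogram and the
modularity of every intermediate partition. The partition kept is the one
of maximal modularity along the merge sequence.

Definitions used here (n nodes, m undirected edges, degrees d(k)):

* lazy transition matrix ``P = (D+I)^-1 (A+I)`` (unit self-loop on every
  vertex, as in the reference implementation); node profile = row of ``P^t``
* community profile = mean of member node profiles
* squared distance ``r2(A, B) = sum_k (pA_k - pB_k)^2 / (d(k)+1)``
* merge cost ``dsigma = (|A||B| / (|A|+|B|)) * r2(A, B) / n``
* modularity ``Q = sum_c [ m_c/m - (d_c/(2m))^2 ]``

Nodes of degree zero have no walk profile; they are pinned as singleton
communities and never merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_model import BrainGraph, Roster, VolitionalProcess, edge_count

__all__ = [
    "Dendrogram",
    "CommunityPartition",
    "walktrap_dendrogram",
    "best_partition",
    "modularity",
    "composition_summary",
]


@dataclass(frozen=True)
class Merge:
    community_a: int
    community_b: int
    height: float  # merge cost dsigma
    resulting_size: int
    modularity: float  # Q of the partition after this merge


@dataclass(frozen=True)
class Dendrogram:
    """Merge sequence over communities.

    Initial communities are numbered 0..n-1 in node order; the community
    created by merge k gets id n + k (scipy-linkage style). ``levels``
    holds the modularity of the partition *before* any merge (index 0) and
    after each merge.
    """

    n_nodes: int
    labels: tuple[str, ...]
    merges: tuple[Merge, ...]
    t_steps: int

    def membership_at(self, level: int) -> dict[str, int]:
        """Node -> community id after the first ``level`` merges (0-renumbered)."""
        parent = list(range(self.n_nodes + level))
        for k, mg in enumerate(self.merges[:level]):
            parent[mg.community_a] = self.n_nodes + k
            parent[mg.community_b] = self.n_nodes + k

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        roots: dict[int, int] = {}
        out = {}
        for i, lab in enumerate(self.labels):
            r = find(i)
            out[lab] = roots.setdefault(r, len(roots))
        return out


@dataclass(frozen=True)
class CommunityPartition:
    membership: dict[str, int]
    n_communities: int
    Q: float
    method_params: dict


def _transition_profiles(adj: np.ndarray, t_steps: int) -> np.ndarray:
    """Rows of P^t for the lazy walk P = (D+I)^-1 (A+I).

    A unit self-loop is added to every vertex before normalizing, as in
    the reference Walktrap implementation: the lazy walk is aperiodic, so
    profiles remain informative on bipartite-ish structures and short even
    cycles.
    """
    lazy = adj + np.eye(adj.shape[0])
    deg = lazy.sum(axis=1)
    return np.linalg.matrix_power(lazy / deg[:, None], t_steps)


def walktrap_dendrogram(
    graph: BrainGraph, t_steps: int = 6, seed: int | None = None
) -> Dendrogram:
    """Build the Walktrap merge dendrogram with t-step walk profiles.

    The agglomeration is fully deterministic (ties broken by smallest
    community ids); ``seed`` is accepted for interface symmetry with the
    stochastic stages and ignored.
    """
    if t_steps < 1:
        raise ValueError("t_steps must be a positive integer")
    n = graph.n_nodes
    adj = graph.adjacency.astype(float)
    deg = adj.sum(axis=1)
    m = edge_count(graph)
    profiles_nodes = _transition_profiles(adj, t_steps)

    # active community state, keyed by community id; the distance
    # normalization uses the lazy-walk degrees d(k) + 1
    inv_deg = 1.0 / (deg + 1.0)
    profile = {i: profiles_nodes[i] for i in range(n)}
    size = {i: 1 for i in range(n)}
    members = {i: [i] for i in range(n)}
    # community-level edge counts: intra[c] and inter-community weights
    intra = {i: 0.0 for i in range(n)}
    between: dict[frozenset, float] = {}
    ii, jj = np.nonzero(np.triu(adj))
    for a, b in zip(ii.tolist(), jj.tolist()):
        between[frozenset((a, b))] = between.get(frozenset((a, b)), 0.0) + 1.0
    d_tot = {i: float(deg[i]) for i in range(n)}

    def dsigma(a: int, b: int) -> float:
        diff = profile[a] - profile[b]
        r2 = float(np.sum(diff * diff * inv_deg))
        return (size[a] * size[b]) / (size[a] + size[b]) * r2 / n

    # merge costs for adjacent pairs only (degree-0 nodes are not adjacent
    # to anything, so they stay singletons automatically)
    cost = {pair: dsigma(*sorted(pair)) for pair in between}

    def partition_Q() -> float:
        if m == 0:
            raise ValueError("modularity undefined for an edgeless graph")
        return sum(
            intra[c] / m - (d_tot[c] / (2 * m)) ** 2 for c in size
        )

    merges: list[Merge] = []
    next_id = n
    while cost:
        pair = min(cost, key=lambda p: (cost[p], sorted(p)))
        a, b = sorted(pair)
        new = next_id
        next_id += 1
        h = cost[pair]
        # merged profile = mean of member node profiles (incremental form)
        profile[new] = (size[a] * profile[a] + size[b] * profile[b]) / (
            size[a] + size[b]
        )
        size[new] = size[a] + size[b]
        members[new] = members[a] + members[b]
        intra[new] = intra[a] + intra[b] + between.pop(pair)
        d_tot[new] = d_tot[a] + d_tot[b]
        del cost[pair]
        # rewire neighbour bookkeeping
        neighbours = set()
        for old in (a, b):
            for p in [p for p in between if old in p]:
                (other,) = p - {old}
                between[frozenset((new, other))] = (
                    between.get(frozenset((new, other)), 0.0) + between.pop(p)
                )
                cost.pop(p, None)
                neighbours.add(other)
        for c in (a, b):
            del profile[c], size[c], members[c], intra[c], d_tot[c]
        for other in neighbours:
            cost[frozenset((new, other))] = dsigma(new, other)
        merges.append(
            Merge(
                community_a=a,
                community_b=b,
                height=h,
                resulting_size=size[new],
                modularity=partition_Q(),
            )
        )
    return Dendrogram(
        n_nodes=n, labels=graph.labels, merges=tuple(merges), t_steps=t_steps
    )


def best_partition(dendrogram: Dendrogram, graph: BrainGraph) -> CommunityPartition:
    """Cut the dendrogram at the modularity-maximal level.

    Level 0 is the all-singletons partition; level k the partition after k
    merges. Ties in Q are broken toward fewer communities (the later
    level).
    """
    m = edge_count(graph)
    q0 = modularity(graph, {lab: i for i, lab in enumerate(graph.labels)}) if m else 0.0
    q_levels = [q0] + [mg.modularity for mg in dendrogram.merges]
    best_level = max(range(len(q_levels)), key=lambda k: (q_levels[k], k))
    membership = dendrogram.membership_at(best_level)
    return CommunityPartition(
        membership=membership,
        n_communities=len(set(membership.values())),
        Q=q_levels[best_level],
        method_params={"t_steps": dendrogram.t_steps},
    )


def modularity(graph: BrainGraph, membership: dict[str, int]) -> float:
    """Newman modularity Q = sum_c [ m_c/m - (d_c/(2m))^2 ]."""
    missing = set(graph.labels) - set(membership)
    if missing:
        raise ValueError(f"membership missing labels: {sorted(missing)[:5]}")
    m = edge_count(graph)
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    comm = np.array([membership[lab] for lab in graph.labels])
    deg = graph.degrees
    q = 0.0
    for c in np.unique(comm):
        mask = comm == c
        m_c = graph.adjacency[np.ix_(mask, mask)].sum() / 2
        d_c = deg[mask].sum()
        q += m_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def composition_summary(
    partition: CommunityPartition, roster: Roster
) -> dict[str, pd.DataFrame]:
    """Community composition by hemisphere and by movement process.

    Returns ``by_hemisphere`` (community x hemisphere node counts,
    zero-filled), ``by_process`` (community x process node counts, nodes
    with several processes counted in each), and ``hemisphere_communities``
    (number of distinct communities touched by each hemisphere).
    """
    unknown = set(partition.membership) - set(roster.labels)
    if unknown:
        raise ValueError(f"partition labels not in roster: {sorted(unknown)[:5]}")
    comms = sorted(set(partition.membership.values()))
    hemis = ["LEFT", "RIGHT"]
    by_h = pd.DataFrame(0, index=comms, columns=hemis)
    by_p = pd.DataFrame(0, index=comms, columns=[p.name for p in VolitionalProcess])
    for lab, c in partition.membership.items():
        node = roster[lab]
        by_h.loc[c, node.hemisphere.name] += 1
        for p in node.processes:
            by_p.loc[c, p.name] += 1
    hemi_comms = pd.Series(
        {h: int((by_h[h] > 0).sum()) for h in hemis}, name="n_communities"
    )
    return {
        "by_hemisphere": by_h.rename_axis("community"),
        "by_process": by_p.rename_axis("community"),
        "hemisphere_communities": hemi_comms,
    }
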