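"""Synthetic graph generators for exercising the analysis pipeline.

The study's connectivity matrix comes from a curated atlas database and is
not distributable, so every pipeline stage is tested on generated graphs
instead: Erdős–Rényi and Watts–Strogatz graphs span the random and
small-world reference regimes used to interpret sigma, planted stochastic
block models give ground truth for community recovery, and
:func:`generate_volitional_like` emulates the regime of the real 82-node
volitional network (ordered-pair density ≈ 0.35, positive degree
assortativity, four planted communities with the right hemisphere split
across three of them and the left across two).

All generators are seed-deterministic: the same parameters and seed yield
a bit-identical graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_model import BrainGraph, Roster, bundled_roster, Hemisphere

__all__ = [
    "SyntheticTruth",
    "generate_er",
    "generate_ws",
    "generate_planted_sbm",
    "generate_volitional_like",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated graph with its planted ground truth."""

    graph: BrainGraph
    planted_membership: dict[str, int]
    generator_params: dict
    roster: Roster | None = field(default=None, compare=False)


def _default_labels(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"n{i:0{width}d}" for i in range(n))


def _graph_from_probabilities(
    labels: tuple[str, ...], prob: np.ndarray, rng: np.random.Generator
) -> BrainGraph:
    """Sample an undirected simple graph with per-pair edge probabilities."""
    n = len(labels)
    draw = rng.random((n, n))
    upper = np.triu(draw < prob, k=1)
    adj = (upper | upper.T).astype(np.uint8)
    return BrainGraph(labels=labels, adjacency=adj)


def generate_er(n: int, p: float, seed: int) -> BrainGraph:
    """Erdős–Rényi G(n, p): each unordered pair is an edge with probability p."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    prob = np.full((n, n), p)
    return _graph_from_probabilities(_default_labels(n), prob, rng)


def generate_ws(n: int, k_neighbors: int, p_rewire: float, seed: int) -> BrainGraph:
    """Watts–Strogatz ring lattice with random rewiring.

    Starts from a circulant lattice where every node links to its
    ``k_neighbors/2`` nearest neighbours on each side, then rewires each
    lattice edge with probability ``p_rewire`` to a uniformly random
    endpoint, skipping rewires that would create self-loops or duplicates.
    """
    if k_neighbors % 2 != 0:
        raise ValueError("k_neighbors must be even")
    if not 2 <= k_neighbors < n:
        raise ValueError("require 2 <= k_neighbors < n")
    if not 0.0 <= p_rewire <= 1.0:
        raise ValueError("p_rewire must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = _default_labels(n)
    adj = np.zeros((n, n), dtype=np.uint8)
    for off in range(1, k_neighbors // 2 + 1):
        for i in range(n):
            j = (i + off) % n
            adj[i, j] = adj[j, i] = 1
    for off in range(1, k_neighbors // 2 + 1):
        for i in range(n):
            j = (i + off) % n
            if rng.random() < p_rewire:
                new = int(rng.integers(0, n))
                if new == i or adj[i, new]:
                    continue
                adj[i, j] = adj[j, i] = 0
                adj[i, new] = adj[new, i] = 1
    return BrainGraph(labels=labels, adjacency=adj)


def generate_planted_sbm(
    block_sizes: list[int], p_in: float, p_out: float, seed: int
) -> SyntheticTruth:
    """Planted-partition stochastic block model.

    Within-block pairs connect with ``p_in``, between-block pairs with
    ``p_out`` (< p_in, otherwise the partition is not assortative and a
    domain error is raised). The block assignment is returned as truth.
    """
    if p_in <= p_out:
        raise ValueError("p_in must exceed p_out for a planted assortative partition")
    n = sum(block_sizes)
    labels = _default_labels(n)
    blocks = np.repeat(np.arange(len(block_sizes)), block_sizes)
    rng = np.random.default_rng(seed)
    same = blocks[:, None] == blocks[None, :]
    prob = np.where(same, p_in, p_out)
    graph = _graph_from_probabilities(labels, prob, rng)
    return SyntheticTruth(
        graph=graph,
        planted_membership={lab: int(b) for lab, b in zip(labels, blocks)},
        generator_params={
            "generator": "planted_sbm",
            "block_sizes": list(block_sizes),
            "p_in": p_in,
            "p_out": p_out,
            "seed": seed,
        },
    )


# --- volitional-like regime -------------------------------------------------

#: Target ordered-pair density of the emulated network.
_TARGET_DENSITY = 0.350798
#: Within- vs between-block relative edge propensity.
_W_IN, _W_OUT = 1.0, 0.12
#: Extra propensity multiplier for hub-hub pairs (two hub nodes per block).
_HUB_BOOST = 3.0
#: Left-hemisphere nodes split across planted blocks {0, 1}; right across
#: {0, 2, 3}; block 0 is bilateral (the large community of the real
#: network). Counts per (block, hemisphere): 41 nodes per hemisphere.
_LEFT_SPLIT = {0: 21, 1: 20}
_RIGHT_SPLIT = {0: 13, 2: 14, 3: 14}


def generate_volitional_like(seed: int) -> SyntheticTruth:
    """An 82-node surrogate of the volitional network's statistical regime.

    Nodes carry the packaged roster's labels, hemispheres, lobes and
    processes. Four blocks are planted with hemispheric asymmetry (left
    spans blocks 0-1, right spans blocks 0, 2, 3; block 0 bilateral with 34
    nodes). Pair probabilities follow a planted-partition kernel with two
    high-propensity "hub" roles per block, globally scaled so the expected
    ordered-pair density is 0.35; the block-density heterogeneity plus hub
    roles induce positive degree assortativity.
    """
    roster = bundled_roster()
    rng = np.random.default_rng(seed)
    left = [n.label for n in roster if n.hemisphere is Hemisphere.LEFT]
    right = [n.label for n in roster if n.hemisphere is Hemisphere.RIGHT]
    membership: dict[str, int] = {}
    pos = 0
    for block, count in _LEFT_SPLIT.items():
        for lab in left[pos : pos + count]:
            membership[lab] = block
        pos += count
    pos = 0
    for block, count in _RIGHT_SPLIT.items():
        for lab in right[pos : pos + count]:
            membership[lab] = block
        pos += count

    labels = tuple(roster.labels)
    blocks = np.array([membership[lab] for lab in labels])
    n = len(labels)
    same = blocks[:, None] == blocks[None, :]
    weight = np.where(same, _W_IN, _W_OUT)
    # two hub roles per block: first two members in roster order
    hubs = np.zeros(n, dtype=bool)
    for b in np.unique(blocks):
        hubs[np.nonzero(blocks == b)[0][:2]] = True
    weight[np.ix_(hubs, hubs)] *= _HUB_BOOST
    np.fill_diagonal(weight, 0.0)
    target_edges = _TARGET_DENSITY * n * (n - 1) / 2
    prob = np.clip(weight * (2 * target_edges / weight.sum()), 0.0, 0.99)
    graph = _graph_from_probabilities(labels, prob, rng)
    return SyntheticTruth(
        graph=graph,
        planted_membership=membership,
        generator_params={
            "generator": "volitional_like",
            "n": n,
            "target_density": _TARGET_DENSITY,
            "w_in": _W_IN,
            "w_out": _W_OUT,
            "hub_boost": _HUB_BOOST,
            "seed": seed,
        },
        roster=roster,
    )
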