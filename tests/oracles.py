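"""Independent brute-force oracles for tiny graphs.

Everything here is written by explicit enumeration over vertices, pairs,
paths and triangles — no shared code with the package — so it can serve as
ground truth for the implementation on graphs small enough to enumerate.
Graphs are passed as (n, edge set of (i, j) tuples with i < j).
"""

from __future__ import annotations

import itertools
import math
import random


def random_connected_graph(n: int, rng: random.Random) -> set[tuple[int, int]]:
    """A uniform-ish random connected simple graph: random spanning tree
    plus each remaining pair independently with probability 0.4."""
    nodes = list(range(n))
    rng.shuffle(nodes)
    edges = set()
    for i in range(1, n):
        a = nodes[i]
        b = nodes[rng.randrange(i)]
        edges.add((min(a, b), max(a, b)))
    for pair in itertools.combinations(range(n), 2):
        if pair not in edges and rng.random() < 0.4:
            edges.add(pair)
    return edges


def neighbors(n: int, edges: set[tuple[int, int]]) -> list[set[int]]:
    nb = [set() for _ in range(n)]
    for a, b in edges:
        nb[a].add(b)
        nb[b].add(a)
    return nb


def all_shortest_paths(n, edges, s, t):
    """All shortest s-t paths by exhaustive simple-path enumeration."""
    nb = neighbors(n, edges)
    paths = []

    def extend(path):
        if path[-1] == t:
            paths.append(list(path))
            return
        for w in nb[path[-1]]:
            if w not in path:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    if not paths:
        return []
    shortest = min(len(p) for p in paths)
    return [p for p in paths if len(p) == shortest]


def distances(n, edges):
    d = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0
        for s, t in itertools.combinations(range(n), 2):
            paths = all_shortest_paths(n, edges, s, t)
            if paths:
                d[s][t] = d[t][s] = len(paths[0]) - 1
    return d


def density(n, edges):
    return 2 * len(edges) / (n * (n - 1))


def mean_shortest_path_and_diameter(n, edges):
    d = distances(n, edges)
    finite = [
        d[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and math.isfinite(d[i][j])
    ]
    return sum(finite) / len(finite), max(finite)


def local_clustering(n, edges):
    nb = neighbors(n, edges)
    out = []
    for i in range(n):
        k = len(nb[i])
        if k < 2:
            out.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(sorted(nb[i]), 2) if (a, b) in edges
        )
        out.append(2 * links / (k * (k - 1)))
    return out


def transitivity(n, edges):
    nb = neighbors(n, edges)
    triangles = sum(
        1
        for a, b, c in itertools.combinations(range(n), 3)
        if (a, b) in edges and (a, c) in edges and (b, c) in edges
    )
    triples = sum(len(nb[i]) * (len(nb[i]) - 1) // 2 for i in range(n))
    return 3 * triangles / triples if triples else 0.0


def betweenness(n, edges):
    """Unnormalized betweenness, each unordered pair once, endpoints excluded."""
    bc = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(n, edges, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def closeness(n, edges):
    d = distances(n, edges)
    out = []
    for i in range(n):
        total = sum(d[i][j] for j in range(n) if j != i and math.isfinite(d[i][j]))
        out.append((n - 1) / total if total else 0.0)
    return out


def assortativity(n, edges):
    """Pearson correlation over ordered edge endpoint degrees, by the
    textbook sum formulas."""
    nb = neighbors(n, edges)
    deg = [len(nb[i]) for i in range(n)]
    xs, ys = [], []
    for a, b in edges:
        xs.extend([deg[a], deg[b]])
        ys.extend([deg[b], deg[a]])
    m = len(xs)
    mean_x = sum(xs) / m
    mean_y = sum(ys) / m
    cov = sum((x - mean_x) * (y - mean_y) for x, y in zip(xs, ys)) / m
    var_x = sum((x - mean_x) ** 2 for x in xs) / m
    var_y = sum((y - mean_y) ** 2 for y in ys) / m
    if var_x == 0 or var_y == 0:
        return None
    return cov / math.sqrt(var_x * var_y)


def modularity(n, edges, membership):
    m = len(edges)
    deg = [0] * n
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    q = 0.0
    for c in set(membership):
        nodes = [i for i in range(n) if membership[i] == c]
        m_c = sum(1 for a, b in edges if a in nodes and b in nodes)
        d_c = sum(deg[i] for i in nodes)
        q += m_c / m - (d_c / (2 * m)) ** 2
    return q


def best_modularity_partition(n, edges):
    """Exhaustive maximum-modularity partition (set partitions of n <= ~9).

    Returns (best_Q, list of all membership tuples achieving it, canonical
    block-count of optima)."""
    best_q = -math.inf
    best = []
    for membership in _set_partitions(n):
        q = modularity(n, edges, membership)
        if q > best_q + 1e-12:
            best_q, best = q, [membership]
        elif abs(q - best_q) <= 1e-12:
            best.append(membership)
    return best_q, best


def _set_partitions(n):
    """All set partitions of range(n) as canonical membership tuples
    (restricted growth strings)."""

    def rec(prefix, mx):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for c in range(mx + 2):
            yield from rec(prefix + [c], max(mx, c))

    yield from rec([0], 0)
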