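"""Node centrality measures.

Six measures per node — degree, betweenness, closeness, eigenvector, hubs
and authorities — held in a :class:`pandas.DataFrame` indexed by node label,
together with their max-normalized twins (each column divided by its
maximum, so values lie in [0, 1] and the top node scores exactly 1). The
normalized values feed the connectogram heat rings.

On an undirected graph the hubs, authorities and eigenvector scores
coincide after normalization; all three are still computed and reported
separately so the identity is visible in the output.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .network_model import BrainGraph

logger = logging.getLogger(__name__)

__all__ = ["RAW_MEASURES", "compute_centralities", "normalize_table", "write_centrality_tsv"]

#: Raw measure column names; each has a normalized twin "<name>_norm".
RAW_MEASURES = ["degree", "betweenness", "closeness", "eigenvector", "hubs", "authorities"]


class ConvergenceError(RuntimeError):
    """An iterative centrality failed to converge."""


def _betweenness(adj: np.ndarray) -> np.ndarray:
    """Shortest-path betweenness by pair-dependency accumulation (Brandes).

    Unnormalized; each unordered source-target pair counted once and
    endpoints excluded, i.e. the sum over s<t of the fraction of s-t
    shortest paths through each interior node.
    """
    n = adj.shape[0]
    neighbors = [np.nonzero(adj[v])[0] for v in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # BFS building the shortest-path DAG
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order = [s]
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for w in neighbors[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            order.extend(nxt)
            frontier = nxt
        # accumulate dependencies in reverse BFS order
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair was visited from both endpoints


def _closeness(dist: np.ndarray) -> np.ndarray:
    """Closeness (n-1)/sum_j d(i,j); component-scaled when disconnected.

    For a node reaching r others, returns (r / total_dist) * (r / (n-1)),
    which reduces to the plain formula on a connected graph.
    """
    n = dist.shape[0]
    out = np.zeros(n)
    for i in range(n):
        finite = np.isfinite(dist[i]) & (np.arange(n) != i)
        r = int(finite.sum())
        total = dist[i, finite].sum()
        if r > 0 and total > 0:
            out[i] = (r / total) * (r / (n - 1))
    return out


def _power_iteration(
    mat: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> np.ndarray:
    """Principal eigenvector by power iteration from a uniform positive start."""
    n = mat.shape[0]
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        y = mat @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return x  # no edges: stay at the uniform vector
        y /= norm
        if np.abs(y - x).max() < tol:
            return y
        x = y
    raise ConvergenceError("power iteration did not converge")


def _has_bipartite_component(adj: np.ndarray) -> bool:
    """True when some connected component with an edge is two-colorable.

    Bipartite components carry a symmetric +/-lambda adjacency spectrum, so
    power iteration on A oscillates and iteration on A^2 stalls inside the
    degenerate top eigenspace; both are cured by a unit diagonal shift.
    """
    n = adj.shape[0]
    color = np.full(n, -1)
    for start in range(n):
        if color[start] >= 0:
            continue
        color[start] = 0
        frontier = [start]
        has_edge = False
        bipartite = True
        while frontier:
            nxt = []
            for v in frontier:
                for w in np.nonzero(adj[v])[0]:
                    has_edge = True
                    if color[w] < 0:
                        color[w] = 1 - color[v]
                        nxt.append(w)
                    elif color[w] == color[v]:
                        bipartite = False
            frontier = nxt
        if has_edge and bipartite:
            return True
    return False


def _eigenvector_like(adj: np.ndarray, measure: str) -> np.ndarray:
    """Eigenvector / hubs / authorities scores, max-normalized.

    Hubs iterate A A^T and authorities A^T A; with a symmetric adjacency
    both collapse to the eigenvector measure, computed here by power
    iteration. When a bipartite component is present, a unit diagonal
    shift (A + I) is applied first: it shifts every eigenvalue by one,
    breaking the +/-lambda degeneracy without changing the eigenvectors or
    their ordering. The shift is also the fallback on plain
    non-convergence.
    """
    a = adj.astype(float)
    if _has_bipartite_component(a):
        logger.info("bipartite component detected; using unit diagonal shift for %s", measure)
        a = a + np.eye(a.shape[0])
    if measure == "hubs":
        mat = a @ a.T
    elif measure == "authorities":
        mat = a.T @ a
    else:
        mat = a
    try:
        vec = _power_iteration(mat)
    except ConvergenceError:
        logger.info("%s power iteration oscillated; applying unit diagonal shift", measure)
        try:
            vec = _power_iteration(mat + np.eye(mat.shape[0]))
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"{measure} centrality did not converge even with diagonal shift"
            ) from exc
    vec = np.abs(vec)
    top = vec.max()
    return vec / top if top > 0 else vec


def compute_centralities(graph: BrainGraph) -> pd.DataFrame:
    """All six centrality measures plus their max-normalized twins.

    Returns a DataFrame indexed by node label with columns ``degree``,
    ``betweenness``, ``closeness``, ``eigenvector``, ``hubs``,
    ``authorities`` and a ``*_norm`` twin for each. Disconnected graphs are
    handled per component (with a warning); closeness is then scaled by
    reachable-set size.
    """
    from .graph_metrics import path_metrics

    adj = graph.adjacency.astype(np.int64)
    pm = path_metrics(graph)
    if pm.disconnected:
        warnings.warn("graph is disconnected; centralities computed per component")
    table = pd.DataFrame(index=pd.Index(graph.labels, name="label"))
    table["degree"] = graph.degrees
    table["betweenness"] = _betweenness(adj)
    table["closeness"] = _closeness(pm.distance_matrix)
    table["eigenvector"] = _eigenvector_like(adj, "eigenvector")
    table["hubs"] = _eigenvector_like(adj, "hubs")
    table["authorities"] = _eigenvector_like(adj, "authorities")
    return normalize_table(table)


def normalize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append a max-normalized twin of every raw measure column.

    Each column is divided by its maximum, mapping values to [0, 1] with
    the top node at exactly 1. An all-zero column stays all-zero (warned).
    """
    out = table[RAW_MEASURES].copy()
    for col in RAW_MEASURES:
        top = out[col].max()
        if top > 0:
            out[col + "_norm"] = out[col] / top
        else:
            warnings.warn(f"centrality column {col!r} is all-zero; left unnormalized")
            out[col + "_norm"] = 0.0
    return out


def write_centrality_tsv(
    table: pd.DataFrame, roster, path, normalized: bool = False
) -> None:
    """Write the centrality table as TSV: code number, label, processes, measures."""
    cols = [m + "_norm" for m in RAW_MEASURES] if normalized else RAW_MEASURES
    out = table[cols].copy()
    out.insert(0, "code", range(1, len(out) + 1))
    out.insert(
        1,
        "processes",
        [
            ";".join(sorted(p.name for p in roster[lab].processes))
            for lab in out.index
        ],
    )
    out.to_csv(path, sep="\t", index=True, index_label="label")
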