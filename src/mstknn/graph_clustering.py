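"""Modified MST-kNN graph partitioning of correlated features.

The method clusters the rows (features) of an expression matrix by:

1. computing a sign-blind correlation distance ``d = 1 - |Spearman|``
   between every pair of features;
2. building a *q*-nearest-neighbour graph with ``q = floor(ln n) + 1``
   instead of the complete graph (escalating *q* until connected);
3. taking a minimum spanning tree of that graph, with each tree edge
   ``(a, b)`` annotated ``p = min(f(a,b), f(b,a))`` where ``f(a,b)`` is
   the 1-based position of *b* in *a*'s sorted nearest-neighbour list;
4. recursively partitioning each component with threshold
   ``t = floor(ln n_c)`` (``n_c`` = component size):

   - MINSIZE: components of at most ``min_size`` (default 3) nodes are
     terminal clusters;
   - C1: if ``p_max > t``, every edge with ``p > t`` is removed — these
     are exactly the edges whose endpoints are not within each other's
     *t* nearest neighbours;
   - C3: if ``p_max == 1`` or ``p_max == t``, the component is a cluster;
   - C2: otherwise (``1 < p_max < t``), the edges with the weakest
     mutual-neighbour support (``p == p_max``) are removed.

Edge annotations ``p`` are computed once from the full distance matrix
and never recomputed per component; only the threshold *t* adapts to
the component size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ClusteringResult

logger = logging.getLogger(__name__)

C2_POLICIES = ("pmax", "pmax-1")


@dataclass
class DistanceMatrix:
    """Pairwise correlation distance ``1 - |Spearman|`` between features."""

    ids: list[str]
    d: np.ndarray  # (n, n) symmetric, zero diagonal, values in [0, 1]

    @property
    def n(self) -> int:
        return len(self.ids)


def correlation_distance(X: pd.DataFrame) -> DistanceMatrix:
    """Distance oracle ``d(i, j) = 1 - |spearman(x_i, x_j)|``.

    Sign-blind by design: features that are strongly anti-correlated are
    as close as strongly positively correlated ones, which is what lets
    positively and negatively marker-correlated features share a
    cluster.  Constant features (undefined Spearman) are dropped with a
    warning.
    """
    if X.shape[1] < 3:
        raise ValueError(f"need at least 3 samples, got {X.shape[1]}")
    values = X.to_numpy(dtype=float)
    constant = np.all(values == values[:, :1], axis=1)
    if constant.any():
        dropped = list(X.index[constant])
        logger.warning("dropping %d constant feature(s): %s", len(dropped), dropped[:5])
        X = X.loc[~constant]
        values = values[~constant]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 non-constant features")
    # Spearman = Pearson on row-wise average ranks
    ranked = stats.rankdata(values, axis=1)
    rho = np.corrcoef(ranked)
    d = 1.0 - np.abs(rho)
    np.clip(d, 0.0, 1.0, out=d)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # enforce exact symmetry
    return DistanceMatrix(ids=list(X.index), d=d)


def neighbor_ranking(D: DistanceMatrix) -> np.ndarray:
    """1-based nearest-neighbour ranks ``f[a, b]`` for every ordered pair.

    For each node *a*, the other nodes are totally ordered by
    ``(d(a, .), node index)`` — ties broken toward the smaller index —
    and ``f[a, b]`` is *b*'s position in that order, in ``[1, n-1]``.
    The diagonal is 0 (a node does not rank itself).
    """
    n = D.n
    f = np.zeros((n, n), dtype=np.int64)
    for a in range(n):
        others = np.delete(np.arange(n), a)
        # lexsort: primary key distance, secondary key node index
        order = others[np.lexsort((others, D.d[a, others]))]
        f[a, order] = np.arange(1, n)
    return f


def initial_q(n: int) -> int:
    """Entry-point neighbourhood size ``q = floor(ln n) + 1``, at most n-1."""
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")
    return min(int(math.floor(math.log(n))) + 1, n - 1)


def build_qnn_graph(D: DistanceMatrix, q: int) -> nx.Graph:
    """Symmetrized q-nearest-neighbour graph over node indices.

    Edge ``{a, b}`` is present iff *b* is among *a*'s *q* nearest
    neighbours or vice versa; edge weight is ``d(a, b)``.  Connectivity
    is not guaranteed.
    """
    n = D.n
    if not 1 <= q <= n - 1:
        raise ValueError(f"q must be in [1, {n - 1}], got {q}")
    f = neighbor_ranking(D)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    mask = (f <= q) & (f >= 1)
    for a, b in zip(*np.nonzero(mask | mask.T)):
        if a < b:
            G.add_edge(int(a), int(b), weight=float(D.d[a, b]))
    return G


def ensure_connected(D: DistanceMatrix, q0: int | None = None) -> tuple[nx.Graph, int]:
    """Smallest ``q >= q0`` whose q-NN graph is connected.

    ``q = n - 1`` is the complete graph, so escalation always
    terminates.  Returns the graph and the *q* actually used.
    """
    if q0 is None:
        q0 = initial_q(D.n)
    for q in range(q0, D.n):
        G = build_qnn_graph(D, q)
        if nx.is_connected(G):
            if q > q0:
                logger.info("q escalated from %d to %d to connect the graph", q0, q)
            return G, q
    raise AssertionError("complete graph must be connected")  # pragma: no cover


def minimum_spanning_tree(G: nx.Graph) -> nx.Graph:
    """Deterministic Kruskal MST.

    Edges are considered in ascending ``(weight, min endpoint, max
    endpoint)`` order, so ties always break the same way and repeated
    runs yield the identical tree.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(G):
        raise ValueError("input graph is disconnected; call ensure_connected first")
    edges = sorted(
        (min(u, v), max(u, v), d["weight"]) for u, v, d in G.edges(data=True)
    )
    edges.sort(key=lambda e: (e[2], e[0], e[1]))
    uf = nx.utils.UnionFind(G.nodes)
    T = nx.Graph()
    T.add_nodes_from(G.nodes)
    for u, v, w in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            T.add_edge(u, v, weight=w)
            if T.number_of_edges() == G.number_of_nodes() - 1:
                break
    return T


def annotate_edges(T: nx.Graph, f: np.ndarray) -> nx.Graph:
    """Attach ``p = min(f(a,b), f(b,a))`` to every tree edge (in place).

    ``p`` measures mutual nearest-neighbour support: ``p = 1`` means at
    least one endpoint is the other's nearest neighbour; large ``p``
    means neither endpoint ranks the other highly.
    """
    n = f.shape[0]
    for a, b in T.edges:
        if a >= n or b >= n:
            raise ValueError(f"node {max(a, b)} missing from the neighbour ranking")
        T.edges[a, b]["p"] = int(min(f[a, b], f[b, a]))
    return T


def component_threshold(n_c: int) -> int:
    """Edge-elimination threshold ``t = floor(ln n_c)`` for one component."""
    if n_c < 2:
        raise ValueError(f"component must have at least 2 nodes, got {n_c}")
    return int(math.floor(math.log(n_c)))


def partition_forest(
    T: nx.Graph,
    min_size: int = 3,
    c2_policy: str = "pmax",
) -> tuple[list[frozenset[int]], list[tuple[int, str, int]]]:
    """Recursively partition an annotated spanning forest into clusters.

    Applies the MINSIZE / C1 / C3 / C2 case analysis per component until
    every component is terminal.  Returns the terminal components and a
    split log of ``(component_size, criterion, removed_edge_count)``.

    ``c2_policy`` selects which edges C2 removes: ``"pmax"`` (default)
    removes the edges with the weakest mutual-neighbour support
    (``p == p_max``); ``"pmax-1"`` removes edges with ``p == p_max - 1``
    and falls back to ``p_max`` when no such edge exists (otherwise the
    recursion could not make progress).
    """
    if c2_policy not in C2_POLICIES:
        raise ValueError(f"c2_policy must be one of {C2_POLICIES}")
    queue = sorted(
        (frozenset(c) for c in nx.connected_components(T)), key=min
    )
    terminal: list[frozenset[int]] = []
    log: list[tuple[int, str, int]] = []
    while queue:
        nodes = queue.pop(0)
        n_c = len(nodes)
        if n_c == 0:
            raise ValueError("empty component")
        if n_c <= min_size:
            log.append((n_c, "MINSIZE", 0))
            terminal.append(nodes)
            continue
        sub = T.subgraph(nodes)
        p_values = {(u, v): d["p"] for u, v, d in sub.edges(data=True)}
        p_max = max(p_values.values())
        t = component_threshold(n_c)
        if p_max > t:
            to_remove = [e for e, p in p_values.items() if p > t]
            criterion = "C1"
        elif p_max == 1 or p_max == t:
            log.append((n_c, "C3", 0))
            terminal.append(nodes)
            continue
        else:  # 1 < p_max < t
            target = p_max if c2_policy == "pmax" else p_max - 1
            to_remove = [e for e, p in p_values.items() if p == target]
            if not to_remove:
                to_remove = [e for e, p in p_values.items() if p == p_max]
            criterion = "C2"
        log.append((n_c, criterion, len(to_remove)))
        remaining = nx.Graph(sub)
        remaining.remove_edges_from(to_remove)
        pieces = sorted((frozenset(c) for c in nx.connected_components(remaining)), key=min)
        queue = pieces + queue  # depth-first, deterministic order
    return terminal, log


def cluster(
    X: pd.DataFrame,
    min_size: int = 3,
    q: int | None = None,
    c2_policy: str = "pmax",
) -> ClusteringResult:
    """Cluster the feature rows of an (assembled) expression matrix.

    Orchestrates the full pipeline: correlation distance, connected
    q-NN graph (``q = floor(ln n) + 1`` unless overridden, escalated
    until connected), deterministic MST, mutual-rank edge annotation,
    and recursive C1/C2/C3 partitioning.  Cluster ids are assigned
    contiguously from 0, ordered by each cluster's lexicographically
    smallest member, so repeated runs on identical input give identical
    results.
    """
    D = correlation_distance(X)
    G, q_used = ensure_connected(D, q0=q)
    logger.info("q-NN graph: n=%d, q=%d, %d edges", D.n, q_used, G.number_of_edges())
    T = minimum_spanning_tree(G)
    f = neighbor_ranking(D)
    annotate_edges(T, f)
    components, log = partition_forest(T, min_size=min_size, c2_policy=c2_policy)
    assignment: dict[str, int] = {}
    for cid, nodes in enumerate(components):
        for node in nodes:
            assignment[D.ids[node]] = cid
    result = ClusteringResult(assignment=assignment, split_log=log)
    return result.relabel_canonical()


def annotated_forest(X: pd.DataFrame, q: int | None = None) -> tuple[nx.Graph, int]:
    """The annotated spanning tree over feature ids (for export/inspection)."""
    D = correlation_distance(X)
    G, q_used = ensure_connected(D, q0=q)
    T = minimum_spanning_tree(G)
    annotate_edges(T, neighbor_ranking(D))
    return nx.relabel_nodes(T, dict(enumerate(D.ids))), q_used
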