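"""Graph-topology measures on binary graphs and per-density profiles.

Four measures characterise each thresholded network:

* modularity Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(g_i, g_j),
  maximised over partitions by deterministic greedy agglomeration with the
  configuration (degree-preserving) null model;
* clustering coefficient C_i = 2 t_i / (k_i (k_i - 1)) with t_i the number
  of triangles through node i, averaged over nodes;
* global efficiency E_glob = (1/(N(N-1))) sum_{i != j} 1 / d_ij with d_ij
  the shortest-path length (1/inf = 0 for disconnected pairs);
* local efficiency E_loc = (1/N) sum_i E_glob(G_i) where G_i is the
  subgraph induced on the neighbours of node i.

A :class:`TopologyProfile` collects these over the link-density sweep;
its per-metric vectors are the features later fed to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .networks import ThresholdedGraph, threshold_to_density

METRIC_NAMES = ("Q", "C_mean", "E_loc", "E_glob")


class ModularityError(ValueError):
    """Modularity is undefined (edgeless graph)."""


@dataclass
class Partition:
    """Community assignment g: node -> community id, ids contiguous from 0."""

    assignment: np.ndarray
    n_communities: int = field(default=0)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        labels = np.unique(self.assignment)
        if labels.size and (labels[0] != 0 or labels[-1] != labels.size - 1):
            # relabel to contiguous ids ordered by first appearance
            order: dict = {}
            for g in self.assignment:
                order.setdefault(int(g), len(order))
            self.assignment = np.array([order[int(g)] for g in self.assignment])
            labels = np.unique(self.assignment)
        self.n_communities = int(labels.size)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_communities)


def quality_of(graph: ThresholdedGraph, partition: Partition | np.ndarray) -> float:
    """Score an arbitrary partition with the modularity double sum.

    Q = (1/2m) sum_ij [A_ij - P_ij] delta(g_i, g_j), with the configuration
    null model P_ij = k_i k_j / (2m).
    """
    A = np.asarray(graph.adjacency, dtype=float)
    m2 = A.sum()
    if m2 == 0:
        raise ModularityError("modularity is undefined on an edgeless graph")
    g = partition.assignment if isinstance(partition, Partition) else np.asarray(partition)
    k = A.sum(axis=1)
    delta = (g[:, None] == g[None, :])
    B = A - np.outer(k, k) / m2
    return float((B * delta).sum() / m2)


def _quality_labels(A: np.ndarray, labels: np.ndarray, m2: float) -> float:
    k = A.sum(axis=1)
    delta = labels[:, None] == labels[None, :]
    return float(((A - np.outer(k, k) / m2) * delta).sum() / m2)


def _refine_partition(A: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style refinement: repeated sweeps in which every node
    is moved exactly once to its best target community (a fresh singleton
    allowed, negative gains permitted), keeping the best intermediate
    state of the sweep.  Sweeps repeat while Q improves.  Argmax ties
    resolve to the smallest (node, community) pair, so the procedure is
    deterministic.  Moving through negative-gain states lets the sweep
    escape local optima that single greedy moves cannot.
    """
    labels = Partition(assignment=labels).assignment.copy()
    k = A.sum(axis=1)
    m2 = A.sum()
    n = A.shape[0]
    q_best = _quality_labels(A, labels, m2)
    for _ in range(50):
        n_comm = int(labels.max()) + 2  # last slot = fresh community
        onehot = np.zeros((n, n_comm))
        onehot[np.arange(n), labels] = 1.0
        K = A @ onehot  # K[v, c] = edges from v into community c
        sigma = k @ onehot  # total degree per community
        cur = labels.copy()
        locked = np.zeros(n, dtype=bool)
        q_cur = q_best
        sweep_best_q, sweep_best = q_best, None
        for _step in range(n):
            k_own = K[np.arange(n), cur]
            sig_own = sigma[cur] - k
            gain = (K - k_own[:, None]) / (m2 / 2.0) - np.outer(k, np.ones(n_comm)) * (
                sigma[None, :] - sig_own[:, None]
            ) / (m2 * m2 / 2.0)
            gain[np.arange(n), cur] = -np.inf
            gain[locked, :] = -np.inf
            flat = int(np.argmax(gain))
            v, c = divmod(flat, n_comm)
            if not np.isfinite(gain[v, c]):
                break
            a = cur[v]
            K[:, a] -= A[:, v]
            K[:, c] += A[:, v]
            sigma[a] -= k[v]
            sigma[c] += k[v]
            q_cur += gain[v, c]
            cur[v] = c
            locked[v] = True
            if c == n_comm - 1:  # opened the fresh slot; provide a new one
                K = np.hstack([K, np.zeros((n, 1))])
                sigma = np.append(sigma, 0.0)
                n_comm += 1
            if q_cur > sweep_best_q + 1e-12:
                sweep_best_q, sweep_best = q_cur, cur.copy()
        if sweep_best is None:
            break
        labels = Partition(assignment=sweep_best).assignment
        q_best = _quality_labels(A, labels, m2)  # exact, no drift
    return labels


def _spectral_partition(A: np.ndarray) -> np.ndarray:
    """Leading-eigenvector recursive bisection of the modularity matrix.

    Each group is split by the sign of the leading eigenvector of its
    generalised modularity matrix, polished by deterministic single-node
    flips, and the split is kept only if it increases Q; eigenvector sign
    is fixed so the procedure is deterministic.
    """
    n = A.shape[0]
    k = A.sum(axis=1)
    m2 = A.sum()
    B = A - np.outer(k, k) / m2
    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        nodes = stack.pop()
        if nodes.size < 2:
            continue
        Bg = B[np.ix_(nodes, nodes)].copy()
        Bg -= np.diag(Bg.sum(axis=1))
        vals, vecs = np.linalg.eigh(Bg)
        if vals[-1] <= 1e-12:
            continue
        v = vecs[:, -1]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        s = np.where(v >= 0, 1.0, -1.0)
        # deterministic single-flip polishing of s^T Bg s
        for _ in range(2 * nodes.size):
            gains = -4.0 * s * (Bg @ s) + 4.0 * np.diag(Bg)
            best = int(np.argmax(gains))
            if gains[best] <= 1e-12:
                break
            s[best] = -s[best]
        dq = float(s @ Bg @ s) / (2.0 * m2)
        side = s > 0
        if dq <= 1e-12 or side.all() or (~side).all():
            continue
        labels[nodes[~side]] = next_label
        next_label += 1
        stack.append(nodes[side])
        stack.append(nodes[~side])
    return labels


def modularity(graph: ThresholdedGraph) -> tuple[float, Partition]:
    """Best-found partition by deterministic modularity maximisation.

    Two deterministic heuristics are run and the higher-Q result wins:
    (1) greedy agglomeration from singleton communities, repeatedly
    merging the pair with the largest gain dQ(a, b) = 2 (e_ab - a_a a_b)
    (ties broken by the smallest community-index pair) and keeping the
    best partition along the full merge path; (2) leading-eigenvector
    recursive bisection of the modularity matrix.  Both candidates are
    polished by deterministic single-node moves.  The all-in-one
    partition (Q = 0) is always a merge candidate, hence the returned Q
    is never negative.
    """
    A = np.asarray(graph.adjacency, dtype=float)
    n = A.shape[0]
    m2 = A.sum()
    if m2 == 0:
        raise ModularityError("modularity is undefined on an edgeless graph")
    # community-aggregated edge fractions E[a, b] = sum_{i in a, j in b} A_ij / 2m
    E = A / m2
    a = E.sum(axis=1)  # degree fraction per community
    parent = np.arange(n)  # community id of each original singleton
    active = np.ones(n, dtype=bool)

    labels = np.arange(n)
    best_labels = labels.copy()
    best_q = float(np.sum(np.diag(E)) - np.sum(a**2))  # singleton partition

    for _ in range(n - 1):
        # modularity gain for every active pair
        gain = 2.0 * (E - np.outer(a, a))
        gain[~active, :] = -np.inf
        gain[:, ~active] = -np.inf
        np.fill_diagonal(gain, -np.inf)
        g_max = gain.max()
        if not np.isfinite(g_max):
            break
        # smallest (a, b) among ties, upper triangle
        cand = np.argwhere(gain >= g_max - 1e-12)
        cand = cand[cand[:, 0] < cand[:, 1]]
        i, j = cand[np.lexsort((cand[:, 1], cand[:, 0]))[0]]
        # merge j into i
        E[i, :] += E[j, :]
        E[:, i] += E[:, j]
        a[i] += a[j]
        active[j] = False
        E[j, :] = 0.0
        E[:, j] = 0.0
        a[j] = 0.0
        labels = labels.copy()
        labels[labels == j] = i
        q = float(np.sum(np.diag(E)[active]) - np.sum(a[active] ** 2))
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels
    best_part = Partition(assignment=best_labels)
    candidates = [
        Partition(assignment=_refine_partition(A, best_part.assignment)),
        Partition(
            assignment=_refine_partition(A, _spectral_partition(A))
        ),
    ]
    for cand in candidates:
        q = quality_of(graph, cand)
        if q > best_q + 1e-12:
            best_q, best_part = q, cand
    return best_q, best_part


def exhaustive_modularity(graph: ThresholdedGraph, max_nodes: int = 10) -> tuple[float, Partition]:
    """Exact optimum by enumerating all partitions (test oracle, n <= max_nodes)."""
    n = graph.n_nodes
    if n > max_nodes:
        raise ValueError(f"exhaustive search limited to {max_nodes} nodes")
    best_q = -np.inf
    best: np.ndarray | None = None
    # enumerate set partitions via restricted growth strings
    labels = np.zeros(n, dtype=int)

    def rec(pos: int, n_used: int) -> None:
        nonlocal best_q, best
        if pos == n:
            q = quality_of(graph, labels)
            if q > best_q:
                best_q = q
                best = labels.copy()
            return
        for c in range(n_used + 1):
            labels[pos] = c
            rec(pos + 1, max(n_used, c + 1))

    rec(0, 0)
    assert best is not None
    return float(best_q), Partition(assignment=best)


def clustering(graph: ThresholdedGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient and its unweighted node average.

    C_i = 2 t_i / (k_i (k_i - 1)); nodes with degree < 2 have no neighbour
    pair and get C_i = 0.
    """
    A = np.asarray(graph.adjacency, dtype=float)
    k = A.sum(axis=1)
    # t_i = number of triangles through i = (A^3)_ii / 2
    t = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return c, float(c.mean())


def shortest_path_matrix(graph: ThresholdedGraph) -> np.ndarray:
    """All-pairs shortest-path lengths in edge counts (np.inf if unreachable)."""
    A = np.asarray(graph.adjacency, dtype=float)
    if A.sum() == 0:
        d = np.full(A.shape, np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return _csgraph_shortest_path(A, method="D", unweighted=True, directed=False)


def _efficiency_from_adjacency(A: np.ndarray) -> float:
    n = A.shape[0]
    if n < 2:
        return 0.0
    if A.sum() == 0:
        return 0.0
    d = _csgraph_shortest_path(A, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(graph: ThresholdedGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    return _efficiency_from_adjacency(np.asarray(graph.adjacency, dtype=float))


def local_efficiency(graph: ThresholdedGraph) -> float:
    """Average, over nodes, of the global efficiency of each node's
    neighbour-induced subgraph; nodes with < 2 neighbours contribute 0."""
    A = np.asarray(graph.adjacency, dtype=float)
    n = A.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size < 2:
            continue
        total += _efficiency_from_adjacency(A[np.ix_(nbrs, nbrs)])
    return total / n


@dataclass
class TopologyProfile:
    """Metric values over the density sweep for one entity (subject or group).

    ``metrics[name]`` is one value per density; ``c_node`` optionally holds
    the per-node clustering coefficients (densities x nodes).
    """

    entity_id: str
    densities: np.ndarray
    metrics: dict
    c_node: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        for name, series in self.metrics.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.densities.shape:
                raise ValueError(
                    f"metric {name!r} has {series.size} values for "
                    f"{self.densities.size} densities"
                )
            self.metrics[name] = series

    def __getitem__(self, name: str) -> np.ndarray:
        return self.metrics[name]


def topology_profile(
    weights: np.ndarray,
    densities,
    entity_id: str = "",
    region_names: list | None = None,
    which: tuple = METRIC_NAMES,
    ranking: str = "signed",
    keep_c_node: bool = False,
) -> TopologyProfile:
    """Threshold ``weights`` at each density and compute the requested metrics.

    ``which`` restricts the computation (local efficiency dominates the
    cost on large graphs); deterministic given its inputs.
    """
    densities = np.asarray(densities, dtype=float)
    out: dict = {name: np.empty(densities.size) for name in which}
    c_rows = [] if keep_c_node else None
    for di, d in enumerate(densities):
        g = threshold_to_density(weights, d, region_names=region_names, ranking=ranking)
        if "Q" in which:
            out["Q"][di] = modularity(g)[0]
        if "C_mean" in which or keep_c_node:
            c_node, c_mean = clustering(g)
            if "C_mean" in which:
                out["C_mean"][di] = c_mean
            if c_rows is not None:
                c_rows.append(c_node)
        if "E_glob" in which:
            out["E_glob"][di] = global_efficiency(g)
        if "E_loc" in which:
            out["E_loc"][di] = local_efficiency(g)
    return TopologyProfile(
        entity_id=entity_id,
        densities=densities,
        metrics=out,
        c_node=np.asarray(c_rows) if c_rows else None,
    )
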