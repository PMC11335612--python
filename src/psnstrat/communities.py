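"""Community detection on the patient similarity network.

Two detectors are provided, both implemented here rather than imported:

* :func:`louvain` — greedy two-phase weighted-modularity maximization
  (local node moves followed by graph aggregation, iterated until the
  modularity gain falls below tolerance). Node visit order is a seeded
  permutation per pass; ties in gain go to the lowest community id, so
  results are deterministic given the seed.
* :func:`bigclam` — overlapping cover by maximizing the cluster-
  affiliation log-likelihood
  ``l(F) = sum_{(u,v) in E} log(1 - exp(-F_u . F_v))
           - sum_{(u,v) not in E} F_u . F_v``
  over a nonnegative node-by-community strength matrix F, via projected
  gradient ascent per node with backtracking line search. A node belongs
  to community c when ``F[u, c] >= sqrt(-log(1 - 1/N))``.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import networkx as nx

from ._utils import round_half_up
from .errors import CoverageError, ParameterError

__all__ = [
    "Partition",
    "OverlappingCover",
    "modularity",
    "louvain",
    "bigclam",
    "module_size_table",
]

_TIE_EPS = 1e-12


@dataclass
class Partition:
    """Exclusive node -> module assignment with its achieved modularity."""

    assignment: dict[Hashable, int]
    modularity: float
    n_modules: int

    def __post_init__(self) -> None:
        ids = set(self.assignment.values())
        if ids and ids != set(range(len(ids))):
            raise ValueError("module ids must be contiguous from 0")
        self.n_modules = len(ids)

    @classmethod
    def from_assignment(
        cls, assignment: Mapping[Hashable, int], modularity: float = 0.0
    ) -> "Partition":
        """Relabel modules contiguously: largest first, ties by smallest
        member id — a canonical, order-independent labelling."""
        groups: dict[int, list] = defaultdict(list)
        for node, mod in assignment.items():
            groups[mod].append(node)
        ordered = sorted(
            groups.values(), key=lambda ns: (-len(ns), min(str(n) for n in ns))
        )
        relabelled = {
            node: idx for idx, nodes in enumerate(ordered) for node in nodes
        }
        return cls(relabelled, modularity, len(ordered))

    def communities(self) -> list[set]:
        out: list[set] = [set() for _ in range(self.n_modules)]
        for node, mod in self.assignment.items():
            out[mod].add(node)
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities()]

    def metadata(self) -> dict:
        return {"modularity": self.modularity, "n_modules": self.n_modules}


@dataclass
class OverlappingCover:
    """Overlapping node -> community-set cover from an affiliation matrix."""

    nodes: list
    strength: np.ndarray  # (n_nodes, n_communities), nonnegative
    memberships: dict[Hashable, frozenset[int]]
    log_likelihood: float
    threshold: float
    ll_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "log_likelihood": self.log_likelihood,
            "threshold": self.threshold,
            "memberships": {
                str(n): sorted(self.memberships[n]) for n in self.nodes
            },
        }


def _weighted_size(graph: nx.Graph) -> float:
    return sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))


def modularity(
    graph: nx.Graph,
    partition: Partition | Mapping[Hashable, int],
    resolution: float = 1.0,
) -> float:
    """Weighted Newman–Girvan modularity of a partition.

    ``Q = sum_c [ in_c / m  -  resolution * (tot_c / 2m)^2 ]`` where
    ``in_c`` is the internal edge weight of community c and ``tot_c``
    the summed weighted degree of its members. Exactly 0 for the
    all-in-one-module partition.
    """
    assignment = (
        partition.assignment if isinstance(partition, Partition) else partition
    )
    missing = [n for n in graph.nodes() if n not in assignment]
    if missing:
        raise CoverageError(f"{len(missing)} nodes missing from partition")
    m = _weighted_size(graph)
    if m <= 0:
        raise ParameterError("modularity requires a network with >= 1 edge")

    internal: dict[int, float] = defaultdict(float)
    for u, v, d in graph.edges(data=True):
        if assignment[u] == assignment[v]:
            internal[assignment[u]] += d.get("weight", 1.0)
    tot: dict[int, float] = defaultdict(float)
    for node, deg in graph.degree(weight="weight"):
        tot[assignment[node]] += deg

    q = 0.0
    for c in set(assignment.values()):
        q += internal.get(c, 0.0) / m - resolution * (tot.get(c, 0.0) / (2 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------


def _local_moves(
    adj: list[dict[int, float]],
    loops: list[float],
    m: float,
    rng: random.Random,
    resolution: float,
) -> tuple[list[int], bool]:
    """Phase 1: greedily move nodes between communities while any move
    strictly improves modularity. Returns (community of each node, moved?)."""
    n = len(adj)
    comm = list(range(n))
    k = [2.0 * loops[i] + sum(adj[i].values()) for i in range(n)]
    tot = k[:]
    order = list(range(n))
    any_move = False
    while True:
        moved = 0
        rng.shuffle(order)
        for u in order:
            cu = comm[u]
            neigh: dict[int, float] = defaultdict(float)
            for v, w in adj[u].items():
                neigh[comm[v]] += w
            tot[cu] -= k[u]
            # gain (scaled by m) of joining community c after removal
            stay = neigh.get(cu, 0.0) - resolution * tot[cu] * k[u] / (2.0 * m)
            best_c, best_gain = cu, stay
            for c in sorted(neigh):
                if c == cu:
                    continue
                gain = neigh[c] - resolution * tot[c] * k[u] / (2.0 * m)
                if gain > best_gain + _TIE_EPS:
                    best_c, best_gain = c, gain
            comm[u] = best_c
            tot[best_c] += k[u]
            if best_c != cu:
                moved += 1
        if moved == 0:
            break
        any_move = True
    return comm, any_move


def _aggregate(
    adj: list[dict[int, float]], loops: list[float], comm: list[int]
) -> tuple[list[dict[int, float]], list[float], dict[int, int]]:
    """Phase 2: collapse each community into a super-node."""
    labels = sorted(set(comm))
    relabel = {c: i for i, c in enumerate(labels)}
    n_new = len(labels)
    new_adj: list[dict[int, float]] = [defaultdict(float) for _ in range(n_new)]
    new_loops = [0.0] * n_new
    for u in range(len(adj)):
        cu = relabel[comm[u]]
        new_loops[cu] += loops[u]
        for v, w in adj[u].items():
            if v <= u:
                continue
            cv = relabel[comm[v]]
            if cu == cv:
                new_loops[cu] += w
            else:
                new_adj[cu][cv] += w
                new_adj[cv][cu] += w
    return [dict(a) for a in new_adj], new_loops, relabel


def _level_modularity(
    adj: list[dict[int, float]],
    loops: list[float],
    comm: list[int],
    m: float,
    resolution: float,
) -> float:
    internal: dict[int, float] = defaultdict(float)
    tot: dict[int, float] = defaultdict(float)
    for u in range(len(adj)):
        internal[comm[u]] += loops[u]
        tot[comm[u]] += 2.0 * loops[u] + sum(adj[u].values())
        for v, w in adj[u].items():
            if v > u and comm[u] == comm[v]:
                internal[comm[u]] += w
    return sum(
        internal[c] / m - resolution * (tot[c] / (2.0 * m)) ** 2 for c in internal
    )


def louvain(
    graph: nx.Graph,
    seed: int = 0,
    tolerance: float = 1e-7,
    resolution: float = 1.0,
) -> Partition:
    """Two-phase greedy modularity maximization over the weighted network.

    Deterministic given *seed*. The returned ``Partition.modularity`` is
    recomputed from scratch with :func:`modularity` on the input graph.
    """
    if graph.number_of_nodes() == 0:
        raise ParameterError("louvain requires a non-empty network")
    nodes = sorted(graph.nodes(), key=str)
    index = {node: i for i, node in enumerate(nodes)}
    m = _weighted_size(graph)
    if m <= 0:
        # edgeless network: every node its own module, Q undefined -> 0
        assignment = {node: i for i, node in enumerate(nodes)}
        return Partition.from_assignment(assignment, 0.0)

    adj: list[dict[int, float]] = [dict() for _ in nodes]
    loops = [0.0] * len(nodes)
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        iu, iv = index[u], index[v]
        if iu == iv:
            loops[iu] += w
        else:
            adj[iu][iv] = adj[iu].get(iv, 0.0) + w
            adj[iv][iu] = adj[iv].get(iu, 0.0) + w

    rng = random.Random(seed)
    # node i of the current level -> community label at that level
    membership = list(range(len(nodes)))  # original node -> current super-node
    q_prev = _level_modularity(adj, loops, list(range(len(adj))), m, resolution)
    while True:
        comm, moved = _local_moves(adj, loops, m, rng, resolution)
        if not moved:
            break
        q_now = _level_modularity(adj, loops, comm, m, resolution)
        adj, loops, relabel = _aggregate(adj, loops, comm)
        membership = [relabel[comm[s]] for s in membership]
        if q_now - q_prev < tolerance:
            break
        q_prev = q_now

    assignment = {node: membership[index[node]] for node in nodes}
    partition = Partition.from_assignment(assignment)
    partition.modularity = modularity(graph, partition, resolution)
    return partition


# ---------------------------------------------------------------------------
# BigClam
# ---------------------------------------------------------------------------

_F_MAX = 1e3
_PROB_FLOOR = 1e-10


def _node_objective(f: np.ndarray, neigh_f: np.ndarray, s_out: np.ndarray) -> float:
    if neigh_f.shape[0]:
        probs = 1.0 - np.exp(-neigh_f @ f)
        edge_term = float(np.sum(np.log(np.clip(probs, _PROB_FLOOR, None))))
    else:
        edge_term = 0.0
    return edge_term - float(f @ s_out)


def _node_gradient(f: np.ndarray, neigh_f: np.ndarray, s_out: np.ndarray) -> np.ndarray:
    if neigh_f.shape[0]:
        dots = neigh_f @ f
        expneg = np.exp(-dots)
        ratio = expneg / np.clip(1.0 - expneg, _PROB_FLOOR, None)
        grad = neigh_f.T @ ratio
    else:
        grad = np.zeros_like(f)
    return grad - s_out


def _global_log_likelihood(
    F: np.ndarray, edges: list[tuple[int, int]]
) -> float:
    col_sum = F.sum(axis=0)
    sq = float(col_sum @ col_sum) - float(np.einsum("ij,ij->", F, F))
    cross_all = sq / 2.0  # sum over unordered pairs of F_u . F_v
    edge_dots = np.array([F[u] @ F[v] for u, v in edges]) if edges else np.array([])
    probs = 1.0 - np.exp(-edge_dots)
    ll_edges = float(np.sum(np.log(np.clip(probs, _PROB_FLOOR, None))))
    return ll_edges - (cross_all - float(edge_dots.sum()))


def _ascend(
    F: np.ndarray,
    neighbors: list[np.ndarray],
    edges: list[tuple[int, int]],
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, list[float]]:
    n = F.shape[0]
    col_sum = F.sum(axis=0)
    trace = [_global_log_likelihood(F, edges)]
    for _ in range(max_iter):
        order = rng.permutation(n)
        for u in order:
            neigh_f = F[neighbors[u]]
            s_out = col_sum - F[u] - neigh_f.sum(axis=0)
            f_old = F[u]
            obj_old = _node_objective(f_old, neigh_f, s_out)
            grad = _node_gradient(f_old, neigh_f, s_out)
            step = 1.0
            for _bt in range(24):
                f_new = np.clip(f_old + step * grad, 0.0, _F_MAX)
                if _node_objective(f_new, neigh_f, s_out) > obj_old:
                    col_sum = col_sum + (f_new - f_old)
                    F[u] = f_new
                    break
                step *= 0.5
        ll = _global_log_likelihood(F, edges)
        trace.append(ll)
        if ll - trace[-2] < tol:
            break
    return F, trace


def bigclam(
    graph: nx.Graph,
    n_communities: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    restarts: int = 3,
) -> OverlappingCover:
    """Overlapping community cover by cluster-affiliation likelihood ascent.

    Runs *restarts* seeded random initializations and keeps the cover with
    the best log-likelihood. The accepted-step likelihood trace of the
    winning run is monotone non-decreasing by construction.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ParameterError("bigclam requires a non-empty network")
    if not 1 <= n_communities <= n:
        raise ParameterError(
            f"n_communities must be in [1, {n}], got {n_communities}"
        )
    nodes = sorted(graph.nodes(), key=str)
    index = {node: i for i, node in enumerate(nodes)}
    edges = sorted(
        (min(index[u], index[v]), max(index[u], index[v]))
        for u, v in graph.edges()
        if u != v
    )
    neighbors = [
        np.array(sorted(index[v] for v in graph.neighbors(node) if v != node), dtype=int)
        for node in nodes
    ]

    best: tuple[float, np.ndarray, list[float]] | None = None
    for child_seq in np.random.SeedSequence(seed).spawn(restarts):
        rng = np.random.default_rng(child_seq)
        F0 = rng.uniform(0.1, 1.0, size=(n, n_communities))
        F, trace = _ascend(F0, neighbors, edges, rng, max_iter, tol)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], F, trace)
    assert best is not None
    ll, F, trace = best

    if n > 1:
        eps = float(np.sqrt(-np.log(1.0 - 1.0 / n)))
    else:
        eps = 0.0
    memberships = {
        nodes[i]: frozenset(int(c) for c in np.where(F[i] >= eps)[0])
        for i in range(n)
    }
    return OverlappingCover(
        nodes=nodes,
        strength=F,
        memberships=memberships,
        log_likelihood=ll,
        threshold=eps,
        ll_trace=trace,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def module_size_table(partition: Partition) -> list[tuple[int, int, float]]:
    """(module id, size, share-of-network %) rows, largest module first;
    shares are percentages of the network node count rounded half-up to
    one decimal."""
    n = len(partition.assignment)
    sizes = partition.sizes()
    rows = [
        (mod, size, round_half_up(100.0 * size / n, 1))
        for mod, size in enumerate(sizes)
    ]
    return sorted(rows, key=lambda r: (-r[1], r[0]))
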