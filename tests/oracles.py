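"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, without
calling the implementation under test: direct all-pairs network
construction, exhaustive set-partition search for modularity, the
closed-form 2x2 chi-square identity, and direct probability-ratio
relative risk.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.stats import chi2 as chi2_dist


def brute_force_psn(records, main_threshold=0.8):
    """Direct all-pairs three-step construction (quadratic, small n only)."""

    def jac(a, b):
        union = a | b
        return len(a & b) / len(union) if union else 0.0

    graph = nx.Graph()
    for r1, r2 in combinations(records, 2):
        a_main, b_main = r1.main_symptoms, r2.main_symptoms
        a_gen, b_gen = r1.general_symptoms, r2.general_symptoms
        if not a_main or not b_main or not a_gen or not b_gen:
            continue
        if jac(a_main, b_main) < main_threshold:
            continue
        w = jac(a_gen, b_gen)
        if w > 0.0:
            graph.add_edge(r1.patient_id, r2.patient_id, weight=w)
    return graph


def all_partitions(items):
    """Every set partition of *items* (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1:]
        yield part + [[first]]


def matrix_modularity(graph, assignment, resolution=1.0):
    """Q from the adjacency-matrix definition
    (1/2m) sum_uv [A_uv - r k_u k_v / 2m] delta(c_u, c_v)."""
    nodes = list(graph.nodes())
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    k = a.sum(axis=1)
    two_m = k.sum()
    labels = np.array([assignment[n] for n in nodes])
    delta = labels[:, None] == labels[None, :]
    return float(((a - resolution * np.outer(k, k) / two_m) * delta).sum() / two_m)


def exhaustive_best_modularity(graph):
    """Maximum modularity over every partition of the node set."""
    best = -2.0
    for part in all_partitions(list(graph.nodes())):
        assignment = {n: i for i, block in enumerate(part) for n in block}
        best = max(best, matrix_modularity(graph, assignment))
    return best


def chi2_closed_form(c_ij, c_i, c_j, n):
    """2x2 Pearson chi-square via N(ad - bc)^2 / (row/col marginal product)."""
    a = c_ij
    b = c_i - c_ij
    c = c_j - c_ij
    d = n - c_i - (c_j - c_ij)
    numerator = n * (a * d - b * c) ** 2
    denominator = (a + b) * (c + d) * (a + c) * (b + d)
    stat = numerator / denominator
    return stat, float(chi2_dist.sf(stat, 1))


def rr_direct(c_ij, c_i, c_j, n):
    """Relative risk as the plain ratio of the two group prevalences."""
    p_in = c_ij / c_i
    out_carriers = c_j - c_ij
    if out_carriers == 0:
        return math.inf if c_ij > 0 else 0.0
    p_out = out_carriers / (n - c_i)
    return p_in / p_out


def random_contingency(rng):
    """A random non-degenerate (c_ij, c_i, c_j, n) tuple."""
    while True:
        n = int(rng.integers(10, 500))
        c_i = int(rng.integers(1, n))
        c_j = int(rng.integers(1, n))
        lo = max(0, c_i + c_j - n)
        hi = min(c_i, c_j)
        c_ij = int(rng.integers(lo, hi + 1))
        table_ok = (
            0 < c_i < n
            and 0 < c_j < n  # non-degenerate marginals
        )
        if table_ok:
            return c_ij, c_i, c_j, n


def bigclam_binary_oracle(graph, n_communities, strengths=(0.5, 1.0, 2.0, 4.0)):
    """Best binary membership pattern under the affiliation likelihood,
    by enumerating every {0, s}^(N x k) matrix over a strength grid."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges()]
    edge_set = set(frozenset(e) for e in edges)

    iu, ju = np.triu_indices(n, k=1)
    is_edge = np.array(
        [frozenset((int(a), int(b))) in edge_set for a, b in zip(iu, ju)]
    )

    def loglik(f):
        dots = (f @ f.T)[iu, ju]
        probs = np.clip(1.0 - np.exp(-dots[is_edge]), 1e-12, None)
        return float(np.log(probs).sum() - dots[~is_edge].sum())

    best_ll, best_pattern = -math.inf, None
    for pattern_id in range(2 ** (n * n_communities)):
        bits = [(pattern_id >> i) & 1 for i in range(n * n_communities)]
        base = np.array(bits, dtype=float).reshape(n, n_communities)
        for s in strengths:
            ll = loglik(base * s)
            if ll > best_ll:
                best_ll, best_pattern = ll, base.astype(bool)
    memberships = {
        nodes[i]: frozenset(np.where(best_pattern[i])[0]) for i in range(n)
    }
    return memberships, best_ll
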