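"""Shared-symptom patient similarity network (PSN) construction.

Three steps: (1) a main-symptom network thresholded at Jaccard >= 0.8,
keeping only near-identical chief complaints; (2) a general-symptom
network over all pairs sharing at least one general symptom; (3) the
edge intersection of the two, weighted by the general-symptom
similarity. Patients left without any qualifying edge drop out of the
final network.

Networks are ``networkx.Graph`` objects with a ``weight`` attribute on
every edge and patient ids as nodes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .curation import PatientRecord
from .errors import UndefinedSimilarityError

__all__ = [
    "jaccard",
    "build_similarity_network",
    "overlap_networks",
    "build_psn",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]

logger = logging.getLogger(__name__)

MAIN_THRESHOLD_DEFAULT = 0.8


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|A n B| / |A u B|. Undefined (raises) when both sets are empty."""
    if not a and not b:
        raise UndefinedSimilarityError("jaccard of two empty sets is undefined")
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


def _candidate_pairs(sets: dict[str, frozenset[str]]) -> Iterable[tuple[str, str]]:
    """Pairs of patients sharing at least one term (all others have
    similarity 0 and can never form an edge)."""
    by_term: dict[str, list[str]] = defaultdict(list)
    for pid in sorted(sets):
        for term in sets[pid]:
            by_term[term].append(pid)
    seen: set[tuple[str, str]] = set()
    for members in by_term.values():
        for pair in combinations(members, 2):
            seen.add(pair)
    return seen


def build_similarity_network(
    records: Sequence[PatientRecord],
    field: str = "main_symptoms",
    min_weight: float = 0.0,
) -> nx.Graph:
    """All-pairs Jaccard network on one symptom field.

    An edge (u, v) is present iff the two patients share at least one
    term and their Jaccard similarity is >= *min_weight* (inclusive).
    Patients with an empty set for *field* are excluded from the node
    set entirely.
    """
    if field not in ("main_symptoms", "general_symptoms"):
        raise ValueError(f"unsupported similarity field {field!r}")
    if not 0.0 <= min_weight <= 1.0:
        raise ValueError("min_weight must lie in [0, 1]")

    sets = {
        r.patient_id: getattr(r, field) for r in records if getattr(r, field)
    }
    n_empty = len(records) - len(sets)
    if n_empty:
        logger.info("excluded %d patients with empty %s", n_empty, field)

    graph = nx.Graph()
    graph.add_nodes_from(sorted(sets))
    for u, v in _candidate_pairs(sets):
        w = jaccard(sets[u], sets[v])
        if w >= min_weight and w > 0.0:
            graph.add_edge(u, v, weight=w)
    if graph.number_of_nodes() < 2:
        logger.warning("similarity network on %s has < 2 nodes", field)
    return graph


def overlap_networks(main_psn: nx.Graph, general_psn: nx.Graph) -> nx.Graph:
    """Edge intersection of the two networks, carrying the general-symptom
    weight; nodes left without edges are dropped."""
    graph = nx.Graph()
    for u, v in main_psn.edges():
        if general_psn.has_edge(u, v):
            graph.add_edge(u, v, weight=general_psn[u][v]["weight"])
    if graph.number_of_edges() == 0:
        logger.warning("overlap of the two networks is empty")
    return graph


def build_psn(
    records: Sequence[PatientRecord],
    main_threshold: float = MAIN_THRESHOLD_DEFAULT,
) -> nx.Graph:
    """The full three-step construction."""
    main_net = build_similarity_network(records, "main_symptoms", main_threshold)
    general_net = build_similarity_network(records, "general_symptoms", 0.0)
    psn = overlap_networks(main_net, general_net)
    # sanity: the overlap can only remove edges from the main network
    assert all(main_net.has_edge(u, v) for u, v in psn.edges())
    return psn


def _canonical_edges(graph: nx.Graph) -> list[tuple[str, str, float]]:
    edges = []
    for u, v, data in graph.edges(data=True):
        a, b = (u, v) if str(u) <= str(v) else (v, u)
        edges.append((a, b, float(data["weight"])))
    return sorted(edges)


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """3-column whitespace-delimited edge list, lexicographic node order."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in _canonical_edges(graph):
            fh.write(f"{u} {v} {w!r}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                u, v, w = parts
                graph.add_edge(u, v, weight=float(w))
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
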