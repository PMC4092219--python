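"""Markov Cluster (MCL) algorithm over the cross-genome similarity graph.

The similarity graph is undirected and weighted; directed hit evidence is
symmetrized by taking the larger of the two directions.  Clustering uses
the canonical MCL iteration — column-normalize, expand (matrix power),
inflate (elementwise power, renormalize), prune — run at a deliberately
stringent inflation (default 5.0) so that clusters err on the side of
splitting rather than lumping paralogous families together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .similarity import SimilarityHit

EVALUE_CAP = 1e-200  # −log10 weight saturates at 200


@dataclass(frozen=True)
class MclParams:
    inflation: float = 5.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")


def graph_from_hits(
    hits: Iterable[SimilarityHit], weighting: str = "neg_log_evalue"
) -> nx.Graph:
    """Build the undirected similarity graph from filtered hits.

    Self-hits are dropped; asymmetric evidence still creates an edge; the
    edge weight is the maximum over the two directions.  ``neg_log_evalue``
    weights are −log10(E) with E capped below at 1e-200 (weight 200).
    """
    if weighting not in {"neg_log_evalue", "bitscore"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    g = nx.Graph()
    for h in hits:
        if h.is_self:
            continue
        if weighting == "neg_log_evalue":
            w = -math.log10(max(h.evalue, EVALUE_CAP))
        else:
            w = h.bitscore
        if w <= 0:
            continue
        prev = g.edges.get((h.query, h.subject), {}).get("weight", 0.0)
        g.add_edge(h.query, h.subject, weight=max(w, prev))
    return g


def _cluster_matrix(m: np.ndarray, nodes: Sequence[str], eps: float) -> list[list[str]]:
    """Interpret the converged MCL matrix as a partition.

    Attractors are nodes with positive mass on their own diagonal; each
    node joins the attractor systems that retain mass on it.  A node
    attracted to several systems is assigned to the larger cluster, ties
    broken by the lexicographically smallest member id.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:  # degenerate; every node its own cluster
        return [[v] for v in nodes]
    # merge attractors that support each other (rows with shared support)
    support = {a: set(np.nonzero(m[a] > eps)[0]) | {a} for a in attractors}
    ag = nx.Graph()
    ag.add_nodes_from(attractors)
    for a in attractors:
        for b in attractors:
            if a < b and (b in support[a] or a in support[b] or support[a] & support[b]):
                ag.add_edge(a, b)
    systems = [sorted(c) for c in nx.connected_components(ag)]
    clusters: dict[int, set[int]] = {i: set(sys) for i, sys in enumerate(systems)}
    for j in range(n):
        memberships = [
            ci
            for ci, sys in enumerate(systems)
            if any(m[a, j] > eps for a in sys)
        ]
        if not memberships:
            clusters.setdefault(-j - 1, {j})  # unattracted: singleton
            continue
        # prefer the larger cluster; ties by lexicographically smallest member
        sizes = {ci: len(clusters[ci]) for ci in memberships}
        mx = max(sizes.values())
        cands = [ci for ci in memberships if sizes[ci] == mx]
        best = min(cands, key=lambda ci: min(nodes[i] for i in clusters[ci]))
        clusters[best].add(j)
    seen: set[int] = set()
    out: list[list[str]] = []
    for members in clusters.values():
        fresh = members - seen
        if fresh:
            out.append(sorted(nodes[i] for i in fresh))
            seen |= members
    return out


def mcl(
    graph: nx.Graph, params: MclParams | None = None, exact: bool = False
) -> list[list[str]]:
    """Cluster the similarity graph; returns a partition of its nodes.

    Deterministic given the (sorted) node ordering.  Disconnected
    components are clustered independently, so clusters can never span
    components.  ``exact`` disables pruning (dense reference mode).
    Non-convergence at ``max_iterations`` emits a warning and returns the
    current attractor-based clustering.
    """
    params = params or MclParams()
    if graph.number_of_nodes() == 0:
        return []
    clusters: list[list[str]] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(nodes)
            continue
        clusters.extend(_mcl_component(graph.subgraph(comp), nodes, params, exact))
    return sorted(clusters, key=lambda c: c[0])


def _mcl_component(
    graph: nx.Graph, nodes: Sequence[str], params: MclParams, exact: bool
) -> list[list[str]]:
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    # self-loops: node's maximum incident weight (regularization)
    for i in range(n):
        m[i, i] = m[i].max() if m[i].max() > 0 else 1.0
    m /= m.sum(axis=0, keepdims=True)
    prune = 0.0 if exact else params.prune_threshold
    converged = False
    for _ in range(params.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = np.power(m, params.inflation)
        if prune > 0.0:
            m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "MCL did not converge within max_iterations; "
            "returning current attractor clustering",
            RuntimeWarning,
            stacklevel=2,
        )
    eps = max(prune, 1e-9)
    return _cluster_matrix(m, nodes, eps)


def write_clusters(clusters: Sequence[Sequence[str]], path) -> None:
    """One cluster per line, tab-separated member ids (MCL dump dialect)."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write("\t".join(c) + "\n")


def read_clusters(path) -> list[list[str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t"))
    return out
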