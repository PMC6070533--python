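"""Structural analysis of the candidate-induced subnetwork.

Two complementary views of the candidate set: maximal cliques (default size
≥ 4) in the subgraph induced by the candidates, which flag putative physical
complexes, and clusters of candidates that co-occur on the retained shortest
paths between the two seed sets, which trace the pathways the score itself
used.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import SeedPair
from .network import Network

logger = logging.getLogger(__name__)

DEFAULT_MIN_CLIQUE = 4
DEFAULT_PATH_CAP = 100


@dataclass
class CandidateSubnetwork:
    """Candidate nodes, their induced edges, and derived structure."""

    nodes: frozenset
    graph: nx.Graph
    cliques: list = field(default_factory=list)
    clusters: dict = field(default_factory=dict)
    cooccurrence: Counter = field(default_factory=Counter)

    @property
    def edges(self) -> set:
        return {tuple(sorted(e, key=str)) for e in self.graph.edges}

    def component_sizes(self) -> list[int]:
        return sorted((len(c) for c in nx.connected_components(self.graph)), reverse=True)


def induced_subnetwork(net: Network, candidates) -> CandidateSubnetwork:
    """Subgraph of the interactome induced by the candidate set."""
    candidates = set(candidates)
    missing = candidates - net.nodes
    if missing:
        raise ValueError(f"candidates absent from the network: {sorted(missing)[:5]}")
    sub = nx.Graph(net.graph.subgraph(candidates))
    sizes = sorted((len(c) for c in nx.connected_components(sub)), reverse=True)
    logger.info("induced subnetwork: %d nodes, %d edges, components %s",
                sub.number_of_nodes(), sub.number_of_edges(), sizes[:5])
    return CandidateSubnetwork(nodes=frozenset(candidates), graph=sub)


def find_cliques(sub: CandidateSubnetwork, min_size: int = DEFAULT_MIN_CLIQUE) -> list:
    """All maximal cliques of at least ``min_size`` nodes.

    Ordered by size descending, then lexicographically by member ids.
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    cliques = [
        tuple(sorted(c, key=str))
        for c in nx.find_cliques(sub.graph)
        if len(c) >= min_size
    ]
    cliques.sort(key=lambda c: (-len(c), c))
    sub.cliques = cliques
    return cliques


def path_cooccurrence(
    net: Network,
    seeds: SeedPair,
    candidates,
    avgd: float,
    path_cap: int = DEFAULT_PATH_CAP,
) -> Counter:
    """Count candidate pairs that ride the same retained shortest path.

    For every seed pair (i ∈ a, j ∈ b) passing the length filter
    d(i,j) ≤ avgd, all shortest paths between i and j are enumerated (capped
    at ``path_cap`` per seed pair, logged when hit); each path increments the
    count of every unordered candidate pair lying on it together.
    """
    if avgd <= 0:
        raise ValueError("avgd must be positive")
    candidates = set(candidates)
    counts: Counter = Counter()
    a = sorted(seeds.seeds_a, key=str)
    b = sorted(seeds.seeds_b, key=str)
    rows = net.distance_rows(a)
    n_capped = 0
    for ii, i_node in enumerate(a):
        for j_node in b:
            d = rows[ii][net.index_of(j_node)]
            if not np.isfinite(d) or d > avgd:
                continue
            paths = itertools.islice(
                nx.all_shortest_paths(net.graph, i_node, j_node), path_cap + 1
            )
            for np_idx, path in enumerate(paths):
                if np_idx == path_cap:
                    n_capped += 1
                    break
                on_path = sorted(candidates.intersection(path), key=str)
                for u, v in itertools.combinations(on_path, 2):
                    counts[(u, v)] += 1
    if n_capped:
        logger.warning("path cap (%d) hit for %d seed pair(s)", path_cap, n_capped)
    return counts


def cluster_candidates(
    cooccurrence: Counter,
    candidates,
    method: str = "hierarchical_average",
    k_or_cut: int | None = None,
) -> dict:
    """Average-linkage clustering of candidates on co-occurrence distance.

    The distance between two candidates is 1 − count / max(count); candidates
    never co-occurring with anything sit at distance 1 from everyone and come
    out as singletons.  The number of clusters is ``k_or_cut`` when given,
    otherwise chosen by the best mean silhouette over k = 2..10.  Labels are
    renumbered 1.. in order of first appearance over the sorted candidates.
    """
    if method != "hierarchical_average":
        raise ValueError(f"unknown clustering method {method!r}")
    members = sorted(set(candidates), key=str)
    if not cooccurrence:
        raise ValueError("empty co-occurrence data")
    if len(members) < 2:
        return {m: 1 for m in members}
    max_count = max(cooccurrence.values())
    idx = {m: i for i, m in enumerate(members)}
    dist = np.ones((len(members), len(members)))
    np.fill_diagonal(dist, 0.0)
    for (u, v), c in cooccurrence.items():
        if u in idx and v in idx:
            d = 1.0 - c / max_count
            dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = d
    link = linkage(squareform(dist, checks=False), method="average")
    if k_or_cut is not None:
        raw = fcluster(link, t=int(k_or_cut), criterion="maxclust")
    else:
        best, raw = -np.inf, None
        for k in range(2, min(10, len(members) - 1) + 1):
            lab = fcluster(link, t=k, criterion="maxclust")
            if len(set(lab)) < 2:
                continue
            s = _mean_silhouette(dist, lab)
            if s > best + 1e-12:
                best, raw = s, lab
        if raw is None:
            raw = np.ones(len(members), dtype=int)
    # deterministic relabeling by first appearance
    remap: dict = {}
    labels = {}
    for m, r in zip(members, raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[m] = remap[r]
    return labels


def _mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient on a precomputed distance matrix."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n = len(labels)
    scores = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        same[i] = False
        a = dist[i, same].mean() if same.any() else 0.0
        b = np.inf
        for u in uniq:
            if u == labels[i]:
                continue
            other = labels == u
            if other.any():
                b = min(b, dist[i, other].mean())
        if not np.isfinite(b) or max(a, b) == 0:
            scores[i] = 0.0
        else:
            scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def analyze_candidates(
    net: Network,
    seeds: SeedPair,
    candidates,
    avgd: float,
    min_clique: int = DEFAULT_MIN_CLIQUE,
    k_clusters: int | None = None,
    path_cap: int = DEFAULT_PATH_CAP,
) -> CandidateSubnetwork:
    """Full structural workup: induced subgraph, cliques, co-occurrence clusters."""
    sub = induced_subnetwork(net, candidates)
    find_cliques(sub, min_clique)
    sub.cooccurrence = path_cooccurrence(net, seeds, candidates, avgd, path_cap)
    if sub.cooccurrence:
        sub.clusters = cluster_candidates(sub.cooccurrence, candidates, k_or_cut=k_clusters)
    return sub
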