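"""Undirected interaction networks: parsing, distances, and rewiring null models.

The in-memory container is a thin wrapper around :class:`networkx.Graph` that
adds a stable node ordering, a cached sparse adjacency matrix for fast BFS
distance queries (via :mod:`scipy.sparse.csgraph`), and the degree-preserving
rewiring null models used by the specificity scores and the robustness
benchmarks.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

#: exact all-pairs average path length is computed up to this many nodes;
#: larger networks fall back to Monte-Carlo pair sampling.
EXACT_AVGD_LIMIT = 2000

#: number of sampled ordered pairs used when estimating the average path length.
DEFAULT_SAMPLE_PAIRS = 100_000


class Network:
    """An undirected, unweighted network with opaque string-like node ids.

    Self-loops are dropped at construction (with a logged count) and parallel
    edges collapse, so the stored graph is simple.  Node identifiers are
    case-sensitive and never normalized.
    """

    def __init__(self, graph: nx.Graph):
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        n_loops = 0
        for u, v in graph.edges:
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        self.graph = g
        self._order: list = sorted(g.nodes, key=str)
        self._index: dict = {n: i for i, n in enumerate(self._order)}
        self._csr: csr_matrix | None = None
        self._avgd: float | None = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], nodes: Iterable = ()) -> "Network":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return cls(g)

    # -- basic queries --------------------------------------------------------

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def node_order(self) -> list:
        """Nodes in the stable (sorted) order used by all matrix views."""
        return list(self._order)

    @property
    def edges(self) -> set:
        """Edges as canonical (min, max) tuples."""
        return {tuple(sorted((u, v), key=str)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node) -> bool:
        return node in self.graph

    def neighbors(self, node) -> set:
        return set(self.graph[node])

    def degree(self, node) -> int:
        return self.graph.degree[node]

    def degree_sequence(self) -> list[int]:
        return sorted(d for _, d in self.graph.degree)

    def index_of(self, node) -> int:
        return self._index[node]

    def copy(self) -> "Network":
        return Network(self.graph)

    # -- distances ------------------------------------------------------------

    def _sparse(self) -> csr_matrix:
        if self._csr is None:
            self._csr = nx.to_scipy_sparse_array(
                self.graph, nodelist=self._order, format="csr", dtype=np.int8
            )
        return self._csr

    def distance_rows(self, sources: Sequence) -> np.ndarray:
        """BFS hop distances from each source to every node.

        Returns a float array of shape ``(len(sources), n_nodes)`` in the
        stable node order; unreachable entries are ``inf``.
        """
        missing = [s for s in sources if s not in self._index]
        if missing:
            raise KeyError(f"unknown node(s): {missing[:5]}")
        if self.n_nodes == 0:
            raise ValueError("empty network")
        idx = np.asarray([self._index[s] for s in sources], dtype=np.intp)
        if self.n_edges == 0:
            d = np.full((len(idx), self.n_nodes), np.inf)
            d[np.arange(len(idx)), idx] = 0.0
            return d
        return shortest_path(self._sparse(), method="D", unweighted=True, indices=idx)


@dataclass
class DistanceMap:
    """Hop distances from a single source; unreachable nodes are absent."""

    source: object
    dist: dict = field(default_factory=dict)

    def __getitem__(self, node) -> int:
        return self.dist[node]

    def get(self, node, default=None):
        return self.dist.get(node, default)


def bfs_distances(net: Network, source) -> DistanceMap:
    """Exact unweighted shortest-path distances from ``source``."""
    if source not in net:
        raise KeyError(f"unknown source node: {source!r}")
    row = net.distance_rows([source])[0]
    dist = {
        node: int(row[i]) for i, node in enumerate(net.node_order) if np.isfinite(row[i])
    }
    return DistanceMap(source=source, dist=dist)


def average_path_length(
    net: Network,
    sample_pairs: int | None = None,
    rng_seed: int = 0,
) -> float:
    """Mean shortest-path length over connected ordered node pairs, avgd(G).

    Exact (all pairs) when the network has at most ``EXACT_AVGD_LIMIT`` nodes
    and ``sample_pairs`` is not given; otherwise a Monte-Carlo estimate over
    uniformly sampled ordered pairs.  Pairs in different components are
    excluded — they contribute to neither numerator nor denominator.
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("empty network")
    if n == 1 or net.n_edges == 0:
        raise ValueError("network has no connected node pair")
    if sample_pairs is None and n <= EXACT_AVGD_LIMIT:
        d = net.distance_rows(net.node_order)
        mask = np.isfinite(d)
        np.fill_diagonal(mask, False)
        if not mask.any():
            raise ValueError("network has no connected node pair")
        return float(d[mask].mean())
    k = sample_pairs if sample_pairs is not None else DEFAULT_SAMPLE_PAIRS
    rng = np.random.default_rng(rng_seed)
    src = rng.integers(0, n, size=k)
    dst = rng.integers(0, n - 1, size=k)
    dst[dst >= src] += 1  # uniform over ordered pairs with src != dst
    order = net.node_order
    uniq, inverse = np.unique(src, return_inverse=True)
    rows = net.distance_rows([order[i] for i in uniq])
    d = rows[inverse, dst]
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("no connected pair among sampled pairs")
    return float(d[finite].mean())


def cached_avgd(net: Network, rng_seed: int = 0) -> float:
    """avgd(G) computed once per Network instance and memoized."""
    if net._avgd is None:
        net._avgd = average_path_length(net, rng_seed=rng_seed)
    return net._avgd


# -- rewiring null models -----------------------------------------------------


def rewire_degree_preserving(
    net: Network, swap_multiplier: float = 10.0, rng_seed: int = 0
) -> Network:
    """Shuffle edges with double-edge swaps, preserving every node's degree.

    Attempts ``swap_multiplier × |E|`` swaps; swaps that would create a
    self-loop or duplicate edge are rejected and retried.  Graphs admitting no
    swap (for example a star) are returned unchanged with a warning.
    """
    if swap_multiplier <= 0:
        raise ValueError("swap_multiplier must be positive")
    g = net.graph.copy()
    if g.number_of_edges() < 2 or g.number_of_nodes() < 4:
        logger.warning("network too small to rewire; returning unchanged copy")
        return Network(g)
    nswap = max(1, int(round(swap_multiplier * g.number_of_edges())))
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=nswap * 20 + 100, seed=rng_seed)
    except nx.NetworkXException as exc:
        # degree sequence is intact even after a truncated swap sequence
        logger.warning("rewiring truncated: %s", exc)
    return Network(g)


def rewire_fraction(net: Network, fraction: float, rng_seed: int = 0) -> Network:
    """Move approximately ``fraction × |E|`` edges via degree-preserving swaps.

    Swaps are applied in chunks until the symmetric difference with the
    original edge set reaches the target, so later swaps cannot silently undo
    the bookkeeping.  ``fraction = 0`` returns an unchanged copy.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    g = net.graph.copy()
    if fraction == 0.0 or g.number_of_edges() < 2 or g.number_of_nodes() < 4:
        return Network(g)
    original = {frozenset(e) for e in g.edges}
    target = int(round(fraction * len(original)))
    rnd = random.Random(rng_seed)
    moved = 0
    for _ in range(200):  # chunk budget; each successful swap moves <= 2 edges
        if moved >= target:
            break
        want = max(1, -(-(target - moved) // 2))
        try:
            nx.double_edge_swap(g, nswap=want, max_tries=want * 50 + 100, seed=rnd)
        except nx.NetworkXException as exc:
            logger.warning("rewiring truncated: %s", exc)
            break
        moved = sum(1 for e in g.edges if frozenset(e) not in original)
    else:
        logger.warning("rewire_fraction stopped before target (%d/%d)", moved, target)
    return Network(g)


# -- file formats -------------------------------------------------------------


def read_edge_list(path, dialect: str | None = None) -> Network:
    """Read a network from a 2-column TSV edge list or a SIF file.

    The dialect is auto-detected by column count: files whose data lines all
    have exactly two tokens are TSV; files with ≥3-token lines are ambiguous
    (could be SIF or annotated TSV) and require an explicit ``dialect``.
    Duplicate edges collapse and self-loops are dropped with a logged count.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    data = [
        (i + 1, ln.split())
        for i, ln in enumerate(lines)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not data:
        raise ValueError(f"{path}: empty edge-list file")
    if dialect is None:
        if all(len(tok) == 2 for _, tok in data):
            dialect = "tsv"
        else:
            raise ValueError(
                f"{path}: lines with 3+ columns are ambiguous; pass dialect='tsv' or 'sif'"
            )
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")

    g = nx.Graph()
    for lineno, tok in data:
        if dialect == "tsv":
            if len(tok) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(tok)}")
            g.add_edge(tok[0], tok[1])
        else:  # sif: source, relation, target...
            if len(tok) == 1:
                g.add_node(tok[0])
            elif len(tok) == 2:
                raise ValueError(
                    f"{path}:{lineno}: SIF line has a relation but no target"
                )
            else:
                for tgt in tok[2:]:
                    g.add_edge(tok[0], tgt)
    return Network(g)


def read_node_list(path) -> list:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    for ln in Path(path).read_text().splitlines():
        s = ln.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out


def write_edge_list(net: Network, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def write_graphml(net: Network, path, node_attrs: Mapping[str, Mapping] | None = None) -> None:
    """Write the network as GraphML, optionally attaching per-node attributes.

    ``node_attrs`` maps attribute name → {node: value}; missing nodes simply
    lack the attribute.
    """
    g = net.graph.copy()
    if node_attrs:
        for name, mapping in node_attrs.items():
            nx.set_node_attributes(g, {k: v for k, v in mapping.items() if k in g}, name)
    nx.write_graphml(g, path)
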