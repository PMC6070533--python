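"""Synthetic base networks and artificial module pairs with known overlap.

The benchmark replaces the real interactome with a preferential-attachment
(Barabási–Albert) graph at interactome-like density, and plants pairs of
overlapping modules of three kinds:

* ``shell`` — a start node plus successive BFS neighborhood shells, the last
  shell randomly subsampled to hit a target size (200–400 nodes by default);
* ``conn`` — connectivity-significance growth, i.e. the same hypergeometric
  criterion DIAMOnD uses for prediction, grown from a single start to a fixed
  size (250 by default), ties broken at random;
* ``rwr`` — the top nodes of a random walk with restart (restart probability
  0.5) from the start node, admitted in decreasing visit-score order along
  module-adjacent nodes so the module is guaranteed connected.

A module pair is produced by starting the second module inside the first and
rejecting pairs whose overlap falls outside the configured bounds (50–125
nodes by default).  Seed sets are uniform samples of each module, optionally
contaminated with random non-member nodes.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import identity
from scipy.sparse.linalg import factorized

from .diamond import connectivity_module
from .network import Network

logger = logging.getLogger(__name__)

MODULE_MODELS = ("shell", "conn", "rwr")

DEFAULT_N_NODES = 5000
DEFAULT_MEAN_DEGREE = 8.0
DEFAULT_SHELL_SIZE_RANGE = (200, 400)
DEFAULT_MODULE_SIZE = 250
DEFAULT_OVERLAP_BOUNDS = (50, 125)
DEFAULT_RESTART_PROB = 0.5


@dataclass(frozen=True)
class ModulePairTruth:
    """A simulated pair of overlapping modules with known ground truth."""

    module_a: frozenset
    module_b: frozenset
    model: str
    base_net: Network

    @property
    def overlap(self) -> frozenset:
        return self.module_a & self.module_b


def make_base_network(
    n_nodes: int = DEFAULT_N_NODES,
    mean_degree: float = DEFAULT_MEAN_DEGREE,
    model: str = "scale_free",
    rng_seed: int = 0,
) -> Network:
    """Connected scale-free surrogate for an interactome.

    Preferential attachment with m = mean_degree / 2 new edges per node,
    restricted to the largest connected component; node ids are strings.
    """
    if model != "scale_free":
        raise ValueError(f"unknown base-network model {model!r}")
    if n_nodes < 100:
        raise ValueError("n_nodes must be >= 100")
    m = max(1, int(round(mean_degree / 2)))
    if m >= n_nodes:
        raise ValueError("mean_degree too large for n_nodes")
    g = nx.barabasi_albert_graph(n_nodes, m, seed=rng_seed)
    giant = max(nx.connected_components(g), key=len)
    g = g.subgraph(giant)
    width = len(str(n_nodes - 1))
    g = nx.relabel_nodes(g, {v: f"n{v:0{width}d}" for v in g.nodes})
    return Network(g)


# -- the three module models --------------------------------------------------


def _shell_module(net: Network, start, target_size: int, rng) -> set:
    module = {start}
    frontier = {start}
    while len(module) < target_size:
        shell = set()
        for v in frontier:
            shell.update(w for w in net.neighbors(v) if w not in module)
        if not shell:
            raise ValueError(
                f"component too small: reached {len(module)} of {target_size} nodes"
            )
        need = target_size - len(module)
        if len(shell) > need:
            shell = set(rng.choice(sorted(shell, key=str), size=need, replace=False))
        module |= shell
        frontier = shell
    return module


def rwr_scores(net: Network, start, restart_prob: float = DEFAULT_RESTART_PROB) -> dict:
    """Stationary visit frequencies of a random walk with restart at ``start``.

    Solves p = c·e_start + (1−c)·W p with W the column-normalized adjacency;
    nodes outside the start's component score 0.
    """
    if not 0.0 < restart_prob < 1.0:
        raise ValueError("restart_prob must lie in (0, 1)")
    order = net.node_order
    solve = _restart_solver(net, restart_prob)
    e = np.zeros(len(order))
    e[net.index_of(start)] = restart_prob
    p = solve(e)
    return {node: float(p[i]) for i, node in enumerate(order)}


def _restart_solver(net: Network, restart_prob: float):
    """LU factorization of (I − (1−c)·W), cached per network instance.

    Module-pair generation solves the restart walk from many start nodes of
    the same network; factorizing once turns each start into a cheap
    triangular solve.
    """
    cache = getattr(net, "_rwr_solvers", None)
    if cache is None:
        cache = net._rwr_solvers = {}
    if restart_prob not in cache:
        adj = net._sparse().astype(float)
        deg = np.asarray(adj.sum(axis=1)).ravel()
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-300), 0.0)
        w = adj.multiply(inv[None, :]).tocsc()  # column-stochastic (no isolated nodes)
        mat = (identity(net.n_nodes, format="csc") - (1.0 - restart_prob) * w).tocsc()
        cache[restart_prob] = factorized(mat)
    return cache[restart_prob]


def _rwr_module(net: Network, start, target_size: int, restart_prob: float) -> set:
    scores = rwr_scores(net, start, restart_prob)
    module = {start}
    # admit nodes in decreasing visit score among neighbors of the module:
    # identical to plain top-k whenever the top-k set is connected
    heap = []
    seen = {start}
    for w in net.neighbors(start):
        heapq.heappush(heap, (-scores[w], str(w), w))
        seen.add(w)
    while len(module) < target_size and heap:
        _, _, v = heapq.heappop(heap)
        module.add(v)
        for w in net.neighbors(v):
            if w not in seen:
                heapq.heappush(heap, (-scores[w], str(w), w))
                seen.add(w)
    if len(module) < target_size:
        raise ValueError(
            f"component too small: reached {len(module)} of {target_size} nodes"
        )
    return module


def make_module(
    net: Network,
    model: str,
    target_size: int,
    start,
    rng_seed: int = 0,
    restart_prob: float = DEFAULT_RESTART_PROB,
) -> set:
    """Grow one artificial module of ``target_size`` nodes containing ``start``."""
    if model not in MODULE_MODELS:
        raise ValueError(f"unknown module model {model!r}")
    if start not in net:
        raise KeyError(f"unknown start node: {start!r}")
    if target_size >= net.n_nodes:
        raise ValueError("target_size must be smaller than the network")
    rng = np.random.default_rng(rng_seed)
    if model == "shell":
        return _shell_module(net, start, target_size, rng)
    if model == "conn":
        return connectivity_module(net, start, target_size, rng)
    return _rwr_module(net, start, target_size, restart_prob)


def make_module_pair(
    net: Network,
    model: str,
    overlap_bounds: tuple[int, int] = DEFAULT_OVERLAP_BOUNDS,
    rng_seed: int = 0,
    max_tries: int = 100,
    shell_size_range: tuple[int, int] = DEFAULT_SHELL_SIZE_RANGE,
    module_size: int = DEFAULT_MODULE_SIZE,
    restart_prob: float = DEFAULT_RESTART_PROB,
) -> ModulePairTruth:
    """Two same-model modules whose overlap size lies within ``overlap_bounds``.

    The first module grows from a uniformly drawn start; the second from a
    start drawn inside the first module, re-drawn until the overlap lands in
    bounds or ``max_tries`` is exhausted.
    """
    lo, hi = overlap_bounds
    rng = np.random.default_rng(rng_seed)
    order = net.node_order

    def draw_size():
        if model == "shell":
            return int(rng.integers(shell_size_range[0], shell_size_range[1] + 1))
        return module_size

    achieved: list[int] = []
    module_a: set | None = None
    for attempt in range(max_tries):
        # shell sizes are redrawn per try; conn/rwr reuse module_a for a few
        # tries (only the second start moves) before redrawing it
        if module_a is None or model == "shell" or attempt % 10 == 9:
            start_a = order[int(rng.integers(0, len(order)))]
            sub = int(rng.integers(0, 2**31 - 1))
            try:
                module_a = make_module(net, model, draw_size(), start_a, sub, restart_prob)
            except ValueError:
                module_a = None
                continue
        members_a = sorted(module_a, key=str)
        start_b = members_a[int(rng.integers(0, len(members_a)))]
        sub = int(rng.integers(0, 2**31 - 1))
        try:
            module_b = make_module(net, model, draw_size(), start_b, sub, restart_prob)
        except ValueError:
            continue
        ov = len(module_a & module_b)
        achieved.append(ov)
        if lo <= ov <= hi:
            return ModulePairTruth(
                module_a=frozenset(module_a),
                module_b=frozenset(module_b),
                model=model,
                base_net=net,
            )
    raise ValueError(
        f"no {model} pair with overlap in [{lo}, {hi}] after {max_tries} tries "
        f"(achieved overlaps ranged {min(achieved)}–{max(achieved)})"
        if achieved
        else f"module generation failed on every one of {max_tries} tries"
    )


def sample_seeds(
    truth: ModulePairTruth,
    fraction: float,
    contamination: float = 0.0,
    rng_seed: int = 0,
) -> tuple[set, set]:
    """Uniform seed samples from each module, optionally contaminated.

    ``floor(fraction × |M|)`` members are drawn per module; then
    ``floor(contamination × sample)`` of them are replaced by uniform random
    network nodes outside the module (false seeds).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if not 0.0 <= contamination < 1.0:
        raise ValueError("contamination must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    net_nodes = sorted(truth.base_net.nodes, key=str)

    def one(module: frozenset) -> set:
        members = sorted(module, key=str)
        k = int(fraction * len(members))
        if k < 1:
            raise ValueError("empty seed sample; raise fraction or module size")
        sample = list(rng.choice(members, size=k, replace=False))
        n_bad = int(contamination * k)
        if n_bad:
            outside = [v for v in net_nodes if v not in module]
            bad = rng.choice(outside, size=n_bad, replace=False)
            sample = sample[: k - n_bad] + list(bad)
        return set(sample)

    return one(truth.module_a), one(truth.module_b)
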