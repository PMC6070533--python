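"""DIAMOnD-style iterative module expansion by connectivity significance.

At each step every node adjacent to the current module is scored with the
hypergeometric tail probability of having at least its observed number of
links into the module, given its degree, the module size s0 and the network
size N:

    p(k_in; k, s0, N) = Σ_{x = k_in}^{k} C(s0, x) C(N − s0, k − x) / C(N, k)

The node with the smallest p joins the module; ties go to the higher-degree
node, then the lexicographically smaller identifier.  Seed weighting is fixed
at 1.  The same growth engine, with a randomized tie-break, also generates the
"connectivity" artificial modules used in the benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .network import Network

logger = logging.getLogger(__name__)


def connectivity_pvalues(k_in: np.ndarray, k: np.ndarray, s0: int, n: int) -> np.ndarray:
    """Vectorized hypergeometric tails P(X >= k_in), X ~ Hypergeom(n, s0, k)."""
    return hypergeom.sf(np.asarray(k_in) - 1, n, s0, np.asarray(k))


def _grow(
    net: Network,
    seeds: set,
    n_steps: int,
    rng: np.random.Generator | None = None,
):
    """Shared growth loop; deterministic tie-break unless ``rng`` is given.

    Works on integer node indices against the cached sparse adjacency; the
    hypergeometric tail is evaluated once per distinct (links-in, degree)
    pair per iteration.  Yields (node, p_value) as nodes join the module.
    """
    order = net.node_order
    csr = net._sparse()
    indptr, nbr = csr.indptr, csr.indices
    n = net.n_nodes
    deg = np.diff(indptr).astype(np.int64)

    in_module = np.zeros(n, dtype=bool)
    k_in = np.zeros(n, dtype=np.int64)
    s0 = 0
    for s in seeds:
        i = net.index_of(s)
        in_module[i] = True
        s0 += 1
    for i in np.flatnonzero(in_module):
        k_in[nbr[indptr[i] : indptr[i + 1]]] += 1

    key_stride = int(deg.max(initial=0)) + 1
    for _ in range(n_steps):
        bidx = np.flatnonzero(~in_module & (k_in > 0))
        if bidx.size == 0:
            return
        kin_b = k_in[bidx]
        deg_b = deg[bidx]
        keys = kin_b * key_stride + deg_b
        uniq, inverse = np.unique(keys, return_inverse=True)
        p_uniq = connectivity_pvalues(uniq // key_stride, uniq % key_stride, s0, n)
        pvals = p_uniq[inverse]
        tied = np.flatnonzero(pvals == pvals.min())
        if rng is not None:
            t = int(tied[rng.integers(0, tied.size)])
        else:
            # higher degree first, then smaller index (= lexicographic id,
            # since the stable node order is sorted)
            t = int(min(tied, key=lambda i: (-deg_b[i], bidx[i])))
        chosen = int(bidx[t])
        in_module[chosen] = True
        s0 += 1
        k_in[nbr[indptr[chosen] : indptr[chosen + 1]]] += 1
        yield order[chosen], float(pvals[t])


@dataclass
class DiamondRun:
    """Ordered expansion record: the nodes added and their p-values."""

    seeds: frozenset
    added: list  # [(node, p_value), ...]

    @property
    def added_nodes(self) -> list:
        return [v for v, _ in self.added]


def diamond_expand(net: Network, seeds, n_iter: int) -> DiamondRun:
    """Run ``n_iter`` expansion steps from a seed set.

    If the module's boundary is exhausted earlier (the seeds cover a whole
    component), the run is truncated with a warning.
    """
    seeds = set(seeds) & net.nodes
    if not seeds:
        raise ValueError("no seed maps to the network")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    added = list(_grow(net, seeds, n_iter))
    if len(added) < n_iter:
        logger.warning(
            "module boundary exhausted after %d of %d iterations", len(added), n_iter
        )
    return DiamondRun(seeds=frozenset(seeds), added=added)


def diamond_overlap_candidates(net: Network, seeds_a, seeds_b, n_iter: int) -> set:
    """Two-disease protocol: expand each seed set separately and intersect."""
    run_a = diamond_expand(net, seeds_a, n_iter)
    run_b = diamond_expand(net, seeds_b, n_iter)
    return set(run_a.added_nodes) & set(run_b.added_nodes)


def connectivity_module(
    net: Network, start, target_size: int, rng: np.random.Generator
) -> set:
    """Grow a module of ``target_size`` from one start node, random tie-break."""
    if start not in net:
        raise KeyError(f"unknown start node: {start!r}")
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    module = {start}
    for node, _ in _grow(net, module, target_size - 1, rng=rng):
        module.add(node)
    if len(module) < target_size:
        raise ValueError(
            f"component too small: reached {len(module)} of {target_size} nodes"
        )
    return module
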