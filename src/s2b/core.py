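"""The double specific betweenness (S2B) score, its threshold, and specificity.

S2B ranks network nodes by how often they sit on short shortest paths linking
two seed sets a and b (known members of two overlapping modules A and B).  For
a node k,

    S2B(k) = [ Σ_{i∈a, j∈b} sp(k,i,j) · t(i,j) ] / [ Σ_{i∈a, j∈b} t(i,j) ]

where sp(k,i,j) = 1 iff d(i,j) = d(i,k) + d(k,j) (k lies on some shortest
path between i and j) and t(i,j) = 1 iff d(i,j) ≤ avgd(G), the network's
average shortest-path length.  Pairs whose two endpoints include k itself are
excluded from both sums, which keeps the score symmetric in the two seed sets;
seeds that were discarded for appearing in both raw sets are not scored at
all.  Disconnected pairs contribute to neither sum; a node whose denominator
is zero scores 0 so the ranking stays total.

Two specificity filters guard against generically central nodes: SS1 compares
the real score against scores under random seed sets of the same sizes, SS2
against scores on degree-preserving rewired networks.  Both are the fraction
of randomizations the real score meets or exceeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Network, average_path_length, cached_avgd, rewire_degree_preserving

logger = logging.getLogger(__name__)

DEFAULT_N_RANDOM = 200
DEFAULT_SS_CUT = 0.90
DEFAULT_SWAP_MULTIPLIER = 10.0


@dataclass(frozen=True)
class SeedPair:
    """The two seed sets after discarding shared members.

    Seeds found in both raw lists are, by definition, already in the module
    overlap; they are removed before scoring and recorded in
    ``shared_discarded``.  Seeds absent from the network are silently dropped
    (with a logged count).
    """

    seeds_a: frozenset
    seeds_b: frozenset
    shared_discarded: frozenset

    def __post_init__(self):
        if self.seeds_a & self.seeds_b:
            raise ValueError("seed sets must be disjoint after construction")


def make_seed_pair(net: Network, raw_a, raw_b) -> SeedPair:
    """Clean two raw seed lists against the network and discard their overlap."""
    in_a = set(raw_a) & net.nodes
    in_b = set(raw_b) & net.nodes
    dropped = (len(set(raw_a)) - len(in_a)) + (len(set(raw_b)) - len(in_b))
    if dropped:
        logger.info("dropped %d seed(s) absent from the network", dropped)
    shared = in_a & in_b
    a = in_a - shared
    b = in_b - shared
    if not a or not b:
        raise ValueError(
            "a seed set is empty after dropping shared/unmapped seeds "
            f"(|a|={len(a)}, |b|={len(b)}, shared={len(shared)})"
        )
    return SeedPair(frozenset(a), frozenset(b), frozenset(shared))


def compute_s2b(net: Network, seeds: SeedPair, avgd: float) -> dict:
    """S2B score for every network node outside ``seeds.shared_discarded``.

    Implemented with one BFS per seed: the distance-additivity identity
    d(i,j) = d(i,k) + d(k,j) detects membership of k on a shortest path
    without ever materializing path sets.
    """
    if avgd <= 0:
        raise ValueError("avgd must be positive")
    a = sorted(seeds.seeds_a, key=str)
    b = sorted(seeds.seeds_b, key=str)
    if not a or not b:
        raise ValueError("seed sets must be non-empty")

    order = net.node_order
    n = len(order)
    da = net.distance_rows(a)  # (|a|, n)
    db = net.distance_rows(b)  # (|b|, n)
    b_idx = np.asarray([net.index_of(x) for x in b], dtype=np.intp)
    a_idx = np.asarray([net.index_of(x) for x in a], dtype=np.intp)

    d_ab = da[:, b_idx]  # (|a|, |b|)
    valid = np.isfinite(d_ab) & (d_ab <= avgd)  # the t(i,j) filter

    num = np.zeros(n)
    for ii in range(len(a)):
        js = np.flatnonzero(valid[ii])
        if js.size == 0:
            continue
        # sp(k, a_ii, b_j) for all k at once: d(i,k) + d(k,j) == d(i,j)
        sp = (da[ii][None, :] + db[js, :]) == d_ab[ii, js][:, None]
        num += sp.sum(axis=0)

    total = float(valid.sum())
    den = np.full(n, total)
    # drop pairs where k is an endpoint (sp is trivially 1 there)
    pairs_with_a = valid.sum(axis=1)  # per a-seed
    pairs_with_b = valid.sum(axis=0)  # per b-seed
    num[a_idx] -= pairs_with_a
    den[a_idx] -= pairs_with_a
    num[b_idx] -= pairs_with_b
    den[b_idx] -= pairs_with_b

    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    shared = seeds.shared_discarded
    return {node: float(score[i]) for i, node in enumerate(order) if node not in shared}


def s2b_threshold(scores: dict) -> float:
    """Elbow threshold of the score-vs-quantile L-curve.

    Each observed score s is mapped to the point (s / max, 1 − quantile(s)),
    where quantile(s) is the empirical fraction of scored nodes with score
    ≤ s; the threshold is the observed score closest to the origin, ties
    broken toward the smaller score.
    """
    vals = np.asarray(sorted(scores.values()), dtype=float)
    if vals.size == 0 or vals[-1] <= 0:
        raise ValueError("threshold undefined: no positive score")
    uniq, counts = np.unique(vals, return_counts=True)
    quantile = np.cumsum(counts) / vals.size
    obj = (uniq / uniq[-1]) ** 2 + (1.0 - quantile) ** 2
    return float(uniq[int(np.argmin(obj))])  # argmin returns first → smaller score


def _random_disjoint_seeds(net: Network, n_a: int, n_b: int, rng) -> SeedPair:
    order = net.node_order
    pick = rng.choice(len(order), size=n_a + n_b, replace=False)
    a = frozenset(order[i] for i in pick[:n_a])
    b = frozenset(order[i] for i in pick[n_a:])
    return SeedPair(a, b, frozenset())


def specificity_seeds(
    net: Network,
    seeds: SeedPair,
    scores: dict,
    n_random: int = DEFAULT_N_RANDOM,
    rng_seed: int = 0,
) -> dict:
    """SS1: fraction of random-seed randomizations the real score matches or beats.

    Random seed pairs are drawn uniformly without replacement from all network
    nodes, with the same sizes as the real sets and forced disjoint.  Every
    randomization contributes to all nodes simultaneously.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(rng_seed)
    avgd = cached_avgd(net)
    nodes = sorted(scores, key=str)
    real = np.asarray([scores[k] for k in nodes])
    wins = np.zeros(len(nodes))
    for _ in range(n_random):
        rnd_pair = _random_disjoint_seeds(net, len(seeds.seeds_a), len(seeds.seeds_b), rng)
        rnd = compute_s2b(net, rnd_pair, avgd)
        wins += real >= np.asarray([rnd[k] for k in nodes])
    return {k: float(w) / n_random for k, w in zip(nodes, wins)}


def specificity_network(
    net: Network,
    seeds: SeedPair,
    scores: dict,
    n_random: int = DEFAULT_N_RANDOM,
    swap_multiplier: float = DEFAULT_SWAP_MULTIPLIER,
    rng_seed: int = 0,
) -> dict:
    """SS2: fraction of degree-preserving rewirings the real score matches or beats.

    Each randomization rewires the network (degrees preserved), recomputes
    avgd on the rewired graph, and rescores the real seed pair there.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(rng_seed)
    nodes = sorted(scores, key=str)
    real = np.asarray([scores[k] for k in nodes])
    wins = np.zeros(len(nodes))
    for _ in range(n_random):
        sub = int(rng.integers(0, 2**31 - 1))
        g_r = rewire_degree_preserving(net, swap_multiplier, rng_seed=sub)
        avgd_r = average_path_length(g_r, rng_seed=sub)
        rnd = compute_s2b(g_r, seeds, avgd_r)
        wins += real >= np.asarray([rnd[k] for k in nodes])
    return {k: float(w) / n_random for k, w in zip(nodes, wins)}


@dataclass
class S2BResult:
    """Scores, specificity, threshold and the selected candidate set."""

    scores: dict
    ss1: dict
    ss2: dict
    threshold: float
    n_random: int
    seeds: SeedPair
    candidates: list = field(default_factory=list)

    def ranked_nodes(self) -> list:
        """All scored nodes, score descending, id ascending on ties."""
        return sorted(self.scores, key=lambda k: (-self.scores[k], str(k)))

    def to_frame(self) -> pd.DataFrame:
        ranked = self.ranked_nodes()
        cand = set(self.candidates)
        return pd.DataFrame(
            {
                "node": ranked,
                "s2b": [self.scores[k] for k in ranked],
                "ss1": [self.ss1.get(k, np.nan) for k in ranked],
                "ss2": [self.ss2.get(k, np.nan) for k in ranked],
                "rank": np.arange(1, len(ranked) + 1),
                "is_candidate": [k in cand for k in ranked],
                "is_seed_a": [k in self.seeds.seeds_a for k in ranked],
                "is_seed_b": [k in self.seeds.seeds_b for k in ranked],
            }
        )


def select_candidates(result: S2BResult, ss_cut: float = DEFAULT_SS_CUT) -> list:
    """Nodes with score strictly above the threshold and both SS above the cut.

    Returned score-descending (ids ascending on ties); shared discarded seeds
    are never candidates (they carry no score).
    """
    if not 0.0 <= ss_cut <= 1.0:
        raise ValueError("ss_cut must lie in [0, 1]")
    keep = [
        k
        for k, s in result.scores.items()
        if s > result.threshold
        and result.ss1.get(k, 0.0) > ss_cut
        and result.ss2.get(k, 0.0) > ss_cut
    ]
    return sorted(keep, key=lambda k: (-result.scores[k], str(k)))


def run_s2b(
    net: Network,
    raw_a,
    raw_b,
    n_random: int = DEFAULT_N_RANDOM,
    ss_cut: float = DEFAULT_SS_CUT,
    swap_multiplier: float = DEFAULT_SWAP_MULTIPLIER,
    rng_seed: int = 0,
    avgd: float | None = None,
) -> S2BResult:
    """Full pipeline: seed cleaning, scoring, threshold, SS1/SS2, selection."""
    seeds = make_seed_pair(net, raw_a, raw_b)
    if avgd is None:
        avgd = cached_avgd(net, rng_seed=rng_seed)
    scores = compute_s2b(net, seeds, avgd)
    threshold = s2b_threshold(scores)
    ss1 = specificity_seeds(net, seeds, scores, n_random, rng_seed=rng_seed + 1)
    ss2 = specificity_network(
        net, seeds, scores, n_random, swap_multiplier, rng_seed=rng_seed + 2
    )
    result = S2BResult(
        scores=scores,
        ss1=ss1,
        ss2=ss2,
        threshold=threshold,
        n_random=n_random,
        seeds=seeds,
    )
    result.candidates = select_candidates(result, ss_cut)
    return result
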