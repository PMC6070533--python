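"""Benchmark metrics and robustness experiments on artificial module pairs.

For each simulated pair the full node ranking by S2B is compared with the
known overlap: precision and neighbor-precision per rank (optionally smoothed
with a centered moving average over consecutive ranks), cumulative recall,
and the DIAMOnD-matched precision where the number of top S2B candidates is
set to the size of the DIAMOnD two-run intersection for the same pair.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import compute_s2b, make_seed_pair
from .diamond import diamond_overlap_candidates
from .network import Network, average_path_length, rewire_fraction
from .simulate import (
    DEFAULT_MEAN_DEGREE,
    DEFAULT_MODULE_SIZE,
    DEFAULT_N_NODES,
    DEFAULT_OVERLAP_BOUNDS,
    DEFAULT_SHELL_SIZE_RANGE,
    ModulePairTruth,
    make_base_network,
    make_module_pair,
    sample_seeds,
)

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from one global seed.

    Hash-based so adding a stage never perturbs the draws of earlier stages.
    """
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def rank_candidates(scores: dict, exclude: set = frozenset()) -> list:
    """Nodes sorted by score descending, id ascending on ties, minus ``exclude``."""
    if not scores:
        raise ValueError("empty score mapping")
    return sorted(
        (k for k in scores if k not in exclude),
        key=lambda k: (-scores[k], str(k)),
    )


def smooth_series(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty(len(values), dtype=float)
    for i in range(len(values)):
        lo = max(0, i - half)
        out[i] = np.mean(values[lo : i + half + 1])
    return out


@dataclass
class EvaluationCurve:
    """Per-rank precision, neighbor precision and recall against the truth."""

    rank: np.ndarray
    precision_at_rank: np.ndarray
    neighbor_precision_at_rank: np.ndarray
    recall_at_rank: np.ndarray
    smoothing_window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.rank,
                "precision": self.precision_at_rank,
                "neighbor_precision": self.neighbor_precision_at_rank,
                "recall": self.recall_at_rank,
            }
        )


def overlap_metrics(
    ranked: list, truth: ModulePairTruth, net: Network, window: int = 3
) -> EvaluationCurve:
    """Evaluate a ranked candidate list against the true module overlap.

    Precision at rank r is the (smoothed) indicator that the r-th candidate
    belongs to the overlap; neighbor precision the indicator that it has at
    least one direct neighbor in the overlap; recall the fraction of the
    overlap found at rank ≤ r (never smoothed, so it stays non-decreasing).
    """
    if not ranked:
        raise ValueError("empty ranking")
    overlap = truth.overlap
    hit = np.asarray([v in overlap for v in ranked], dtype=float)
    neigh = np.asarray(
        [any(w in overlap for w in net.neighbors(v)) for v in ranked], dtype=float
    )
    recall = np.cumsum(hit) / max(len(overlap), 1)
    return EvaluationCurve(
        rank=np.arange(1, len(ranked) + 1),
        precision_at_rank=smooth_series(hit, window),
        neighbor_precision_at_rank=smooth_series(neigh, window),
        recall_at_rank=recall,
        smoothing_window=window,
    )


class MatchedPrecision(NamedTuple):
    precision_s2b: float  # NaN when n_matched == 0
    precision_diamond: float
    n_matched: int


def matched_precision(
    s2b_ranked: list, diamond_candidates: set, truth: ModulePairTruth
) -> MatchedPrecision:
    """Precision of both methods at DIAMOnD's own candidate count.

    With an empty DIAMOnD intersection the precisions are undefined (NaN) and
    the pair is excluded from medians downstream.
    """
    n = len(diamond_candidates)
    if n == 0:
        return MatchedPrecision(float("nan"), float("nan"), 0)
    overlap = truth.overlap
    p_diamond = sum(1 for v in diamond_candidates if v in overlap) / n
    top = s2b_ranked[:n]
    p_s2b = sum(1 for v in top if v in overlap) / len(top)
    return MatchedPrecision(p_s2b, p_diamond, n)


@dataclass
class BenchmarkConfig:
    """Settings for one artificial-module benchmark run.

    Defaults reproduce the scaled-down study conditions: a 5,000-node
    preferential-attachment surrogate interactome at mean degree 8, 50 module
    pairs per model, 50% of each module used as seeds, DIAMOnD run for 250
    iterations per module.
    """

    models: tuple = ("shell",)
    n_pairs: int = 50
    n_nodes: int = DEFAULT_N_NODES
    mean_degree: float = DEFAULT_MEAN_DEGREE
    seed_fraction: float = 0.5
    contamination: float = 0.0
    rewire_frac: float = 0.0
    diamond_iters: int = 250
    overlap_bounds: tuple = DEFAULT_OVERLAP_BOUNDS
    shell_size_range: tuple = DEFAULT_SHELL_SIZE_RANGE
    module_size: int = DEFAULT_MODULE_SIZE
    top_k: int = 20
    window: int = 3
    max_tries: int = 100
    run_diamond: bool = True
    discard_shared: bool = True
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BenchmarkResult:
    per_pair: pd.DataFrame
    summary: pd.DataFrame
    n_failed: int
    config: BenchmarkConfig


def _quartiles(x: pd.Series) -> tuple[float, float, float]:
    x = x.dropna()
    if x.empty:
        return float("nan"), float("nan"), float("nan")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation (type 7)
    return float(med), float(q1), float(q3)


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Simulate module pairs, score them with S2B (and DIAMOnD), and tabulate.

    Per pair the table records module/overlap sizes, the DIAMOnD intersection
    size and precision, the matched S2B precision, the top-k precision, and
    the number of top-3 candidates inside the overlap (used for the pooled
    top-rank precision).  Known-overlap (shared) seeds are excluded from the
    candidate ranking when ``discard_shared`` is set; single-set seeds stay
    rankable, since they are legitimate candidates for the other module.
    """
    seed = config.rng_seed
    base = make_base_network(
        config.n_nodes, config.mean_degree, rng_seed=stage_seed(seed, "base")
    )
    scoring_net = base
    if config.rewire_frac > 0:
        scoring_net = rewire_fraction(
            base, config.rewire_frac, rng_seed=stage_seed(seed, "rewire")
        )
    avgd = average_path_length(scoring_net, rng_seed=stage_seed(seed, "avgd"))
    logger.info(
        "base network: %d nodes, %d edges, avgd=%.3f",
        base.n_nodes, base.n_edges, avgd,
    )

    rows = []
    n_failed = 0
    for model in config.models:
        for i in range(config.n_pairs):
            tag = f"{model}:{i}"
            try:
                truth = make_module_pair(
                    base,
                    model,
                    overlap_bounds=config.overlap_bounds,
                    rng_seed=stage_seed(seed, f"pair:{tag}"),
                    max_tries=config.max_tries,
                    shell_size_range=config.shell_size_range,
                    module_size=config.module_size,
                )
                raw_a, raw_b = sample_seeds(
                    truth,
                    config.seed_fraction,
                    config.contamination,
                    rng_seed=stage_seed(seed, f"seeds:{tag}"),
                )
                pair = make_seed_pair(scoring_net, raw_a, raw_b)
            except (ValueError, KeyError) as exc:
                logger.warning("pair %s skipped: %s", tag, exc)
                n_failed += 1
                continue

            scores = compute_s2b(scoring_net, pair, avgd)
            exclude = set(pair.shared_discarded) if config.discard_shared else set()
            ranked = rank_candidates(scores, exclude=exclude)

            overlap = truth.overlap
            top3 = ranked[:3]
            topk = ranked[: config.top_k]
            row = {
                "model": model,
                "pair": i,
                "size_a": len(truth.module_a),
                "size_b": len(truth.module_b),
                "overlap": len(overlap),
                "n_shared_seeds": len(pair.shared_discarded),
                "top3_hits": sum(1 for v in top3 if v in overlap),
                "top3_n": len(top3),
                "prec_topk": sum(1 for v in topk if v in overlap) / len(topk),
            }
            if config.run_diamond:
                inter = diamond_overlap_candidates(
                    scoring_net, raw_a, raw_b, config.diamond_iters
                )
                mp = matched_precision(ranked, inter, truth)
                row.update(
                    n_diamond=mp.n_matched,
                    prec_diamond=mp.precision_diamond,
                    prec_s2b_matched=mp.precision_s2b,
                )
            rows.append(row)

    per_pair = pd.DataFrame(rows)
    summary_rows = []
    if not per_pair.empty:
        metric_cols = [
            c
            for c in ("prec_s2b_matched", "prec_diamond", "n_diamond", "prec_topk")
            if c in per_pair.columns
        ]
        for model, grp in per_pair.groupby("model"):
            srow: dict = {"model": model, "n_pairs": len(grp)}
            for col in metric_cols:
                med, q1, q3 = _quartiles(grp[col])
                srow[f"{col}_median"] = med
                srow[f"{col}_q1"] = q1
                srow[f"{col}_q3"] = q3
            srow["top_rank_precision"] = (
                grp["top3_hits"].sum() / grp["top3_n"].sum()
                if grp["top3_n"].sum()
                else float("nan")
            )
            summary_rows.append(srow)
    summary = pd.DataFrame(summary_rows)
    if n_failed:
        logger.warning("%d pair(s) failed generation and were skipped", n_failed)
    return BenchmarkResult(per_pair=per_pair, summary=summary, n_failed=n_failed, config=config)
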