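"""Rank aggregation across scoring metrics.

Each metric ranks every candidate (best = 1; ties share the mean rank;
missing scores rank last within that metric).  The median of those
per-metric ranks gives a coarse total order; the best ``top_n`` candidates
by median rank are then re-ordered with the Schulze method, a
Condorcet-style scheme that treats each metric's ranking as one ballot and
orders candidates by widest (strongest) paths in the pairwise-preference
graph.  Ties at every stage break deterministically: by median rank, then
by input order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_TOP_N = 1000

#: ranking direction per built-in metric; cfd measures off-target *risk*
METRIC_DIRECTIONS = {
    "hsu2013": "higher",
    "cfd": "lower",
    "doench2014": "higher",
    "crisprscan": "higher",
}


def metric_ranks(values: pd.Series, direction: str) -> pd.Series:
    """Rank one metric's scores: best = 1, mean rank on ties, NaN last."""
    if direction not in ("higher", "lower"):
        raise ValueError(f"direction must be higher|lower, got {direction!r}")
    return values.rank(
        ascending=(direction == "lower"), method="average", na_option="bottom"
    )


def pairwise_preferences(ballots: np.ndarray) -> np.ndarray:
    """d[a, b] = number of ballots ranking candidate a above candidate b."""
    ballots = np.asarray(ballots, dtype=float)
    n = ballots.shape[1]
    d = np.zeros((n, n), dtype=np.int64)
    for r in ballots:
        d += (r[:, None] < r[None, :]).astype(np.int64)
    return d


def path_strengths(d: np.ndarray) -> np.ndarray:
    """Widest-path strengths p[a, b] over the pairwise-preference graph
    (Floyd-Warshall on the max-min semiring; only edges with d > d.T
    carry weight)."""
    p = np.where(d > d.T, d, 0).astype(np.int64)
    n = d.shape[0]
    for k in range(n):
        np.maximum(p, np.minimum(p[:, k, None], p[None, k, :]), out=p)
    np.fill_diagonal(p, 0)
    return p


def schulze_order(ballots: np.ndarray) -> list[int]:
    """Total order of candidates from rank ballots via widest paths.

    ``ballots`` is (n_ballots, n_candidates); lower rank = preferred.
    Returns candidate indices from winner to loser.  Candidates are ordered
    by their number of pairwise path victories, ties broken by mean ballot
    rank then by index.
    """
    ballots = np.asarray(ballots, dtype=float)
    n = ballots.shape[1]
    if n == 0:
        return []
    p = path_strengths(pairwise_preferences(ballots))
    wins = (p > p.T).sum(axis=1)
    mean_rank = ballots.mean(axis=0)
    order = sorted(range(n), key=lambda i: (-wins[i], mean_rank[i], i))
    return order


def rank_aggregate(
    scores: pd.DataFrame,
    metrics: list[tuple[str, str]],
    top_n: int = DEFAULT_TOP_N,
) -> pd.DataFrame:
    """Median rank for every candidate plus a Schulze rank for the top_n.

    ``scores`` holds one column per metric; ``metrics`` is an ordered list
    of (column, direction).  Returns a frame indexed like ``scores`` with
    ``medianRank`` (float) and ``schulzeRank`` (1..top_n, <NA> outside the
    re-ranked set).
    """
    if not metrics:
        raise ValueError("at least one metric is required")
    rank_cols = {}
    for name, direction in metrics:
        if name not in scores.columns:
            raise KeyError(f"metric column {name!r} missing from scores")
        rank_cols[name] = metric_ranks(scores[name], direction)
    ranks = pd.DataFrame(rank_cols, index=scores.index)
    median = ranks.median(axis=1)

    out = pd.DataFrame(index=scores.index)
    out["medianRank"] = median
    out["schulzeRank"] = pd.array([pd.NA] * len(scores), dtype="Int64")

    # deterministic selection of the top_n by (median rank, input order)
    positional = np.lexsort((np.arange(len(scores)), median.to_numpy()))
    chosen = positional[: min(top_n, len(scores))]
    if len(chosen):
        ballots = ranks.to_numpy().T[:, chosen]
        order = schulze_order(ballots)
        col = out.columns.get_loc("schulzeRank")
        for place, local_idx in enumerate(order, start=1):
            out.iloc[chosen[local_idx], col] = place
    return out
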