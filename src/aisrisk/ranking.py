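"""Quantile risk ranks and per-rank summaries.

Predicted introduction probabilities are classified into five quintile
"risk ranks": 5 very high, 4 high, 3 intermediate, 2 low, 1 negligible.
Class boundaries are the 20/40/60/80 percentiles of the probability vector
(linear-interpolation percentile definition); a value lying exactly on a
boundary goes to the lower class, so a constant vector is all rank 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyInputError

__all__ = [
    "RANK_LABELS",
    "RiskRanking",
    "rank_by_quantiles",
    "percentage",
    "count_at_or_above",
    "union_at_rank",
]

RANK_LABELS = {5: "very high", 4: "high", 3: "intermediate", 2: "low", 1: "negligible"}


@dataclass(frozen=True)
class RiskRanking:
    """Per-waterbody probability and quantile risk rank."""

    ids: tuple[str, ...]
    probabilities: np.ndarray
    ranks: np.ndarray  # int in 1..n_classes
    n_classes: int = 5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "prob": self.probabilities, "rank": self.ranks}
        )

    def ids_at_rank(self, rank: int) -> set[str]:
        return {i for i, r in zip(self.ids, self.ranks) if r == rank}


def rank_by_quantiles(
    ids, probabilities, n_classes: int = 5, ties: str = "lower"
) -> RiskRanking:
    """Classify probabilities into quantile risk ranks.

    ``ties`` controls boundary membership: "lower" (default) sends values on
    a class boundary to the lower class; "upper" to the higher one.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.size == 0:
        raise EmptyInputError("cannot rank an empty probability vector")
    qs = np.percentile(
        probabilities, np.linspace(0, 100, n_classes + 1)[1:-1], method="linear"
    )
    if ties == "lower":
        ranks = 1 + (probabilities[:, None] > qs[None, :]).sum(axis=1)
    elif ties == "upper":
        ranks = 1 + (probabilities[:, None] >= qs[None, :]).sum(axis=1)
    else:
        raise ValueError("ties must be 'lower' or 'upper'")
    return RiskRanking(
        ids=tuple(ids),
        probabilities=probabilities,
        ranks=ranks.astype(int),
        n_classes=n_classes,
    )


def percentage(
    count: int, total: int, decimals: int = 2, mode: str = "truncate"
) -> float:
    """Share of ``count`` in ``total`` as a percentage, to ``decimals`` places.

    The default convention truncates (floors) at the requested precision —
    the convention the source surveillance reports follow (e.g. 125 of
    18,411 prints as 0.67 %, not 0.68 %).  ``mode="round"`` applies banker's
    rounding instead.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    scale = 10**decimals
    if mode == "truncate":
        return math.floor(pct * scale + 1e-12) / scale
    if mode == "round":
        return round(pct, decimals)
    raise ValueError("mode must be 'truncate' or 'round'")


def count_at_or_above(ranking: RiskRanking, rank: int) -> tuple[int, float]:
    """Waterbodies with risk rank >= ``rank``: count and % of all waterbodies."""
    if not 1 <= rank <= ranking.n_classes:
        raise ValueError(f"rank must be in 1..{ranking.n_classes}")
    count = int((ranking.ranks >= rank).sum())
    return count, percentage(count, len(ranking.ids))


def union_at_rank(
    ranking_a: RiskRanking, ranking_b: RiskRanking, rank: int = 5
) -> dict[str, float]:
    """Union/intersection of the two species' sets at exactly ``rank``.

    Inclusion–exclusion in integer arithmetic: |A ∪ B| = |A| + |B| − |A ∩ B|.
    Percentage is of the full waterbody set.
    """
    if set(ranking_a.ids) != set(ranking_b.ids):
        raise AlignmentError("rankings cover different waterbody sets")
    a = ranking_a.ids_at_rank(rank)
    b = ranking_b.ids_at_rank(rank)
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return {
        "count_a": len(a),
        "count_b": len(b),
        "intersection": inter,
        "union": union,
        "union_pct": percentage(union, len(ranking_a.ids)),
    }
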