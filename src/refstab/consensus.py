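"""Arithmetic-mean-rank consensus across the three stability algorithms.

geNorm, NormFinder and BestKeeper frequently disagree on the exact order of
candidate reference genes.  The comprehensive ranking used here converts
each algorithm's output to dense ranks (1 = most stable; tied genes share a
rank and the next distinct value gets the previous rank + 1 — so a tied top
pair is followed by rank 2, not 3) and averages the three ranks per gene.
The gene list is then sorted ascending by mean rank; the mean is reported
to one decimal, rounded half-up, with full precision retained for ordering.

Dense ranking matters: with a geNorm ranking (A/B tied, C, D, ...) gene D
holds dense rank 3, and only that convention combines with single ranks
from the other algorithms into the familiar one-decimal consensus values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .stability.report import StabilityReport

__all__ = ["ConsensusRanking", "assign_dense_ranks", "mean_rank_consensus", "round_half_up"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (1.666... -> 1.7, 3.25 -> 3.3 at 1 decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConsensusRanking:
    """Comprehensive ranking table.

    ``table`` columns: rank_genorm, rank_normfinder, rank_bestkeeper,
    mean_rank (full precision), mean_rank_display (one decimal, half-up);
    rows sorted ascending by mean_rank, ties broken by geNorm rank then
    input order.  ``order`` repeats the sorted gene list.
    """

    table: pd.DataFrame
    order: list[str]

    def top(self, n: int = 4) -> list[str]:
        return self.order[:n]


def assign_dense_ranks(
    report: StabilityReport,
    unrankable: Literal["error", "last"] = "error",
) -> dict[str, int]:
    """Dense ranks (1 = most stable) from a stability report.

    Genes are sorted by metric in the report's stable direction; exactly
    equal metric values share a rank and the next distinct value receives
    the previous rank + 1.  Reports carrying precomputed ranks (geNorm's
    stepwise ordering with its structurally tied final pair) return those.
    Unrankable genes (undefined metric) raise by default, or are all
    assigned the last rank + 1 under ``unrankable="last"``.
    """
    if report.ranks is not None:
        return {g: int(r) for g, r in report.ranks.items()}
    metric = report.metric
    undefined = list(metric.index[metric.isna()])
    if undefined and unrankable == "error":
        raise ValueError(f"unrankable genes with undefined metric: {undefined}")
    defined = metric.dropna()
    keyed = defined if report.direction == "lower" else -defined
    ranks = keyed.rank(method="dense").astype(int)
    out = {g: int(ranks[g]) for g in metric.index if g in ranks}
    last = (max(out.values()) if out else 0) + 1
    for g in undefined:
        out[g] = last
    return out


def mean_rank_consensus(
    genorm: Mapping[str, int],
    normfinder: Mapping[str, int],
    bestkeeper: Mapping[str, int],
) -> ConsensusRanking:
    """Average the three algorithms' dense ranks per gene.

    All three maps must cover the same gene set; gene order follows the
    geNorm map.  mean_rank = (r_geNorm + r_NormFinder + r_BestKeeper) / 3.
    """
    genes = list(genorm)
    for name, other in (("normfinder", normfinder), ("bestkeeper", bestkeeper)):
        missing = [g for g in genes if g not in other]
        extra = [g for g in other if g not in genorm]
        if missing or extra:
            raise ValueError(
                f"gene sets differ between genorm and {name}: "
                f"missing={missing} extra={extra}"
            )
    rg = np.array([genorm[g] for g in genes], dtype=float)
    rn = np.array([normfinder[g] for g in genes], dtype=float)
    rb = np.array([bestkeeper[g] for g in genes], dtype=float)
    mean = (rg + rn + rb) / 3.0
    table = pd.DataFrame(
        {
            "rank_genorm": rg.astype(int),
            "rank_normfinder": rn.astype(int),
            "rank_bestkeeper": rb.astype(int),
            "mean_rank": mean,
            "mean_rank_display": [round_half_up(v, 1) for v in mean],
        },
        index=pd.Index(genes, name="gene"),
    )
    table["_input"] = np.arange(len(genes))
    table = table.sort_values(
        ["mean_rank", "rank_genorm", "_input"], kind="stable"
    ).drop(columns="_input")
    return ConsensusRanking(table=table, order=list(table.index))
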