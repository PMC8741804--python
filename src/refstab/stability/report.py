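"""Common result container for the three stability algorithms."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

__all__ = ["StabilityReport"]


@dataclass
class StabilityReport:
    """Per-gene stability metric and rank for one algorithm.

    ``metric`` holds the algorithm's native statistic (geNorm M, NormFinder
    stability value, BestKeeper Pearson r) indexed by gene in input order.
    ``direction`` states which end of the metric means stable:
    ``"lower"`` for M and the NormFinder stability value, ``"higher"`` for
    BestKeeper's r.  ``ranks`` is a dense ranking (1 = most stable, tied
    metric values share a rank); when an algorithm defines its own ordering
    beyond the raw metric — geNorm's stepwise exclusion with the final tied
    pair — the precomputed ranks stored here are authoritative.
    """

    algorithm: str
    metric: pd.Series
    direction: Literal["lower", "higher"]
    ranks: pd.Series | None = None
    unrankable: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in ("lower", "higher"):
            raise ValueError(f"direction must be 'lower' or 'higher', got {self.direction!r}")
        self.metric = self.metric.astype(float)
        if self.metric.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in metric")
        if self.ranks is not None:
            if set(self.ranks.index) != set(self.metric.index):
                raise ValueError("ranks and metric must cover the same genes")
            self.ranks = self.ranks.astype(int).reindex(self.metric.index)

    @property
    def genes(self) -> list[str]:
        return list(self.metric.index)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (gene, metric, rank) table sorted most-stable first."""
        from ..consensus import assign_dense_ranks  # local import, avoids cycle

        ranks = pd.Series(assign_dense_ranks(self))
        out = pd.DataFrame(
            {"gene": self.metric.index, "metric": self.metric.values,
             "rank": ranks.reindex(self.metric.index).values}
        )
        return out.sort_values(["rank", "gene"], kind="stable").reset_index(drop=True)
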