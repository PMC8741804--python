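"""BestKeeper: descriptive Ct statistics and correlation with the index.

BestKeeper summarizes each candidate gene's raw Ct distribution (geometric
mean, arithmetic mean, min, max, SD, CV) and scores stability by the
Pearson correlation of the gene's Ct with the BestKeeper index — the
per-sample geometric mean of all candidate genes' Ct values.  A gene that
tracks the panel-wide signal has r near 1; genes with high r rank as more
stable.

The dispersion column is the classical sample standard deviation of Ct by
default, with ``sd_method="mad"`` switching to the mean absolute deviation
from the gene's geometric mean (the convention of the original
spreadsheet tool).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from ..ct_io import CtMatrix, as_collapsed
from .report import StabilityReport

__all__ = ["BestKeeperStats", "bestkeeper_stats", "bestkeeper_report"]


@dataclass
class BestKeeperStats:
    """Per-gene descriptive table plus the per-sample BestKeeper index.

    ``table`` columns: geo_mean, arith_mean, min, max, sd, cv_pct, r,
    rankable — on the Ct scale; cv_pct = 100 * sd / arith_mean.  Genes with
    zero Ct variance have undefined r and are flagged not rankable.
    """

    table: pd.DataFrame
    index: pd.Series

    def ranking(self) -> pd.Series:
        """Dense ranks by descending r over the rankable genes."""
        r = self.table.loc[self.table["rankable"], "r"]
        order = (-r).round(12)  # guard float dust before tie detection
        return order.rank(method="dense").astype(int)


def bestkeeper_stats(
    m: CtMatrix, sd_method: Literal["sd", "mad"] = "sd"
) -> BestKeeperStats:
    """Compute BestKeeper descriptive statistics and index correlations."""
    m = as_collapsed(m)
    if m.n_samples < 2:
        raise ValueError("BestKeeper needs at least 2 samples")
    ct = m.values
    gm = stats.gmean(ct, axis=1)
    am = ct.mean(axis=1)
    if sd_method == "sd":
        sd = ct.std(axis=1, ddof=1)
    elif sd_method == "mad":
        sd = np.abs(ct - gm[:, None]).mean(axis=1)
    else:
        raise ValueError(f"unknown sd_method {sd_method!r}")
    index = stats.gmean(ct, axis=0)  # per-sample geometric mean over genes
    r = np.full(m.n_genes, np.nan)
    rankable = np.zeros(m.n_genes, dtype=bool)
    idx_const = np.ptp(index) == 0.0
    for i in range(m.n_genes):
        if np.ptp(ct[i]) == 0.0 or idx_const:
            continue  # zero variance: correlation undefined
        r[i] = stats.pearsonr(ct[i], index).statistic
        rankable[i] = True
    table = pd.DataFrame(
        {
            "geo_mean": gm,
            "arith_mean": am,
            "min": ct.min(axis=1),
            "max": ct.max(axis=1),
            "sd": sd,
            "cv_pct": 100.0 * sd / am,
            "r": r,
            "rankable": rankable,
        },
        index=m.genes,
    )
    return BestKeeperStats(table=table, index=pd.Series(index, index=m.samples, name="index"))


def bestkeeper_report(
    m: CtMatrix,
    sd_method: Literal["sd", "mad"] = "sd",
    unrankable: Literal["error", "last"] = "error",
) -> StabilityReport:
    """BestKeeper as a :class:`StabilityReport` (metric = r, higher stable).

    ``unrankable`` controls genes with undefined r: ``"error"`` raises,
    ``"last"`` keeps them with r = NaN so downstream ranking can push them
    to the bottom.
    """
    bk = bestkeeper_stats(m, sd_method=sd_method)
    bad = list(bk.table.index[~bk.table["rankable"]])
    if bad and unrankable == "error":
        raise ValueError(
            f"genes with undefined BestKeeper correlation (zero Ct variance): {bad}"
        )
    return StabilityReport(
        algorithm="BestKeeper",
        metric=bk.table["r"],
        direction="higher",
        unrankable=bad,
    )
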