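"""geNorm: pairwise-variation M values, stepwise ranking and V(n/n+1).

The geNorm measure of a gene's expression stability is the arithmetic mean
of its pairwise variations with every other candidate, where the pairwise
variation of genes j and k is the standard deviation over samples of the
log2 ratio of their relative quantities.  Because a loading shift common to
all genes in a sample cancels in every ratio, M is invariant to per-sample
additive Ct shifts — the property that lets stably co-expressed genes be
identified without knowing true input amounts.

Stepwise ranking repeatedly removes the gene with the highest M and
recomputes on the remainder; the last two genes cannot be distinguished by
ratios and are reported as a tied top pair.  The pairwise variation
V(n/n+1) between normalization factors built from the n and n+1 most stable
genes guides how many reference genes to use (the conventional advisory
cutoff is V < 0.15).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..ct_io import CtMatrix, as_collapsed
from .report import StabilityReport

__all__ = ["GeNormResult", "genorm_m_values", "genorm_stepwise_ranking", "genorm_report"]

#: advisory pairwise-variation cutoff below which adding a gene is unnecessary
V_CUTOFF = 0.15


@dataclass
class GeNormResult:
    """Stepwise geNorm output.

    ``m_values`` holds each gene's M at the step where it was excluded (for
    the final pair, their shared two-gene M) — the values a stability plot
    reports.  ``exclusion_order`` lists genes least-stable first.  ``ranks``
    is dense with the final pair tied at 1.  ``v_ratios`` maps n to
    V(n/n+1); ``recommended_n`` is the smallest n with V < 0.15 (None when
    no n qualifies).
    """

    m_values: pd.Series
    exclusion_order: list[str]
    ranks: pd.Series
    v_ratios: dict[int, float]
    recommended_n: int | None
    stability_order: list[str]


def _log2_quantities(m: CtMatrix, efficiency) -> np.ndarray:
    """log2 relative quantities per gene x sample.

    Q_ij = (1+E_i/100)^(Ctmin_i - Ct_ij); log2 Q = (Ctmin - Ct) * log2(1+E).
    The default E = 100% makes one Ct unit one twofold change, matching the
    2^-ddCt convention used downstream.
    """
    ct = m.values
    if efficiency is None:
        eff = np.full(m.n_genes, 100.0)
    elif np.isscalar(efficiency):
        eff = np.full(m.n_genes, float(efficiency))
    else:
        eff = np.asarray([efficiency[g] for g in m.genes], dtype=float)
    if np.any(eff <= 0):
        raise ValueError("amplification efficiencies must be positive")
    log2_base = np.log2(1.0 + eff / 100.0)
    return (ct.min(axis=1, keepdims=True) - ct) * log2_base[:, None]


def _m_from_log2q(q: np.ndarray) -> np.ndarray:
    """M_j = mean over k != j of SD_samples(log2 Q_j - log2 Q_k)."""
    G = q.shape[0]
    V = np.zeros((G, G))
    for j in range(G):
        for k in range(j + 1, G):
            V[j, k] = V[k, j] = np.std(q[j] - q[k], ddof=1)
    return V.sum(axis=1) / (G - 1)


def genorm_m_values(m: CtMatrix, efficiency=None) -> pd.Series:
    """Expression-stability measure M for every gene of a complete panel.

    ``efficiency`` may be None (E = 100% for all genes), a scalar percent,
    or a mapping gene -> percent.  Requires >= 2 samples and >= 3 genes;
    with exactly 2 genes M equals the pair's single pairwise variation for
    both genes and a warning is emitted (the original tool's behavior).
    """
    m = as_collapsed(m)
    if m.n_samples < 2:
        raise ValueError("geNorm needs at least 2 samples")
    if m.n_genes < 2:
        raise ValueError("geNorm needs at least 2 genes")
    if m.n_genes == 2:
        warnings.warn(
            "geNorm M for exactly 2 genes equals their single pairwise "
            "variation and cannot separate them",
            stacklevel=2,
        )
    q = _log2_quantities(m, efficiency)
    return pd.Series(_m_from_log2q(q), index=m.genes, name="M")


def genorm_stepwise_ranking(m: CtMatrix, efficiency=None) -> GeNormResult:
    """Iterative exclusion ranking plus the V(n/n+1) sequence.

    At each step the gene with the highest M (ties broken by input order)
    is removed and M recomputed on the remainder, until two genes are left;
    those two are the tied most-stable pair.  Normalization factors for the
    V statistic are geometric means of the n most stable genes' quantities,
    i.e. arithmetic means on the log2 scale.
    """
    m = as_collapsed(m)
    if m.n_genes < 3:
        raise ValueError("stepwise geNorm needs at least 3 genes")
    if m.n_samples < 2:
        raise ValueError("geNorm needs at least 2 samples")
    q_full = _log2_quantities(m, efficiency)
    genes = list(m.genes)
    remaining = list(range(m.n_genes))
    exclusion: list[int] = []
    m_at_exclusion = np.empty(m.n_genes)
    while len(remaining) > 2:
        mvals = _m_from_log2q(q_full[remaining])
        worst = int(np.argmax(mvals))  # first index attaining the max: input order
        m_at_exclusion[remaining[worst]] = mvals[worst]
        exclusion.append(remaining.pop(worst))
    pair_v = np.std(q_full[remaining[0]] - q_full[remaining[1]], ddof=1)
    for idx in remaining:
        m_at_exclusion[idx] = pair_v

    stability_idx = list(remaining) + exclusion[::-1]  # most stable first
    ranks = np.empty(m.n_genes, dtype=int)
    ranks[remaining] = 1
    for pos, idx in enumerate(exclusion[::-1]):
        ranks[idx] = pos + 2

    # V(n/n+1) between normalization factors of the n and n+1 most stable genes
    v_ratios: dict[int, float] = {}
    for n in range(2, m.n_genes):
        nf_n = q_full[stability_idx[:n]].mean(axis=0)
        nf_n1 = q_full[stability_idx[: n + 1]].mean(axis=0)
        v_ratios[n] = float(np.std(nf_n - nf_n1, ddof=1))
    recommended = next((n for n, v in sorted(v_ratios.items()) if v < V_CUTOFF), None)

    return GeNormResult(
        m_values=pd.Series(m_at_exclusion, index=genes, name="M"),
        exclusion_order=[genes[i] for i in exclusion],
        ranks=pd.Series(ranks, index=genes, name="rank"),
        v_ratios=v_ratios,
        recommended_n=recommended,
        stability_order=[genes[i] for i in stability_idx],
    )


def genorm_report(m: CtMatrix, efficiency=None) -> StabilityReport:
    """Stepwise geNorm as a :class:`StabilityReport` (ranks authoritative)."""
    res = genorm_stepwise_ranking(m, efficiency)
    return StabilityReport(
        algorithm="geNorm",
        metric=res.m_values,
        direction="lower",
        ranks=res.ranks,
    )
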