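"""Expression-table analysis: candidate screening, z-scores, K-means, DE filter.

This module operates on FPKM-like abundance tables (or relative-expression
tables from the ddCt step).  It covers the surrounding analysis chain of a
reference-gene study:

* screening candidate reference genes from RNA-seq — flat (max pairwise
  fold change < 2), expressed (FPKM >= 5 everywhere) and non-significant
  (q >= 0.05 in every comparison);
* per-gene z-score standardization prior to heatmap clustering;
* K-means clustering of standardized profiles (k = 12 for RNA-seq panels,
  k = 6 for qPCR panels by default);
* a differential-expression filter applying fold change > 2 and p < 0.05
  over all pairwise group comparisons (6 comparisons for 4 tissues), with
  Welch t-tests on log2 values per comparison and a one-way ANOVA per gene
  as the overall statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .ct_io import ExpressionMatrix

__all__ = [
    "ClusterResult",
    "DEResult",
    "screen_candidate_references",
    "zscore_standardize",
    "kmeans_cluster",
    "pairwise_comparisons",
    "differential_expression_filter",
    "group_mean_table",
]

DEFAULT_MIN_FPKM = 5.0
DEFAULT_MAX_FOLD = 2.0
DEFAULT_MIN_Q = 0.05


@dataclass
class ClusterResult:
    """K-means assignment of standardized expression profiles.

    ``labels`` maps each gene to a cluster id in 1..k; ``centroids`` is a
    k x samples table of cluster centers; ``inertia`` is the within-cluster
    sum of squares of the best restart.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    k: int
    seed: int
    inertia: float


@dataclass
class DEResult:
    """Pairwise differential-expression calls.

    ``table`` rows: (gene, comparison, fold_change, p_value, passes) with
    fold_change the direction-agnostic ratio of group means
    (max(a/b, b/a)); ``anova_p`` is the per-gene one-way ANOVA p value
    across all groups.  passes <=> fold_change > fold_threshold and
    p_value < alpha.
    """

    table: pd.DataFrame
    anova_p: pd.Series
    fold_threshold: float
    alpha: float


def _group_columns(e: ExpressionMatrix) -> dict[str, list[str]]:
    if e.groups is None:
        # ungrouped table: every column is its own group (tissue means)
        return {s: [s] for s in e.samples}
    out: dict[str, list[str]] = {}
    for s in e.samples:
        out.setdefault(e.groups[s], []).append(s)
    return out


def group_mean_table(e: ExpressionMatrix) -> pd.DataFrame:
    """Genes x groups table of group mean abundances."""
    cols = _group_columns(e)
    return pd.DataFrame({g: e.values[c].mean(axis=1) for g, c in cols.items()})


def pairwise_comparisons(groups: list[str]) -> list[tuple[str, str]]:
    """All unordered group pairs in enumeration order (4 groups -> 6 pairs)."""
    return list(itertools.combinations(groups, 2))


def screen_candidate_references(
    e: ExpressionMatrix,
    qvalues: pd.DataFrame,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    max_fold: float = DEFAULT_MAX_FOLD,
    min_q: float = DEFAULT_MIN_Q,
) -> list[str]:
    """Select candidate reference genes from an RNA-seq abundance table.

    A gene is retained when (i) its abundance is at least ``min_fpkm`` in
    every tissue (group mean), (ii) its largest pairwise fold change
    between tissues is below ``max_fold``, and (iii) its q value is at
    least ``min_q`` in every supplied comparison.  ``qvalues`` is a
    genes x comparisons table covering all of ``e``'s genes.
    """
    missing = [g for g in e.genes if g not in qvalues.index]
    if missing:
        raise ValueError(f"genes without q values: {missing[:5]}")
    means = group_mean_table(e)
    kept: list[str] = []
    for g in e.genes:
        row = means.loc[g]
        if (row < min_fpkm).any():
            continue
        hi, lo = float(row.max()), float(row.min())
        fold = np.inf if lo == 0 else hi / lo
        if fold >= max_fold:
            continue
        if (qvalues.loc[g] < min_q).any():
            continue
        kept.append(g)
    return kept


def zscore_standardize(
    values: pd.DataFrame | ExpressionMatrix, ddof: int = 1
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene z-score standardization of an expression table.

    Each row is centered to mean 0 and scaled to SD 1 (sample SD, ddof=1,
    by default; ``ddof=0`` for the population convention).  Zero-variance
    rows are mapped to all-zeros and flagged in the returned boolean
    series rather than producing NaNs.
    """
    frame = values.values if isinstance(values, ExpressionMatrix) else values
    if frame.shape[1] < 2:
        raise ValueError("z-score standardization needs at least 2 samples")
    arr = frame.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = sd[:, 0] == 0.0
    sd[degenerate] = 1.0
    z = (arr - mean) / sd
    z[degenerate] = 0.0
    return (
        pd.DataFrame(z, index=frame.index, columns=frame.columns),
        pd.Series(degenerate, index=frame.index, name="zero_variance"),
    )


def kmeans_cluster(
    standardized: pd.DataFrame, k: int, seed: int, n_restarts: int = 10
) -> ClusterResult:
    """Cluster gene profiles with Lloyd's algorithm, k-means++ seeding.

    Runs ``n_restarts`` initializations and keeps the lowest-inertia
    solution; deterministic for a fixed ``seed``.  Cluster ids are
    relabeled 1..k in order of first appearance down the gene list so the
    labeling is independent of scikit-learn internals.
    """
    if k > len(standardized):
        raise ValueError(f"k={k} exceeds the number of genes ({len(standardized)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(standardized.to_numpy(dtype=float))
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = pd.Series([relabel[lab] for lab in raw], index=standardized.index,
                       name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[[lab for lab, _ in sorted(relabel.items(), key=lambda t: t[1])]],
        index=pd.Index(range(1, k + 1), name="cluster"),
        columns=standardized.columns,
    )
    return ClusterResult(labels=labels, centroids=centroids, k=k, seed=seed,
                         inertia=float(km.inertia_))


def differential_expression_filter(
    e: ExpressionMatrix,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    strict: bool = True,
    log_offset: float = 0.0,
) -> DEResult:
    """Pairwise fold-change + p-value differential-expression calls.

    For every pair of groups the fold change is the ratio of group mean
    abundances (direction-agnostic) and the p value a two-sided Welch
    t-test on log2 values; a gene passes a comparison when fold > 2 and
    p < 0.05 (defaults).  A one-way ANOVA across all groups is reported
    per gene as the overall statistic.  Groups without replication cannot
    yield p values: ``strict=True`` raises, ``strict=False`` emits
    fold-only rows with p = NaN (never passing).  ``log_offset`` is added
    before the log2 transform when tables contain zeros.
    """
    cols = _group_columns(e)
    groups = list(cols)
    if len(groups) < 2:
        raise ValueError("differential expression needs at least 2 groups")
    unreplicated = [g for g, c in cols.items() if len(c) < 2]
    if unreplicated and strict:
        raise ValueError(f"groups without replication: {unreplicated}")
    with np.errstate(divide="ignore"):
        log2v = {g: np.log2(e.values[c].to_numpy() + log_offset) for g, c in cols.items()}
    means = group_mean_table(e)

    rows = []
    for a, b in pairwise_comparisons(groups):
        ma, mb = means[a].to_numpy(), means[b].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mb > 0, ma / mb, np.inf)
            fold = np.where(ratio >= 1.0, ratio, np.where(ratio > 0, 1.0 / ratio, np.inf))
        if len(cols[a]) >= 2 and len(cols[b]) >= 2:
            p = stats.ttest_ind(log2v[a], log2v[b], axis=1, equal_var=False).pvalue
        else:
            p = np.full(len(e.genes), np.nan)
        passes = (fold > fold_threshold) & (p < alpha)
        for i, gene in enumerate(e.genes):
            rows.append((gene, f"{a}_vs_{b}", float(fold[i]), float(p[i]),
                         bool(passes[i])))
    table = pd.DataFrame(rows, columns=["gene", "comparison", "fold_change",
                                        "p_value", "passes"])
    replicated = [g for g in groups if len(cols[g]) >= 2]
    if len(replicated) >= 2:
        anova = stats.f_oneway(*(log2v[g] for g in replicated), axis=1).pvalue
    else:
        anova = np.full(len(e.genes), np.nan)
    return DEResult(
        table=table,
        anova_p=pd.Series(anova, index=e.genes, name="anova_p"),
        fold_threshold=fold_threshold,
        alpha=alpha,
    )
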