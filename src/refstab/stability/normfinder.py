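"""NormFinder: model-based stability from intra- and inter-group variation.

NormFinder treats log-scale expression of gene i in sample j of group g as

    y_igj = alpha_ig + beta_gj + eps_igj,   Var(eps_igj) = sigma_ig^2

where ``beta_gj`` is a sample effect common to all genes (template amount)
and ``alpha_ig = mu_i + d_ig`` splits into a gene level and a gene x group
interaction ``d_ig`` — the systematic inter-group bias a poor reference
gene introduces.  Working on y = -Ct (so larger means more template; Ct is
already a log2 quantity up to sign and offset):

* intra-group variances ``sigma_ig^2`` are estimated from the doubly
  centered residuals within each group with a moment correction that
  removes the contamination each gene's residual picks up from the other
  genes through the per-sample centering;
* inter-group deviations ``d_ig`` are the two-way-centered gene x group
  means, shrunk toward zero in proportion to their sampling variance so a
  deviation supported by little data is discounted;
* the stability value of gene i averages, over groups, the magnitude of
  the shrunken deviation plus the intra-group SD ``sigma_ig`` — both on
  the cycle (log2) scale, so systematic bias and random noise contribute
  commensurably.  Lower is more stable.

Without group labels the same two-way model is fit to the whole matrix and
the per-gene residual SD (after the same moment correction) is returned —
pure intra-group variation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..ct_io import CtMatrix, as_collapsed
from .report import StabilityReport

__all__ = ["normfinder_stability", "normfinder_variances"]


def _corrected_gene_variances(y: np.ndarray) -> np.ndarray:
    """Moment-corrected per-gene residual variances for one group.

    ``y`` is (genes, samples).  Residuals remove gene and sample means; the
    naive residual mean square m_i then satisfies
    ``E[m_i] = (1 - 2/I) sigma_i^2 + (1/I^2) sum_k sigma_k^2``,
    which is inverted for sigma_i^2.  Negative estimates (possible at
    small n) are clamped to zero.
    """
    I, n = y.shape
    if I < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    if n < 2:
        raise ValueError("each group needs at least 2 samples")
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    m = (resid**2).sum(axis=1) / (n - 1)
    total = m.sum() / (1.0 - 1.0 / I)
    sigma2 = (m - total / I**2) / (1.0 - 2.0 / I)
    return np.clip(sigma2, 0.0, None)


def normfinder_variances(m: CtMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grouped variance decomposition: (sigma2_ig, d_ig, n_g) arrays.

    sigma2_ig and d_ig are (genes, groups); n_g is the per-group sample
    count.  Exposed separately for diagnostics and testing.
    """
    m = as_collapsed(m)
    if m.groups is None:
        raise ValueError("grouped decomposition requires group labels")
    y = -m.values  # negate Ct: larger = more template
    labels = [m.groups[s] for s in m.samples]
    group_names = list(dict.fromkeys(labels))
    cols = {g: [j for j, lab in enumerate(labels) if lab == g] for g in group_names}
    n_g = np.array([len(cols[g]) for g in group_names])
    if len(group_names) < 2:
        raise ValueError("grouped NormFinder needs at least 2 groups")
    if np.any(n_g < 2):
        bad = [g for g, n in zip(group_names, n_g) if n < 2]
        raise ValueError(f"groups with fewer than 2 samples: {bad}")
    sigma2 = np.column_stack([_corrected_gene_variances(y[:, cols[g]]) for g in group_names])
    gmeans = np.column_stack([y[:, cols[g]].mean(axis=1) for g in group_names])
    # two-way centering of gene x group means gives the interaction estimate
    d = (
        gmeans
        - gmeans.mean(axis=1, keepdims=True)
        - gmeans.mean(axis=0, keepdims=True)
        + gmeans.mean()
    )
    return sigma2, d, n_g


def normfinder_stability(m: CtMatrix, grouped: bool | None = None) -> StabilityReport:
    """Rank candidate reference genes by the NormFinder stability value.

    ``grouped=None`` uses group labels when the matrix carries them.  The
    grouped mode requires >= 2 groups with >= 2 samples each; ungrouped
    mode requires >= 3 samples and returns the model-based per-gene
    variation only.
    """
    m = as_collapsed(m)
    if grouped is None:
        grouped = m.groups is not None
    if grouped:
        sigma2, d, n_g = normfinder_variances(m)
        G = len(n_g)
        samp_var = sigma2 / n_g[None, :]  # sampling variance of each d_ig
        # method-of-moments estimate of the true inter-group variance
        gamma2 = max(0.0, float((d**2).mean() - samp_var.mean()))
        with np.errstate(invalid="ignore"):
            shrink = np.where(gamma2 + samp_var > 0, gamma2 / (gamma2 + samp_var), 0.0)
        d_shrunk = d * shrink
        rho = (np.abs(d_shrunk) + np.sqrt(sigma2)).mean(axis=1)
        metric = pd.Series(rho, index=m.genes, name="stability")
        if np.any(sigma2 == 0.0):
            warnings.warn(
                "negative intra-group variance estimate(s) clamped to 0",
                stacklevel=2,
            )
    else:
        if m.n_samples < 3:
            raise ValueError("ungrouped NormFinder needs at least 3 samples")
        sigma2 = _corrected_gene_variances(-m.values)
        metric = pd.Series(np.sqrt(sigma2), index=m.genes, name="stability")
    return StabilityReport(algorithm="NormFinder", metric=metric, direction="lower")
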