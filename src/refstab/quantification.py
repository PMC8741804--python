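"""Relative quantification by 2^-ddCt against a multi-reference factor.

Target expression is normalized to a set of validated reference genes via
their geometric mean: because 2^-(mean Ct of the references) equals the
geometric mean of the individual 2^-Ct quantities, the per-sample
reference factor is simply the arithmetic mean of the reference genes' Ct
values on the cycle scale.  Then

    dCt_js  = Ct_target,s - reffactor_s
    ddCt_js = dCt_js - dCt_calibrator
    fold    = 2^-ddCt

with the calibrator either a single sample or a group (mean dCt over the
group's samples).  Amplification efficiency is fixed at 100% (one cycle =
one doubling); efficiency-corrected variants are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_io import CtMatrix, as_collapsed

__all__ = ["RelativeExpression", "reference_factor", "delta_delta_ct"]


@dataclass
class RelativeExpression:
    """Fold changes of target genes relative to a calibrator.

    ``delta_ct``, ``delta_delta_ct`` and ``fold_change`` are
    targets x samples DataFrames; fold_change = 2^-ddCt is positive
    everywhere and exactly 1 at a sample calibrator by construction.
    """

    delta_ct: pd.DataFrame
    delta_delta_ct: pd.DataFrame
    fold_change: pd.DataFrame
    references: list[str]
    calibrator: str


def reference_factor(m: CtMatrix, refs: list[str]) -> pd.Series:
    """Per-sample normalization Ct: arithmetic mean of the reference genes' Ct.

    Equivalent to the geometric mean of the reference quantities under a
    common efficiency.
    """
    m = as_collapsed(m)
    if not refs:
        raise ValueError("reference gene set must be non-empty")
    missing = [g for g in refs if g not in m.genes]
    if missing:
        raise ValueError(f"reference genes absent from matrix: {missing}")
    idx = [m.genes.index(g) for g in refs]
    return pd.Series(m.values[idx].mean(axis=0), index=m.samples, name="ref_ct")


def delta_delta_ct(
    m: CtMatrix,
    targets: str | list[str],
    refs: list[str],
    calibrator: str,
) -> RelativeExpression:
    """Comparative 2^-ddCt quantification of one or more target genes.

    ``calibrator`` names either a sample or, when the matrix carries group
    labels, a group (its samples' mean dCt becomes the baseline).  Targets
    may not be part of the reference set.
    """
    m = as_collapsed(m)
    if isinstance(targets, str):
        targets = [targets]
    overlap = sorted(set(targets) & set(refs))
    if overlap:
        raise ValueError(f"targets also listed as references: {overlap}")
    missing = [g for g in targets if g not in m.genes]
    if missing:
        raise ValueError(f"target genes absent from matrix: {missing}")

    ref_ct = reference_factor(m, refs)
    rows = [m.genes.index(g) for g in targets]
    dct = pd.DataFrame(
        m.values[rows] - ref_ct.to_numpy()[None, :], index=targets, columns=m.samples
    )
    if calibrator in m.samples:
        base = dct[calibrator]
    elif m.groups is not None and calibrator in set(m.groups.values()):
        cols = [s for s in m.samples if m.groups[s] == calibrator]
        base = dct[cols].mean(axis=1)
    else:
        raise ValueError(f"calibrator {calibrator!r} is neither a sample nor a group")
    ddct = dct.sub(base, axis=0)
    return RelativeExpression(
        delta_ct=dct,
        delta_delta_ct=ddct,
        fold_change=2.0**(-ddct),
        references=list(refs),
        calibrator=calibrator,
    )
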