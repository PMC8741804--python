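"""Reading, writing and validation of Ct tables, dilution series and expression tables.

The central container is :class:`CtMatrix`: quantification-cycle (Ct) values
for a panel of genes measured across samples, optionally carrying a technical
replicate axis and a sample -> group assignment (e.g. woody tissue zones).
Stability algorithms operate on a complete, replicate-collapsed matrix;
:func:`collapse_replicates` averages the replicate axis and reports per-cell
replicate SD for QC.

Two delimited-text layouts are supported for Ct data:

* wide — first column is the gene identifier, remaining columns are samples;
  technical replicates may be encoded as repeated sample columns with a
  numeric suffix (``S1_1, S1_2, S1_3``);
* long — columns ``gene, sample, replicate, ct``.

Delimiters are auto-detected among comma and tab; decimal points only.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "DilutionSeries",
    "ExpressionMatrix",
    "CtParseError",
    "read_ct_table",
    "write_ct_table",
    "collapse_replicates",
    "read_expression_table",
    "write_expression_table",
    "read_group_table",
    "read_dilution_series",
    "write_dilution_series",
]

#: strings interpreted as a missing Ct value (empty cell included)
MISSING_TOKENS = frozenset({"", "na", "n/a", "nan", "nd", "null", "none"})

_REPLICATE_SUFFIX = re.compile(r"^(?P<base>.+?)[._](?P<rep>\d+)$")


class CtParseError(ValueError):
    """Raised when a delimited Ct/expression table cannot be parsed."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CtMatrix:
    """Ct values per gene x sample, optionally with a technical replicate axis.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_samples)`` or
        ``(n_genes, n_samples, n_replicates)``.  All entries must be finite
        and strictly positive (cycles).
    genes, samples
        Unique ordered identifiers matching the first two axes.
    groups
        Optional mapping sample -> group label; when present every sample
        must have exactly one label.
    """

    values: np.ndarray
    genes: list[str]
    samples: list[str]
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        if self.values.ndim not in (2, 3):
            raise ValueError(f"values must be 2-D or 3-D, got ndim={self.values.ndim}")
        if self.values.shape[0] != len(self.genes):
            raise ValueError("gene axis does not match number of gene identifiers")
        if self.values.shape[1] != len(self.samples):
            raise ValueError("sample axis does not match number of sample identifiers")
        if self.values.ndim == 3 and self.values.shape[2] < 1:
            raise ValueError("replicate axis must have at least one replicate")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Ct values must all be finite")
        if not np.all(self.values > 0):
            raise ValueError("Ct values must be strictly positive")
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if self.groups is not None:
            missing = [s for s in self.samples if s not in self.groups]
            if missing:
                raise ValueError(f"samples without a group label: {missing}")
            self.groups = {s: str(self.groups[s]) for s in self.samples}

    # -- shape -------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def has_replicates(self) -> bool:
        return self.values.ndim == 3

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2] if self.has_replicates else 1

    # -- views -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Genes x samples DataFrame (requires a collapsed, 2-D matrix)."""
        if self.has_replicates:
            raise ValueError("matrix has a replicate axis; collapse_replicates first")
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def group_series(self) -> pd.Series | None:
        if self.groups is None:
            return None
        return pd.Series([self.groups[s] for s in self.samples], index=self.samples)

    def subset_genes(self, genes: list[str]) -> "CtMatrix":
        idx = [self.genes.index(g) for g in genes]
        return CtMatrix(self.values[idx], list(genes), list(self.samples), self.groups)


@dataclass
class DilutionSeries:
    """Mean Ct of a template dilution series for one assay.

    ``log10_quantity`` is log10 of relative template input (most concentrated
    point conventionally at 0; fivefold steps give increments of -log10(5)).
    """

    gene: str
    log10_quantity: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.log10_quantity = np.asarray(self.log10_quantity, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.log10_quantity.shape != self.ct.shape or self.log10_quantity.ndim != 1:
            raise ValueError("log10_quantity and ct must be 1-D arrays of equal length")
        if len(self.ct) < 3:
            raise ValueError("a dilution series needs at least 3 points")
        diffs = np.diff(self.log10_quantity)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("log10_quantity must be strictly monotone")
        if not np.all(np.isfinite(self.ct)):
            raise ValueError("Ct values must be finite")


@dataclass
class ExpressionMatrix:
    """Non-negative abundance values (FPKM or relative expression), genes x samples."""

    values: pd.DataFrame
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if np.any(arr < 0):
            raise ValueError("expression values must be non-negative")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.groups is not None:
            missing = [s for s in self.values.columns if s not in self.groups]
            if missing:
                raise ValueError(f"samples without a group label: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text.splitlines() else ""
    if first.count("\t") > first.count(","):
        return "\t"
    return ","


def _read_rows(path) -> list[list[str]]:
    text = Path(path).read_text()
    if not text.strip():
        raise CtParseError(f"{path}: file is empty")
    delim = _sniff_delimiter(text)
    rows = [row for row in csv.reader(io.StringIO(text), delimiter=delim) if row]
    return [[cell.strip() for cell in row] for row in rows]


def _parse_cell(raw: str, *, row_id: str, col_id: str, path) -> float:
    """Parse one Ct/expression cell; distinguish missing from malformed."""
    if raw.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(raw)
    except ValueError:
        raise CtParseError(
            f"{path}: non-numeric value {raw!r} at row {row_id!r}, column {col_id!r}"
        ) from None


def _is_long_ct_header(header: list[str]) -> bool:
    low = [h.lower() for h in header]
    return len(low) >= 4 and low[:4] == ["gene", "sample", "replicate", "ct"]


def _wide_replicate_layout(columns: list[str]) -> tuple[list[str], int] | None:
    """Detect 'S1_1,S1_2,...' replicate-suffixed columns.

    Returns (ordered base sample names, replicate count) when every column
    carries a numeric suffix and each base repeats the same number of times;
    otherwise None (plain wide layout).
    """
    bases: dict[str, int] = {}
    order: list[str] = []
    for col in columns:
        m = _REPLICATE_SUFFIX.match(col)
        if m is None:
            return None
        base = m.group("base")
        if base not in bases:
            bases[base] = 0
            order.append(base)
        bases[base] += 1
    counts = set(bases.values())
    if counts == {1} or len(counts) != 1:
        return None
    return order, counts.pop()


def _drop_missing_samples(
    values: np.ndarray, samples: list[str], missing_policy: str, path
) -> tuple[np.ndarray, list[str]]:
    flat = values.reshape(values.shape[0], values.shape[1], -1)
    bad = np.isnan(flat).any(axis=(0, 2))
    if not bad.any():
        return values, samples
    if missing_policy != "drop_sample":
        g, s = np.argwhere(np.isnan(flat))[0][:2]
        raise CtParseError(
            f"{path}: missing Ct at row {g + 1} (gene axis), sample {samples[s]!r}; "
            "set missing='drop_sample' to discard incomplete samples"
        )
    keep = ~bad
    return values[:, keep], [s for s, k in zip(samples, keep) if k]


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def read_ct_table(
    path,
    *,
    missing: Literal["error", "drop_sample"] = "error",
    groups: dict[str, str] | None = None,
) -> CtMatrix:
    """Read a wide or long delimited Ct table into a :class:`CtMatrix`.

    File ordering of genes and samples is preserved.  ``missing`` selects the
    policy for empty/NA cells: ``"error"`` (default) rejects them naming the
    cell, ``"drop_sample"`` removes every sample with any missing value so
    downstream algorithms see a complete matrix.
    """
    rows = _read_rows(path)
    header = rows[0]
    if _is_long_ct_header(header):
        mat, genes, samples = _read_long_ct(rows[1:], path)
    else:
        mat, genes, samples = _read_wide_ct(rows, path)
    mat, samples = _drop_missing_samples(mat, samples, missing, path)
    if groups is not None:
        groups = {s: groups[s] for s in samples if s in groups}
        if len(groups) < len(samples):
            groups = None if not groups else groups
    return CtMatrix(mat, genes, samples, groups)


def _read_wide_ct(rows: list[list[str]], path) -> tuple[np.ndarray, list[str], list[str]]:
    header = rows[0]
    columns = header[1:]
    if not columns:
        raise CtParseError(f"{path}: wide table needs at least one sample column")
    genes: list[str] = []
    for row in rows[1:]:
        if row[0] in genes:
            raise CtParseError(f"{path}: duplicate gene id {row[0]!r}")
        genes.append(row[0])
    rep_layout = _wide_replicate_layout(columns)
    raw = np.empty((len(genes), len(columns)))
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise CtParseError(f"{path}: row for gene {row[0]!r} has {len(row) - 1} "
                               f"values, expected {len(columns)}")
        for j, cell in enumerate(row[1:]):
            raw[i, j] = _parse_cell(cell, row_id=row[0], col_id=columns[j], path=path)
    if rep_layout is None:
        return raw, genes, list(columns)
    samples, n_rep = rep_layout
    # columns may interleave; gather by base name preserving suffix order
    cube = np.empty((len(genes), len(samples), n_rep))
    for s_idx, base in enumerate(samples):
        cols = [j for j, c in enumerate(columns)
                if _REPLICATE_SUFFIX.match(c).group("base") == base]
        cols.sort(key=lambda j: int(_REPLICATE_SUFFIX.match(columns[j]).group("rep")))
        cube[:, s_idx, :] = raw[:, cols]
    return cube, genes, samples


def _read_long_ct(rows: list[list[str]], path) -> tuple[np.ndarray, list[str], list[str]]:
    genes: list[str] = []
    samples: list[str] = []
    cells: dict[tuple[str, str], list[float]] = {}
    for row in rows:
        if len(row) < 4:
            raise CtParseError(f"{path}: long-format row too short: {row}")
        gene, sample = row[0], row[1]
        if gene not in genes:
            genes.append(gene)
        if sample not in samples:
            samples.append(sample)
        value = _parse_cell(row[3], row_id=f"{gene}/{sample}", col_id="ct", path=path)
        cells.setdefault((gene, sample), []).append(value)
    counts = {len(v) for v in cells.values()}
    if len(cells) != len(genes) * len(samples):
        missing = [(g, s) for g in genes for s in samples if (g, s) not in cells]
        raise CtParseError(f"{path}: incomplete gene x sample grid, missing {missing[:5]}")
    if len(counts) != 1:
        raise CtParseError(f"{path}: uneven replicate counts per cell: {sorted(counts)}")
    n_rep = counts.pop()
    mat = np.empty((len(genes), len(samples), n_rep))
    for (g, s), vals in cells.items():
        mat[genes.index(g), samples.index(s), :] = vals
    if n_rep == 1:
        mat = mat[:, :, 0]
    return mat, genes, samples


def write_ct_table(m: CtMatrix, path, *, layout: Literal["wide", "long"] = "wide",
                   sep: str = ",") -> None:
    """Write a CtMatrix back to delimited text (round-trips with read_ct_table)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        if layout == "long":
            w.writerow(["gene", "sample", "replicate", "ct"])
            vals = m.values if m.has_replicates else m.values[:, :, None]
            for i, g in enumerate(m.genes):
                for j, s in enumerate(m.samples):
                    for r in range(vals.shape[2]):
                        w.writerow([g, s, r + 1, repr(float(vals[i, j, r]))])
        elif layout == "wide":
            if m.has_replicates:
                cols = [f"{s}_{r + 1}" for s in m.samples for r in range(m.n_replicates)]
                w.writerow(["gene", *cols])
                flat = m.values.reshape(m.n_genes, -1)
                for i, g in enumerate(m.genes):
                    w.writerow([g, *(repr(float(x)) for x in flat[i])])
            else:
                w.writerow(["gene", *m.samples])
                for i, g in enumerate(m.genes):
                    w.writerow([g, *(repr(float(x)) for x in m.values[i])])
        else:
            raise ValueError(f"unknown layout {layout!r}")


def collapse_replicates(
    m: CtMatrix, method: Literal["mean"] = "mean"
) -> tuple[CtMatrix, pd.DataFrame]:
    """Average the technical-replicate axis.

    Returns the collapsed matrix together with the per-cell replicate
    standard deviation (ddof=1; zero when only one replicate) for QC.
    Averaging is the arithmetic mean of Ct, the convention of the
    downstream stability tools.
    """
    if method != "mean":
        raise ValueError(f"unsupported collapse method {method!r}")
    if not m.has_replicates:
        raise ValueError("matrix has no replicate axis")
    collapsed = m.values.mean(axis=2)
    if m.n_replicates > 1:
        sd = m.values.std(axis=2, ddof=1)
    else:
        sd = np.zeros((m.n_genes, m.n_samples))
    qc = pd.DataFrame(sd, index=m.genes, columns=m.samples)
    return CtMatrix(collapsed, list(m.genes), list(m.samples), m.groups), qc


def as_collapsed(m: CtMatrix) -> CtMatrix:
    """Return a 2-D matrix, averaging technical replicates if present."""
    if m.has_replicates:
        m, _ = collapse_replicates(m)
    return m


# ---------------------------------------------------------------------------
# expression tables, group designs, dilution series
# ---------------------------------------------------------------------------

def read_expression_table(path, *, groups: dict[str, str] | None = None) -> ExpressionMatrix:
    """Read a wide genes x samples abundance table (FPKM or relative units)."""
    rows = _read_rows(path)
    header = rows[0]
    columns = header[1:]
    genes = []
    data = np.empty((len(rows) - 1, len(columns)))
    for i, row in enumerate(rows[1:]):
        if row[0] in genes:
            raise CtParseError(f"{path}: duplicate gene id {row[0]!r}")
        genes.append(row[0])
        for j, cell in enumerate(row[1:]):
            v = _parse_cell(cell, row_id=row[0], col_id=columns[j], path=path)
            if np.isnan(v):
                raise CtParseError(f"{path}: missing value at row {row[0]!r}, "
                                   f"column {columns[j]!r}")
            if v < 0:
                raise CtParseError(f"{path}: negative abundance {v} at row {row[0]!r}, "
                                   f"column {columns[j]!r}")
            data[i, j] = v
    frame = pd.DataFrame(data, index=genes, columns=columns)
    return ExpressionMatrix(frame, groups)


def write_expression_table(e: ExpressionMatrix, path, *, sep: str = ",") -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["gene", *e.values.columns])
        for g, row in e.values.iterrows():
            w.writerow([g, *(repr(float(x)) for x in row)])


def read_group_table(path) -> dict[str, str]:
    """Read a two-column (sample, group) design; a header row is optional."""
    rows = _read_rows(path)
    if rows and rows[0][0].lower() in {"sample", "id"}:
        rows = rows[1:]
    out: dict[str, str] = {}
    for row in rows:
        if len(row) < 2:
            raise CtParseError(f"{path}: design rows need (sample, group), got {row}")
        if row[0] in out:
            raise CtParseError(f"{path}: sample {row[0]!r} assigned twice")
        out[row[0]] = row[1]
    return out


def read_dilution_series(path, *, gene: str | None = None) -> DilutionSeries:
    """Read a two-column (log10_quantity, ct) dilution table for one assay."""
    rows = _read_rows(path)
    if rows and not _is_float(rows[0][0]):
        rows = rows[1:]
    lq, ct = [], []
    for row in rows:
        if len(row) < 2:
            raise CtParseError(f"{path}: dilution rows need (log10_quantity, ct)")
        lq.append(_parse_cell(row[0], row_id=row[0], col_id="log10_quantity", path=path))
        ct.append(_parse_cell(row[1], row_id=row[0], col_id="ct", path=path))
    return DilutionSeries(gene or Path(path).stem, np.asarray(lq), np.asarray(ct))


def write_dilution_series(d: DilutionSeries, path, *, sep: str = ",") -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["log10_quantity", "ct"])
        for q, c in zip(d.log10_quantity, d.ct):
            w.writerow([repr(float(q)), repr(float(c))])


def _is_float(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False
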