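"""Reading, writing and preprocessing of expression and clinical tables.

Preprocessing mirrors the conventional bulk RNA-seq route into
signature scoring: quantile normalization across samples followed by a
log2(x + 1) transform. Quantile normalization is a documented default
for inputs that arrive un-normalized; pre-normalized matrices can skip
it (see :class:`stromasig.config.RunConfig`).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLINICAL_COLUMNS, LOG2, RAW, ClinicalTable, ExpressionMatrix
from .errors import DomainError, ParseError

logger = logging.getLogger(__name__)


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ParseError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    return "\t" if dialect == "tsv" else ","


def read_expression(
    path: str | Path,
    dialect: str | None = None,
    duplicate_genes: str = "mean",
) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV/CSV.

    First column = gene symbols, header row = sample identifiers.
    Duplicate gene rows are collapsed by ``mean`` (default) or by
    keeping the ``first`` occurrence; either way a warning is logged.
    A blank or non-numeric cell raises :class:`ParseError` naming the
    offending gene and sample.
    """
    if duplicate_genes not in ("mean", "first"):
        raise ParseError(f"duplicate_genes must be 'mean' or 'first', got {duplicate_genes!r}")
    sep = _sep_for(path, dialect)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ParseError(f"{path}: cannot parse expression matrix: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    if raw.columns.duplicated().any() or any(
        str(c).startswith("Unnamed:") or str(c) == "" for c in raw.columns
    ):
        raise ParseError(f"{path}: malformed header (blank or duplicate sample identifiers)")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric or blank cell at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} (value {raw.iat[i, j]!r})"
        )
    numeric.index = numeric.index.astype(str)
    if numeric.index.duplicated().any():
        dupes = sorted(set(numeric.index[numeric.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene symbols by %s: %s",
            len(dupes), duplicate_genes, dupes[:10],
        )
        if duplicate_genes == "mean":
            order = numeric.index.drop_duplicates()
            numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
        else:
            numeric = numeric[~numeric.index.duplicated(keep="first")]
    return ExpressionMatrix(numeric.astype(float), scale=RAW)


def write_expression(m: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    m.data.to_csv(path, sep=_sep_for(path, dialect), index_label="gene")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to a shared reference distribution.

    The reference is the vector of row-wise means of the column-sorted
    matrix; ties within a column receive the mean of the reference
    quantiles they span. Requires a raw-scale, non-negative matrix.
    """
    if m.scale != RAW:
        raise DomainError(f"quantile_normalize expects a raw-scale matrix, got {m.scale!r}")
    X = m.values.astype(float)
    if (X < 0).any():
        raise DomainError("quantile_normalize requires non-negative values")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average the assigned reference values within tie groups
        out[:, j] = pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), scale=RAW
    )


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Apply log2(x + pseudocount) cell-wise; flags the matrix as log2-scale."""
    if pseudocount <= 0:
        raise DomainError(f"pseudocount must be positive, got {pseudocount}")
    if (m.values < 0).any():
        raise DomainError("log2_transform requires non-negative values")
    return ExpressionMatrix(np.log2(m.data + pseudocount), scale=LOG2)


def read_clinical(path: str | Path, dialect: str | None = None) -> ClinicalTable:
    """Read a clinical table with columns sample, time, event (+ covariates).

    Records with missing time or event are dropped (count logged);
    an event value outside {0, 1} is a parse error.
    """
    sep = _sep_for(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: cannot parse clinical table: {exc}") from exc
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: clinical table missing columns {missing}")
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    drop = time.isna() | event.isna()
    if drop.any():
        logger.warning("dropping %d clinical records with missing time/event", int(drop.sum()))
        df, time, event = df[~drop], time[~drop], event[~drop]
    if len(df) == 0:
        raise ParseError(f"{path}: no usable clinical records")
    if not event.isin([0, 1]).all():
        bad = sorted(set(event[~event.isin([0, 1])]))
        raise ParseError(f"{path}: event values outside {{0,1}}: {bad[:5]}")
    df = df.copy()
    df["sample"] = df["sample"].astype(str)
    df["time"] = time.astype(float)
    df["event"] = event.astype(int)
    return ClinicalTable(df.reset_index(drop=True))


def write_clinical(t: ClinicalTable, path: str | Path, dialect: str | None = None) -> None:
    t.data.to_csv(path, sep=_sep_for(path, dialect), index=False)
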