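"""Signature scoring: sum of per-gene z-scaled expression, and the
ECM/stromal-to-immune-activation ratio statistic.

The score of a sample for a gene set is the plain sum of the z-scaled
(per-gene, across samples) log2 expression of the set's genes — an
unweighted sum, not an enrichment statistic. Because such sums are
centred at zero, a raw quotient of two scores is undefined or unstable
whenever the denominator crosses zero; the default ``rank_ratio`` mode
therefore divides fractional ranks (strictly positive, monotone in each
score), with ``minmax_ratio`` and ``difference`` as alternatives.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import LOG2, ZSCORE, ExpressionMatrix
from .errors import DomainError, ParseError, ValidationError
from .signatures import GeneSignature, normalize_symbol

logger = logging.getLogger(__name__)

RATIO_MODES = ("rank_ratio", "minmax_ratio", "difference")


@dataclasses.dataclass
class ScoreTable:
    """Per-sample signature scores plus the optional derived ratio.

    ``scores`` is a samples x signatures DataFrame; ``missing`` records,
    per signature, genes absent from the scored matrix (provenance).
    """

    scores: pd.DataFrame
    ratio: pd.Series | None = None
    ratio_definition: str | None = None
    missing: dict[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.columns.duplicated().any():
            raise ValidationError("duplicate signature names in score table")
        if self.ratio is not None and not self.ratio.index.equals(self.scores.index):
            raise ValidationError("ratio vector must align with score table samples")

    @property
    def samples(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.rename(columns=lambda c: f"score_{c}")
        if self.ratio is not None:
            out = out.assign(ratio=self.ratio)
        out.index.name = "sample"
        return out


def zscale_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sd 1 (denominator n-1).

    Zero-variance rows become all-zero with a logged warning. Requires
    a log2-scale matrix with at least two samples.
    """
    if m.scale != LOG2:
        raise DomainError(f"zscale_genes expects a log2-scale matrix, got {m.scale!r}")
    if m.n_samples < 2:
        raise DomainError("z-scaling is undefined for a single-sample matrix")
    X = m.values.astype(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning(
            "%d zero-variance gene rows set to all-zero: %s",
            int(flat.sum()), [m.genes[i] for i in np.nonzero(flat)[0][:10]],
        )
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    Z[flat, :] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(Z, index=m.data.index, columns=m.data.columns), scale=ZSCORE
    )


def score_signature(
    m: ExpressionMatrix,
    sig: GeneSignature,
    min_coverage: float = 1.0,
) -> tuple[pd.Series, tuple[str, ...]]:
    """Sum the z-scaled expression of a signature's genes per sample.

    Returns the score vector and the tuple of signature genes missing
    from the matrix. Symbol matching is alias-aware and
    case-insensitive. Raises if the present fraction of signature genes
    falls below ``min_coverage``.
    """
    if m.scale != ZSCORE:
        raise DomainError(f"score_signature expects a z-scaled matrix, got {m.scale!r}")
    row_of = {normalize_symbol(g): g for g in m.genes}
    present = [g for g in sig.genes if g in row_of]
    absent = tuple(g for g in sig.genes if g not in row_of)
    coverage = len(present) / len(sig.genes)
    if coverage < min_coverage:
        raise ValidationError(
            f"signature {sig.name!r}: coverage {coverage:.2f} below "
            f"min_coverage {min_coverage:.2f}; missing genes: {list(absent)}"
        )
    if absent:
        logger.warning("signature %s: %d genes absent: %s", sig.name, len(absent), list(absent))
    score = m.data.loc[[row_of[g] for g in present]].sum(axis=0)
    score.name = sig.name
    return score, absent


def score_signatures(
    m: ExpressionMatrix,
    signatures: list[GeneSignature],
    min_coverage: float = 1.0,
) -> ScoreTable:
    """Score several signatures on one matrix into a :class:`ScoreTable`."""
    cols, missing = {}, {}
    for sig in signatures:
        s, absent = score_signature(m, sig, min_coverage=min_coverage)
        cols[sig.name] = s
        missing[sig.name] = absent
    scores = pd.DataFrame(cols)
    scores.index.name = "sample"
    return ScoreTable(scores=scores, missing=missing)


def _fractional_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks mapped into (0, 1]."""
    return rankdata(x, method="average") / len(x)


def _minmax_unit(x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones_like(x, dtype=float)
    return eps + (x - lo) * (1.0 - eps) / (hi - lo)


def ratio_score(
    table: ScoreTable,
    numerator: str = "ECM_STROMAL",
    denominator: str = "IA",
    mode: str = "rank_ratio",
) -> pd.Series:
    """Derive the numerator-vs-denominator ratio statistic per sample.

    Modes: ``rank_ratio`` (fractional ranks divided; strictly positive),
    ``minmax_ratio`` (scores min-max mapped into (1e-6, 1] then
    divided) and ``difference`` (numerator - denominator). All three
    are strictly increasing in the numerator score and strictly
    decreasing in the denominator score for tie-free inputs. The result
    is also stored on ``table.ratio``.
    """
    for name in (numerator, denominator):
        if name not in table.scores.columns:
            raise ValidationError(f"score table has no signature {name!r}")
    if mode not in RATIO_MODES:
        raise ValidationError(f"unknown ratio mode {mode!r}; expected one of {RATIO_MODES}")
    num = table.scores[numerator].to_numpy(dtype=float)
    den = table.scores[denominator].to_numpy(dtype=float)
    if mode == "rank_ratio":
        values = _fractional_ranks(num) / _fractional_ranks(den)
    elif mode == "minmax_ratio":
        values = _minmax_unit(num) / _minmax_unit(den)
    else:
        values = num - den
    ratio = pd.Series(values, index=table.scores.index, name="ratio")
    table.ratio = ratio
    table.ratio_definition = f"{mode}({numerator}/{denominator})"
    return ratio


def write_scores(table: ScoreTable, path: str | Path, dialect: str | None = None) -> None:
    sep = "," if str(path).lower().endswith(".csv") or dialect == "csv" else "\t"
    table.to_frame().to_csv(path, sep=sep)


def read_scores(path: str | Path, dialect: str | None = None) -> ScoreTable:
    sep = "," if str(path).lower().endswith(".csv") or dialect == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    score_cols = [c for c in df.columns if c.startswith("score_")]
    if not score_cols:
        raise ParseError(f"{path}: no score_<name> columns found")
    scores = df[score_cols].rename(columns=lambda c: c[len("score_"):])
    ratio = df["ratio"] if "ratio" in df.columns else None
    return ScoreTable(scores=scores, ratio=ratio)
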