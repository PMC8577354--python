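"""Spearman correlation structure with significance masking.

The tabular twin of a correlogram figure: all pairwise Spearman
coefficients among a set of variables (genes across samples, or
signature scores), their p-values, and a boolean mask of cells
significant at level alpha. Per the display convention this mirrors,
significance is a per-pair p < alpha rule with no multiplicity
correction by default; Benjamini-Hochberg is available as a switch.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations, permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import ValidationError
from .scoring import ScoreTable

logger = logging.getLogger(__name__)


def spearman_pair(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "t_approx",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rho and p-value for one pair of vectors.

    ``t_approx`` (default) uses the t-statistic approximation
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df; ``permutation`` enumerates
    all orderings exactly for n <= 8 and Monte-Carlo samples otherwise.
    A constant vector has undefined correlation: returns (nan, nan)
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman_pair requires two equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValidationError(f"spearman_pair requires n >= 3, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("spearman_pair requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman correlation undefined")
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-15:
        return (float(np.sign(rho)), 0.0)
    if method == "t_approx":
        return (rho, float(p))
    if method != "permutation":
        raise ValidationError(f"unknown p-value method {method!r}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(rho)
    if n <= 8:
        stats_all = [
            abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) for perm in permutations(ry)
        ]
        p_perm = float(np.mean(np.asarray(stats_all) >= obs - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            r = abs(np.corrcoef(rx, rng.permutation(ry))[0, 1])
            hits += r >= obs - 1e-12
        p_perm = (hits + 1) / (n_perm + 1)
    return (rho, float(p_perm))


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho / p-value matrices plus significance mask."""

    rho: pd.DataFrame
    pvalue: pd.DataFrame
    mask: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        labs = list(self.rho.index)
        for frame in (self.rho, self.pvalue, self.mask):
            if list(frame.index) != labs or list(frame.columns) != labs:
                raise ValidationError("correlation matrices must share one label set")

    @property
    def labels(self) -> list[str]:
        return list(self.rho.index)

    def to_long(self) -> pd.DataFrame:
        rows = []
        labs = self.labels
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "rho": self.rho.loc[a, b],
                        "p": self.pvalue.loc[a, b],
                        "significant": bool(self.mask.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows, columns=["var1", "var2", "rho", "p", "significant"])


def _as_observation_frame(data) -> pd.DataFrame:
    """Coerce input to an observations x variables DataFrame."""
    if isinstance(data, ExpressionMatrix):
        return data.data.T  # samples become observations, genes variables
    if isinstance(data, ScoreTable):
        frame = data.scores.copy()
        if data.ratio is not None:
            frame["ratio"] = data.ratio
        return frame
    if isinstance(data, pd.DataFrame):
        return data
    raise ValidationError(f"cannot correlate object of type {type(data).__name__}")


def correlogram(
    data,
    alpha: float = 0.05,
    adjust: str | None = None,
    min_pairs: int = 3,
) -> CorrelationMatrix:
    """All pairwise Spearman correlations with a significance mask.

    ``data`` may be an observations x variables DataFrame, an
    :class:`ExpressionMatrix` (variables = genes) or a
    :class:`ScoreTable` (variables = scores [+ ratio]). Pairs are
    evaluated on pairwise-complete observations; fewer than
    ``min_pairs`` complete pairs (or a constant vector) yields a
    missing cell. ``adjust="bh"`` applies Benjamini-Hochberg to the
    off-diagonal p-values before masking.
    """
    frame = _as_observation_frame(data)
    if frame.shape[1] < 2:
        raise ValidationError("correlogram requires at least 2 variables")
    if frame.shape[0] < 3:
        raise ValidationError("correlogram requires at least 3 observations")
    if adjust not in (None, "bh"):
        raise ValidationError(f"unknown adjust method {adjust!r}")
    labs = list(frame.columns)
    k = len(labs)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        sub = frame.iloc[:, [i, j]].dropna()
        if len(sub) < min_pairs:
            r, p = float("nan"), float("nan")
        else:
            x = sub.iloc[:, 0].to_numpy(dtype=float)
            y = sub.iloc[:, 1].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning(
                    "constant variable in pair (%s, %s): correlation undefined",
                    labs[i], labs[j],
                )
                r, p = float("nan"), float("nan")
            else:
                r, p = spearman_pair(x, y)
        rho[i, j] = rho[j, i] = r
        pval[i, j] = pval[j, i] = p
    if adjust == "bh":
        iu = np.triu_indices(k, 1)
        flat = pval[iu]
        ok = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = _benjamini_hochberg(flat[ok])
        padj = pval.copy()
        padj[iu] = adj
        padj.T[iu] = adj
        pval_for_mask = padj
    else:
        pval_for_mask = pval
    with np.errstate(invalid="ignore"):
        mask = pval_for_mask < alpha
    np.fill_diagonal(mask, True)
    idx = pd.Index(labs)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        pvalue=pd.DataFrame(pval_for_mask, index=idx, columns=idx),
        mask=pd.DataFrame(mask, index=idx, columns=idx),
        alpha=alpha,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def write_correlogram(cm: CorrelationMatrix, long_path: str | Path, matrix_path: str | Path | None = None) -> None:
    """Write long-format pairs TSV and, optionally, the square rho matrix."""
    cm.to_long().to_csv(long_path, sep="\t", index=False)
    if matrix_path is not None:
        cm.rho.to_csv(matrix_path, sep="\t", index_label="variable")
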