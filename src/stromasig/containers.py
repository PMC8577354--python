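"""Core in-memory containers: expression matrices and clinical tables.

Both are thin, validated wrappers around :class:`pandas.DataFrame` so
that every downstream module can rely on the same invariants (unique
identifiers, finite numeric values, a tracked expression scale) without
re-checking them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Expression-scale flags tracked on :class:`ExpressionMatrix`.
RAW = "raw"
LOG2 = "log2"
ZSCORE = "zscore"
_SCALES = (RAW, LOG2, ZSCORE)

CLINICAL_COLUMNS = ("sample", "time", "event")


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x samples matrix of normalized expression values.

    Parameters
    ----------
    data:
        DataFrame with gene symbols as the index and sample identifiers
        as columns. Values must be finite numerics.
    scale:
        One of ``"raw"``, ``"log2"`` or ``"zscore"``; records which
        preprocessing steps have been applied.
    """

    data: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("ExpressionMatrix.data must be a pandas DataFrame")
        if self.scale not in _SCALES:
            raise ValidationError(
                f"unknown scale flag {self.scale!r}; expected one of {_SCALES}"
            )
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        genes = self.data.index
        if genes.duplicated().any():
            dupes = sorted(set(genes[genes.duplicated()]))
            raise ValidationError(f"duplicate gene symbols: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = sorted(set(self.data.columns[self.data.columns.duplicated()]))
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        for g in genes:
            if not isinstance(g, str) or not g:
                raise ValidationError(f"gene symbol must be a non-empty string, got {g!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {genes[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class ClinicalTable:
    """Per-sample follow-up: overall-survival time and event indicator.

    ``data`` holds columns ``sample`` (unique identifiers), ``time``
    (non-negative, in whatever unit the source file provides — the
    pipeline never converts units) and ``event`` (1 = death observed,
    0 = censored), plus optional free covariate columns (stage,
    histology, ...).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("ClinicalTable.data must be a pandas DataFrame")
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        if self.data["sample"].duplicated().any():
            dupes = sorted(set(self.data.loc[self.data["sample"].duplicated(), "sample"]))
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        time = pd.to_numeric(self.data["time"], errors="coerce")
        if time.isna().any() or not np.isfinite(time.to_numpy()).all():
            raise ValidationError("clinical time column contains missing/non-numeric values")
        if (time < 0).any():
            raise ValidationError("survival times must be non-negative")
        event = self.data["event"]
        if not event.isin([0, 1]).all():
            bad = sorted(set(event[~event.isin([0, 1])]))
            raise ValidationError(f"event indicator must be 0 or 1, got {bad[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.data["sample"])

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)
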