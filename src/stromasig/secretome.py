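"""Cytokine-panel analysis: vehicle-referenced fold changes, strict
>threshold induction calls, synergy/additivity classification of
combined stimulation, the Tukey ladder-of-powers display transform, and
the top-k secreted-protein ("mesenchymal secretory") signature.

The panel design mirrors a multiplex immunoassay of supernatants from
cells stimulated with vehicle, TNFα, IFNγ, or both simultaneously, with
several donors as biological replicates. Synergy is scored by a
Bliss-style effect-sum rule on vehicle-subtracted means: the combined
effect is synergistic when it exceeds the sum of single-stimulus
effects by more than a tolerance band (default 25%), additive when it
falls inside the band, sub-additive below it. This rule is an
implementation decision and configurable — the labels it emits are a
formalization, not a reproduction of any by-eye annotation.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ParseError, ValidationError
from .signatures import GeneSignature, normalize_symbol

logger = logging.getLogger(__name__)

VEHICLE = "vehicle"
CONDITIONS = ("vehicle", "tnf", "ifng", "combo")
PANEL_COLUMNS = ("analyte", "condition", "donor", "concentration")
INTERACTION_LABELS = ("synergistic", "additive", "sub_additive", "none")


@dataclasses.dataclass
class SecretomePanel:
    """Long-format analyte x condition x donor concentration table."""

    data: pd.DataFrame
    units: str = "pg/mL"

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"secretome panel missing columns: {missing}")
        conditions = set(self.data["condition"].unique())
        unknown = conditions - set(CONDITIONS)
        if unknown:
            raise ValidationError(
                f"unknown conditions {sorted(unknown)}; expected subset of {CONDITIONS}"
            )
        if VEHICLE not in conditions:
            raise ValidationError("secretome panel must contain a vehicle condition")
        conc = self.data["concentration"]
        finite = conc.dropna()
        if (finite < 0).any() or np.isinf(finite.to_numpy(dtype=float)).any():
            raise ValidationError("concentrations must be non-negative and finite")

    @property
    def analytes(self) -> list[str]:
        return list(pd.unique(self.data["analyte"]))

    @property
    def conditions(self) -> list[str]:
        return [c for c in CONDITIONS if c in set(self.data["condition"])]

    def condition_means(self) -> pd.DataFrame:
        """Analyte x condition mean concentration over donors."""
        means = self.data.pivot_table(
            index="analyte", columns="condition", values="concentration", aggfunc="mean"
        )
        return means.reindex(index=self.analytes, columns=self.conditions)

    def smallest_positive(self) -> float:
        pos = self.data.loc[self.data["concentration"] > 0, "concentration"]
        return float(pos.min()) if len(pos) else 1.0


def read_panel(path: str | Path, units: str = "pg/mL") -> SecretomePanel:
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: cannot parse secretome panel: {exc}") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: secretome panel missing columns {missing}")
    df["concentration"] = pd.to_numeric(df["concentration"], errors="coerce")
    return SecretomePanel(df, units=units)


def write_panel(panel: SecretomePanel, path: str | Path) -> None:
    panel.data.to_csv(path, sep="\t", index=False)


def default_floor(panel: SecretomePanel) -> float:
    """Vehicle floor: smallest positive observed concentration / 10."""
    return panel.smallest_positive() / 10.0


def fold_changes(panel: SecretomePanel, floor: float | None = None) -> pd.DataFrame:
    """Per-analyte fold change of each stimulated condition vs vehicle.

    fold(cond) = mean_donors conc(cond) / max(mean vehicle, floor). The
    floor guards division by near-zero vehicle values and is recorded
    in ``result.attrs["floor"]``. Analytes with no measurable values
    are dropped with a warning.
    """
    if floor is None:
        floor = default_floor(panel)
    if floor <= 0:
        raise DomainError(f"floor must be positive, got {floor}")
    means = panel.condition_means()
    all_missing = means.isna().all(axis=1)
    if all_missing.any():
        logger.warning(
            "dropping %d all-missing analytes: %s",
            int(all_missing.sum()), list(means.index[all_missing])[:10],
        )
        means = means[~all_missing]
    denom = means[VEHICLE].fillna(0.0).clip(lower=floor)
    stim = [c for c in means.columns if c != VEHICLE]
    folds = means[stim].div(denom, axis=0)
    folds.attrs["floor"] = floor
    return folds


def classify_induction(folds: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Induced iff fold > threshold, strictly; one label column per condition."""
    if (folds.dropna() < 0).to_numpy().any():
        raise DomainError("fold changes must be non-negative")
    labels = folds.apply(
        lambda col: np.where(col > threshold, "induced", "not_induced")
    )
    return pd.DataFrame(labels, index=folds.index, columns=folds.columns).rename(
        columns=lambda c: f"class_{c}"
    )


def _effects(panel: SecretomePanel) -> pd.DataFrame:
    """Vehicle-subtracted condition means, clipped at zero."""
    means = panel.condition_means()
    deltas = means.drop(columns=VEHICLE).sub(means[VEHICLE], axis=0)
    return deltas.clip(lower=0.0)


def classify_interaction(
    panel: SecretomePanel,
    analyte: str | None = None,
    tolerance: float = 0.25,
):
    """Label the combined-stimulation effect per analyte.

    With vehicle-subtracted, zero-clipped effects dT, dI, dC and
    s = dT + dI: synergistic if dC > (1+tolerance)*s, additive if
    |dC - s| <= tolerance*s, sub_additive if 0 < dC < (1-tolerance)*s,
    and none when dC <= 0 or both single effects are <= 0.
    """
    if tolerance < 0:
        raise DomainError(f"tolerance must be non-negative, got {tolerance}")
    have = set(panel.conditions)
    missing = set(CONDITIONS) - have
    if missing:
        raise ValidationError(f"interaction classification needs all conditions; missing {sorted(missing)}")
    eff = _effects(panel)
    if analyte is not None:
        if analyte not in eff.index:
            raise ValidationError(f"unknown analyte {analyte!r}")
        eff = eff.loc[[analyte]]
    dT = eff["tnf"].to_numpy(dtype=float)
    dI = eff["ifng"].to_numpy(dtype=float)
    dC = eff["combo"].to_numpy(dtype=float)
    s = dT + dI
    labels = np.full(len(eff), "none", dtype=object)
    active = (dC > 0) & ((dT > 0) | (dI > 0))
    syn = active & (dC > (1 + tolerance) * s)
    add = active & (np.abs(dC - s) <= tolerance * s)
    sub = active & (dC < (1 - tolerance) * s) & ~add
    labels[sub] = "sub_additive"
    labels[add] = "additive"
    labels[syn] = "synergistic"
    result = pd.Series(labels, index=eff.index, name="interaction")
    return result.iloc[0] if analyte is not None else result


def induction_calls(
    panel: SecretomePanel,
    threshold: float = 5.0,
    tolerance: float = 0.25,
    floor: float | None = None,
) -> pd.DataFrame:
    """Full per-analyte call table: folds, induction classes, interaction.

    If the combo condition is absent the interaction column is omitted
    with a warning (graceful degradation).
    """
    folds = fold_changes(panel, floor=floor)
    calls = folds.rename(columns=lambda c: f"fold_{c}")
    classes = classify_induction(folds.drop(columns="combo", errors="ignore"), threshold)
    calls = calls.join(classes)
    if "combo" in panel.conditions:
        calls = calls.join(classify_interaction(panel, tolerance=tolerance))
    else:
        logger.warning("combo condition absent: skipping interaction classification")
    calls.index.name = "analyte"
    return calls


def tukey_ladder(
    x: np.ndarray,
    lambda_min: float = -2.0,
    lambda_max: float = 2.0,
    step: float = 0.025,
) -> tuple[float, np.ndarray]:
    """Tukey ladder-of-powers transform maximizing Shapiro-Wilk W.

    Grid-searches lambda over [lambda_min, lambda_max]; the transform
    is x**lambda for lambda > 0, log(x) at lambda = 0 and -x**lambda
    for lambda < 0 (sign-preserving ladder). Requires strictly positive
    input with n >= 3. Returns (lambda, transformed values).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise DomainError("tukey_ladder requires a 1-d vector with n >= 3")
    if not np.isfinite(x).all() or (x <= 0).any():
        raise DomainError("tukey_ladder requires strictly positive finite values")
    steps = int(round((lambda_max - lambda_min) / step))
    grid = lambda_min + step * np.arange(steps + 1)
    best_lam, best_w, best_t = 1.0, -np.inf, x
    for lam in grid:
        t = _ladder_transform(x, lam)
        if np.ptp(t) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = float(stats.shapiro(t).statistic)
        if np.isfinite(w) and w > best_w:
            best_lam, best_w, best_t = float(lam), w, t
    return best_lam, best_t


def _ladder_transform(x: np.ndarray, lam: float) -> np.ndarray:
    if lam > 0:
        return x ** lam
    if lam == 0:
        return np.log(x)
    return -(x ** lam)


def tukey_matrix(panel: SecretomePanel, floor: float | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Ladder-transformed condition-mean matrix (heatmap's numeric twin).

    Per analyte, lambda is selected on the pooled donor-level values
    (zeros lifted to the vehicle floor) and then applied to the
    condition means. Returns (transformed matrix, lambda per analyte).
    """
    if floor is None:
        floor = default_floor(panel)
    means = panel.condition_means()
    out = pd.DataFrame(index=means.index, columns=means.columns, dtype=float)
    lams = pd.Series(index=means.index, dtype=float, name="lambda")
    for analyte in means.index:
        vals = panel.data.loc[panel.data["analyte"] == analyte, "concentration"].dropna()
        vals = vals.to_numpy(dtype=float).clip(min=floor)
        if len(vals) < 3 or np.ptp(vals) == 0:
            lam = 1.0
        else:
            lam, _ = tukey_ladder(vals)
        lams[analyte] = lam
        out.loc[analyte] = _ladder_transform(
            means.loc[analyte].to_numpy(dtype=float).clip(min=floor), lam
        )
    return out, lams


def secretory_signature(
    panel: SecretomePanel,
    k: int = 10,
    rank_by: str = "combo",
    name: str = "SECRETORY",
) -> GeneSignature:
    """Top-k secreted analytes as a gene signature.

    Analytes are ranked by mean concentration under ``rank_by`` (one of
    the panel conditions, or ``"max"`` for the max over conditions);
    ties break alphabetically. Analyte names are mapped to gene symbols
    through the alias map so the signature is scoreable on expression
    matrices.
    """
    means = panel.condition_means()
    if rank_by == "max":
        basis = means.max(axis=1)
    else:
        if rank_by not in means.columns:
            raise ValidationError(f"panel has no condition {rank_by!r}")
        basis = means[rank_by]
    basis = basis.dropna()
    if len(basis) < k:
        raise ValidationError(f"need at least {k} analytes, have {len(basis)}")
    ranked = basis.sort_index().sort_values(ascending=False, kind="mergesort")
    symbols: list[str] = []
    for analyte in ranked.index:
        sym = normalize_symbol(str(analyte))
        if sym in symbols:
            logger.warning("analyte %s maps to already-selected symbol %s; skipped", analyte, sym)
            continue
        symbols.append(sym)
        if len(symbols) == k:
            break
    if len(symbols) < k:
        raise ValidationError(f"only {len(symbols)} unique gene symbols available for top-{k}")
    return GeneSignature(name=name, genes=tuple(symbols))
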