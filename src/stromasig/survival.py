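"""Survival machinery: Kaplan-Meier / Nelson-Aalen estimation, the
two-group log-rank test, and optimal-cutpoint dichotomization of a
continuous marker by maximally selected rank statistics.

The cutpoint search scans every admissible split of the marker (each
side keeping at least ceil(minprop * n) samples), computes the
standardized log-rank statistic of the induced two-group comparison,
and takes the split maximizing its absolute value. Because the maximum
of many correlated statistics is not chi-square distributed, the
reported p-value adjusts for the selection: either the
Miller-Siegmund Brownian-bridge bound for maximally selected rank
statistics (fast, default) or a full permutation re-scan (reference).

Tie conventions (documented, standard): subjects censored exactly at an
event time are still at risk at that time; a sample whose marker equals
the cutpoint goes to the "low" group (strict > defines "high").
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

SURVIVAL_COLUMNS = ("time", "event")


def _check_time_event(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValidationError("time and event must be equal-length 1-d arrays")
    if len(time) == 0:
        raise ValidationError("empty survival table")
    if not np.isfinite(time).all() or (time < 0).any():
        raise ValidationError("survival times must be finite and non-negative")
    if not np.isin(event, [0, 1]).all():
        raise ValidationError("event indicator must be 0 or 1")
    return time, event.astype(int)


@dataclasses.dataclass
class KMCurve:
    """Product-limit survival curve and Nelson-Aalen cumulative hazard.

    Arrays are aligned over the distinct event times (times with at
    least one observed death). A fully censored sample yields empty
    arrays and S(t) = 1 everywhere.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    cumhaz: np.ndarray
    n: int

    def __post_init__(self) -> None:
        k = len(self.event_times)
        for arr in (self.survival, self.at_risk, self.n_events, self.cumhaz):
            if len(arr) != k:
                raise ValidationError("KMCurve arrays must have equal length")
        if k and (np.diff(self.survival) > 1e-12).any():
            raise ValidationError("survival must be non-increasing")
        if k and (np.diff(self.cumhaz) < -1e-12).any():
            raise ValidationError("cumulative hazard must be non-decreasing")

    @property
    def median(self) -> float:
        """First event time at which S(t) <= 0.5; nan if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if len(below) else float("nan")

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "cumhaz": self.cumhaz,
            }
        )


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Nelson-Aalen hazard.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times;
    censorings tied with an event time are counted at risk at that time.
    """
    time, event = _check_time_event(time, event)
    n = len(time)
    et = np.unique(time[event == 1])
    d = np.array([np.sum((time == t) & (event == 1)) for t in et], dtype=float)
    at_risk = np.array([np.sum(time >= t) for t in et], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, d / at_risk, 0.0)
    survival = np.cumprod(1.0 - frac)
    cumhaz = np.cumsum(frac)
    return KMCurve(
        event_times=et,
        survival=survival,
        at_risk=at_risk.astype(int),
        n_events=d.astype(int),
        cumhaz=cumhaz,
        n=n,
    )


@dataclasses.dataclass
class LogrankResult:
    chi2: float
    pvalue: float
    observed_minus_expected: float  # for the first group


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> LogrankResult:
    """Standard two-group log-rank test.

    At each distinct pooled event time, the observed deaths in group A
    minus their hypergeometric expectation are accumulated;
    chi2 = (sum O-E)^2 / (sum V) on 1 df.
    """
    time_a, event_a = _check_time_event(time_a, event_a)
    time_b, event_b = _check_time_event(time_b, event_b)
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    in_a = np.concatenate([np.ones(len(time_a), bool), np.zeros(len(time_b), bool)])
    if event.sum() == 0:
        return LogrankResult(chi2=0.0, pvalue=1.0, observed_minus_expected=0.0)
    et = np.unique(time[event == 1])
    U = 0.0
    V = 0.0
    for t in et:
        at_risk = time >= t
        n_tot = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d_a = (dying & in_a).sum()
        U += d_a - n_a * d / n_tot
        if n_tot > 1:
            V += d * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d) / (n_tot - 1)
    if V <= 0:
        return LogrankResult(chi2=0.0, pvalue=1.0, observed_minus_expected=float(U))
    chi2 = U * U / V
    return LogrankResult(
        chi2=float(chi2),
        pvalue=float(stats.chi2.sf(chi2, df=1)),
        observed_minus_expected=float(U),
    )


def _admissible_candidates(
    marker: np.ndarray, n: int, minprop: float
) -> tuple[np.ndarray, np.ndarray]:
    min_side = math.ceil(minprop * n)
    uniq = np.unique(marker)
    counts_le = np.searchsorted(np.sort(marker), uniq, side="right")
    admissible = (counts_le >= min_side) & (n - counts_le >= min_side)
    if not admissible.any():
        raise ValidationError(
            "no candidate cutpoint leaves at least "
            f"ceil(minprop*n) = {min_side} samples on each side; "
            "use a larger cohort or a smaller minprop"
        )
    return uniq[admissible], counts_le[admissible]


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject log-rank scores a_i = event_i - H(t_i) (Nelson-Aalen)."""
    et = np.unique(time[event == 1])
    if len(et) == 0:
        return np.zeros(len(time), dtype=float)
    d = np.array([np.sum((time == t) & (event == 1)) for t in et], dtype=float)
    at_risk = np.array([np.sum(time >= t) for t in et], dtype=float)
    cumhaz = np.cumsum(d / at_risk)
    idx = np.searchsorted(et, time, side="right") - 1
    H = np.where(idx >= 0, cumhaz[np.clip(idx, 0, None)], 0.0)
    return event.astype(float) - H


def _standardized_scan(
    time: np.ndarray,
    event: np.ndarray,
    marker: np.ndarray,
    minprop: float,
    stat: str = "scores",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized log-rank statistic for every admissible marker split.

    Returns (candidates, z, n_low) where candidate c splits the cohort
    into low = {marker <= c} and high = {marker > c}; z is the high
    group's standardized statistic. ``stat="scores"`` standardizes the
    linear log-rank-scores statistic with the Lausen-Schumacher
    subset-sampling variance (the maximally-selected-rank-statistics
    convention); ``stat="logrank"`` standardizes with the per-split
    log-rank test's hypergeometric variance. The O-E numerator is the
    same in both.
    """
    n = len(time)
    candidates, counts_le = _admissible_candidates(marker, n, minprop)
    et = np.unique(time[event == 1])
    if len(et) == 0:
        return candidates, np.zeros(len(candidates)), counts_le
    if stat == "scores":
        a = logrank_scores(time, event)
        order = np.argsort(marker, kind="mergesort")
        cum = np.cumsum(a[order])
        m_low = counts_le
        s_high = a.sum() - cum[m_low - 1]
        m_high = n - m_low
        abar = a.mean()
        ssq = np.sum((a - abar) ** 2)
        V = m_high * (n - m_high) / (n * (n - 1)) * ssq
        U = s_high - m_high * abar
    elif stat == "logrank":
        # incidence matrices: rows = event times, cols = samples
        at_risk = (time[None, :] >= et[:, None]).astype(float)
        dying = ((time[None, :] == et[:, None]) & (event[None, :] == 1)).astype(float)
        d = dying.sum(axis=1)
        n_tot = at_risk.sum(axis=1)
        high = (marker[:, None] > candidates[None, :]).astype(float)
        n_high = at_risk @ high
        d_high = dying @ high
        U = (d_high - n_high * (d / n_tot)[:, None]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = n_high / n_tot[:, None]
            var_terms = (d * (n_tot - d) / np.maximum(n_tot - 1, 1))[:, None] * frac * (1 - frac)
            var_terms[n_tot <= 1, :] = 0.0
        V = var_terms.sum(axis=0)
    else:
        raise ValidationError(f"unknown scan statistic {stat!r}")
    z = np.zeros(len(candidates))
    ok = V > 0
    z = np.where(ok, U / np.sqrt(np.where(ok, V, 1.0)), 0.0)
    return candidates, z, counts_le


@dataclasses.dataclass
class CutpointResult:
    """Optimal marker cutpoint by maximally selected rank statistics."""

    cutpoint: float
    standardized_statistic: float
    p_selected: float
    n_high: int
    n_low: int
    minprop: float
    pmethod: str
    stat: str
    scan: pd.DataFrame  # columns: candidate, statistic

    def to_dict(self) -> dict:
        return {
            "cutpoint": self.cutpoint,
            "standardized_statistic": self.standardized_statistic,
            "p_selected": self.p_selected,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "minprop": self.minprop,
            "pmethod": self.pmethod,
            "stat": self.stat,
        }


def _miller_siegmund_p(b: float, eps_low: float, eps_high: float) -> float:
    """Brownian-bridge bound on P(sup |B(t)|/sqrt(t(1-t)) > b) over
    t in [eps_low, eps_high] (Miller & Siegmund improved Bonferroni)."""
    if b <= 0:
        return 1.0
    phi = math.exp(-0.5 * b * b) / math.sqrt(2 * math.pi)
    log_term = math.log((eps_high * (1 - eps_low)) / (eps_low * (1 - eps_high)))
    p = 4 * phi / b + phi * (b - 1 / b) * log_term
    return float(min(max(p, 0.0), 1.0))


def maxstat_cutpoint(
    time: np.ndarray,
    event: np.ndarray,
    marker: np.ndarray,
    minprop: float = 0.1,
    pmethod: str = "lausen_approx",
    n_perm: int = 1000,
    seed: int | None = None,
    stat: str = "scores",
) -> CutpointResult:
    """Optimal survival cutpoint for a continuous marker.

    Scans all admissible splits, picks the one maximizing the absolute
    standardized log-rank statistic (smallest marker value on ties) and
    reports a selection-adjusted p-value: the Brownian-bridge bound
    (``lausen_approx``) or a permutation re-scan (``permutation``).
    ``stat`` selects the standardization of the scan statistic:
    ``"scores"`` (Lausen-Schumacher subset-sampling variance, the
    convention of the R maxstat tooling; default) or ``"logrank"``
    (each split standardized as its own two-group log-rank test).
    """
    time, event = _check_time_event(time, event)
    marker = np.asarray(marker, dtype=float)
    if marker.shape != time.shape or not np.isfinite(marker).all():
        raise ValidationError("marker must be a finite vector aligned with time/event")
    if not 0 < minprop < 0.5:
        raise ValidationError(f"minprop must lie in (0, 0.5), got {minprop}")
    if pmethod not in ("lausen_approx", "permutation"):
        raise ValidationError(f"unknown pmethod {pmethod!r}")
    n = len(time)
    candidates, z, n_low = _standardized_scan(time, event, marker, minprop, stat=stat)
    abs_z = np.abs(z)
    b = float(abs_z.max())
    # smallest candidate among (floating-point) ties for the maximum
    idx = int(np.nonzero(abs_z >= b * (1 - 1e-12) - 1e-300)[0][0])
    cutpoint = float(candidates[idx])
    if pmethod == "lausen_approx":
        eps_low = n_low[0] / n
        eps_high = n_low[-1] / n
        p_sel = _miller_siegmund_p(b, eps_low, eps_high)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            _, z_perm, _ = _standardized_scan(
                time, event, rng.permutation(marker), minprop, stat=stat
            )
            hits += np.abs(z_perm).max() >= b - 1e-12
        p_sel = (hits + 1) / (n_perm + 1)
    return CutpointResult(
        cutpoint=cutpoint,
        standardized_statistic=float(z[idx]),
        p_selected=float(p_sel),
        n_high=int(n - n_low[idx]),
        n_low=int(n_low[idx]),
        minprop=minprop,
        pmethod=pmethod,
        stat=stat,
        scan=pd.DataFrame({"candidate": candidates, "statistic": z}),
    )


def stratify(table: pd.DataFrame, cut: CutpointResult, marker_col: str = "marker") -> pd.DataFrame:
    """Label samples 'high' (marker > cutpoint) or 'low' (ties to low)."""
    if marker_col not in table.columns:
        raise ValidationError(f"survival table has no column {marker_col!r}")
    marker = table[marker_col].to_numpy(dtype=float)
    if not (marker.min() <= cut.cutpoint <= marker.max()):
        raise ValidationError("cutpoint lies outside the marker range")
    out = table.copy()
    out["group"] = np.where(marker > cut.cutpoint, "high", "low")
    n_high = int((out["group"] == "high").sum())
    if n_high != cut.n_high:
        raise ValidationError(
            f"stratified group sizes ({n_high} high) disagree with cutpoint result "
            f"({cut.n_high} high); marker differs from the scanned one"
        )
    return out


@dataclasses.dataclass
class SurvivalReport:
    """Two-group survival comparison: KM curves, log-rank, medians."""

    curves: dict[str, KMCurve]
    chi2: float
    pvalue: float
    median: dict[str, float]
    n: dict[str, int]
    direction: str  # "high_worse" | "low_worse" | "none"

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "pvalue": self.pvalue,
            "median": {k: (None if math.isnan(v) else v) for k, v in self.median.items()},
            "n": self.n,
            "direction": self.direction,
        }

    def curves_frame(self) -> pd.DataFrame:
        frames = []
        for name, curve in sorted(self.curves.items()):
            f = curve.to_frame()
            f.insert(0, "group", name)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def survival_report(table: pd.DataFrame) -> SurvivalReport:
    """Compare the 'high' vs 'low' strata of a stratified table.

    Expects columns time, event, group. Direction is read off the sign
    of the high group's observed-minus-expected deaths.
    """
    for col in ("time", "event", "group"):
        if col not in table.columns:
            raise ValidationError(f"stratified survival table needs column {col!r}")
    groups = sorted(table["group"].unique())
    if set(groups) != {"high", "low"}:
        raise ValidationError(f"expected groups high/low, got {groups}")
    high = table[table["group"] == "high"]
    low = table[table["group"] == "low"]
    lr = logrank_test(
        high["time"].to_numpy(), high["event"].to_numpy(),
        low["time"].to_numpy(), low["event"].to_numpy(),
    )
    curves = {
        "high": km_estimate(high["time"].to_numpy(), high["event"].to_numpy()),
        "low": km_estimate(low["time"].to_numpy(), low["event"].to_numpy()),
    }
    if abs(lr.observed_minus_expected) < 1e-9:
        direction = "none"
    elif lr.observed_minus_expected > 0:
        direction = "high_worse"  # more deaths in the high group than expected
    else:
        direction = "low_worse"
    return SurvivalReport(
        curves=curves,
        chi2=lr.chi2,
        pvalue=lr.pvalue,
        median={g: curves[g].median for g in curves},
        n={g: len(table[table["group"] == g]) for g in ("high", "low")},
        direction=direction,
    )


def write_report(report: SurvivalReport, json_path: str | Path, curves_path: str | Path | None = None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if curves_path is not None:
        report.curves_frame().to_csv(curves_path, sep="\t", index=False)
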