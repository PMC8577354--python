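"""Synthetic cohorts and cytokine panels with planted structure.

The generator emulates the statistical skeleton the analysis assumes,
so every stage is testable without external downloads:

* block-correlated log2 expression for the two signature gene sets,
  with the cross-block gene correlation calibrated so the two
  sum-scores correlate at a target value;
* proportional-hazards (or threshold) survival whose hazard increases
  with the ECM-vs-IA score contrast, under independent uniform
  administrative censoring tuned to a target censoring fraction;
* 40-analyte secretome panels with planted >threshold-induced,
  synergistic and additive analytes and multiplicative log-normal
  donor noise.

It makes no attempt to mimic real TCGA gene-gene covariance beyond the
planted blocks, and no batch effects.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import LOG2, ClinicalTable, ExpressionMatrix
from .errors import ValidationError
from .secretome import SecretomePanel
from .signatures import ECM_STROMAL, IA

CONDITION_ORDER = ("vehicle", "tnf", "ifng", "combo")

#: Default 40-analyte panel, grouped by planted behaviour:
#: 15 TNF-induced, 5 IFNg-induced, 5 synergistic, 10 additive, 5 background.
DEFAULT_ANALYTES: tuple[str, ...] = (
    # TNF-induced (15)
    "CCL2", "CCL5", "CCL11", "CCL13", "CCL20", "CCL22", "CXCL1", "CXCL2",
    "CXCL5", "GM-CSF", "IL-6", "IL-8", "IL-10", "IL-1B", "IL-17A",
    # IFNg-induced (5)
    "CCL23", "CCL25", "CXCL10", "CXCL11", "IL-15",
    # synergistic (5)
    "IL-16", "CCL8", "CX3CL1", "CXCL9", "TGFB1",
    # additive (10)
    "CCL1", "CCL7", "CCL15", "CCL17", "CCL19", "CCL24", "CCL26", "CXCL16",
    "M-CSF", "IL-2",
    # background (5)
    "IL-4", "IL-5", "IL-7", "IL-12", "IL-13",
)


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a simulated expression + survival cohort.

    ``effect`` is the log hazard ratio per standard deviation of the
    (standardized) ECM-minus-IA score contrast under the proportional
    model; under the threshold model the hazard jumps by
    ``hazard_ratio`` for samples above ``threshold_percentile`` of the
    contrast. Baseline is Weibull(shape, scale) — shape 1 gives an
    exponential — with times on a day-like scale.
    """

    n_samples: int = 500
    n_background_genes: int = 100
    rho_within_ecm: float = 0.6
    rho_within_ia: float = 0.6
    rho_cross: float = 0.4
    hazard_model: str = "proportional"  # or "threshold"
    effect: float = math.log(2.0)
    hazard_ratio: float = 2.0
    threshold_percentile: float = 0.6
    baseline_shape: float = 1.0
    baseline_scale: float = 1000.0
    censor_rate: float = 0.3
    gene_mean: float = 8.0
    gene_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValidationError("n_samples must be at least 10")
        if self.n_background_genes < 0:
            raise ValidationError("n_background_genes must be non-negative")
        for field in ("rho_within_ecm", "rho_within_ia"):
            v = getattr(self, field)
            if not 0 <= v < 1:
                raise ValidationError(f"{field} must lie in [0, 1), got {v}")
        if not -1 < self.rho_cross < 1:
            raise ValidationError(f"rho_cross must lie in (-1, 1), got {self.rho_cross}")
        if self.hazard_model not in ("proportional", "threshold"):
            raise ValidationError(f"unknown hazard model {self.hazard_model!r}")
        if not 0 < self.threshold_percentile < 1:
            raise ValidationError("threshold_percentile must lie in (0, 1)")
        if self.hazard_ratio <= 0 or self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValidationError("hazard_ratio, baseline_shape, baseline_scale must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValidationError(f"censor_rate must lie in [0, 1), got {self.censor_rate}")
        # constructing the covariance validates positive semi-definiteness
        self.signature_covariance()

    def cross_gene_correlation(self) -> float:
        """Gene-level cross-block correlation hitting the score target.

        With p-gene equicorrelated blocks, var(sum) = p + p(p-1)rho_w
        and cov(S1, S2) = p1 p2 r; solving corr(S1, S2) = rho_cross for
        r gives the value used in the block covariance.
        """
        p1, p2 = len(ECM_STROMAL), len(IA)
        v1 = p1 + p1 * (p1 - 1) * self.rho_within_ecm
        v2 = p2 + p2 * (p2 - 1) * self.rho_within_ia
        return self.rho_cross * math.sqrt(v1 * v2) / (p1 * p2)

    def signature_covariance(self) -> np.ndarray:
        """Joint correlation matrix of the two signature gene blocks."""
        p1, p2 = len(ECM_STROMAL), len(IA)
        r = self.cross_gene_correlation()
        cov = np.empty((p1 + p2, p1 + p2))
        cov[:p1, :p1] = self.rho_within_ecm
        cov[p1:, p1:] = self.rho_within_ia
        cov[:p1, p1:] = r
        cov[p1:, :p1] = r
        np.fill_diagonal(cov, 1.0)
        min_eig = float(np.linalg.eigvalsh(cov).min())
        if min_eig < -1e-8:
            raise ValidationError(
                "infeasible correlation combination: the implied "
                f"{p1 + p2}x{p1 + p2} signature covariance has minimum "
                f"eigenvalue {min_eig:.3g} < 0 (cross-block correlation "
                f"{r:.3g} is too large for the within-block structure)"
            )
        return cov


def _solve_censor_horizon(event_times: np.ndarray, target: float) -> float:
    """Horizon tau of uniform(0, tau) censoring achieving the target rate.

    P(censored) = mean_i min(T_i / tau, 1), strictly decreasing in tau.
    """
    def gap(tau: float) -> float:
        return float(np.mean(np.minimum(event_times / tau, 1.0))) - target

    lo = float(event_times.min()) * 1e-6 + 1e-12
    hi = float(event_times.max()) * 1e6 + 1.0
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10, rtol=1e-12))


def simulate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Draw one cohort: a log2-scale expression matrix and survival data.

    Signature genes come from a block multivariate Gaussian on the log2
    scale; background genes are independent Gaussians. Survival times
    follow the chosen hazard model driven by the standardized
    ECM-minus-IA latent score contrast. Fully reproducible from
    ``spec.seed``.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(3)
    rng_expr = np.random.default_rng(streams[0])
    rng_surv = np.random.default_rng(streams[1])
    rng_cens = np.random.default_rng(streams[2])

    p1, p2 = len(ECM_STROMAL), len(IA)
    n = spec.n_samples
    cov = spec.signature_covariance()
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    latent = rng_expr.standard_normal((n, p1 + p2)) @ chol.T  # samples x genes
    background = rng_expr.standard_normal((n, spec.n_background_genes))

    genes = list(ECM_STROMAL.genes) + list(IA.genes) + [
        f"BG{i + 1:04d}" for i in range(spec.n_background_genes)
    ]
    samples = [f"S{i + 1:04d}" for i in range(n)]
    values = spec.gene_mean + spec.gene_sd * np.concatenate([latent, background], axis=1)
    expr = ExpressionMatrix(
        pd.DataFrame(values.T, index=genes, columns=samples), scale=LOG2
    )

    contrast = latent[:, :p1].sum(axis=1) - latent[:, p1:].sum(axis=1)
    contrast = (contrast - contrast.mean()) / contrast.std(ddof=1)
    if spec.hazard_model == "proportional":
        lp = spec.effect * contrast
    else:
        threshold = np.quantile(contrast, spec.threshold_percentile)
        lp = math.log(spec.hazard_ratio) * (contrast > threshold)
    # Weibull PH: T = scale * (-log U / exp(lp))^(1/shape)
    u = rng_surv.uniform(size=n)
    t_event = spec.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / spec.baseline_shape)
    if spec.censor_rate > 0:
        tau = _solve_censor_horizon(t_event, spec.censor_rate)
        t_cens = rng_cens.uniform(0.0, tau, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)

    clinical = ClinicalTable(
        pd.DataFrame({"sample": samples, "time": time, "event": event})
    )
    return expr, clinical


@dataclasses.dataclass
class PanelSpec:
    """Parameters of a simulated secretome panel.

    Planted sets are disjoint analyte index sets into the analyte list;
    defaults mirror a 40-analyte panel with 15 TNF-induced, 5
    IFNγ-induced, 5 synergistic and 10 additive analytes. Induced
    analytes rise ``induced_fold``-fold in their condition; synergy and
    additive analytes get single-stimulus effects at ``partial_fold``
    (kept below the induction threshold so the planted sets stay
    disjoint), with combined effects of twice, respectively exactly,
    the single-effect sum. Donor noise is multiplicative log-normal
    with coefficient of variation ``donor_cv``.
    """

    n_analytes: int = 40
    n_donors: int = 8
    donor_cv: float = 0.1
    induced_fold: float = 8.0
    partial_fold: float = 3.0
    base_log_mean: float = math.log(50.0)
    base_log_sd: float = 1.0
    planted_induced_tnf: tuple[int, ...] = tuple(range(0, 15))
    planted_induced_ifng: tuple[int, ...] = tuple(range(15, 20))
    planted_synergistic: tuple[int, ...] = tuple(range(20, 25))
    planted_additive: tuple[int, ...] = tuple(range(25, 35))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_analytes < 1 or self.n_donors < 1:
            raise ValidationError("n_analytes and n_donors must be positive")
        if self.donor_cv < 0:
            raise ValidationError("donor_cv must be non-negative")
        if self.induced_fold <= 1 or self.partial_fold <= 1:
            raise ValidationError("planted folds must exceed 1")
        sets = [
            self.planted_induced_tnf, self.planted_induced_ifng,
            self.planted_synergistic, self.planted_additive,
        ]
        flat = [i for s in sets for i in s]
        if len(set(flat)) != len(flat):
            raise ValidationError("planted analyte sets must be disjoint")
        if flat and (min(flat) < 0 or max(flat) >= self.n_analytes):
            raise ValidationError("planted indices must lie in [0, n_analytes)")

    def analyte_names(self) -> list[str]:
        if self.n_analytes == len(DEFAULT_ANALYTES):
            return list(DEFAULT_ANALYTES)
        return [f"AN{i + 1:02d}" for i in range(self.n_analytes)]

    def planted_names(self, which: str) -> list[str]:
        names = self.analyte_names()
        idx = getattr(self, f"planted_{which}")
        return [names[i] for i in idx]


def simulate_panel(spec: PanelSpec) -> SecretomePanel:
    """Draw one secretome panel with the planted condition structure.

    Planted TNF-/IFNγ-only analytes return to vehicle level under
    combined stimulation (no combined change), so interaction labels
    recover exactly the planted synergistic and additive sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    names = spec.analyte_names()
    base = np.exp(spec.base_log_mean + spec.base_log_sd * rng.standard_normal(spec.n_analytes))

    mean = np.tile(base[:, None], (1, len(CONDITION_ORDER)))  # analyte x condition
    col = {c: i for i, c in enumerate(CONDITION_ORDER)}
    f, s = spec.induced_fold, spec.partial_fold
    for i in spec.planted_induced_tnf:
        mean[i, col["tnf"]] = base[i] * f
    for i in spec.planted_induced_ifng:
        mean[i, col["ifng"]] = base[i] * f
    for i in spec.planted_synergistic:
        mean[i, col["tnf"]] = base[i] * s
        mean[i, col["ifng"]] = base[i] * s
        mean[i, col["combo"]] = base[i] * (1 + 4 * (s - 1))  # 2x the single-effect sum
    for i in spec.planted_additive:
        mean[i, col["tnf"]] = base[i] * s
        mean[i, col["ifng"]] = base[i] * s
        mean[i, col["combo"]] = base[i] * (1 + 2 * (s - 1))  # exactly the sum

    if spec.donor_cv > 0:
        sigma = math.sqrt(math.log(1 + spec.donor_cv ** 2))
        noise = np.exp(
            -0.5 * sigma ** 2
            + sigma * rng.standard_normal((spec.n_analytes, len(CONDITION_ORDER), spec.n_donors))
        )
    else:
        noise = np.ones((spec.n_analytes, len(CONDITION_ORDER), spec.n_donors))
    conc = mean[:, :, None] * noise

    rows = []
    for i, analyte in enumerate(names):
        for j, condition in enumerate(CONDITION_ORDER):
            for d in range(spec.n_donors):
                rows.append((analyte, condition, f"D{d + 1:02d}", conc[i, j, d]))
    frame = pd.DataFrame(rows, columns=["analyte", "condition", "donor", "concentration"])
    return SecretomePanel(frame)
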