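# stromasig

Tumours rich in activated CD8+ T cells tend to do well — unless the
surrounding stroma is also rich in TGFβ1-responsive, matrix-depositing
mesenchymal cells (CAF/pericyte-like), which can neutralize that immune
activity. `stromasig` implements the transcriptomic side of that
question for bulk tumour cohorts (e.g. lung adenocarcinoma and
squamous-cell carcinoma): it scores a 12-gene **ECM/stromal** signature
(VCAN, FAP, COL1A1, POSTN, THY1, FBLN1, TGFB1, IL6, CSPG4, PDPN, HGF,
SERPINE1) against a 12-gene **immune-activation (IA)** signature (IFNG,
GZMA, GZMB, GZMK, PRF1, GNLY, IL2, PDCD1, CD274, CTLA4, CXCR3, IL7R),
asks whether a high stromal-to-immune balance predicts shorter overall
survival, and analyses the cytokine secretome of the stromal cells that
plausibly produce the signature.

It is written for computational biologists who want the full pathway —
preprocessing, scoring, correlation structure, optimal-cutpoint
survival stratification, secretome synergy calls — as tested,
scriptable Python rather than a stack of one-off R snippets.

## The statistics at the core

**Signature score.** With log2 expression z-scaled per gene across
samples (z_gj = (x_gj − mean_g) / sd_g, denominator n−1), the score of
sample *j* for gene set *G* is the unweighted sum
S_j = Σ_{g∈G} z_gj. No enrichment statistic, by design.

**Stromal-to-immune ratio.** Sums of z-scores are centred at zero, so a
raw quotient is unstable; the default `rank_ratio` statistic divides
fractional ranks, r_j = rank(S_j^ECM)/n ÷ rank(S_j^IA)/n, which is
strictly positive and monotone in each score. `minmax_ratio` and
`difference` are alternatives.

**Optimal cutpoint.** The cohort is dichotomized at the marker value c*
maximizing the absolute standardized log-rank statistic over all splits
leaving at least ⌈minprop·n⌉ samples per side (maximally selected rank
statistics). The default standardization is the Lausen–Schumacher
subset-sampling variance of the log-rank-scores linear statistic (the
convention of R's `maxstat`/`surv_cutpoint`); a per-split log-rank-test
variance is available via `stat="logrank"`. Because c* is selected, the
reported p-value is adjusted: a Brownian-bridge bound (Miller–Siegmund)
by default, or a full permutation re-scan.

**Inference.** Kaplan–Meier product-limit curves S(t) = Π (1 − d_i/n_i),
Nelson–Aalen cumulative hazard Σ d_i/n_i, the two-group log-rank test,
and Spearman correlograms with a per-pair p < α significance mask
(Benjamini–Hochberg optional).

**Secretome.** For analyte × {vehicle, TNFα, IFNγ, combined} × donor
concentration panels: vehicle-referenced fold changes with a floor
guard, strictly-greater-than-threshold induction calls (default 5-fold),
a Bliss-style synergy rule on vehicle-subtracted effects
(synergistic if ΔC > (1+τ)(ΔT+ΔI), additive within the τ band,
default τ = 0.25), the Tukey ladder-of-powers display transform
(λ chosen on a grid to maximize Shapiro–Wilk W), and a top-k
secreted-protein signature scoreable on expression matrices.

A synthetic-data generator (`stromasig.synthetic`) produces cohorts and
panels with planted, recoverable structure, so the whole pipeline is
testable without external downloads.

## Worked example

```sh
stromasig simulate --seed 42 --outdir sim --n-samples 120
stromasig survcut --expression sim/expression.tsv --clinical sim/clinical.tsv \
    --already-log2 --seed 7 --outdir results
```

`results/cutpoint.json`:

```json
{
  "cutpoint": 0.65,
  "n_high": 86, "n_low": 34,
  "p_selected": 2.928e-05,
  "standardized_statistic": 5.018,
  "stat": "scores", "pmethod": "lausen_approx", "minprop": 0.1
}
```

`results/survival_report.json`:

```json
{
  "chi2": 22.216, "pvalue": 2.44e-06,
  "direction": "high_worse",
  "median": {"high": 391.1, "low": 1806.7},
  "n": {"high": 86, "low": 34}
}
```

Read: the optimal cutpoint of the ECM/IA rank-ratio splits this
simulated cohort 86 high vs 34 low; even after adjusting for having
scanned every admissible split, the association is overwhelming
(selection-adjusted p ≈ 3e-5), and the high-ratio group does worse —
median survival 391 vs 1807 days, log-rank p ≈ 2.4e-6, exactly the
planted direction (the generator ties hazard to the stromal-vs-immune
contrast). `results/correlation_scores.tsv` shows the two scores
positively correlated (Spearman ρ = 0.29, p = 0.001) while the ratio
correlates positively with the ECM score and negatively with IA, as it
must. The secretome pathway runs analogously:
`stromasig secretome --panel sim/panel.tsv --outdir results` writes
fold changes, induction and synergy calls, the ladder-transformed
matrix, and the top-10 secretory signature.

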