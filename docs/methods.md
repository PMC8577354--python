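# Methods

This note records the models, conventions and numerical choices behind
`stromasig`, the reasoning where the design was genuinely open, and
what the synthetic-data experiments do and do not establish.

## Preprocessing

Input matrices are genes × samples, non-negative, on a raw (linear)
scale. The default route is quantile normalization across samples
followed by log2(x + 1).

* **Quantile normalization.** The reference distribution is the vector
  of row means of the column-sorted matrix. Ties within a column
  receive the mean of the reference values their rank span covers.
  The operation is exactly idempotent on tie-free columns; with
  heterogeneous tie patterns across columns the tie-averaging
  projections do not commute and a second pass can shift values at
  machine-precision-to-small magnitudes. The property test therefore
  asserts idempotence on continuous (almost surely tie-free) input.
  Normalization method choice is a documented default, not a claim
  about any particular upstream pipeline; pre-normalized matrices
  should set `normalize: false` or `already_log2: true`.
* **Pseudocount** defaults to 1 (configurable); **duplicate gene rows**
  collapse by mean (configurable to first-occurrence), with a warning.

## Signatures and scoring

Gene sets are stored uppercase; matching is case-insensitive through a
small alias map covering protein-style spellings (TGFβ1→TGFB1,
PD-L1→CD274, CD90→THY1, IL-8→CXCL8, GM-CSF→CSF2, ...). Unmatched
symbols are reported, never silently dropped; by default every
signature gene must be present (`min_coverage = 1.0`) because the sets
are small and curated. The immune-activation set is sometimes described
in the source literature as a 13-gene panel, but only 12 distinct
symbols are ever enumerated; the registry ships those 12 rather than
guessing a 13th.

Scores are plain sums of per-gene z-scores (sample sd, n−1). Zero
variance rows z-scale to zero with a warning. Consequences asserted by
tests: scores are invariant to per-gene additive shifts, permute with
samples, and respond to dropping a gene by exactly that gene's z-row.

**Ratio statistic.** The stromal-to-immune balance divides two
zero-centred sums, so the package never forms the raw quotient.
Default `rank_ratio` divides fractional ranks (range (0, 1], average
ranks for ties); `minmax_ratio` maps each score into (1e-6, 1] by
min–max first; `difference` subtracts. All three are strictly monotone
(up in the numerator, down in the denominator) for tie-free scores;
when the two scores are perfectly anti-correlated all three order
samples identically.

## Correlation structure

Spearman ρ with the t-approximation p-value
(t = ρ√((n−2)/(1−ρ²)), n−2 df; |ρ| = 1 ⇒ p = 0); an exact/Monte-Carlo
permutation p is available and recommended for n ≤ 10, where the
discrete null makes the t-approximation mildly anticonservative
(measured null rejection 0.054 at n = 10, 0.052 at n = 50, α = 0.05).
Constant vectors yield missing cells with a warning. The correlogram
masks cells at per-pair p < α with no multiplicity correction by
default — matching the display convention it mirrors — with
Benjamini–Hochberg as a switch. Cells use pairwise-complete
observations, minimum 3 pairs.

## Survival analysis

* **Kaplan–Meier / Nelson–Aalen** over distinct event times; subjects
  censored exactly at an event time are counted at risk at that time
  (standard product-limit convention). Median = first event time with
  S(t) ≤ 0.5, missing if never reached.
* **Log-rank test**: hypergeometric O−E accumulation, χ² on 1 df.
  Cross-checked in tests against an independent survival library and a
  frozen hand tabulation (χ² = 49/17 on a four-event example).
* **Optimal cutpoint.** Candidates are the distinct marker values whose
  split leaves ≥ ⌈minprop·n⌉ samples per side (minprop default 0.1,
  mirroring the convention of the R cutpoint tooling). Ties for the
  maximum resolve to the smallest marker value; ties of the marker with
  the cutpoint go to the "low" group (strict > defines "high").

  Two standardizations of the scan statistic are provided. They share
  the O−E numerator and differ only in the variance: `"scores"`
  (default) uses the Lausen–Schumacher subset-sampling variance of the
  log-rank-scores linear statistic — the maximally-selected-rank-
  statistics convention — while `"logrank"` standardizes each split as
  its own two-group log-rank test, which is the formulation the
  brute-force oracle in the test suite enumerates. Their argmaxes
  disagree on roughly a third of small random tables; the default
  follows the field-standard tool convention and, in our planted-
  threshold experiments, localizes the true threshold slightly better.
  One counter-intuitive consequence, true of both: with two
  well-separated survival blocks the scan maximum generally sits at an
  unbalanced split inside a block, not at the block boundary, because
  standardized statistics are compared across splits with different
  variances.
* **Selection-adjusted p.** Default `lausen_approx` is the
  Miller–Siegmund Brownian-bridge bound
  p ≈ 4φ(b)/b + φ(b)(b − 1/b)·log[ε₂(1−ε₁)/(ε₁(1−ε₂))] at b = max|z|,
  with ε the observed candidate-range proportions, clamped to [0, 1].
  Measured null behaviour is conservative-to-nominal (rejection ≈ 0.03
  at α = 0.05, n = 60, 2000 replicates). `permutation` re-runs the full
  scan on shuffled markers and is the reference oracle.
* Unadjusted two-group comparisons only: no Cox regression, covariate
  adjustment or competing risks. Time units are whatever the clinical
  table provides; nothing is converted.

## Secretome analysis

Fold change = condition mean over donors ÷ max(vehicle mean, floor);
the floor (default: smallest positive observed concentration / 10)
guards near-zero vehicles and is recorded in provenance. Induction is
strictly fold > threshold (default 5). The synergy rule operates on
vehicle-subtracted, zero-clipped effect means ΔT, ΔI, ΔC with
s = ΔT + ΔI and tolerance τ = 0.25: synergistic if ΔC > (1+τ)s,
additive if |ΔC − s| ≤ τs, sub-additive if 0 < ΔC < (1−τ)s, and none
when ΔC ≤ 0 or both single effects vanish. The rule is a Bliss-style
formalization and configurable; it is not claimed to reproduce any
by-eye annotation analyte-by-analyte. Because it labels *any* analyte
with positive deltas, pure-noise analytes can draw a (usually
sub-additive) label; exact whole-panel label recovery is therefore a
noiseless-data property, while under noise the recovery criterion is
that every planted analyte receives its planted label.

The Tukey ladder searches λ ∈ [−2, 2] in steps of 0.025 (x^λ for
λ > 0, log x at 0, −x^λ for λ < 0) and keeps the λ maximizing
Shapiro–Wilk W, so the selected transform is never less normal than
the input. The "secretory signature" takes the k = 10 analytes with the
highest mean concentration under combined stimulation (configurable to
other conditions or the max over conditions), ties broken
alphabetically, names mapped to gene symbols through the alias map.

## Synthetic data

**Cohorts.** The two signature blocks are drawn from a joint Gaussian
copula on the log2 scale: equicorrelated within blocks (ρ_w = 0.6 each
by default) with a constant cross-block gene correlation solved from
the target score–score correlation ρ_x = 0.4 via
r = ρ_x·√(v₁v₂)/(p₁p₂), v = p + p(p−1)ρ_w. For two equal 12-gene
blocks this construction is positive semi-definite for every
|ρ_x| < 1; the PSD check at construction is defensive. Background
genes are independent Gaussians; all genes sit at mean 8, sd 1 on the
log2 scale. Survival follows a Weibull proportional-hazards model
(default shape 1, scale 1000 days) with linear predictor
effect × standardized ECM-minus-IA contrast, or a threshold model where
the hazard jumps by a given ratio above a contrast percentile.
Censoring is independent uniform on [0, τ], with τ solved by
root-finding so the expected censoring fraction hits the target
(default 0.3, a realistic overall-survival censoring level). All
randomness flows from one seed through spawned substreams
(expression / survival / censoring), so outputs are byte-reproducible.

**Panels.** 40 analytes, 8 donors, vehicle levels log-normal
(median 50, log-sd 1). Planted structure: 15 TNF-induced and 5
IFNγ-induced analytes at fold 8 in their condition; 5 synergistic and
10 additive analytes with single-stimulus effects at fold 3 — kept
below the 5-fold induction threshold so the planted sets stay
disjoint — and combined effects of twice, respectively exactly, the
single-effect sum. Induced-only analytes return to vehicle level under
combined stimulation (a pattern real panels show for some chemokines),
which keeps the interaction labels identified with the planted
synergy/additive sets. Donor noise is multiplicative log-normal,
mean-preserving, with CV 0.1 by default.

**What the generator does not emulate:** real gene–gene covariance
beyond the planted blocks, batch effects, assay detection limits, or
donor-level correlation across analytes. Passing tests establish that
the estimators recover the structure they assume — not that real
cohorts satisfy those assumptions.

## Measured operating characteristics

Numbers below are computed by the test suite and
`scripts/acceptance.py` at their stated problem sizes (nothing here is
asserted without being recomputed):

* Log-rank type-I error ≈ 0.05 (2000 null replicates, n = 50 + 50).
* Correlogram null mask rate ≈ α (2000 replicates, n = 10, two
  variables).
* Selection-adjusted cutpoint p: null rejection ≈ 0.03 ≤ 0.05
  (2000 replicates, n = 60) — conservative, as the bound predicts.
* Log-rank power ≈ 1.0 at hazard ratio 2 (threshold split, n = 300) and
  ≈ 0.05 at hazard ratio 1.
* Planted score correlation 0.4 recovered within ±0.1 at n = 500.
* Secretome: noiseless panels classified perfectly; at 10% donor CV the
  planted induction sets and interaction labels are recovered in
  ≈ 100% of 200 replicates; 15/5/5/10 induced/synergistic/additive
  counts on the default panel.
* **Known limitation — cutpoint localization.** Under the planted-
  threshold design (n = 300, hazard ratio 2, threshold at the 60th
  marker percentile, minprop 0.1) the argmax cutpoint recovers the
  threshold within ±5 percentile points in ≈ 75–79% of replicates
  (percentile-error sd ≈ 0.07), for both variance conventions and with
  or without censoring. Dichotomization at a selected cutpoint is a
  noisy estimator of a true changepoint at this effect size; users
  needing tighter localization should raise the effect size, the
  cohort size, or treat the cutpoint as descriptive.
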