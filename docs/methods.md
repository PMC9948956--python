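# Methods

## The pseudobulk negative-binomial offset model

For one brain region, timepoint, and treatment-vs-control pair, cells are
grouped by animal and cell type and summed: row *i* of the pseudobulk
table carries `target_umi` (y_i), `total_umi` (T_i) and `n_cells`. The
model is an NB2 GLM with log link and exposure offset:

    y_i ~ NB(mu_i, theta),  Var = mu_i + mu_i^2/theta
    log mu_i = beta_ct(i) + beta_ct(i):trt(i) + log T_i

with one free baseline log-rate per cell type (a cell-means
parameterization; no global intercept) and one interaction coefficient per
cell type × non-reference treatment. `exp(beta_int)` is the mean residual
target fraction; the 95% CI is `exp(beta_int ± 1.96 SE)`, computed on the
log scale and exponentiated so the ordering `ci_low ≤ residual ≤ ci_high`
is structural. Comparisons involving several ASOs against a shared control
are fit as separate pairwise models.

**Estimation.** Alternating maximization: IRLS for beta at fixed theta
(working weights mu/(1 + mu/theta)), then profile likelihood for theta at
fixed beta — a bounded Brent search on log theta over [−10, 15] whose
result is polished by analytic Newton steps (digamma/trigamma score and
curvature), which keeps the theta update deterministic where the profile
is numerically flat. Joint convergence requires max|Δbeta| < 1e-8 and
|Δlog theta| < 1e-8 (default cap 200 outer iterations; non-convergence is
flagged, never silent). On ≤12-row tables the attained log-likelihood
matches direct Nelder–Mead maximization to 1e-6, and with equal offsets
the intercept MLE equals the ratio of sums to 1e-10 (the score equation
forces Σy = Σmu). The fit also matches the independent NB2 ML
implementation in statsmodels to ~1e-7 in beta.

**Standard errors** come from the observed information for beta at the
optimum, conditional on the fitted theta — the per-row curvature is
theta·mu·(y + theta)/(theta + mu)², a single dispersion shared across cell
types (one model call implies one theta; treated as an assumption).

**Per-animal estimates** use the log-ratio residual rho_i =
log(y_i/mu_hat_i), so exp(beta_int + rho_i) equals that animal's observed
ratio divided by the fitted control rate — the unique residual definition
with that property. Which residual type (deviance, Pearson, working) the
procedure "adds back" was genuinely open; the log-ratio choice is ours.
Zero counts use y + 0.5 and are flagged.

**Degenerate inputs.** A cell type × arm whose counts are all zero makes
the interaction coefficient unbounded (separation): those rows get a 0.5
continuity correction, the coefficient is flagged and its SE reported
infinite, keeping the output shape stable rather than dropping the cell
type. Cells with zero total UMIs carry no exposure and are dropped with a
warning before aggregation. No multiple-testing correction is applied;
p-values are reported as nominal.

## Single-cell knockdown architecture

Given a control-arm fit and a residual fraction r (taken from the
pseudobulk model or a raw ratio — both are accepted; it is not
re-estimated jointly), two candidate PMFs for treated-cell counts:

    scaled_mu:   NB(r·mu, theta)            P0 = (theta/(theta+r·mu))^theta
    zero_subset: r·NB(mu, theta) + (1−r)δ0  P0 = (1−r) + r(theta/(theta+mu))^theta

Both have mean r·mu exactly; they differ in zero mass (P0_subset ≥
P0_scaled for all 0 < r < 1) and higher moments. The observed histogram is
scored by multinomial log-likelihood over support 0..K plus a lumped tail
bin, K being the smaller of the observed maximum and the 99.9th percentile
of the control fit (tail lumping stabilizes the multinomial term). The
higher-likelihood architecture is preferred; |Δ log-likelihood| < 2 is
called indeterminate — conventional likelihood-comparison slack that
avoids overclaiming when the PMFs nearly coincide (e.g. r near 1).

The control NB is fit marginally — a single (mu, theta) for the pooled
per-cell counts of one cell type, matching a single fitted curve over a
histogram. The marginal mu MLE is the sample mean exactly, leaving a 1-D
theta search; underdispersed data push theta to its cap (log theta = 15,
numerically Poisson) and are flagged. An exposure-normalized variant
(counts rescaled to 10,000 total UMIs) is provided for sensitivity
analysis. At 2,000 treated cells, mu = 2, theta = 2, r = 0.5, the
comparison identifies the generating architecture in effectively 100% of
replicates; power falls as r → 1 and as mu or cell count shrink.

## Cross-condition summaries

Weighted Pearson correlation and weighted SD treat cells-per-type as
frequency weights normalized to sum to n (the number of cell types):
rho is the weighted covariance over the product of weighted SDs, the SD is
the square root of the unbiased frequency-weighted variance
(Σw(x−x̄)²/(n−1)), and the correlation p-value uses
t = rho·√((n−2)/(1−rho²)) on n−2 df, two-sided — the common
frequency-weight convention; the df convention was an open choice and is
ours. Equal weights reduce both to the ordinary formulas (tested to
1e-12).

The *difference from overall residual* is a cell type's residual percent
minus the overall residual percent, where "overall" is re-fit from the
single all-cells pseudobulk (cell types pooled per animal), not the
weighted mean of per-type estimates. Positive differences mean weaker
knockdown than bulk. All reported scales are percent (0–100); an input
profile whose values all lie at or below 1.5 is rejected as a likely
fraction/percent mix-up. Washout recovery is late-minus-early residual in
percentage points.

ΔΔCt quantification averages technical duplicates on the Ct scale, forms
ΔCt = Ct_target − Ct_housekeeping, centers on the reference-arm mean ΔCt,
and reports 2^(−ΔΔCt)·100%; the reference arm is centered at 100% on the
log scale by construction. Dose arithmetic is
dose/molecular-weight × Avogadro, divided over cells, times the productive
uptake fraction.

## The synthetic cohort generator

`generate_cohort` emulates the count structure the analysis assumes, not a
full transcriptome. Per cell: a type drawn from the specified proportions;
a total UMI count drawn log-normal (defaults log-mean = log 7650,
log-SD = 0.5 — heavy-tailed library sizes at the reported per-cell scale)
rounded and floored at 100; a target count drawn NB2 with mean
basal_rate × total × exp(animal effect) and per-type dispersion theta.
Treated cells follow one of the two architectures above: `scaled_mu`
multiplies the mean by r; `zero_subset` keeps the control draw with
probability r and forces 0 otherwise. A single aggregate "other" feature
makes every column sum equal the drawn total exactly (only target and
total counts enter the analysis, so filler genes would only bloat
fixtures). Identical spec + seed gives bit-identical output.

Choices worth knowing:

- **animal_sigma defaults to 0.** The animal-level variance of knockdown
  is not a measured quantity here; zero makes the generator's pseudobulk
  law coincide with the fitted model family, which is the right condition
  for checking the estimator and its CI machinery. The parameter is
  exposed (multiplicative log-normal effect on the target mean only —
  isolating replicate variance where the model expects it) for
  sensitivity runs; the model has no random effect, so large sigma will
  widen true sampling variation beyond what theta can absorb.
- **Target counts are clipped at the cell's total.** An unconstrained NB
  draw can in principle exceed the total; at the default scales the event
  has negligible probability, but the conservation invariant is kept
  exact.
- The generator does not simulate doublets, ambient RNA, empty droplets,
  batch structure, or cluster geometry; passing tests therefore speak to
  the count model and estimator, not to upstream QC of real data.

## Calibration conditions and what they show

Parameter recovery runs cohorts in the *sparse-target regime*: six cell
types with basal rates 0.3–2.0 × 10⁻⁴ target UMIs per total UMI (≈0.2–1.5
target UMIs per 7,650-UMI nucleus, straddling the sub-UMI expression
typical of protein-coding ASO targets), per-cell theta = 2, four animals
per arm, 2,000 cells per animal, true residual uniform across types at
0.1/0.5/0.9. Under these conditions the pooled 95%-CI coverage sits near
93% and the pooled median |r̂ − r| near 0.016.

Known limitation: with dispersion estimated by ML from few animals, Wald
intervals run slightly below nominal, and the shortfall grows for abundant
targets, where the NB variance term dominates Poisson counting noise and
the upward bias of the ML theta (≈ n/(n−p) in precision, a nuisance-
parameter effect that is design-intrinsic at 4 animals/arm) feeds directly
into the SEs — expect ≈90% coverage in a Malat1-like regime. A Cox–Reid-
adjusted dispersion would mitigate this at the cost of no longer being the
maximum-likelihood fit; the package keeps plain ML and documents the
behavior. CIs shrink with cell count, so rare cell types carry wide
intervals; coverage statements assume the generator's conditions
(in particular animal_sigma = 0).

Problem sizes used by the shipped runs: 500 cohorts (×6 cell types) for
coverage, 200 replicates per architecture (2,000 cells each) for
discrimination; the `analysis/05_calibration.py` driver runs a 150-cohort
/ 100-replicate version for a quick look.
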