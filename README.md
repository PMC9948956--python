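# kdquant

Quantifying antisense-oligonucleotide (ASO) target knockdown from
single-nucleus RNA sequencing counts.

Gapmer ASOs lower a target RNA throughout a tissue, but bulk measurements
cannot say *how* that lowering is distributed over cells: 50% residual
target in bulk could mean 50% knockdown in every cell, or complete
silencing of half the cells. `kdquant` implements the count-level analysis
that answers both questions from single-nucleus UMI data:

1. **Per-cell-type residual target.** Cells are collapsed to pseudobulk
   sums of target UMIs and total UMIs per (animal, cell type), and a
   negative-binomial regression with a log link and exposure offset is fit:

   ```
   y_i ~ NB(mu_i, theta),   Var(y_i) = mu_i + mu_i^2 / theta
   log mu_i = beta_celltype(i) + beta_celltype(i):treatment(i) + log(total_umi_i)
   ```

   The exponentiated cell-type × treatment interaction coefficient is the
   mean residual target RNA in that cell type (exp(beta) = 0.5 means 50%
   of control expression remains), with 95% CI exp(beta ± 1.96·SE) and
   per-animal point estimates exp(beta + rho_i) from each animal's
   log-ratio residual rho_i.

2. **Single-cell knockdown architecture.** Given the control-arm NB fit
   (mu, theta) and a bulk residual fraction r, two hypotheses make the
   same pseudobulk but different histograms:

   - *scaled-mu* (uniform partial knockdown): NB(r·mu, theta), with
     P(0) = (theta/(theta + r·mu))^theta
   - *zero-subset* (complete silencing of a 1−r fraction):
     r·NB(mu, theta) + (1−r)·δ₀, with
     P(0) = (1−r) + r·(theta/(theta + mu))^theta

   A multinomial likelihood comparison of the observed treated-cell
   histogram under the two candidate PMFs decides between them.

3. **Cross-condition summaries.** Cell-count-weighted Pearson correlations
   and weighted SDs across cell types, each cell type's difference from
   the overall (all-cells) residual, washout recovery in percentage
   points, ΔΔCt residuals from bulk qPCR Ct tables
   (residual = 2^(−ΔΔCt)), and dose → molecules-per-cell arithmetic.

A seeded synthetic-cohort generator (`kdquant.synthetic`) reproduces the
count structure the analysis assumes — log-normal per-cell totals around
7,650 UMIs, NB target counts from sparse (<1 UMI/cell) to abundant,
multiple cell types with distinct basal expression and knockdown depth,
4 animals per arm, and both knockdown architectures — so the whole chain
is testable without any sequencing data.

## Worked example

The numbered scripts under `analysis/` run the pipeline on a simulated
three-cell-type cohort (true residuals: astrocytes 56%, neurons 30%,
microglia 80%, uniform per-cell scaling; 4 animals/arm, 2,000 cells/animal):

```bash
python analysis/01_simulate.py
python analysis/02_fit.py
python analysis/03_modes.py
python analysis/04_summarize.py
python analysis/05_calibration.py
```

`02_fit.py` prints the recovered residuals with their 95% CIs:

```
residual target RNA (% of control), 95% CI:
  astrocyte   56.9% [ 54.0,  59.9]  (3220 cells)
  microglia   84.7% [ 77.5,  92.5]  (1589 cells)
  neuron      30.7% [ 29.3,  32.2]  (3191 cells)
```

Each estimate is the exponentiated interaction coefficient; all three CIs
cover the simulated truth, and the rarest cell type (microglia) has the
widest interval. `03_modes.py` then identifies the single-cell
architecture:

```
astrocyte  r=0.57  preferred=scaled_mu   delta=   199.6  ...
microglia  r=0.85  preferred=indeterminate delta=    -0.8  ...
neuron     r=0.31  preferred=scaled_mu   delta=   911.3  ...
```

The cohort was simulated under uniform scaling and the likelihood
comparison says so decisively wherever knockdown is deep; at 85% residual
the two hypotheses nearly coincide and the call is correctly withheld.
`04_summarize.py` reports the overall residual (43.5%), each type's
difference from it (e.g. neurons −12.8 points: deeper knockdown than
bulk), the cell-weighted SD across types (24.6 points), and a matched
synthetic bulk qPCR ΔΔCt estimate (42.1%) agreeing with the
single-nucleus overall.

The same pipeline is exposed as a CLI (`kdquant simulate | aggregate |
fit | modes | summarize | all`) for use on real 10x-style inputs
(Matrix Market counts + features/barcodes sidecars + an annotation TSV).

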