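# Methods

This note records the models behind each stage of `hamkit`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would otherwise have
to reverse-engineer from the code.

## Gene set and DE scores

Expression is stabilized as `log2(x + 1)` on a nonnegative layer (nRPKM,
normalizedCount, or raw counts for simulated data). For each dataset
separately, each gene's mean over that dataset's control samples is
subtracted; scores are never centered across datasets, because platform and
cohort offsets would otherwise masquerade as biology. The gene set score of
a sample is the unweighted mean of the centered values over the set's
members present in the matrix; the DE score weights annotated down-genes by
−1. Members absent from a matrix are dropped (never imputed as zero) and
the count of genes actually used is carried in the result; when scores are
compared across datasets, sets are first intersected with the genes present
in every dataset so that all studies score the same members.

A direct consequence of centering, asserted by property tests: the mean
score over the centering control set is exactly 0 (to 1e-9) for every gene
set, plain or signed.

Group contrasts report `delta = mean(AD) − mean(control)` (a log2 fold
change of the set's average expression) with a two-sided t test. Student's
pooled-variance variant is the default — matching the test named in the
cohort tables this package recomputes — with Welch selectable. Degenerate
contrasts (both groups constant and equal) report p = 1; a dataset with a
single control sample still supports centering and a delta but no p value,
which is reported as NaN.

## Myeloid balancing

Whole-tissue cohorts confound diagnosis with myeloid-cell abundance. The
balancing procedure bins samples by myeloid-marker score and thins the
over-represented diagnosis group within each bin:

* **Bins** are equal-count (quantile) bins of the pooled scores, 20 by
  default, with ties assigned to the lower bin. Quantile bins guarantee
  nonempty bins and are invariant to monotone transforms of the score;
  equal-width binning is available behind a flag.
* **Single-group bins** carry no within-abundance information and are
  dropped wholly. The **target AD fraction** is then the AD fraction among
  the samples of the remaining mixed bins — computing it before dropping
  would chase a ratio that the retained bins cannot represent.
* Within each mixed bin, the over-represented group is thinned **uniformly
  at random** with a counter-based (Philox) generator keyed by a required,
  logged seed, to the discard count that brings the bin's AD fraction
  closest to the target. Samples are only ever discarded, never duplicated
  or reweighted. The same seed reproduces the identical plan; different
  seeds can differ only in which equivalent samples are discarded, never in
  per-bin kept counts.

## Pseudobulk aggregation and QC

Cells are filtered by per-study QC rules with the boundary semantics of the
source descriptions (kept at exactly 800 and 400 total UMIs, at exactly 30%
and 5% mitochondrial fraction, at exactly log10 total UMIs = 3.25).
Mitochondrial fraction is computed on raw counts, before any normalization,
because the thresholds are defined on raw UMIs. Mitochondrial genes are
identified by a configurable id prefix (default `MT-`), since no universal
rule exists across annotations. Cluster assignment (which cells are
microglia) is upstream input; the package aggregates whatever cells it is
handed, restricted to caller-designated cell types.

Aggregation sums UMIs per gene over each (sample, cell type) group with at
least 10 cells (configurable); the result is normalized by median-of-ratios
size factors (reference profile = per-gene geometric mean over columns,
restricted to genes positive everywhere; factor = median ratio to the
reference). Per-cell total-transcript normalization — each cell scaled to a
common total, default the median cell depth since only proportionality is
required — is provided for cell-level visualization and preserves
within-cell gene proportions exactly.

## Differential expression stage

The DE engine is per-gene ordinary least squares on log2(x+1) values
against a shared design matrix — deliberately simple and fully auditable.
It is *not* a negative-binomial or precision-weighted fit: this package's
DE stage is validated against simulations and analytic invariants (type-I
error, planted-effect recovery, closed-form OLS identities), not against
any published real-data gene counts, which depend on the original engines
and raw data. Covariate adjustment (age, sex, PMI, ApoE4) is additional
design columns of the same fit, not separate code paths.

Because the design is shared across genes, the hat matrix is computed once
and the per-gene coefficient, SE, t (m−p df, two-sided p), and per-sample
Cook's distances

```
D_j = r_j^2 * h_jj / (p * s^2 * (1 - h_jj)^2)
```

are vectorized. Genes whose maximum Cook's distance exceeds the upper-0.99
quantile of F(p, m−p) — the alpha = 0.01 critical value, equivalently a
Cook's p below 0.01 — are excluded from DE lists. The analytic distances
are pinned to the leave-one-out refit definition within 1e-8 by tests. A
numerically perfect fit (residual sum of squares at rounding-noise level
relative to the response) is treated as zero-residual: SE 0, p 0, no
influence; this avoids dividing rounding error by rounding error.

One behavior worth knowing: in a balanced two-group design, a single
outlier sample inflates its own gene's variance estimate, which bounds its
Cook's distance near (m−p)/(p·k) for group size k — below the alpha = 0.01
critical value at typical cohort sizes. Under a pure per-gene OLS the
filter therefore trips on high-leverage configurations (e.g. an aberrant
value at an extreme covariate), not on lone outliers in balanced indicator
designs; engines that shrink dispersion across genes behave differently.
Both regimes are pinned by tests.

BH adjustment is applied within each contrast separately. The 4-way
concordance analysis intersects two DE results, classifies genes by
significance (A only / B only / both / neither) and fold-change sign
quadrant, and reports the sign-concordance fraction among genes significant
in either dataset.

## qPCR processing

Order of operations is pinned by tests: per-assay ceiling imputation, then
duplicate collapse, then ΔCt.

1. Per assay, maxCt is the maximum Ct among quality > 0 records, computed
   on the raw replicate records (before duplicate averaging); every record
   with Ct > maxCt — including the 999 undetected sentinel — is set to
   maxCt + 0.5. An assay with no usable record is dropped with a warning.
   The step is idempotent.
2. Duplicate pairs differing by more than 2.82 cycles are discarded as
   irreproducible (a pair differing by exactly 2.82 has sample SD
   2.82/√2 ≈ 2 cycles); otherwise the mean is kept. The threshold
   comparison carries a 1e-9 tolerance so that values representing exactly
   2.82 in decimal are kept despite binary rounding.
3. ΔCt(sample, assay) = Ct − median Ct over that sample's assays. Lower
   ΔCt means higher expression; ΔCt is invariant to per-sample additive
   shifts (plate loading). Samples with fewer than three assays get a
   median-instability warning.

Group DE on ΔCt reuses the linear-model stage on −ΔCt, so a positive
effect means higher expression in AD, sign-comparable to RNA-seq log2 fold
changes.

## Cohort statistics

Fisher's exact test uses the summation convention (two-sided p = sum of
hypergeometric point probabilities ≤ the observed table's, with relative
tolerance 1e-7), which is the convention of the mainstream statistical
environments; the doubling convention is available behind a flag. Tables
with a zero margin report p = 1 with a warning. Quartiles use linear
interpolation between order statistics (type 7), the default of mainstream
environments; printed medians and IQRs cannot adjudicate between quartile
conventions without raw data, so the common default is used. Whether
published age/PMI contrasts used pooled or Welch t cannot be determined
from summaries either; both variants are provided, pooled by default.

## Synthetic-data generator

The generator exists so that each pipeline stage can be exercised under
known ground truth. Defaults mirror the study conditions the package is
designed around: 15 control / 10 AD sorted-cell profiles; 42 / 158
whole-tissue profiles (the recovery suites use a 50/50 cohort, the
condition under which the balancing guarantees are stated); NB counts
parameterized by mean and dispersion alpha with variance mu + alpha·mu^2
(dispersion 0.1, a typical bulk RNA-seq value); gene base means lognormal
with median 100 counts; three cell types with 50-gene marker blocks
elevated 16-fold.

Whole-tissue samples are convex mixtures of cell-type signature profiles.
The myeloid mixing weight is drawn per sample from a diagnosis-specific
normal — control mean 0.10, AD mean 0.20, SD 0.05 for both, clipped to
[0.01, 0.95] — and recorded as ground truth. The SD was chosen once as a
realistic 25–50% coefficient of variation for tissue cell-fraction
estimates; it controls how much the two diagnosis distributions overlap
and hence how many samples balancing retains. Planted disease effects
multiply AD samples' mean expression by 2^(log2FC) and are independent of
the myeloid weight.

Cell-level data: per-cell depth lognormal (median 1,000 UMIs, sigma 0.5,
so a tail of cells fails UMI-based QC by construction), mitochondrial
fraction Beta(1, 99) (≈1% mean) allocated to dedicated `MT-` genes, gene
counts multinomial given the cell's (diagnosis, cell type) profile. qPCR:
Ct = a − b·log2(expression) + Gaussian replicate noise (a = 40, b = 1,
SD 0.25 cycles), duplicates per sample × assay, detection ceiling 35
cycles; undetected reactions are recorded as the 999 sentinel with
quality 0.

All randomness flows through counter-based Philox generators keyed by
(seed, stream tag), so fixed seeds give byte-identical outputs across
platforms and the four generators' streams are independent.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: batch effects and library-preparation artifacts;
gene–gene correlation beyond cell-type structure (genes are conditionally
independent given composition); ambient RNA, doublets, and empty droplets;
length biases (simulated counts are already gene-level); and any
dependence of dropout on biology beyond depth. Conclusions about the
statistical machinery (bias, type-I error, confound removal) transfer;
conclusions about real-data effect sizes do not.

## Problem sizes and runtime

The default suites use a few hundred genes per simulated cohort (5,000 for
the type-I check), 100 seeds for bias estimation, and 200 replicates for
the balancing rates; the whole test suite runs in well under a minute and
the acceptance script in a few seconds on one CPU. These sizes were chosen
as the smallest at which the Monte Carlo error of each checked rate is an
order of magnitude below its tolerance band.

## Known limitations

* The DE stage's OLS-on-log-counts is anticonservative for very low counts
  at small n; the type-I guarantee is demonstrated at the generator's
  default expression levels (median 100 counts).
* Gene identifiers are opaque strings; symbol/alias harmonization across
  annotations is a caller-supplied translation table (default identity).
* nRPKM's exact historical formula is not fully specified by its name; the
  implementation uses size-factor-normalized counts per kb of exonic model
  per million total reads, with a flag to fall back to raw library size.
* Balancing assumes the myeloid score is a monotone proxy for myeloid
  abundance; if marker genes are themselves disease-regulated, balancing
  removes part of the disease signal along with the composition effect.
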