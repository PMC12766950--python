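# Methods

This document describes the statistical model behind each module, the
parameters (with units and defaults), the synthetic-data generators and their
realism limits, and the numerical choices. It makes no empirical claims beyond
what the test suite and `scripts/acceptance.py` compute.

## Core statistics (`wntaxis.stats`)

All tests return a `TestResult` (statistic, p-value, alternative, method,
optional effect size). P-values are floored at 1e-12 and never exactly 0.

### Spearman correlation

Ranks are midranks (ties averaged); rho is the Pearson correlation of the
ranks. For n ≤ 10 the two-sided p-value is exact: all n! orderings of one
rank vector are enumerated (in chunks, as a matrix product) and the fraction
with |rho| at least the observed value (within 1e-9) is reported. For n > 10
the t-approximation is used: t = rho·sqrt((n−2)/(1−rho²)) with n−2 degrees of
freedom. Constant input vectors raise `UndefinedStatisticError` rather than
returning NaN.

### Rank-sum (two-sample Wilcoxon)

The default mode is the normal approximation on the rank sum W of the first
sample, without tie correction and without continuity correction — the same
convention as `scipy.stats.ranksums`, which is the convention used by the
analyses this package reproduces. `exact=True` enumerates all C(n, n1)
assignments of the pooled midranks (capped at 3×10⁶ combinations). With ties
the exact mode is a permutation test on midranks.

### One-sample signed-rank

Zero differences are dropped; at least 5 nonzero differences are required.
For n ≤ 20 the exact null distribution of the positive-rank sum is built by
dynamic programming over the (doubled, hence integer) midranks; beyond 20 the
normal approximation (no tie or continuity correction) is used.

### Fisher's exact test

2×2: hypergeometric tails; the two-sided p sums all tables with point
probability ≤ the observed one (with a 1+1e-9 relative slack against
floating-point ties). The effect size is the sample odds ratio ad/bc
(infinite when bc = 0). r×c: exact enumeration of all tables with the
observed margins when the grand total is ≤ 40 and the shape is within 3×5;
otherwise fixed-margin Monte Carlo (shuffling column labels and splitting by
row margins) with the add-one estimate p = (k+1)/(n_mc+1), so the smallest
reportable p is 1/(n_mc+1). All-zero rows or columns are dropped with a
warning.

### Multiple-testing correction

`bonferroni` (p·m capped at 1) and `bh` (Benjamini-Hochberg step-up with the
cumulative-minimum from the largest p). BH never exceeds Bonferroni
(property-tested).

### qPCR score

`40 − (CT_target − CT_reference)`, with CT values validated to (0, 40]
cycles. Higher scores mean higher expression.

## Signature derivation (`wntaxis.signature`)

Counts are normalised to counts per 10 000 (CP10K) and log1p-transformed.
Per gene, the two genotypes (each ≥ 20 cells) are compared with the
two-sided rank-sum test; the fold change is the ratio of CP10K means with a
pseudocount of 1e-9. The rank-sum test is a deliberate stand-in for a
hurdle-model test (MAST); an externally computed DE table can be injected
instead. Selection is strict: adjusted p < 0.01 **and** log2 fold change > 1
(both inequalities strict; values exactly at a threshold are excluded).
Surviving genes are mapped to human orthologs (unmapped genes dropped with a
warning, duplicate targets collapsed) and intersected with a hallmark set
(result in sorted hallmark order). Default correction is Bonferroni;
adjusted p-values are additionally clipped to be ≥ the raw p-value.

**Compositional caveat.** CP10K is a relative (library-size) normalisation:
strongly shifting one group of genes depresses the normalised values of all
other genes, so background genes can reach significance in the *down*
direction, and a planted fold change of exactly 2 shrinks below the strict
log2FC > 1 threshold when the shifted genes are a nontrivial fraction of the
library. This is an inherent property of relative counts, not an artefact of
the implementation.

## Pan-cancer screen (`wntaxis.screen`)

* **Eligibility**: a tissue enters the screen only with strictly more than
  `min_lines` (default 20) cell lines.
* **Correlation**: per (tissue, gene), Spearman rho of the gene against the
  target across the tissue's lines; significance mask at unadjusted
  p > `alpha` (default 0.05). An optional Benjamini-Hochberg mode adjusts
  across the whole gene × tissue grid before masking (off by default —
  no correction is part of the original procedure). Genes absent from the
  matrix and constant vectors yield NaN and are masked.
* **Quartiles**: samples are ranked by the signature gene descending, ties
  broken by sample id; Q1 is the **highest** quartile. Quartile sizes differ
  by at most one, extras to the top (n = 10 gives 3,3,2,2 from Q1). Target
  expression in Q1 vs Q4 is compared with a one-sided (greater) rank-sum
  test.
* **Positivity**: a gene is flagged when rho > 0 and unmasked in at least
  `min_tissues` (default 5) tissues — "at least" is inclusive.
* **Clustering**: genes are clustered on their binary significance profiles
  with the asymmetric binary (Jaccard) distance — mismatches over positions
  where either profile is 1, with the all-zero/all-zero pair defined as
  distance 0 — under average linkage; the dendrogram leaf order is reported.
* **Performance**: for tissues with more than 10 lines the per-tissue
  correlations are computed as one vectorised rank matrix product using the
  same formulas as the scalar `stats.spearman` path (pinned by a unit test);
  at n ≤ 10 the exact-p scalar path is used per pair.

## Pathway activity (`wntaxis.pathway`)

Pseudo-bulk profiles sum the UMI counts of `n_cells` (default 500) cells of
one genotype sampled without replacement within a replicate (replicates drawn
independently, default 10 replicates), then CP10K + log1p normalised.

The enrichment score ranks genes by profile value descending (ties broken by
gene id). Walking the ranked list, a set member increments the running sum by
|v|^w / Σ_hits |v|^w (weight w = 1 by default) and a non-member decrements it
by 1/(N − n_hits); the ES is the running sum at its maximum absolute
deviation (signed). Degenerate sets score 1 (set = all genes) or 0 (empty
overlap after filtering). Signed sets score ES(positive members) −
ES(negative members) by default; an alternative mode folds |weights| into the
hit increments. Sets overlapping the profile in fewer than `min_set_size`
(default 5) genes are rejected.

The permutation null permutes gene labels: `times` (default 10 000) random
subsets of the same size(s) are scored (vectorised in chunks of 2 000), and
the one-sided p is (k+1)/(times+1) with k the number of permutation scores ≥
the observed ES (within 1e-12). Genotypes are compared by a one-sided
rank-sum test on the per-replicate ES values.

## In-situ scoring (`wntaxis.ish`)

Each cell carries a dot count and a clustered-dot fraction. Ordinal classes:

| class | rule (applied in order) |
|---|---|
| 4 | dots > 15 |
| 3 | 10 ≤ dots ≤ 15, **or** cluster fraction > 0.10 with dots ≥ 4 |
| 2 | 4 ≤ dots ≤ 9 |
| 1 | 1 ≤ dots ≤ 3 |
| 0 | otherwise (no dots) |

The original semi-quantitative scheme has overlapping clauses; the fixed
precedence above makes the classifier total and mutually exclusive. "No or
very few clusters" is interpreted as a clustered-dot fraction ≤ 10%, and the
cluster escalator requires at least 4 dots so sparse cells stay in class 1.
An optional field-level mode reassigns class-1 cells to class 0 when their
condition's mean dot count is below 0.1 (the "fewer than 1 dot per 10 cells"
reading). Conditions are compared with the r×c Fisher test on the class
table. Expressing-cell fractions (nonzero UMI of a target gene) are compared
between genotypes within a cluster by a 2×2 Fisher test.

## Synthetic generators (`wntaxis.simulate`)

All generators use `numpy.random.default_rng` (PCG64) and are bit-reproducible
under a fixed seed.

* **Cell-line matrix**: per tissue, a latent standard-normal target variable;
  in planted tissues each signature gene's latent variable is
  rho·z_target + sqrt(1−rho²)·ε (a Gaussian copula), so the implied Spearman
  correlation is (6/π)·asin(rho/2) — about 0.582 at rho = 0.6. Latents are
  shifted by per-gene baselines (uniform 1–6), scaled by `noise_sd`, and
  mapped through a strictly monotone softplus/log2 transform onto a
  non-negative log2(TPM+1)-like scale (monotone, hence rank-preserving:
  planted Spearman correlations survive exactly). Defaults mirror the screen
  setting: 22 tissues × 30 lines, 33 signature genes, 100 noise genes,
  planted in 6/22 tissues.
* **Single-cell counts**: negative-binomial background genes (gene means
  lognormal(−0.5, 1), dispersion 0.5, size r = 1/dispersion); cluster labels
  drawn from per-genotype proportions over 7 epithelial states; a pathway
  gene block whose means are multiplied by exp(shift) in the KRAS-active
  genotype (default shift log 2); and a target gene whose per-(genotype,
  cluster) nonzero fraction is planted directly (Bernoulli gate, expressing
  cells get 1 + Poisson(1) UMIs). Mouse symbols are the capitalised human
  symbols so ortholog mapping is exercised nontrivially.
* **ISH observations**: Poisson dot counts per condition (default rates
  0.5 / 2 / 12 dots per cell) and Bernoulli-gated clustered fractions
  (Uniform(0.12, 0.6) when gated on).

**Realism limits.** These generators are statistical stand-ins, not
biological simulators: no batch effects, no library-size variation between
cells beyond sampling noise, no gene–gene correlation among background genes,
no dropout model beyond the negative binomial, no doublets or ambient RNA,
independent cells and lines, and tissue blocks that differ only in the
planted correlation. They exist to give the pipeline inputs with known
ground truth, not to benchmark methods against real data.

## Numerical choices

* Exact enumerations are chunked and vectorised (rank permutations, subset
  sums, contingency tables) with documented caps; beyond the caps the
  documented approximations take over.
* Monte-Carlo p-values use the add-one (k+1)/(n+1) estimator, so they are
  never 0 and are bounded below by the resolution of the run.
* Permutation ES computation scatters hit increments into a miss-filled
  matrix and takes a single cumulative sum per chunk — identical results to
  the scalar path, pinned by oracle tests.
* All file formats are plain text (TSV/CSV, MatrixMarket triplets, GMT);
  delimiters are inferred from the extension (.csv comma, otherwise tab).

## Limitations

* The DE step is a rank-sum stand-in; it does not model dropout as a hurdle
  process, and CP10K introduces the compositional effects described above.
* The screen's positivity rule uses unadjusted per-tissue p-values by design;
  the BH mode is provided but off by default.
* Exact r×c enumeration is limited to small tables; larger tables get
  Monte-Carlo p-values with seed-dependent jitter of order 1/sqrt(n_mc).
* The ssGSEA permutation null permutes gene labels within a profile; it does
  not model inter-gene correlation, so p-values are calibrated against the
  label-permutation null only.
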