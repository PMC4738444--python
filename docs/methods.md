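# Methods

## The problem

A SNP-by-genome interaction scan fixes one "repeating" SNP `x` and, for every
other ("non-repeating") SNP `z` in the genome, fits the product-term model

    y = β₀ + β₁x + β₂z + β₃xz + ε

to a quantitative trait `y`, testing H₀: β₃ = 0 with a 1-df Wald/F test.  The
conventional measure of type I error for such a scan is the genomic inflation
factor computed on the interaction term,

    λ₃ = median(t₃²) / median(χ²₁),

with median(χ²₁) ≈ 0.4549 (0.455 at three decimals).  Unlike a main-effect
GWAS, the product terms within one scan all share the repeating SNP and are
therefore correlated; a stochastic bias in the test statistics — above all
finite-sample heteroskedasticity across the repeating SNP's genotype classes —
pushes the whole scan in the same direction instead of averaging out.  Under
the null, λ₃ consequently fluctuates far more than a main-effect λ, the more
so at small sample size and low repeating-SNP minor-allele frequency (MAF).
This package measures that fluctuation, diagnoses its drivers, and provides
the interpretation device that follows from it: comparison of an observed λ₃
to a simulation-based empirical null distribution.  λ₃ is never used to
*correct* interaction statistics — part of its deviation from 1 reflects
non-independence, not bias, so genomic-control division would itself bias the
scan; the API deliberately omits such an operation.

## Null-data simulation

`simulate` generates datasets under the global null: genotypes are independent
draws from the three-class Hardy-Weinberg distribution ((1−p)², 2p(1−p), p²)
for each SNP's MAF p; phenotypes are either fresh standard-normal columns or
independently permuted copies of supplied trait columns (the permutation
device preserves each marginal distribution — including outliers and
non-normality — while destroying all genotype-phenotype and cross-trait
dependence).  MAFs come from a `MafSpectrum`: an inclusive grid (built with
integer index arithmetic so floating steps cannot drift past the endpoint) or
an empirical list sampled with replacement.  A packaged default list spans
0.05–0.5 with density ∝ 1/p, the shape of a common-variant site-frequency
spectrum after a 5% MAF filter.

What the generator deliberately omits — because the null model omits it —
is linkage disequilibrium, population substructure, relatedness, missingness
and any SNP effect on the phenotype mean.  Passing tests on these data
therefore demonstrate behaviour of the *statistics* under a clean null; they
say nothing about confounding patterns (substructure, LD with the repeating
SNP) that real cohorts add on top.

Randomness: one master seed per generated object; per-SNP and per-trait
substreams are spawned from a `numpy.random.SeedSequence`, so a single column
can be regenerated without touching the rest, and genotype, phenotype and
permutation streams are tagged apart so reusing a seed across calls cannot
alias them.  SNPs whose realized sample MAF is 0 are retained by the
generator and later skipped by the scan engine, keeping generation
side-effect free.

## Regression core

OLS is fitted by reduced QR (never an explicit inverse); leverages are the row
sums of squares of Q; singular values of R below `max(n,k)·eps·max|R_ii|` are
treated as rank deficiency, raising a structured error that names the
collapsed columns so the scan engine can convert it to a skip.  Coefficient
covariance is the sandwich (X′X)⁻¹X′Ω̂X(X′X)⁻¹ with

* OLS:  Ω̂ = (Σe²/(n−k))·I   (reduces algebraically to s²(X′X)⁻¹),
* HC0:  Ω̂ = diag[e_i²],
* HC3:  Ω̂ = diag[e_i²/(1−h_ii)²].

HC1/HC2 are not implemented.  Single-coefficient P-values use the t reference
with n−k df for every estimator, including HC0/HC3 — a finite-sample
convention (the asymptotic reference is normal) recorded here as a documented
approximation.  Multi-df interaction tests (2-df on {β₁,β₃} or {β₂,β₃} of the
product-term model; 4-df on the four product terms of the additive+dominance
model) are RSS-based F tests under OLS only; sandwich multi-df Wald tests are
out of scope because heteroskedasticity-consistent inference is applied to the
product term alone.

## Scan engine

Filter order, fixed and not re-evaluated downstream: (1) minor-allele recode
of every SNP on the full analyzed sample; (2) dataset-level MAF threshold on
the non-repeating SNPs (boundary inclusive); (3) per-pair complete-case
subset; (4) per-pair minimum-cell-count filter — subjects in populated
two-locus genotype cells smaller than the minimum are dropped in a single
pass (counts computed once; cells left sparse by the dropping are not
re-examined; empty cells impose no constraint); (5) fit and test.  The
repeating SNP's own column is excluded from the non-repeating iteration
(self-pairing is degenerate); SNPs merely correlated with it are not.
Dataset-level minor-allele coding is kept inside each pair's filtered subset
rather than recomputed.

Defaults: no cell minimum for OLS, five for HC0/HC3 — the guard against
sandwich collapse in sparse cells; `min_cell_count` can be forced for either
(the OLS-with-minimum configuration exists precisely so OLS/HC comparisons are
fair).  Degenerate pairs yield skip rows tagged `monomorphic`, `singular` or
`insufficient_cells`; skips are archived, excluded from λ and observed-alpha
denominators, and counted per scan.  λ₃ uses the exact χ²₁ median by default;
the printed 0.455 is available for reproducing literature arithmetic, and the
mode is recorded in every λ record.  Multi-df scans convert each F P-value to
the χ²₁ deviate with the same upper-tail probability before taking the
median.  P = 0 is capped at 1e-300 with a warning.  Q-Q expected quantiles
use (i−0.5)/m; observed alpha counts P strictly below the level.  Both
conventions are stated because neither is standardised in the literature.

## Diagnostics

Genotypic variance ratios: phenotype variances (n−1 denominator) within the
repeating SNP's genotype classes, classes ordered by size descending with
ties broken by dosage ascending; the headline ratio is largest-class over
smallest-class variance.  The documented direction — lower variance in the
largest class inflates λ₃, higher deflates it — holds equally when the
variance structure is injected and when it arises stochastically from a
homoskedastic generator: at low MAF the smallest class's realized variance
fluctuates strongly, and λ₃ tracks the realized ratio (negative rank
correlation).  Leverage comparison reports per-cell maximum hat values under
the two-locus and product-term models; adding the product column enlarges the
column space, so leverages can only rise, and they rise most in sparse
rare/rare corners — the mechanism that makes product-term inference fragile
and that HC3's (1−h)² adjustment targets.

## Empirical null and comparison

`build_null_distribution` simulates one matched dataset (sample size, genome
size, MAF spectrum, repeating-SNP grid, filters, estimator) and scans it
exhaustively, yielding one λ₃ per (repeating SNP, phenotype).  `compare_lambda`
places an observed λ₃ in that collection: midrank percentile
100·(#{null<obs}+½·#{ties})/B and permutation-style two-sided tail probability
2·min(r+1, B−r+1)/(B+1) capped at 1.  No accept/reject verdict is rendered;
the user sees the percentile and tail probability.  Because λ₃ spread depends
strongly on repeating-SNP MAF, a `nearest_band` mode (±0.05) restricts the
null to comparable repeating SNPs and refuses bands holding fewer than 20
values — an unmatched comparison is anti-conservative at low MAF.  λ values
from one simulated dataset share its genome and are correlated; where an
accurate null is needed (e.g. the calibration experiment) distributions from
several independent datasets are pooled.

## Reduced-scale experiment sizes

The `experiments` module fixes the study conditions used by the acceptance
checks.  Genomes are a few thousand SNPs (2,000 for the λ-spread studies,
4,000 for the sparse-cell outlier study, 1,000 for the heteroskedasticity
direction, 200 for calibration replicates) rather than the 2×10⁴–5×10⁵ of a
full study: λ is a per-scan median, so its value stabilises quickly in genome
size, while the across-scan patterns of interest are driven by sample size
(1,053 vs 5,000 subjects), repeating-SNP MAF (grid 0.05–0.5), estimator and
filters, which are kept at full strength.  Phenotype counts are 5–10 per
study; the calibration uses 200 replicate datasets against a pooled null of
400 values from 8 independent datasets.  The injected heteroskedasticity uses
per-dosage SDs (0.8, 1.0, 1.3) at repeating MAF 0.06 — a largest/smallest
variance ratio of ≈0.38, within the 0.4–3.7 range a small cohort exhibits.

## Known limitations

* The t reference for HC-based product-term tests is a convention, not an
  exact distribution; at very small n the HC3 test remains conservative or
  anticonservative depending on the design.
* The empirical-null machinery assumes exchangeability between the observed
  dataset and the simulator's null (no substructure, no LD); an observed λ₃
  outside the null band identifies a discrepancy but not its source.
* VCF import reads the GT field only (no dosage/imputation fields) and skips
  multi-allelic records.
* No relatedness, covariate adjustment or principal-component machinery:
  phenotypes are assumed to be pre-adjusted standardized residuals.
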