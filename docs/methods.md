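# Methods

This note documents the models, conventions and numerical choices behind
`xherit`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and where the design
was genuinely open.

## Gene-content coding on the X chromosome

Genotypes are allele-B counts. Autosomes are 0/1/2 for everyone. On X,
females are 0/1/2 and males are hemizygous, which admits two codings:

* **vc coding** (variance components): male B-carriers are 1. This is the
  natural gene-content scale on which the pedigree matrix `S` and the
  genomic matrix `G_X` are defined.
* **gwas coding** (dosage compensation): male B-carriers are 2, treating
  the single male allele as a diploid dose, the convention of
  mixed-model association tools when X inactivation equalizes expression.

`encode_dosage` converts between them; the pseudo-autosomal region is not
special-cased. Files that code male X hemizygotes diploid-style (0/2) can
declare it (`male_x_raw="diploid"`), in which case a male "1" is treated
as a genotyping artifact and set missing.

## Relationship matrices

`A` uses the tabular method; `A^-1` Henderson's rules with inbreeding
(tabular inbreeding coefficients — adequate at the package's target scale
of a few thousand animals).

`S` is the X analogue of `A` under the scaling Cov(content_i, content_j) /
2p(1-p) at a neutral locus: founder females 1, founder males 0.5 on the
diagonal; a daughter's row is `S_js + 0.5 S_jd` (she always receives the
sire's single X), a son's row is `0.5 S_jd` (his X comes only from his
dam); female diagonal `1 + S_sd`, male diagonal 0.5. The cited X-matrix
literature prints no recursion, so the recursion is pinned by an
*independent oracle*: gene dropping of 200,000 unlinked X loci through a
fixed mixed-sex pedigree must reproduce `S` entrywise within 3 Monte-Carlo
standard errors (`simdata.gene_drop_covariance`). The same oracle with
autosomal rules validates `A`. `S^-1` is taken dense; the Fernando-
Grossman rule-based fast inverse is a possible optimization, not a need at
this scale.

`G_auto` is VanRaden's first matrix. `G_X` centers male content by `1p'`
and female content by `2p'` and shares the autosomal denominator
`2 Σ p(1-p)`, so female diagonals average ≈1 and male diagonals ≈0.5 —
commensurate with `S`, which matters because the two are mixed in the
single-step matrix. Any residual scale mismatch is absorbed by tuning.

**Tuning and blending.** Before blending, `G` is moment-matched to its
pedigree counterpart: scalars `(a, b)` solve mean-diagonal and
mean-off-diagonal equality of `a + bG` with `A22` (or `S22`), then
`G* = 0.90 (a + bG) + 0.10 P22`. The blend guarantees positive
definiteness; if the smallest eigenvalue is still nonpositive a ridge
(1e-8, escalating tenfold to at most 1e-4) is added and recorded in the
matrix metadata. Dense Cholesky inversion is used throughout, same ridge
policy.

**Allele frequencies** are observed frequencies with males contributing a
single allele on X. MAF filtering uses mixed-sex counts; the
heterozygosity-deviation rule (HWE proxy, |obs - 2p(1-p)| > 0.15) uses
females only on X, since male X calls carry no heterozygosity information.

## Genotype quality control

Rules run in a fixed order — SNP call rate (0.90), animal call rate
(0.90), MAF (0.05), heterozygosity deviation (0.15), Mendelian conflicts
(1%, the offspring of a conflicting pair is removed since a conflict only
localizes to the pair and the younger animal carries less downstream
information), duplicates/unmapped — because frequency-based rules should
see post-call-rate data and deterministic reports require a fixed order.
Each removed item carries the first failing rule as its single reason.
X-specific Mendelian logic: dam-son conflicts compare the son's single
allele against the dam's homozygotes; sire-son X pairs are not comparable.

## Variance components

The animal model `y = Xb + Wg + Z u_auto + Z u_x + e` is fitted by Gibbs
sampling against the *inverse* structures `H^-1`, `H_X^-1`; the hybrid
matrices are never formed. Random vectors are updated as joint
multivariate-normal draws (blocked Gibbs): the full-conditional precision
of a genetic vector is `H^-1/s2_u + Z'Z/s2_e`. When every animal in the
structure carries exactly one record (`Z'Z = I`, the common case here), a
one-off eigendecomposition of `H^-1` makes each joint draw two
matrix-vector products; otherwise a dense Cholesky is taken per
iteration. Variances use scaled-inverse-chi-square full conditionals with
a flat default prior (df -2, scale 0). Fixed effects get flat priors;
class terms are dummy-coded drop-first under an intercept, and a
rank-deficient fixed design is rejected up front with the offending
dimension named.

Categorical traits use the threshold (liability) model: latent liabilities
drawn from truncated normals (inverse-CDF method) given the category and
current mean; for binary traits the residual variance is fixed at 1 and
the single threshold at 0 (probit identification); for K > 2 the first
threshold is 0 and interior thresholds are drawn uniformly between the
adjacent liability order statistics.

Because blocked updates mix far better than scalar single-site sweeps,
desk-scale chains default to (8,000; 2,000; 4). The recovery studies in
the tests use (2,500; 800; 2), which at ~1,800 animals keeps a ten-seed
study under four minutes on one core; production-scale settings
(1,000,000; 250,000; 100 — retaining 7,500 draws) are a config away.
Divergence (any variance above 1e8) aborts with a diagnostic.

**Summaries.** The 90% HPD interval is the shortest contiguous window
over sorted draws holding ceil(0.9 n) of them, leftmost on ties;
equal-tail 5%/95% quantiles are reported alongside because the two are
often conflated in applied write-ups. Geweke's Z compares the first 10%
against the last 50% of the chain with batch-means variance estimates (20
batches); on stationary chains this statistic is slightly heavier-tailed
than normal (t-like with ~19 df per window), so its pass rate at 1.96 is
~93%, not 95% — the test suite asserts that behaviour rather than
pretending normality. A constant chain returns Z = 0. Heritabilities are
computed per retained draw, `h2_auto + h2_x = h2_total` holding exactly,
and averaged (posterior mean of ratios). The denominator excludes the
management-group variance, following the printed partition formulas; with
a management-group term in the model, reported heritabilities are
therefore h2 relative to the non-group variance.

## Deregression and GWAS

Pedigree-only EBVs come from the mixed-model equations with PEV from the
inverse coefficient matrix and reliability `r2 = 1 - PEV/sigma2_u`, where
`sigma2_u` is the total additive variance (autosomal + X) — the coherent
scale for dEBVs that precede the genomic split.

Deregression reconstructs the 2x2 {parent average, individual} system
from reliabilities. With `lambda = (1-h2)/h2`, the coefficient matrix is
`[[c_PA + 4 lambda, -2 lambda], [-2 lambda, c_i + 2 lambda]]`; the
information contents `(c_PA, c_i)` solve `0.5 - lambda [C^-1]_11 = r2_PA`
and `1 - lambda [C^-1]_22 = r2_i` in closed form (the PA reliability is
defined on the individual's sigma2_u scale, which is where the classic
`1/(0.5 - r2_PA)` factor comes from). The right-hand side of the
individual's equation is regenerated and divided by `c_i`. Animals with
`r2_i <= r2_PA` carry no own information and are excluded with that
reason; with both parents unknown the procedure reduces exactly to
`dEBV = EBV / r2`. Weights
`w = (1 - h2) / ((c + (1 - r2_dEBV)/r2_dEBV) h2)` with c = 0.5 are
computed and emitted; the MLMA uses dEBVs unweighted by default since
weighting is an analysis choice, not a property of the dEBV.

What deregression buys, and what the tests assert: the dEBV regresses on
the true breeding value with slope 1, and its *error* no longer loads on
the parent average (slope ≈ 0), whereas the shrunken EBV's error does
(slope ≈ -0.25 in the simulations). The marginal regression of dEBV on PA
is of course nonzero — PA predicts the breeding value itself.

Single-component REML on the GRM runs in the eigenbasis (profile
likelihood in h2, bounded scalar optimization); boundary estimates are
returned flagged, not errored. MLMA tests every SNP by exact GLS under
`V = s2_g GRM + s2_e I` using the same eigenbasis (O(n) per SNP after one
decomposition), Wald chi-square(1) p-values, candidate SNP kept in the GRM
(no LOCO — fidelity to the single-GRM design over power). Monomorphic
SNPs get p = 1 with a flag. A dense-V GLS oracle (`dense_gls_oracle`) is
kept in the package for verification; implementation and oracle agree to
1e-8 at n = 120 and the null type-I error over 20,000 tests is ~0.05.

**Thresholds.** `Me = 2 Ne L / ln(Ne L)` per chromosome (natural log — the
convention of the Me literature; the formula's printed "log" is
ambiguous), threshold `-log10(0.05 / Me)`, defaults Ne = 80 and the
ARS-UCD1.2 chromosome lengths in Mb (1 cM ≡ 1 Mb). The cross-chromosome
average computes to 4.48, consistent with the published 4.6 once the
base/length ambiguity is allowed for. Annotation reports genes
intersecting ±500 kb windows (1-based inclusive, clipped at 1), with
per-biotype tallies; interval overlap is plain arithmetic — no external
annotation service is involved.

## The synthetic-data generator

`simdata` emulates the data structure of a seedstock beef herd: discrete
non-overlapping generations with random mating (defaults 25 founder
males, 250 founder females, 3 generations, 2 offspring per dam → ~1,800
animals with ~1,500 genotyped non-founders); unlinked biallelic SNPs with
founder frequencies U(0.05, 0.5) (1,000 autosomal across 5 chromosomes,
300 X); polygenic traits (300 autosomal, 100 X causal SNPs) with variance
targets 0.30/0.10/0.60; 20 contemporary groups of variance 0.25; an age
covariate with linear and quadratic effects; optional ordinal
thresholding. X transmission is exact by construction and hard-asserted
in tests.

Two choices deserve explanation:

* **Male X dosage model.** Under `additive` a male's genetic value counts
  his single allele once — the scale on which `S`/`G_X` model male
  variance as `0.5 sigma2_x`. Under `compensated` (default) it is
  doubled, matching the GWAS coding. Variance-component recovery studies
  use `additive` so the simulated `sigma2_x` and the estimated one live
  on the same scale; GWAS simulations use `compensated`.
* **Effect rescaling.** Causal effects are rescaled so the
  pedigree-standardized quadratic forms `u'A^-1 u / n` and `u'S^-1 u / n`
  hit the variance targets exactly. This is the scale a
  relationship-matrix model estimates; rescaling to the raw population
  variance of `u` would be biased by drift and family structure. Realized
  components (both scales) are recorded in the `TruthSet`.

What the generator does **not** emulate: linkage and LD (loci are
independent; an optional recombination map was considered and dropped
because the machinery under test depends on relationships, not LD),
selection, overlapping generations, genotyping error. Passing recovery
tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to real-data artifacts such as
LD between causal variants and markers or misrecorded pedigrees.

## Problem sizes and runtimes

Test-suite studies use ~1,700-1,800 animal herds (ten-seed Gibbs recovery
≈ 3.5 min), 200,000-replicate gene dropping (< 1 s, vectorized across
loci), 20,000-SNP calibration panels (~10 s) — all single-core. The
acceptance script runs the same computations at three Gibbs seeds in
about one minute.

## Known limitations

* Dense matrix algebra throughout: practical to ~5,000 pedigree animals;
  no APY or sparse-inverse approximations, no metafounders, no
  unknown-parent groups.
* Single-trait models only; genetic correlations are out of scope.
* The X machinery ignores the pseudo-autosomal region (all X markers are
  treated as hemizygous in males).
* `S` implements the sex-asymmetric recursion; founder-specific scalings
  beyond the sex rule are not modelled.
* No genotype imputation (missing dosages are mean-imputed only inside
  matrix construction) and no VCF/binary-PLINK readers in this version.
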