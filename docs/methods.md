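# Methods

`rrsgs` re-creates, end to end and with known ground truth, the
cross-generational genomic-selection workflow of a reciprocal recurrent
selection (RRS) program for interspecific *Eucalyptus* hybrids: two pure
species are improved for the performance of their hybrid, prediction
models are trained on one generation (G1) and validated against the
pedigree-based values of the next (G2) at harvest age. This note records
the models, the generator that stands in for the field data, the numerical
choices, and the limits of what the synthetic results demonstrate.

## Genetic evaluation models

All evaluations are univariate linear mixed models
`y = Xb + Σ_k Z_k u_k + e`, `u_k ~ N(0, σ²_k K_k)`, `e ~ N(0, σ²_e I)`.

**Pedigree BLUP (ABLUP).** Response: age-adjusted stem volume or MAI.
Fixed: trial (and optionally block-in-trial contrasts). Random: blocks
within trials (identity covariance), additive genetic effects with
Wright's numerator relationship matrix `A`, and optionally dominance
effects with the pedigree dominance matrix `D`. `A` is built by the
tabular recursion (`a_ii = 1 + a_{sd}/2`), its inverse by Henderson's
rules with inbreeding through the Mendelian-sampling variances
`d_i = 1/2 − (F_s + F_d)/4`. `D` uses the classical non-inbred formula
`d_ij = (a_{s(i)s(j)}a_{d(i)d(j)} + a_{s(i)d(j)}a_{d(i)s(j)})/4`;
inbreeding is ignored in `D`, consistent with the outbred polymix family
structure the generator produces.

**Genomic BLUP (GBLUP / GBLUP+D).** Two-stage design: the response is the
vector of EBVs (additive) or EGVs (additive + dominance deviation) from a
prior ABLUP fit, with an overall mean as the only fixed effect. The
additive genomic matrix is the per-locus-standardized form
`G_A = WW'/M`, `w_ij = (x_ij − 2p_j)/√(2p_j q_j)`; the dominance matrix
codes heterozygotes `1 − 2pq` and homozygotes `−2pq` and scales by
`2Σ p_j q_j (1 − 2p_j q_j)`. Allele frequencies are computed from the
supplied genotyped set.

**Single-step BLUP (HBLUP).** The additive covariance is the blended
matrix `H` that keeps pedigree expectations for ungenotyped trees and
replaces the genotyped block with realized genomic relationships:

    H11 = A11 + A12 A22⁻¹ (G_A − A22) A22⁻¹ A21
    H12 = A12 A22⁻¹ G_A,  H22 = G_A

and `H⁻¹ = A⁻¹ + [0 0; 0 τ(G_A⁻¹ − A22⁻¹)]` with τ = 1 by default. No
blending of `G_A` toward `A22` is applied by default; a ridge `εI`
(default ε = 1e−6) is added to `G_A` only inside the inversion, because
the centered `G_A` is exactly singular (`G_A·1 = 0`). Note that `‖H⁻¹‖`
scales like `1/ε`, so absolute comparisons of `H⁻¹` against a dense
inverse are conditioning-limited at small ridges; the validation
experiment uses ε = 1e−5 identically on both sides for that reason.

**REML.** With a single genetic term the restricted likelihood is
profiled exactly: one eigendecomposition of `ZKZ'` diagonalizes `V`, the
ratio `γ = σ²_g/σ²_e` is optimized by bounded scalar search on `log γ`
(range e±12) and `σ²_e` has a closed form. When the likelihood is flat in
`γ` (e.g. `K = I`, where the split is unidentifiable) the tie is broken
toward the boundary — the most parsimonious genetic variance. Models with
several random terms use average-information REML on the marginal
covariance with step-halving, an EM-style scaled-gradient fallback when
the AI step leaves the parameter space, projection to ≥1e−10, and
convergence at `|Δ logL| < 1e−8`. Non-convergence is flagged on the
returned fit, never silent.

**Solutions and reliabilities.** BLUE/BLUP solutions and prediction error
variances are computed in the marginal (V-based) form —
`û_k = σ²_k K_k Z_k' V⁻¹(y − Xβ̂)`, `PEV = σ²_k K − σ²_k² K Z' P Z K` —
which is algebraically identical to Henderson's mixed-model equations but
requires no `K⁻¹`, hence tolerates the singular `G_A`. Reliabilities are
`r²_i = 1 − PEV_i/σ²_a`, clipped to [0, 1]; de-regression is
`dEBV = EBV/r²` with parent-average effects deliberately not removed.

**Heritability.** `h²_a = σ²_a/(σ²_a + σ²_d + σ²_e)` and
`h²_g = (σ²_a + σ²_d)/(σ²_a + σ²_d + σ²_e)`; block and trial variances
are excluded from the denominator. This convention reproduces the
published variance-component worked examples exactly.

## Genotype QC

SNP filters are inclusive thresholds on call rate (default ≥ 0.90) and
MAF (≥ 0.01); the sample filter keeps call rate ≥ 0.85. Missing calls are
imputed deterministically from the expected B-allele dosage `2p`: 0 when
`2p < 2/3`, 1 when `2/3 ≤ 2p < 4/3`, 2 when `2p ≥ 4/3` — both boundaries
left-closed. Imputation is idempotent and column-order independent.
Platform merging intersects SNP panels (first platform's order) and
recomputes frequencies on the pooled calls. Parentage verification counts
opposing homozygotes (0 vs 2) per genotyped parent–offspring pair;
gene-dropped data give exactly zero conflicts, so any positive rate flags
a pedigree or genotyping error (default flag threshold 1 %).

## Growth-curve age adjustment

Trials are measured at heterogeneous ages near 3 and 6 years; volumes are
harmonized to the reference ages 2.76 and 5.40 (the "age 3"/"age 6"
labels) by per-tree random-regression curves:

| model     | curve                      | linearized regression        |
|-----------|----------------------------|------------------------------|
| linear    | y = b0 + b1·x              | y ~ x                        |
| logistic1 | y = 1/(1 + b0·e^{b1·x})    | log(1/y − 1) ~ x             |
| logistic2 | y = 1/(1 + (x/b0)^{b1})    | log(1/y − 1) ~ log x         |
| gompertz  | y = exp(−e^{b0 − b1·x})    | log(−log y) ~ x              |

The logistic-1 sign convention follows the printed curve: growth requires
`b0 > 0, b1 < 0`. Bounded models operate on volumes scaled into (0,1) by
a per-trial constant (default 1.2 × the trial maximum). With two
measurements per tree the per-tree fit is the exact interpolating solve,
so adjustment at a measured age is a no-op; an optional empirical-Bayes
shrinkage pulls linearized coefficients toward trial means (method-of-
moments between-tree variance; with two points there is no within-tree
replicate, so a mild 10 % proxy is used). Back-transform(linearize(y))
round-trips to 1e−10 on the valid domains. Stem volume uses the
form-factor formula `v = π/4 (dbh/100)² · height · 0.45` and
`MAI = v · 1200 / age` (m³ ha⁻¹ yr⁻¹).

Model comparison is residual variance against a known target at the
reference ages versus carrying the raw measurement to the nearest
reference age; on data generated from logistic-1 curves the generating
model ranks first and all models beat the unadjusted baseline. This
required the generating trees to be genuine members of the fitted family
(per-tree curve parameters, shared asymptote scale): trees with
individual asymptotes are *not* a logistic-1 subfamily once scaled by a
common constant.

## The synthetic breeding program

The generator emulates the study design with full ground truth:

* **G0**: two founder species (default 30 + 30). Per-SNP ancestral
  frequencies `p0 ~ U(0.05, 0.95)` diverge by a Balding–Nichols model,
  `p_s ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F)` with `F = fst` (default 0.20, a
  plausible divergence for two eucalypt species); genotypes are
  Hardy–Weinberg within species. The paper gives no founder genetic
  model; this is the field-standard choice.
* **G1**: per species, maternal half-sib polymix families (true sire
  drawn per offspring from the species pollen pool, recorded internally
  but exported as unknown in the nominal pedigree), plus reciprocal
  interspecific hybrid full-sib families.
* **G2**: hybrid full-sib families from G1 pure-species parents selected
  on a single noisy own-phenotype record (genotypic value + environmental
  noise). Selection on *true* breeding values was tried first and
  rejected: at desk scale it is so accurate that G2 between-family
  variance collapses and the G2 REML fit degenerates to the boundary,
  which contradicts every field observation of such trials.
* **Genotypes** descend by gene dropping at unlinked loci (each parent
  transmits the B allele with probability dosage/2, independently per
  locus). Opposing-homozygote conflicts are impossible by construction.
  Linkage is irrelevant to every estimator implemented, so no
  recombination map is simulated.
* **Trait**: per-SNP Gaussian additive effects and (optionally)
  heterozygote dominance deviations, rescaled so the *within-species*
  founder variances hit `σ²_a : σ²_d : σ²_e` ratios implied by the target
  narrow-sense heritability (default 0.40) and dominance fraction
  (default 0.15) given the residual variance (default 0.010 m⁶).
  Within-species scaling matters: pooled-founder scaling counts the
  between-species mean difference, which trial-stratified REML never
  sees, and biases recovered h² downward by ~25 %. With residual variance
  zero the effects keep the additive:dominance ratio on a fixed unit
  scale (heritability is then trivially 1).
* **Phenotypes**: `vol(x) = s(x)·(μ + a + d) + block + s(x)·ε` with a
  shared logistic factor `s(x) = 1/(1 + 17.8 e^{−0.7368x})` (≈0.30 at age
  2.76, ≈0.75 at 5.40), block effects `N(0, 0.002)` per trial×block, and
  residual sd scaled by `s(x)` so the narrow-sense heritability equals
  the target at every measurement age. Ages carry a per-trial jitter
  (±0.15 yr) to emulate heterogeneous measurement campaigns. Volumes are
  floored at 1 mm³.

Default scale is desk scale (hundreds to a few thousand trees, 2,000–5,000
SNPs); the study's ~17,000 trees × 16,000 SNPs are reachable through the
same configuration.

## The cross-generation experiment

The pipeline trains GBLUP/GBLUP+D/HBLUP on combinations of three G1
cohorts — hybrids (H), the direct parents of the G2 families (P), and
pure-species "uncles" (U) — and validates against the G2 candidates'
pedigree values at harvest age. Two timing choices mirror the study:
training EBVs/EGVs are estimated from G1 records only (all that exists
when candidates are seedlings), while harvest-age reference values come
from the joint multi-trial evaluation of G1+G2 records linked by
pedigree. The joint reference is what carries the parent-average
information that makes parents-only training strong; validating against a
G2-trial-only fit systematically understates every training set.

For the relatedness-ordering experiment the U cohort is restricted to
trees sharing no founder ancestor with the candidates
(`uncles_unrelated`). In the study the analogous cohort were actual
relatives yet predicted poorly, for reasons this generator cannot express
(pure-species vs hybrid genetic correlation below one, environment): here
the trait transfers perfectly between species contexts, so only genuine
pedigree unrelatedness reproduces the qualitative contrast.

Assessment metrics: realized predictive ability (Pearson correlation of
id-aligned genomic vs reference values), bias `1 − b` with `b` the OLS
slope of reference on genomic (`b > 1` = underestimation), Spearman rank
concordance, and top-k coincidence with `k = round(p·n)` (minimum 1; this
rounding reproduces the published 197 × 2.5 % → 5 mapping) and
deterministic tie-breaking by id. Cross-validation partitions ids into
near-equal folds, stratified by family by default so full sibs never
straddle the split; leave-one-out is rejected (per-fold correlation
undefined on one point).

## Problem sizes used in the validation runs

Chosen as the package's study-scale defaults: heritability recovery uses
10 replicate programs per target (two species × 50 polymix families × 20
offspring = 2,000 phenotyped trees each); sib-pair genomic relationship
checks use 5,000 SNPs and 25 full-sib plus 25 half-sib families of 8;
the relatedness ordering uses 10 replicate programs with 30 founders per
species, 30 × 25 pure-species families, 14 G2 families of 30 with half
the candidates genotyped at ~1,000 SNPs; the growth-model comparison
uses 500 trees. Oracle equivalences run on 50–200 individuals.

## Known limitations

* Unlinked loci, no mutation, at most three generations, no
  genotype-by-environment interaction or enviromics.
* The trait is genetically identical in pure-species and hybrid contexts;
  consequences for interpreting the uncle cohorts are discussed above.
* `D` ignores inbreeding; `H` is additive-only (no genomic dominance in
  the single-step blend); no metafounders or unknown-parent groups.
* PEV comes from dense inversion — appropriate at desk scale, not for
  national-evaluation sizes.
* Heterogeneous residual/block variances across trials are out of scope;
  the homogeneous model is the one the analysis standardizes on.
* Passing synthetic-data checks shows the estimators are correct under
  the generator's assumptions; it does not certify performance on real
  field data with pedigree errors, spatial trends, or selective
  measurement.
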