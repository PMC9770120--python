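# Methods

This note records the models behind each module, the defaults that matter,
the numerical choices, and what the synthetic cohorts do and do not emulate.

## Genotypes, keys, and harmonization

Variants are keyed by `(chrom, pos, ref, alt)` with 1-based positions (VCF
convention); rsIDs are carried but never used for identity, because
sequencing data is positionally keyed and rsID annotation is incomplete.
Genotypes are effect-allele dosage matrices in `{0,1,2}` with NaN for
missing calls. No liftover is attempted: all inputs must share a genome
build.

Scoring files are matched to genotypes by `(chrom, pos)` (falling back to
rsID when a record has no position), then oriented by allele comparison:
effect allele = ALT keeps the dosage, effect allele = REF uses `2 − d`, and
the same rules are retried on strand-complemented alleles. Unmatched
records are dropped and counted — with sequencing data the sensible default,
since imputing scoring variants absent from the call set would require a
reference panel. Strand-ambiguous (A/T, C/G) records are kept and matched
positionally by default, the appropriate choice when scores are applied to
same-build sequencing data where strand flips cannot arise; `drop_ambiguous`
is available for array-sourced inputs. Missing dosages at scoring time are
imputed with twice the cohort effect-allele frequency (the usual PRS
convention); `zero` and `error` policies are provided.

## PRS standardization and the ensemble

Scores are z-standardized with the n−1 denominator, either over the whole
cohort or within each ancestry stratum. Per-ancestry standardization
removes ancestry-driven location/scale differences in the raw score before
any case-control comparison; a zero-variance stratum is an error naming the
stratum rather than a silent NaN.

The ensemble score is, by default, the unweighted mean of the component
z-scores, re-standardized. This is the minimal construction that profits
from components carrying partly orthogonal information; it requires no
outcome data and cannot overfit. A `stacked` mode replaces the mean with
the out-of-fold linear predictor of a logistic regression of case status on
the component z-scores (5 stratified folds, seed 42), for when a
data-adaptive combination is wanted. Underperforming components are never
dropped automatically — that is an analyst decision.

## Association and discrimination

Logistic regressions are full maximum likelihood (statsmodels Newton
solver, tolerance 1e-8, at most 100 iterations) with Wald z tests and CIs.
Non-convergence, rank-deficient designs, and (quasi-)separation raise
errors with diagnostics instead of returning unstable estimates; the
separation heuristic treats |β| > 30 as divergence.

`OR_1sd` is `exp(β_PRS)` from `status ~ z + covariates`; the default
covariate set mirrors a standard cohort adjustment (age, sex, BMI, all
principal components), each element optional. The AUC reported with it is
the crude discrimination of the score alone; when covariates strongly
associate with status (e.g. a large case-control age gap), the full-model
AUC is much higher than the score's own — which is why the age/sex-matched
sub-cohort view exists.

AUC uses midranks (ties count one half), variance and the paired
two-correlated-AUCs test use DeLong's structural components `V10`/`V01`.
Identical score vectors short-circuit to z=0, p=1.

Deciles are assigned by count-balanced quantile cut on the z-scores with
stable-order tie-breaking, so bin sizes differ by at most one sample.
`OR_vsAll` (decile 10 vs the rest) and `OR_vsLowest` (decile 10 vs decile
1) are crude 2×2 Woolf estimates — the headline choice, since decile ORs
are descriptive risk-stratification quantities — with covariate-adjusted
logistic versions emitted alongside when covariates are supplied. A zero
cell triggers the Haldane-Anscombe +0.5 correction, and the result is
flagged as corrected.

Control matching is greedy: cases in input order each draw their
nearest-age unused control within the exact sex stratum (ratio 1:1 by
default). Greedy nearest-age matching is deterministic and transparent;
optimal matching would change little at a 6:1 control surplus. A shortfall
of controls is reported, never fatal.

## Post-GWAS machinery

λ is the median association χ² over 0.4549, computed from p-values via the
1-df quantile transform. Clumping is greedy and distance-only (default
window 300 kb, matching the replication window): repeatedly take the
lowest-p unassigned variant as a lead and absorb same-chromosome variants
within the window. LD-aware clumping would need an LD reference, which the
package deliberately does not manage; with a precomputed LD table the
greedy loop accepts an r² filter. Exact locus counts from LD-based
clumping are therefore not reproduced.

Window replication calls a lead replicated when it lies within 300 kb of a
catalog variant, counting distinct catalog locus names. Exact-match
replication intersects on `(chrom, pos)` and applies Bonferroni `α/n` over
the overlap plus a secondary 0.01 cutoff.

Fixed-effect meta-analysis weights by inverse squared SE; the first study
carrying a variant fixes the effect-allele orientation and later studies
are sign-flipped when their alleles are swapped. Strand-ambiguous allele
mismatches are errors, not guesses. Heterogeneity is summarized only as
the spread of study betas (`HET_RANGE`); I²/Cochran Q are out of scope.

## Rare-variant burden

MAF here is the alternate/effect-allele frequency over non-missing calls —
never minor-allele folded, so CCR direction is preserved. The pseudo-CCR
denominator is the minimum nonzero control MAF over the analyzed variant
set; in a cohort with 6009 controls a control singleton gives
`1/12018 ≈ 8.32e-5`, so case allele counts of 2, 3, 4 produce the
pseudo-CCR family 11.85 / 17.78 / 23.70. Variants with zero case MAF are
ignored (sentinel), per the substitution rule. "Rare" defaults to MAF ≤
0.01 and is configurable.

Gene-level CCR is emitted two ways: the ratio of summed case/control
allele frequencies (default headline) and the ratio of mean per-variant
MAFs. Carriers hold at least one qualifying alternate allele in the gene;
qualifying means high impact *or* ClinVar P/LP, under the rare-MAF cap.
The collapsing test is the two-sided Fisher exact on the carrier table.

The variance-component score test uses
`Q = Σ_j w_j² (g_j'(y − μ̂₀))²` with the null model's fitted probabilities
and Beta(1, 25) MAF weights by default. The null distribution — a weighted
sum of 1-df chi-squares with weights the eigenvalues of the
covariate-projected kernel — is evaluated by Liu's moment-matching
approximation, exact in the single-eigenvalue case. Davies' exact
inversion is not implemented; the p-value is flagged approximate in the
docstring and its type-I error is verified by simulation in the test
suite. Missing genotypes enter the test as homozygous reference.

## Haplotype EM

For k ≤ 10 SNVs, each sample's unphased genotype is expanded into its
compatible unordered haplotype pairs (missing sites marginalized over both
alleles). The E-step weights pairs by `2^{h1≠h2} p_{h1} p_{h2}` (HWE within
the estimation group); the M-step re-estimates frequencies from expected
counts. Initialization is uniform over observed-compatible haplotypes with
lexicographic tie-breaking, so runs are deterministic; convergence is a
max frequency change below 1e-8 (cap 1000 iterations, warning on
non-convergence). The log-likelihood is non-decreasing by construction and
asserted in tests. Samples are grouped by genotype vector first, so cost
scales with distinct genotypes, not cohort size.

The case-control test avoids a phased-data requirement: status is
regressed on each sample's posterior expected copies of the target
haplotype computed under pooled-cohort frequencies, giving a score-type
1-df test (optionally covariate-adjusted). Per-group frequencies reported
alongside come from independent per-group EM runs. No omnibus
all-haplotypes test is provided.

## Power

The per-allele (log-additive) power calculation converts the control
frequency p₀ and odds ratio to the case frequency
`p₁ = p₀·OR/(1 + p₀(OR−1))` and applies the two-proportion normal
approximation over 2n alleles per group, two-sided. Both rejection tails
are included (the wrong-direction tail matters only near OR=1, making the
null value exactly α). With 1014/6009 and OR=1.2 at MAF 0.4 this gives
0.962 and 0.876 at α=0.05 and 0.01. A Monte-Carlo companion simulates
binomial allele-count tables and applies the same test, with a binomial CI
on the rejection rate.

## The synthetic cohorts

`SimConfig` defaults define the study conditions: a 1:7-scaled cohort of
145 cases / 860 controls (the full 1014/6009 behind `full_scale()`), six
ancestry strata with the observed mixing proportions (55.65% / 31.55% /
4.9% / 4.1% / 2.2% / 1.6%), Balding-Nichols differentiation at Fst 0.05,
a true polygenic effect of ln(1.8) per liability SD, and age/sex effects
(1.0 per age SD, 0.55 for male sex) that reproduce the hospital-case vs
biobank-control imbalance — cases emerge older and more often male from
the disease model itself rather than by construction. The logistic
intercept is tuned by bisection so the *expected* case fraction matches
the configured one to within 0.5% (the realized count fluctuates
binomially, ~1% SD at this size, so an exact realized fraction is not a
meaningful contract). Principal components are computed from the centered
dosage matrix by SVD.

Rare variants are planted as heterozygous carriers with per-gene group
rates mirroring the lipid-gene burden excess (LDLR at 9/1014 vs 9/6009,
APOB/ANGPTL4 similar, PCSK9 milder), plus a dedicated control-singleton
variant so the pseudo-CCR denominator is always defined. The haplotype
block draws two haplotypes per sample i.i.d. from a four-haplotype pool
(protective CCAAATT at 0.17/0.213 in cases/controls) and discards phase.

What the generator does **not** emulate: linkage disequilibrium among the
common variants (they are independent given ancestry), admixture tracts,
genotyping error, relatedness, imputation artifacts, and realistic
site-frequency spectra. Passing tests therefore demonstrate correctness of
the statistical machinery under its stated assumptions — not robustness to
LD-induced redundancy in scoring files or to cryptic relatedness, which
real analyses must address upstream.

## Problem sizes in the test suite

Stochastic checks run at sizes chosen to make their Monte-Carlo error
small relative to the tested bands: OR recovery at the full cohort size
(n=7023, 100 replicates), DeLong calibration at n=300 over 1000 null
replicates, variance-component calibration at n=1000 over 500 replicates,
EM recovery at n=5000 per group, ensemble comparisons at n=2000 over 50
replicates. Oracle-equivalence checks (pair-counting AUC, WLS pooling,
exhaustive clumping) are exact to 1e-12.

## Known limitations

* No mixed-model association (SAIGE-style) — per-variant association is
  plain covariate-adjusted logistic regression.
* Liu's approximation can be slightly anticonservative in the extreme tail
  of the variance-component test.
* The EM haplotype machinery is for small SNV sets (2^k state space), not
  chromosome-scale phasing.
* Decile ORs with zero cells are continuity-corrected; with very small
  cohorts the correction dominates.
* The published ensemble construction is not uniquely determined by its
  description; the mean-of-z and stacked modes bracket the reasonable
  choices but neither is guaranteed to match any specific published score
  exactly.
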