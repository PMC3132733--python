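# Methods

## Problem and model

`pathgwas` tests whether a pre-specified pathway (gene set) is collectively
associated with a binary case-control phenotype, using genome-wide SNP data.
Single-marker scans often miss pathways whose member variants each
contribute weakly; aggregating association evidence over a functionally
related gene set can recover that signal. The procedure:

1. **SNP QC.** Per SNP, in the total sample: call rate, minor allele
   frequency (MAF) among non-missing genotypes, and the exact conditional
   Hardy-Weinberg equilibrium (HWE) test. A SNP is kept iff
   call rate ≥ 0.90, HWE p ≥ 1e-7 and MAF ≥ 0.01 (boundary values pass —
   only strictly worse SNPs are discarded). SNPs whose labelled minor
   allele is the commoner one are recoded so "minor" is defined once, on
   the total sample, and reused everywhere.
2. **Per-SNP association.** Logistic regression
   `logit P(case) = b0 + β·dosage + b_age·age + b_sex·sex` with additive
   coding (dosage = minor-allele count 0/1/2), Wald z = β/ŝe, two-sided
   normal p, per-allele OR = exp(β) with 95% CI exp(β ∓ 1.959964·ŝe).
   Subjects missing the genotype are dropped for that SNP only.
3. **Genomic control.** Each p maps to its χ²₁ quantile;
   λ = median(χ²)/0.4549364. When λ > 1, statistics are deflated by λ and p
   recomputed; when λ ≤ 1 p-values are untouched.
4. **Gene statistic and ranking.** A gene is represented by its smallest
   surviving SNP p-value, ranked by r = −log₁₀(p_min) descending (a χ²₁
   quantile transform is available as an option). Genes with no surviving
   SNP drop out of the list.
5. **Enrichment score.** Walking the ranked list L (N genes), the running
   sum gains |r_j|^p / N_R at members of the set S (N_R = Σ_{S} |r|^p,
   weight exponent p = 1 by default) and loses 1/(N − N_S) at non-members.
   ES is the maximum positive deviation; the leading edge is the members
   of S at or before the first position attaining ES.
6. **Permutation null.** Case/control labels are permuted across subjects
   (genotypes and covariates stay attached to their subjects) and steps
   2, 4, 5 are fully recomputed per permutation (default K = 1,000).
   Nominal p = #(permuted ES ≥ observed ES)/K;
   NES = ES / mean(positive permuted ES).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_call_rate` | 0.90 | minimum fraction of non-missing calls per SNP |
| `hwe_p_floor` | 1e-7 | minimum exact HWE p (extreme-deviation filter) |
| `min_maf` | 0.01 | minimum minor allele frequency, total sample |
| `weight_p` | 1.0 | ES weight exponent; 0 gives the unweighted KS walk |
| `k_permutations` | 1000 | phenotype permutations for the null |
| `lambda_adjust` | on | λ-deflate reported per-SNP p when λ > 1 |

## Design choices

- **Exact HWE test, not chi-square.** The 1e-7 floor operates in the
  extreme tail at potentially tiny genotype counts, exactly where the
  chi-square approximation fails. The exact conditional test enumerates
  heterozygote counts (log-space, tie-tolerant to 1e-9 relative) and is
  validated against exact rational enumeration for every configuration
  with ≤ 30 subjects.
- **Ranking statistic.** −log₁₀(p_min) is positive, monotone in evidence,
  and weights extreme genes heavily — matching the intent of the weighted
  running sum. The χ²₁-quantile alternative (`stat="chi2"`) weights tails
  even more aggressively.
- **Positive deviation only.** ES is the maximum *positive* running-sum
  deviation, so depletion of a set from the top of the list is never
  reported as enrichment.
- **Tie rules.** Permuted ES equal to the observed ES count as at least as
  extreme (p can never be artificially small); tied p_min within a gene
  resolves to the lexicographically smaller SNP id; tied gene statistics
  rank by gene id ascending. All outputs are deterministic given a seed.
- **NES.** ES divided by the mean of positive permuted ES — the standard
  normalisation for a one-sided positive score. p = 0 is reported in
  formatted output as "<1/K".
- **Separation.** Fits with |β| > 12, non-convergence, or a singular
  information matrix are flagged and excluded from gene statistics rather
  than reported as unstable ORs (a per-allele OR of e¹² is never a
  credible estimate at these sample sizes).
- **λ interaction with enrichment.** Gene ranking uses raw p-values;
  λ-adjustment is a monotone transform, so it cannot change the ranking,
  and the permutation null already calibrates the pathway test. Both raw
  and λ-adjusted p appear in the per-SNP report.
- **Covariates under permutation.** Only the case/control label moves;
  age and sex stay with their subjects, preserving genotype-covariate
  structure.

## Numerical implementation

The permutation null refits every SNP's logistic model for every
permutation, so the scan is a vectorised Newton (IRLS) solver fitting all
SNPs simultaneously: the design differs across SNPs only in the dosage
column, so gradients and Hessians assemble from a few (SNPs × subjects) ×
(subjects × covariates) matrix products; converged SNPs leave the active
set. The batch solver agrees with a per-SNP statsmodels fit to ~1e-13 (see
`tests/test_association.py`); the permutation path relaxes the Newton step
tolerance to 1e-6, far below anything the permuted-ES ranking can resolve.
Linear predictors are clipped at ±30 and the Hessian carries a 1e-12
diagonal ridge for degenerate columns.

## The synthetic cohort generator

Because the pipeline's guarantees are statistical, validation runs on
simulated cohorts with known truth: biallelic SNPs drawn as
Binomial(2, MAF) per subject (HWE proportions), independent missingness,
age ~ Normal(67, 6.5) years and sex ~ Bernoulli(0.5) (defaults chosen to
resemble an elderly fracture case-control cohort), and disease status from
an additive logistic risk model with optional per-SNP per-allele log-odds
and optional age/sex effects (zero by default). Planted effects are placed
one SNP per causal gene inside a designated "truth" gene set. A
rejection-sampling mode yields fixed designs (e.g. 350 cases / 350
controls). Missing genotypes contribute their expectation 2·MAF to the
risk score (generation only; association drops those subjects per SNP).

What the generator does **not** emulate: linkage disequilibrium, haplotype
structure, population stratification/admixture, genotyping-batch artefacts,
and age/sex confounding unless explicitly configured. Passing tests
therefore demonstrate correctness and calibration of the statistics under
independent-SNP, homogeneous-population conditions — not robustness to LD
(which the phenotype permutation handles by construction, since genotype
correlation is preserved) or to stratification (which the λ diagnostic only
flags; height/weight-type covariates are out of scope).

## Validation scales

The statistical acceptance checks run at sizes chosen to give stable
Monte-Carlo estimates: CI coverage over 500 replicates (n = 600); type-I
error of the pathway test on one null cohort of 2,000 SNPs / 200 genes /
400 subjects with 100 gene sets at K = 200; power on 50 replicates of a
300-SNP / 100-gene genome with a 38-gene truth set (7 causal genes,
per-allele OR 1.6, MAF 0.3, 500/500 subjects) at K = 200; λ on 10,000
null-scanned SNPs. `scripts/acceptance.py` runs the full pipeline at
K = 1,000 on a 350/350 cohort with the same 38-gene / 7-causal truth
structure.

## Known limitations

- No LD-aware gene statistic: a gene's min-p is not corrected for its SNP
  count, so SNP-dense genes rank high more easily under the null; the
  phenotype permutation absorbs this into the null distribution, but the
  ranking itself is size-biased.
- The permutation test is exchangeable-labels based and assumes no
  structure linking phenotype to genotype other than the tested
  association (no relatedness, no stratification).
- Only biallelic autosomal-style SNPs; no VCF/BED binary formats in v1.
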