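# Methods

This note documents the models and procedures implemented in `prspop`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make runs reproducible.

## Variant QC and harmonization

QC is applied to the pooled target dataset (all populations together):
variants are removed at missingness > 2%, minor allele frequency < 0.01
(computed from non-missing dosages), or Hardy–Weinberg exact p < 1e-6.
The HWE test is the exact conditional test (Wigginton–Cutler–Abecasis):
conditioning on the observed allele counts, the probabilities of all
heterozygote configurations of matching parity are summed when at most the
observed configuration's probability. An exact test matters here because
the threshold sits 6 orders of magnitude into the tail, where the chi-square
approximation is unreliable. Monomorphic variants return p = 1 by
convention. Note that pooling differentiated populations induces a Wahlund
heterozygote deficit; at the sample sizes used here this stays far above
the 1e-6 threshold except for strongly differentiated SNPs, which is the
intended behaviour of a pooled filter.

Summary statistics are matched to genotypes by variant id and oriented to
the genotype's counted allele (a1): an (effect, other) pair equal to
(a2, a1) negates the effect; a pair matching after complementing both
alleles is strand-flipped first; anything irreconcilable is removed as
mismatched. A/T and C/G pairs cannot be strand-resolved and are dropped by
default (`ambiguous_policy="keep"` trusts the reported strand instead).
Odds ratios are log-transformed at ingest so a single signed effect flows
through the pipeline. Duplicate summary-statistic ids are removed entirely
(both copies), since neither copy can be trusted.

## LD: r², clumping, pruning

r² is the squared Pearson correlation of unphased genotype dosages
(composite LD), the convention of mainstream genotype tooling; missing
dosages are handled by pairwise-complete deletion and monomorphic vectors
yield an undefined (NaN) r² that downstream aggregation excludes.

Clumping is greedy and p-value ordered: candidates with p ≤ threshold are
sorted ascending by p (ties broken by chromosome then position); the best
remaining variant becomes an index SNP and removes all remaining candidates
on its chromosome within ±250 kb with r² > 0.1 against it. The retained set
is therefore mutually quasi-independent, and relaxing the p threshold can
only append to the retained set (candidates are processed in the same order),
which gives the monotone SNP counts of the sensitivity sweep
{5e-8, 1e-5, 1e-3, 0.05, 1}. Clump LD uses all samples pooled by default;
a sample subset can be supplied when a population-specific LD reference is
wanted.

Pruning (used before PCA) is association-agnostic: a left-to-right
positional scan per chromosome keeps a variant iff its r² with every
previously kept variant within 100 kb is ≤ 0.1.

## Unweighted PRS

The score is the risk-allele count: per clumped SNP the risk allele is the
effect allele when the harmonized effect is positive, otherwise the other
allele, and a sample's score sums risk-allele dosages over SNPs. This
equals sign-weighted dosage scoring up to the affine constant
2·#negative-effect SNPs; the count form keeps scores in [0, 2·n_snps].
SNPs with effect exactly 0 carry no direction and are excluded with a
warning. Missing dosages are mean-imputed per SNP from the observed
risk-allele dosages (`omit_rescale` rescales to the full SNP count
instead); mean imputation matches common scoring-tool behaviour and keeps
the score additive over disjoint SNP sets. Country means are standardized
across countries with the population (ddof = 0) variance — either
convention is defensible; one is fixed for reproducible outputs.

## Resampling inference

All empirical p-values use the +1/(N+1) correction, so p = 0 is never
reported, and a result is flagged significant when p ≤ 0.05 — at 100 null
sets this is exactly the "observed beyond the null's 95th percentile" rule.

* **Permutation p** (two-sided): prevalence is shuffled across countries
  1000 times; p counts permutations with |r| ≥ |observed|.
* **Random-SNP-set empirical p** (one-sided, greater): each null set draws
  as many SNPs as the observed clumped set, uniformly without replacement
  from the post-QC pool, assigns each SNP an independent fair-coin risk
  direction (a `minor`-allele-as-risk scheme is available), scores samples
  identically to the real PRS, and correlates country means with
  prevalence. Coin directions are the neutral choice when nothing is known
  about the null SNPs' direction of effect; random sets are not clumped by
  default (a clumped-null option exists) since independence constraints are
  not part of the minimal null description.
* **Conservation nulls**: the identical region-LD / mean-FST procedure is
  repeated on random SNP sets (at full scale 100 sets of 1000 SNPs). The LD
  test is one-sided greater (conserved = higher cross-population r²
  correlation), the FST test one-sided less (conserved = lower mean θ).

## FST estimation

Per-SNP differentiation uses the Weir & Cockerham (1984) two-population θ
from the a, b, c variance components with observed heterozygote
frequencies; the estimate can be slightly negative and is undefined
(excluded) when a SNP is monomorphic in both populations. The
conservation-test statistic is the *mean of per-SNP θ* ("average of
ratios"), matching the framing of a mean FST over a SNP set. For estimating
a genome-wide differentiation parameter the package provides the combined
multi-locus estimator (ratio of summed components), which W&C recommend for
aggregating loci: the per-SNP average is noticeably biased toward zero at
high differentiation (≈0.157 recovered at true F = 0.2 in a two-population
Balding–Nichols simulation, versus ≈0.20 for the combined estimator), so
recovery checks use the combined form while the conservation tests keep the
average-of-ratios statistic — the bias there is common to observed and null
sets and cancels from the rank-based empirical p.

## PCA

Variants in configurable exclusion intervals are dropped first; defaults
are the conventional GRCh37 MHC (chr6:25–34 Mb) and chromosome 8 inversion
(chr8:8–12 Mb) intervals, supplied as data rather than hard-coded. After
pruning, each variant is normalized by (d − 2p̂)/√(p̂(1−p̂)) with
p̂ = (1 + Σd)/(2 + 2n) — the posterior-smoothed frequency keeps the
denominator positive for near-monomorphic variants. Missing entries
contribute 0 after centering. Components come from an SVD of the
normalized matrix; eigenvalues are singular values squared over the variant
count, and each eigenvector's sign is fixed by forcing its
largest-magnitude variant loading positive, so coordinate files are
reproducible. The original smartPCA's iterative outlier removal is omitted.
Country-mean PC1/PC2 are correlated with country-mean PRS using
t-distribution p-values (n − 2 df).

## Synthetic generator

The generator produces the statistical structure the analysis consumes,
not demographic realism.

* **Differentiation**: Balding–Nichols — ancestral frequency per LD block
  from Uniform(0.1, 0.9), population frequency from
  Beta(p(1−F)/F, (1−p)(1−F)/F) per block and population. F = 0 returns the
  ancestral frequency exactly. Default per-population F values
  (0.02, 0.05, 0.08, 0.12, 0.16) span the range typical of within- and
  between-continental human differentiation.
* **LD**: blocks of 10 SNPs, 5 kb apart, blocks separated by 500 kb (beyond
  every window used, so blocks are independent). Within a block, haplotype
  alleles follow a first-order Markov chain whose conditionals reproduce
  the per-locus marginals and an exact adjacent correlation (default 0.8,
  so adjacent r² ≈ 0.64, decaying geometrically). Frequencies are anchored
  per block (one ancestral draw and one Balding–Nichols deviate per block,
  per-locus logit jitter sd 0.15): loci in strong LD necessarily have
  similar frequencies, and the chain can only reach its target correlation
  when marginals are close. A side effect worth knowing: pooled-sample r²
  slightly exceeds the within-population target because block frequencies
  covary across populations (a Wahlund-type inflation, present in real data
  too).
* **Architecture**: 20 causal SNPs (one per block) per disorder, direction
  ±1; causal risk-allele frequencies are shifted on the logit scale along a
  linear population gradient (strength 0.5), so expected country-mean PRS
  — recorded in the truth object as 2·Σ risk-allele frequencies — is
  ordered along the gradient up to Balding–Nichols noise.
* **Summary statistics**: causal SNPs get log-uniform p-values below 5e-8
  and effects encoding their true direction; the rest get Uniform(0, 1)
  p-values and coin directions. Effect alleles are reported as a1 or a2 at
  random and strand-flipped with probability 0.1 to exercise
  harmonization; allele pairs are drawn non-strand-ambiguous so the
  default drop policy does not silently remove causal SNPs (ambiguous-SNP
  handling is tested separately at the unit level).
* **Prevalence**: coupled mode sets
  prevalence_c = a + b·z_c + N(0, noise_sd), floored at 0, where z_c is the
  *standardized* true expected mean PRS — standardizing puts b (default 1
  percentage point per SD of true risk) and noise_sd (default 0.2) on a
  common scale whatever the causal count. Null mode is independent
  Gaussian noise around the intercept.
* **Missingness**: 1% of genotypes at random, enough to exercise missing
  handling without dominating QC.

What the generator does **not** emulate: admixture and migration clines,
realistic recombination-rate variation and long-range LD, sample-size
imbalance between countries, GWAS estimation noise correlated with allele
frequency, and ascertainment of genotyping arrays. Passing recovery and
calibration tests on this generator therefore demonstrates correctness of
the *statistical machinery* under the stated model, not robustness to every
property of real cohort data.

One interaction to be aware of when interpreting synthetic runs: because
causal risk-allele frequencies follow the population gradient, the
generator's PRS SNPs are *more* frequency-differentiated than random SNPs.
The FST conservation test on coupled-mode data consequently reports
empirical p near 1 — the synthetic risk loci are anti-conserved by
construction. When the tested SNPs are instead exchangeable with the pool
(no gradient, e.g. `gradient_strength=0` or random SNP sets), both
conservation tests calibrate at their nominal 5% rate, which is what the
calibration tests verify.

## Problem sizes and test design

The validation suite runs at desk scale, chosen so the full suite completes
in about a minute: the standard world is 5 populations × 100 samples ×
2,000 SNPs; estimator-recovery simulations use 10,000 SNPs at 500 samples
per population; null-calibration runs use 200 replicates with 19 null sets
(the smallest count at which p ≤ 0.05 has exactly 5% probability under
exchangeability) and proportionally reduced set sizes, since the full-scale
pool (1.6 M SNPs, 100 × 1000-SNP sets) is a property of the original data,
not of the method. Ordering-recovery assertions compare observed and true
country rankings only on pairs whose true separation exceeds four standard
errors of the observed means — pairs closer than sampling resolution carry
no recoverable ordering information.

## Known limitations

* Two-population FST only; hierarchical/multi-level FST is out of scope.
* Clumping and pruning are O(candidates × neighbours) dense-matrix
  computations — appropriate for ~10⁵–10⁶ variants at cohort sample sizes,
  but no attempt is made at out-of-core operation.
* The permutation test enumerates nothing: at very small country counts
  (n < 4) the permutation space is tiny and the p-value coarse (a warning
  is emitted).
* Prevalence is treated as known per country; measurement uncertainty in
  prevalence estimates is not propagated.
* The pipeline's re-entrancy is whole-run (config-hash match skips
  recomputation); per-stage caching is not implemented.
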